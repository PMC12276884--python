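import random

import dendropy
import numpy as np
import pytest

import sggm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(p=5, m=4, mean_ni=6, tau=0.1, seed=0, density=0.2):
    """Small simulated dataset + ground truth for solver tests."""
    gen = np.random.default_rng(seed)
    truth = sggm.generate_precision(p, density, gen)
    data, truth = sggm.simulate_dataset(
        truth, m=m, mean_ni=mean_ni,
        scenario={"kind": "homogeneous", "tau": tau}, rng=gen)
    return data, truth


def make_cross_sectional(p=6, n=40, seed=0, density=0.2):
    """One observation per subject: the independent-data special case."""
    gen = np.random.default_rng(seed)
    truth = sggm.generate_precision(p, density, gen)
    chol = np.linalg.cholesky(truth.sigma)
    blocks = [
        sggm.SubjectBlock(f"s{i}", [float(i)],
                          (chol @ gen.standard_normal(p)).reshape(1, -1))
        for i in range(n)
    ]
    return sggm.LongitudinalDataset(blocks), truth


def random_blocks(gen, m=3, p=3, max_ni=4):
    blocks = []
    for i in range(m):
        ni = int(gen.integers(1, max_ni + 1))
        t = np.sort(gen.uniform(0, 5, ni))
        while ni > 1 and np.min(np.diff(t)) < 1e-3:
            t = np.sort(gen.uniform(0, 5, ni))
        blocks.append(sggm.SubjectBlock(f"s{i}", t, gen.standard_normal((ni, p))))
    return blocks


def random_spd(gen, p):
    a = gen.standard_normal((p, p))
    return a @ a.T + p * np.eye(p)


def random_birth_death_tree(labels, seed):
    taxa = dendropy.TaxonNamespace(labels)
    return dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, taxon_namespace=taxa,
        num_extant_tips=len(labels), rng=random.Random(seed))
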