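# sggm — microbial interaction networks from longitudinal abundance data

`sggm` infers sparse microbial interaction networks from 16S-style
longitudinal abundance profiles in which subjects are sampled at
irregular times and each subject contributes only a handful of
observations — the setting where time-series and functional-data methods
do not apply, and where ignoring the within-subject correlation (as
cross-sectional pipelines such as SPIEC-EASI must) costs real power.

## The model

Transformed abundances of `p` taxa are centered Gaussian vectors sharing
a precision matrix `Ω`; the network is the off-diagonal support of `Ω`
(zero ⇔ conditional independence given all other taxa). Observations of
subject `i` at times `t_1 < … < t_{n_i}` are correlated with the
separable covariance

```
Cov(y_i) = Φ_i ⊗ Ω⁻¹,   Φ_i[j,k] = exp(−τ_i |t_j − t_k|),
```

where `τ_i` is the subject's correlation dampening rate. The package
fits the L1-penalized maximum likelihood network under three rate
models, each reducing to a graphical lasso on a rate-weighted scatter
matrix:

- **homogeneous** — one shared `τ` (block coordinate descent);
- **heterogeneous** — `τ_i ~ Exponential(α)` latent per subject
  (Monte-Carlo EM with a grid E-step);
- **covariate-adjusted** — `τ_i ~ Exponential(exp(αᵀx_i))` with
  per-subject covariates (EM with a convex BFGS M-step).

Penalty paths are scored by the extended BIC,
`EBIC(G) = −2 loglik + |G| log n + |G| log p / T` with `T = 2`. A
synthetic-data engine reproduces the benchmark simulation designs
(G-Wishart precision matrices at edge density 0.1, Poisson observation
schedules, heterogeneous sub-communities, left-censoring), and an
evaluation module provides TPR/FPR, path-ensemble ROC curves and the
pooled glasso / neighborhood-selection baselines. A permutation test
measures concordance between an estimated network and a phylogenetic
tree. See `docs/methods.md` for the full model account, including the
likelihood degeneracy that motivates the solvers' EBIC-guided early
stopping.

## Worked example

```python
import numpy as np
import sggm

rng = np.random.default_rng(7)

# a 30-taxon ground-truth network and 10 subjects' irregular series,
# each with its own dampening rate drawn around E[tau] = 0.018
truth = sggm.generate_precision(p=30, edge_density=0.1, rng=rng)
data, truth = sggm.simulate_dataset(
    truth, m=10, mean_ni=10,
    scenario={"kind": "heterogeneous", "alpha": 1 / 0.018}, rng=rng)

path = sggm.solution_path(data, "heterogeneous", n_lambdas=10,
                          lambda_min_ratio=0.02, rng=1)
best = path.select(T=2.0)
tpr, fpr = sggm.tpr_fpr(best.adjacency(), truth.adjacency)
print(f"selected lambda = {best.lam:.3f}")
print(f"edges = {best.n_edges}")
print(f"estimated mean dampening rate 1/alpha = {1/best.dampening.alpha:.4f}")
print(f"TPR = {tpr:.3f}, FPR = {fpr:.3f}")
```

Output:

```
selected lambda = 0.104
edges = 63
estimated mean dampening rate 1/alpha = 0.0327
TPR = 0.619, FPR = 0.094
```

The EBIC-selected network has 63 edges against 42 true ones, recovering
62% of the true interactions at a 9% false-positive rate, and the fitted
mean dampening rate 0.033 sits near the generative 0.018 — the data are
strongly autocorrelated (lag-one correlation ≈ 0.98 at unit spacing),
which is exactly the regime where the longitudinal likelihood pays off.

The same pipeline is available from the shell:

```
sggm simulate --scenario s4 --p 30 --m 10 --seed 7 --out-prefix sim
sggm path sim.data.tsv --model heterogeneous --seed 1 --out-prefix net
sggm evaluate net.adjacency.tsv --truth sim.true_adjacency.tsv
sggm permtest net.adjacency.tsv --tree tree.nwk --n-perm 5000 --seed 1
```

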