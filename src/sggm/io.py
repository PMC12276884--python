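"""Readers and writers for longitudinal tables, networks and fit reports.

Tables are plain TSV/CSV (delimiter inferred from the extension).  Long
format has columns ``subject_id, time, taxon, value``; wide format has
``subject_id, time`` followed by one column per taxon.  Taxon ordering is
deterministic: first appearance in the input.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import (
    EDGE_TOL,
    DataValidationError,
    LongitudinalDataset,
    SGGMFit,
    SubjectBlock,
    center_dataset,
)

__all__ = ["read_longitudinal", "write_longitudinal", "write_network",
           "read_adjacency", "read_covariates"]


def _sep(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_longitudinal(path, fmt: str = "long", center: bool = True
                      ) -> LongitudinalDataset:
    """Load a longitudinal abundance table.

    Values must already be on the (real-valued) transformed scale; raw
    counts go through :func:`sggm.phylo.alr_transform` instead.  Each
    taxon is centered to global mean zero unless ``center=False``.
    """
    df = pd.read_csv(path, sep=_sep(path))
    if fmt == "long":
        required = {"subject_id", "time", "taxon", "value"}
        if not required.issubset(df.columns):
            raise DataValidationError(
                f"long format needs columns {sorted(required)}; "
                f"found {list(df.columns)}")
        dup = df.duplicated(subset=["subject_id", "time", "taxon"])
        if dup.any():
            raise DataValidationError("duplicate (subject, time, taxon) rows")
        taxa = list(pd.unique(df["taxon"]))
        wide = df.pivot_table(index=["subject_id", "time"], columns="taxon",
                              values="value", sort=False)
        if wide.isna().any().any():
            ragged = wide.columns[wide.isna().any()].tolist()
            raise DataValidationError(f"ragged taxa (missing values): {ragged}")
        wide = wide[taxa].reset_index()
    elif fmt == "wide":
        if not {"subject_id", "time"}.issubset(df.columns):
            raise DataValidationError("wide format needs subject_id and time columns")
        if df.duplicated(subset=["subject_id", "time"]).any():
            raise DataValidationError("duplicate (subject, time) rows")
        taxa = [c for c in df.columns if c not in ("subject_id", "time")]
        wide = df
    else:
        raise ValueError("fmt must be 'long' or 'wide'")

    vals = wide[taxa].to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise DataValidationError("non-numeric abundance values")
    blocks = []
    for sid, idx in wide.groupby("subject_id", sort=False).indices.items():
        idx = np.asarray(idx)
        t = wide["time"].to_numpy(dtype=float)[idx]
        order = np.argsort(t)
        blocks.append(SubjectBlock(str(sid), t[order],
                                   vals[idx][order].astype(float)))
    data = LongitudinalDataset(blocks, taxon_names=[str(t) for t in taxa])
    return center_dataset(data) if center else data


def write_longitudinal(data: LongitudinalDataset, path, fmt: str = "long") -> None:
    rows = []
    for blk in data.subjects:
        for t, row in zip(blk.times, blk.values):
            if fmt == "long":
                rows.extend({"subject_id": blk.subject_id, "time": t,
                             "taxon": name, "value": v}
                            for name, v in zip(data.taxon_names, row))
            else:
                rows.append({"subject_id": blk.subject_id, "time": t,
                             **dict(zip(data.taxon_names, row))})
    pd.DataFrame(rows).to_csv(path, sep=_sep(path), index=False)


def write_network(fit: SGGMFit, prefix, taxon_names: list[str],
                  threshold: float = EDGE_TOL, extras: Optional[dict] = None) -> dict:
    """Write ``<prefix>.edges.tsv``, ``<prefix>.adjacency.tsv`` and
    ``<prefix>.fit.json``; returns the paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    adj = fit.adjacency(threshold)
    iu = np.triu_indices_from(adj, k=1)
    edges = pd.DataFrame({
        "taxon_a": [taxon_names[i] for i, j in zip(*iu) if adj[i, j]],
        "taxon_b": [taxon_names[j] for i, j in zip(*iu) if adj[i, j]],
        "omega": [fit.omega[i, j] for i, j in zip(*iu) if adj[i, j]],
    })
    edges_path = prefix.with_suffix(".edges.tsv")
    edges.to_csv(edges_path, sep="\t", index=False)
    adj_path = prefix.with_suffix(".adjacency.tsv")
    pd.DataFrame(adj, index=taxon_names, columns=taxon_names).to_csv(adj_path, sep="\t")
    payload = fit.to_dict()
    payload.update(extras or {})
    json_path = prefix.with_suffix(".fit.json")
    json_path.write_text(json.dumps(payload, indent=2))
    return {"edges": edges_path, "adjacency": adj_path, "fit": json_path}


def read_adjacency(path) -> tuple[np.ndarray, list[str]]:
    """Read an adjacency TSV written by :func:`write_network`."""
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    return df.to_numpy(), [str(c) for c in df.columns]


def read_covariates(path, data: LongitudinalDataset) -> np.ndarray:
    """Per-subject covariate CSV (``subject_id`` + named columns) matched to
    the dataset's subject order; returns the design with intercept column."""
    df = pd.read_csv(path, sep=_sep(path))
    if "subject_id" not in df.columns:
        raise DataValidationError("covariate table needs a subject_id column")
    df = df.set_index(df["subject_id"].astype(str)).drop(columns=["subject_id"])
    missing = [b.subject_id for b in data.subjects if b.subject_id not in df.index]
    if missing:
        raise DataValidationError(f"covariates missing for subjects: {missing}")
    rows = df.loc[[b.subject_id for b in data.subjects]].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(data.subjects)), rows])
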