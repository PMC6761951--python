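"""Autosome-anchored modified-quantile normalization and FPKM.

Standard per-million FPKM scaling is dominated by a handful of very highly
expressed genes and, in a ZW design, by the asymmetry of Z-linked expression
between sexes. The library scale factor used here is therefore the sum of
counts of *autosomal* genes after discarding zero-count genes and the top 25%
most highly expressed of the remainder. That factor replaces the "per million
mapped reads" term of FPKM:

    FPKM[g, j] = count[g, j] * 1e9 / (length_g * F_j)

Genes without a chromosome assignment still receive FPKM values, but they
never enter the factor computation.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "UnusableLibraryError",
    "scale_factor",
    "scale_factors",
    "fpkm_matrix",
    "replicate_spearman",
    "group_means",
    "group_key",
]


class UnusableLibraryError(ValueError):
    """A library with no usable autosomal signal cannot be scaled."""


def scale_factor(
    counts: pd.Series, autosomal_gene_ids: Iterable[str], top_fraction: float = 0.25
) -> float:
    """Modified-quantile scale factor for one library.

    Restrict to autosomal genes, drop zero counts, remove the
    ``ceil(top_fraction * n_nonzero)`` highest-count genes (ties at the
    boundary broken by gene id, lexicographically smaller ids removed first
    among equals) and return the sum of the remaining counts.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must lie in (0, 1)")
    sub = counts.loc[list(autosomal_gene_ids)]
    nonzero = sub[sub > 0]
    n = len(nonzero)
    if n == 0:
        raise UnusableLibraryError("all autosomal counts are zero")
    if n < 4:
        raise UnusableLibraryError(f"only {n} nonzero autosomal genes; need >= 4")
    k = math.ceil(top_fraction * n)
    # deterministic tie-break: sort by (count desc, gene_id asc)
    frame = nonzero.rename("count").rename_axis("gene_id").reset_index()
    frame = frame.sort_values(["count", "gene_id"], ascending=[False, True])
    kept = frame.iloc[k:]
    return float(kept["count"].sum())


def scale_factors(
    counts: pd.DataFrame, autosomal_gene_ids: Iterable[str], top_fraction: float = 0.25
) -> pd.Series:
    """Per-sample modified-quantile factors for a genes x samples matrix."""
    ids = list(autosomal_gene_ids)
    return pd.Series(
        {s: scale_factor(counts[s], ids, top_fraction) for s in counts.columns},
        name="scale_factor",
    )


def fpkm_matrix(
    counts: pd.DataFrame, lengths: pd.Series, factors: pd.Series
) -> pd.DataFrame:
    """Renormalized FPKM: count * 1e9 / (length * factor)."""
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"missing gene lengths for {len(missing)} genes")
    missing_f = [s for s in counts.columns if s not in factors.index]
    if missing_f:
        raise ValueError(f"missing scale factors for samples: {missing_f}")
    if (factors.loc[counts.columns] <= 0).any():
        raise ValueError("scale factors must be positive")
    L = lengths.loc[counts.index].to_numpy(dtype=float)[:, None]
    F = factors.loc[counts.columns].to_numpy(dtype=float)[None, :]
    vals = counts.to_numpy(dtype=float) * 1e9 / (L * F)
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def replicate_spearman(
    fpkm: pd.DataFrame, metadata: pd.DataFrame, threshold: float = 0.8
) -> pd.DataFrame:
    """Pairwise Spearman correlation within each sex x stage replicate group.

    Returns one row per within-group sample pair with the tie-corrected rho
    and a low-correlation flag; constant columns yield a missing rho.
    """
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    rows = []
    for (stage, sex), grp in meta.groupby(["stage", "sex"], sort=False):
        ids = [s for s in grp.index if s in fpkm.columns]
        if len(ids) < 2:
            raise ValueError(f"group {stage}/{sex} has fewer than 2 replicates")
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                xa, xb = fpkm[a].to_numpy(), fpkm[b].to_numpy()
                if np.all(xa == xa[0]) or np.all(xb == xb[0]):
                    rho = np.nan
                else:
                    rho = float(stats.spearmanr(xa, xb).statistic)
                rows.append(
                    {
                        "stage": stage,
                        "sex": sex,
                        "sample_a": a,
                        "sample_b": b,
                        "rho": rho,
                        "low": bool(rho < threshold) if not np.isnan(rho) else True,
                    }
                )
    return pd.DataFrame(rows)


def group_key(stage: str, sex: str) -> str:
    """Column label used for sex x stage group means."""
    return f"{stage}_{sex}"


def group_means(fpkm: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean FPKM per gene over each sex x stage replicate group."""
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    out = {}
    for (stage, sex), grp in meta.groupby(["stage", "sex"], sort=False):
        ids = [s for s in grp.index if s in fpkm.columns]
        if not ids:
            raise ValueError(f"group {stage}/{sex} has no samples in the matrix")
        out[group_key(stage, sex)] = fpkm[ids].mean(axis=1)
    return pd.DataFrame(out)
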