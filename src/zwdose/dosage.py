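"""Dosage-compensation statistics.

Z:A and M:F ratios of median expression with percentile-bootstrap confidence
intervals and Mann-Whitney U tests, Kruskal-Wallis + Dunn per-chromosome
comparisons, the quartile breakdown of Z-linked expression, and the rerun
with sex-biased genes excluded.

Conventions:

* **Z:A** — per sex x stage, genes with zero group-mean FPKM dropped for
  that sex x stage, median of Z-linked over median of autosomal values.
* **M:F** — per chromosome class x stage, restricted to genes expressed
  (group-mean FPKM > 0) in *both* sexes of that stage.
* Bootstrap resamples genes independently in the numerator and denominator
  sets, at original sizes, and takes the 2.5/97.5 percentiles of the
  resampled ratio of medians (genes are the exchangeable units).
* The Mann-Whitney test uses exact enumeration when both groups have fewer
  than 8 observations and the tie-corrected, continuity-corrected normal
  approximation otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .normalize import group_key

__all__ = [
    "MWUResult",
    "RatioEstimate",
    "DosageResults",
    "mwu",
    "median_ratio_bootstrap",
    "za_analysis",
    "mf_analysis",
    "kruskal_dunn",
    "per_chromosome_tests",
    "quartile_analysis",
    "run_dosage",
    "exclude_and_rerun",
]


@dataclass(frozen=True)
class MWUResult:
    u: float
    p: float


@dataclass(frozen=True)
class RatioEstimate:
    """Ratio of medians with a percentile-bootstrap CI and MWU p-value."""

    point: float
    ci_low: float
    ci_high: float
    n_numerator: int
    n_denominator: int
    n_boot: int
    p_mwu: float
    u_mwu: float


def _exact_mwu(x: np.ndarray, y: np.ndarray) -> MWUResult:
    """Tie-aware exact two-sided Mann-Whitney test by subset-sum counting.

    Enumerates the permutation distribution of U over all C(N, n_x)
    relabelings via dynamic programming on doubled midranks (integers even
    under ties), so the p-value is exact including tied data.
    """
    nx, ny = len(x), len(y)
    N = nx + ny
    if N > 60:
        raise ValueError("exact Mann-Whitney enumeration limited to N <= 60")
    pooled = np.concatenate([x, y])
    ranks2 = np.rint(2.0 * stats.rankdata(pooled)).astype(np.int64)
    s_obs = int(ranks2[:nx].sum())
    total_sum = int(ranks2.sum())
    dp = np.zeros((nx + 1, total_sum + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for r in ranks2:
        for k in range(nx, 0, -1):
            dp[k, r:] += dp[k - 1, : total_sum + 1 - r]
    dist = dp[nx]
    total = dist.sum()
    sums = np.arange(total_sum + 1)
    p_le = dist[sums <= s_obs].sum() / total
    p_ge = dist[sums >= s_obs].sum() / total
    p = min(1.0, 2.0 * min(p_le, p_ge))
    u = s_obs / 2.0 - nx * (nx + 1) / 2.0
    return MWUResult(u=u, p=p)


def mwu(x: Sequence[float], y: Sequence[float], method: str = "auto") -> MWUResult:
    """Two-sided Mann-Whitney U test; U is reported for the first sample.

    ``method``: "exact" (enumeration, tie-aware), "asymptotic" (tie-corrected
    normal with continuity correction), or "auto" (exact when both groups
    have fewer than 8 observations).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError("method must be auto, exact or asymptotic")
    if method == "auto":
        method = "exact" if (len(x) < 8 and len(y) < 8) else "asymptotic"
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        # fully tied data: U at its null mean, no evidence either way
        return MWUResult(u=len(x) * len(y) / 2.0, p=1.0)
    if method == "exact":
        return _exact_mwu(x, y)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return MWUResult(u=float(res.statistic), p=float(min(res.pvalue, 1.0)))


def median_ratio_bootstrap(
    numerator: Sequence[float],
    denominator: Sequence[float],
    n_boot: int = 10000,
    ci: float = 0.95,
    rng: np.random.Generator | int | None = None,
) -> RatioEstimate:
    """Ratio of medians with an independent-resampling percentile CI.

    Each set is resampled with replacement at its original size, the ratio of
    medians recomputed, and the CI taken from the empirical percentiles of
    the ``n_boot`` resampled ratios. Deterministic given the rng/seed.
    """
    num = np.asarray(numerator, dtype=float)
    den = np.asarray(denominator, dtype=float)
    if len(num) == 0 or len(den) == 0:
        raise ValueError("both sets must be non-empty")
    med_den = float(np.median(den))
    if med_den <= 0:
        raise ValueError("denominator median must be positive")
    if not 0 < ci < 1:
        raise ValueError("ci must lie in (0, 1)")
    point = float(np.median(num)) / med_den
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    ratios = np.empty(n_boot, dtype=float)
    per_iter = len(num) + len(den)
    chunk = max(1, int(5_000_000 // max(per_iter, 1)))
    for start in range(0, n_boot, chunk):
        k = min(chunk, n_boot - start)
        bn = np.median(num[gen.integers(0, len(num), size=(k, len(num)))], axis=1)
        bd = np.median(den[gen.integers(0, len(den), size=(k, len(den)))], axis=1)
        ratios[start : start + k] = bn / np.where(bd > 0, bd, np.nan)
    lo, hi = np.nanquantile(ratios, [(1 - ci) / 2.0, 1 - (1 - ci) / 2.0])
    test = mwu(num, den, method="auto")
    return RatioEstimate(
        point=point,
        ci_low=float(lo),
        ci_high=float(hi),
        n_numerator=len(num),
        n_denominator=len(den),
        n_boot=n_boot,
        p_mwu=test.p,
        u_mwu=test.u,
    )


def _cells(group_means: pd.DataFrame) -> list[tuple[str, str]]:
    cells = []
    for col in group_means.columns:
        stage, sex = col.rsplit("_", 1)
        cells.append((stage, sex))
    return cells


def za_analysis(
    group_means: pd.DataFrame,
    chrom_class: pd.Series,
    n_boot: int = 10000,
    ci: float = 0.95,
    rng: np.random.Generator | int | None = None,
    exclude_by_stage: Mapping[str, Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Z:A median-expression ratio per sex x stage.

    Zero-expression genes are dropped separately for each sex x stage cell;
    unassigned genes are excluded throughout. ``exclude_by_stage`` optionally
    removes further genes (e.g. the sex-biased set) per stage.
    """
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    cls = chrom_class.reindex(group_means.index)
    rows = []
    for stage, sex in _cells(group_means):
        vals = group_means[group_key(stage, sex)]
        drop = set(exclude_by_stage.get(stage, ())) if exclude_by_stage else set()
        keep = ~vals.index.isin(drop)
        pos = (vals > 0) & keep
        z = vals[pos & (cls == "Z")].to_numpy()
        a = vals[pos & (cls == "A")].to_numpy()
        if len(z) == 0:
            raise ValueError(f"no expressed Z-linked genes in {stage}/{sex}")
        if len(a) == 0:
            raise ValueError(f"no expressed autosomal genes in {stage}/{sex}")
        est = median_ratio_bootstrap(z, a, n_boot=n_boot, ci=ci, rng=gen)
        rows.append(
            {
                "stage": stage,
                "sex": sex,
                "comparison": "Z:A",
                "point": est.point,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "n_numerator": est.n_numerator,
                "n_denominator": est.n_denominator,
                "p_mwu": est.p_mwu,
            }
        )
    return pd.DataFrame(rows)


def mf_analysis(
    group_means: pd.DataFrame,
    chrom_class: pd.Series,
    n_boot: int = 10000,
    ci: float = 0.95,
    rng: np.random.Generator | int | None = None,
    exclude_by_stage: Mapping[str, Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Male:female median-expression ratio per chromosome class x stage.

    Restricted to genes with positive group-mean expression in both sexes of
    the stage, separately for autosomal and Z-linked genes.
    """
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    cls = chrom_class.reindex(group_means.index)
    stages = list(dict.fromkeys(s for s, _ in _cells(group_means)))
    rows = []
    for stage in stages:
        m = group_means[group_key(stage, "M")]
        f = group_means[group_key(stage, "F")]
        drop = set(exclude_by_stage.get(stage, ())) if exclude_by_stage else set()
        both = (m > 0) & (f > 0) & ~group_means.index.isin(drop)
        for klass in ("A", "Z"):
            mask = both & (cls == klass)
            if mask.sum() == 0:
                raise ValueError(f"no genes expressed in both sexes for {stage}/{klass}")
            est = median_ratio_bootstrap(
                m[mask].to_numpy(), f[mask].to_numpy(), n_boot=n_boot, ci=ci, rng=gen
            )
            rows.append(
                {
                    "stage": stage,
                    "chrom_class": klass,
                    "comparison": "M:F",
                    "point": est.point,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "n_genes": int(mask.sum()),
                    "p_mwu": est.p_mwu,
                }
            )
    return pd.DataFrame(rows)


def kruskal_dunn(
    values: Sequence[float],
    groups: Sequence[str],
    focal: str = "Z",
    p_adjust: str | None = None,
) -> tuple[float, float, pd.DataFrame]:
    """Kruskal-Wallis H over all groups plus Dunn z for focal-vs-each-other.

    Groups with fewer than 2 observations are dropped. Dunn's z uses pooled
    midranks with the tie-corrected variance
    ``(N(N+1)/12 - sum(t^3 - t)/(12(N-1))) * (1/n_i + 1/n_j)``; p-values are
    two-sided normal, optionally BH- or Holm-adjusted across comparisons.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = [g for g in pd.unique(groups) if (groups == g).sum() >= 2]
    if len(labels) < 2:
        raise ValueError("need at least 2 groups with >= 2 observations")
    if focal not in labels:
        raise ValueError(f"focal group {focal!r} missing or too small")
    keep = np.isin(groups, labels)
    values, groups = values[keep], groups[keep]
    arrays = [values[groups == g] for g in labels]

    if np.all(values == values[0]):
        dunn = pd.DataFrame(
            {"group": [g for g in labels if g != focal]}
        ).assign(z=0.0, p=1.0)
        return 0.0, 1.0, dunn

    H, p_kw = stats.kruskal(*arrays)

    ranks = stats.rankdata(values)
    N = len(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_factor = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))
    mean_rank = {g: ranks[groups == g].mean() for g in labels}
    n_per = {g: int((groups == g).sum()) for g in labels}

    rows = []
    for g in labels:
        if g == focal:
            continue
        se = math.sqrt(var_factor * (1.0 / n_per[focal] + 1.0 / n_per[g]))
        z = (mean_rank[focal] - mean_rank[g]) / se if se > 0 else 0.0
        rows.append({"group": g, "z": z, "p": 2.0 * stats.norm.sf(abs(z))})
    dunn = pd.DataFrame(rows)
    if p_adjust is not None:
        method = {"bh": "fdr_bh", "holm": "holm"}[p_adjust]
        dunn["p_adj"] = multipletests(dunn["p"].to_numpy(), method=method)[1]
    return float(H), float(p_kw), dunn


def per_chromosome_tests(
    group_means: pd.DataFrame,
    chromosome: pd.Series,
    p_adjust: str | None = None,
    exclude_by_stage: Mapping[str, Iterable[str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Kruskal-Wallis across chromosomes and Dunn Z-vs-autosome tests.

    Runs per sex x stage on genes with an individual chromosome assignment
    and positive group-mean expression in that cell. Returns (kw, dunn)
    frames.
    """
    chrom = chromosome.reindex(group_means.index)
    kw_rows = []
    dunn_rows = []
    for stage, sex in _cells(group_means):
        vals = group_means[group_key(stage, sex)]
        drop = set(exclude_by_stage.get(stage, ())) if exclude_by_stage else set()
        mask = (vals > 0) & chrom.notna() & (chrom != "unassigned") & ~vals.index.isin(drop)
        H, p_kw, dunn = kruskal_dunn(
            vals[mask].to_numpy(), chrom[mask].to_numpy(), focal="Z", p_adjust=p_adjust
        )
        kw_rows.append({"stage": stage, "sex": sex, "H": H, "p": p_kw})
        dunn = dunn.assign(stage=stage, sex=sex)
        dunn_rows.append(dunn)
    return pd.DataFrame(kw_rows), pd.concat(dunn_rows, ignore_index=True)


def quartile_analysis(male: pd.Series, female: pd.Series) -> pd.DataFrame:
    """Male-vs-female tests within four expression-magnitude bins of Z genes.

    Genes are ranked by their maximum group-mean expression in either sex
    (ties broken by gene id), cut into four equal-size bins — remainders go
    to the lower bins — and tested male-vs-female within each bin. Under a
    chromosome-wide (global) dosage mechanism the sex difference should be
    uniform across all four bins.
    """
    idx = male.index.intersection(female.index)
    male, female = male.loc[idx], female.loc[idx]
    mx = pd.concat([male, female], axis=1).max(axis=1)
    keep = mx > 0
    male, female, mx = male[keep], female[keep], mx[keep]
    n = len(mx)
    if n < 8:
        raise ValueError(f"need >= 8 genes for quartile analysis, got {n}")
    order = mx.rename("mx").rename_axis("gene_id").reset_index().sort_values(
        ["mx", "gene_id"], kind="mergesort"
    )
    base, rem = divmod(n, 4)
    sizes = [base + 1] * rem + [base] * (4 - rem)
    rows = []
    start = 0
    for q, size in enumerate(sizes, start=1):
        ids = order["gene_id"].iloc[start : start + size]
        start += size
        mvals = male.loc[ids].to_numpy()
        fvals = female.loc[ids].to_numpy()
        test = mwu(mvals, fvals, method="auto")
        rows.append(
            {
                "quartile": f"q{q}",
                "n_genes": size,
                "male_median": float(np.median(mvals)),
                "female_median": float(np.median(fvals)),
                "U": test.u,
                "p": test.p,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class DosageResults:
    """All dosage statistics for one run (full or sex-bias-excluded)."""

    za: pd.DataFrame
    mf: pd.DataFrame
    chrom_kw: pd.DataFrame | None
    chrom_dunn: pd.DataFrame | None
    quartiles: pd.DataFrame


def run_dosage(
    group_means: pd.DataFrame,
    chrom_class: pd.Series,
    chromosome: pd.Series | None = None,
    n_boot: int = 10000,
    ci: float = 0.95,
    rng: np.random.Generator | int | None = None,
    exclude_by_stage: Mapping[str, Iterable[str]] | None = None,
    dunn_p_adjust: str | None = None,
) -> DosageResults:
    """Run the complete dosage-statistics battery on one gene set."""
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    za = za_analysis(
        group_means, chrom_class, n_boot=n_boot, ci=ci, rng=gen,
        exclude_by_stage=exclude_by_stage,
    )
    mf = mf_analysis(
        group_means, chrom_class, n_boot=n_boot, ci=ci, rng=gen,
        exclude_by_stage=exclude_by_stage,
    )
    chrom_kw = chrom_dunn = None
    if chromosome is not None:
        chrom_kw, chrom_dunn = per_chromosome_tests(
            group_means, chromosome, p_adjust=dunn_p_adjust,
            exclude_by_stage=exclude_by_stage,
        )
    cls = chrom_class.reindex(group_means.index)
    q_rows = []
    stages = list(dict.fromkeys(s for s, _ in _cells(group_means)))
    for stage in stages:
        drop = set(exclude_by_stage.get(stage, ())) if exclude_by_stage else set()
        z_genes = group_means.index[(cls == "Z") & ~group_means.index.isin(drop)]
        q = quartile_analysis(
            group_means.loc[z_genes, group_key(stage, "M")],
            group_means.loc[z_genes, group_key(stage, "F")],
        )
        q_rows.append(q.assign(stage=stage))
    quartiles = pd.concat(q_rows, ignore_index=True)
    return DosageResults(za=za, mf=mf, chrom_kw=chrom_kw, chrom_dunn=chrom_dunn, quartiles=quartiles)


def exclude_and_rerun(
    group_means: pd.DataFrame,
    chrom_class: pd.Series,
    labels_by_stage: Mapping[str, pd.Series],
    chromosome: pd.Series | None = None,
    n_boot: int = 10000,
    ci: float = 0.95,
    rng: np.random.Generator | int | None = None,
    dunn_p_adjust: str | None = None,
) -> tuple[DosageResults, DosageResults]:
    """Full run and the rerun with sex-biased genes removed, side by side.

    ``labels_by_stage`` maps stage -> per-gene labels; genes labeled
    male-biased or female-biased at a stage are excluded from that stage's
    statistics in the second run.
    """
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    # both runs start from the same child seed so that an empty exclusion
    # set reproduces the full run exactly
    child = int(gen.integers(0, 2**31))
    full = run_dosage(
        group_means, chrom_class, chromosome=chromosome, n_boot=n_boot, ci=ci,
        rng=np.random.default_rng(child), dunn_p_adjust=dunn_p_adjust,
    )
    exclude = {
        stage: set(lab.index[lab.isin(["male-biased", "female-biased"])])
        for stage, lab in labels_by_stage.items()
    }
    reduced = run_dosage(
        group_means, chrom_class, chromosome=chromosome, n_boot=n_boot, ci=ci,
        rng=np.random.default_rng(child), exclude_by_stage=exclude,
        dunn_p_adjust=dunn_p_adjust,
    )
    return full, reduced
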