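"""Sex-biased expression: NB Wald test, classification, Z enrichment.

Per developmental stage, male and female replicates are contrasted with a
negative-binomial log-linear model (log link, library-size offset, known
family/batch covariate):

    count[g, j] ~ NB(mu[g, j], alpha_g),   Var = mu + alpha * mu^2
    log mu[g, j] = log sf_j + beta0_g + beta_sex * 1[j is male] + family terms

Per-gene dispersions are estimated by a Pearson method-of-moments step after
a Poisson pre-fit and shrunk in log space toward a fitted a0 + a1/mean trend,
which stabilizes the Wald statistic at 3-versus-3 replication. The sex
coefficient is tested two-sided against a normal reference and BH-adjusted
across the tested genes.

A gene is *male-biased* when padj < 0.05, log2FC > 1 and baseMean > 10
(female-biased symmetrically); enrichment of biased genes on the Z chromosome
is assessed with Fisher's exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "filter_genes",
    "nb_differential",
    "classify",
    "chromosomal_enrichment",
    "EnrichmentResult",
]

_LN2 = math.log(2.0)


def filter_genes(
    counts: pd.DataFrame, metadata: pd.DataFrame, stage: str
) -> tuple[pd.DataFrame, dict]:
    """Remove lowly/spuriously expressed genes before the stage contrast.

    Two rules: (1) genes with nonzero counts in at most one sample of the
    whole matrix are dropped; (2) genes whose mean count is below 1 in *every*
    sex group of the contrasted stage are dropped (a gene is retained if at
    least one sex group reaches mean >= 1). Returns the filtered matrix and a
    report of how many genes each rule removed.
    """
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    if stage not in set(meta["stage"]):
        raise ValueError(f"unknown stage {stage!r}")

    expressed_in = (counts > 0).sum(axis=1)
    rule1 = expressed_in <= 1

    stage_meta = meta[meta["stage"] == stage]
    low_everywhere = pd.Series(True, index=counts.index)
    for sex, grp in stage_meta.groupby("sex"):
        ids = [s for s in grp.index if s in counts.columns]
        low_everywhere &= counts[ids].mean(axis=1) < 1
    rule2 = low_everywhere & ~rule1

    keep = ~(rule1 | rule2)
    report = {
        "n_input": int(len(counts)),
        "n_removed_single_sample": int(rule1.sum()),
        "n_removed_low_mean": int(rule2.sum()),
        "n_kept": int(keep.sum()),
    }
    return counts.loc[keep], report


def _design_matrix(meta: pd.DataFrame, covariates: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    """Intercept + male indicator + full-rank covariate dummies."""
    cols = [np.ones(len(meta)), (meta["sex"] == "M").to_numpy(dtype=float)]
    names = ["intercept", "sex_M"]
    X = np.column_stack(cols)
    for cov in covariates:
        if cov not in meta.columns:
            continue
        levels = sorted(meta[cov].astype(str).unique())
        for lev in levels[1:]:  # drop-first coding
            col = (meta[cov].astype(str) == lev).to_numpy(dtype=float)
            cand = np.column_stack([X, col])
            if np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(X):
                X = cand
                names.append(f"{cov}_{lev}")
    return X, names


def _irls_nb(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched IRLS for the NB GLM with known per-gene dispersion.

    ``y`` is (G, n); the design ``X`` (n, p) and offset (n,) are shared across
    genes. Returns (beta (G, p), se (G, p), converged (G,)).
    """
    G, n = y.shape
    p = X.shape[1]
    # init from a log-linear least-squares fit on pseudo-counted data
    z0 = np.log(np.maximum(y, 0.5)) - offset[None, :]
    beta, *_ = np.linalg.lstsq(X, z0.T, rcond=None)
    beta = beta.T  # (G, p)
    a = alpha[:, None]
    converged = np.zeros(G, dtype=bool)
    A = None
    for _ in range(max_iter):
        eta = beta @ X.T + offset[None, :]
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        W = mu / (1.0 + a * mu)  # mu^2 / (mu + alpha mu^2)
        z = (eta - offset[None, :]) + (y - mu) / mu
        A = np.einsum("ni,gn,nj->gij", X, W, X)
        A += np.eye(p)[None, :, :] * 1e-10
        b = np.einsum("ni,gn,gn->gi", X, W, z)
        new = np.linalg.solve(A, b[..., None])[..., 0]
        step = np.abs(new - beta).max(axis=1)
        beta = new
        converged = step < tol
        if converged.all():
            break
    cov = np.linalg.inv(A)
    se = np.sqrt(np.clip(np.diagonal(cov, axis1=1, axis2=2), 0.0, np.inf))
    ok = converged & (np.abs(beta).max(axis=1) < 25.0) & np.isfinite(se).all(axis=1)
    return beta, se, ok


def _dispersion_trend(base_mean: np.ndarray, alpha_mom: np.ndarray) -> tuple[float, float]:
    """Fit alpha(mu) = a0 + a1/mu by iteratively reweighted NNLS.

    ``alpha_mom`` are residual-df-corrected method-of-moments values and may
    be negative (sample variance below Poisson); keeping them unclipped keeps
    the conditional-mean fit unbiased. Weights 1/trend^2 mimic a
    gamma-family regression so the many high-mean genes do not drown out the
    1/mu component.
    """
    use = (base_mean > 0) & np.isfinite(alpha_mom)
    if use.sum() < 10:
        pos = alpha_mom[np.isfinite(alpha_mom) & (alpha_mom > 0)]
        return (max(float(np.median(pos)), 1e-4) if len(pos) else 0.1), 0.0
    am = alpha_mom[use]
    # winsorize only the top tail; the noisy low/negative values are needed
    # for unbiasedness of the mean trend
    am = np.minimum(am, np.quantile(am, 0.975))
    A = np.column_stack([np.ones(use.sum()), 1.0 / base_mean[use]])
    sol, _ = optimize.nnls(A, np.maximum(am, 0.0))
    a0, a1 = max(float(sol[0]), 1e-4), max(float(sol[1]), 0.0)
    for _ in range(20):
        fit = np.maximum(a0 + a1 * A[:, 1], 1e-6)
        w = 1.0 / fit
        sol, _ = optimize.nnls(A * w[:, None], am * w)
        new_a0, new_a1 = max(float(sol[0]), 1e-4), max(float(sol[1]), 0.0)
        if abs(new_a0 - a0) < 1e-6 * (a0 + 1e-6) and abs(new_a1 - a1) < 1e-4 * (a1 + 1e-4):
            a0, a1 = new_a0, new_a1
            break
        a0, a1 = new_a0, new_a1
    return a0, a1


def _profile_dispersion(
    y: np.ndarray,
    mu: np.ndarray,
    X: np.ndarray,
    grid: np.ndarray | None = None,
) -> np.ndarray:
    """Per-gene dispersion by Cox-Reid-adjusted profile likelihood.

    Holds the fitted means fixed and maximizes the NB likelihood over a
    log-spaced alpha grid, with the Cox-Reid term ``-0.5 logdet(X'WX)``
    correcting for the estimated mean parameters — the standard remedy for
    the severe downward bias of moment/ML dispersion estimates at few
    replicates.
    """
    from scipy.special import gammaln

    if grid is None:
        grid = np.exp(np.linspace(math.log(1e-5), math.log(30.0), 80))
    G, n = y.shape
    best_ll = np.full(G, -np.inf)
    best_alpha = np.full(G, grid[0])
    for a in grid:
        inv = 1.0 / a
        ll = (
            gammaln(y + inv)
            - gammaln(inv)
            + y * np.log(a * mu / (1.0 + a * mu))
            - inv * np.log1p(a * mu)
        ).sum(axis=1)
        W = mu / (1.0 + a * mu)
        info = np.einsum("ni,gn,nj->gij", X, W, X)
        sign, logdet = np.linalg.slogdet(info)
        ll = ll - 0.5 * np.where(sign > 0, logdet, np.inf)
        better = ll > best_ll
        best_ll[better] = ll[better]
        best_alpha[better] = a
    return best_alpha


def nb_differential(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    stage: str,
    covariates: tuple[str, ...] = ("family",),
    size_factors: pd.Series | None = None,
    shrinkage: float = 0.75,
) -> pd.DataFrame:
    """Male-versus-female NB Wald test for one stage.

    Parameters
    ----------
    counts
        Filtered gene x sample integer matrix (all stages may be present;
        only the stage's samples are used).
    metadata
        sample_id, sex, stage and any covariate columns.
    size_factors
        Per-library scale factors (e.g. the autosome-anchored factors from
        :mod:`zwdose.normalize`); rescaled internally to unit geometric mean.
        When absent, the modified-quantile rule over all genes is used.
    shrinkage
        Weight of the fitted mean-dispersion trend when shrinking per-gene
        method-of-moments dispersions in log space.

    Returns
    -------
    One row per gene: baseMean, log2fc, se_log2fc, stat, p, padj, flagged.
    Genes whose GLM fit did not converge (typically one sex all zero) fall
    back to a pseudo-counted refit and are flagged.
    """
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    meta = meta[meta["stage"] == stage]
    ids = [s for s in meta.index if s in counts.columns]
    meta = meta.loc[ids]
    for sex in ("F", "M"):
        if (meta["sex"] == sex).sum() < 2:
            raise ValueError(f"need >= 2 {sex} replicates in stage {stage!r}")
    sub = counts[ids]

    if size_factors is None:
        from .normalize import scale_factors as _sf

        size_factors = _sf(sub, sub.index)
    sf = size_factors.loc[ids].to_numpy(dtype=float)
    sf = sf / np.exp(np.mean(np.log(sf)))  # unit geometric mean

    y = sub.to_numpy(dtype=float)
    norm = y / sf[None, :]
    base_mean = norm.mean(axis=1)

    X, names = _design_matrix(meta, covariates)
    sex_idx = names.index("sex_M")
    n, p = X.shape
    offset = np.log(sf)

    # Poisson pre-fit, residual-df-corrected moments -> provisional trend
    beta_p, _, _ = _irls_nb(y, X, offset, np.zeros(len(y)))
    mu_p = np.exp(np.clip(beta_p @ X.T + offset[None, :], -30, 30))
    denom = (mu_p**2).sum(axis=1)
    df_corr = n / max(n - p, 1)
    alpha_mom = (df_corr * (y - mu_p) ** 2 - mu_p).sum(axis=1) / np.maximum(denom, 1e-12)
    a0, a1 = _dispersion_trend(base_mean, alpha_mom)
    alpha0 = np.clip(a0 + a1 / np.maximum(base_mean, 1e-8), 1e-8, 50.0)

    # NB fit at the provisional trend, Cox-Reid profile dispersions at the
    # fitted means, final trend through those
    beta_0, _, _ = _irls_nb(y, X, offset, alpha0)
    mu_0 = np.exp(np.clip(beta_0 @ X.T + offset[None, :], -30, 30))
    alpha_cr = _profile_dispersion(y, mu_0, X)
    a0, a1 = _dispersion_trend(base_mean, alpha_cr)
    alpha_trend = np.clip(a0 + a1 / np.maximum(base_mean, 1e-8), 1e-8, 50.0)

    # shrink the per-gene estimate toward the trend in log space, capping its
    # influence at a factor 8 either side of the trend
    w = float(np.clip(shrinkage, 0.0, 1.0))
    capped = np.clip(alpha_cr, alpha_trend / 8.0, alpha_trend * 8.0)
    alpha = np.exp(w * np.log(alpha_trend) + (1.0 - w) * np.log(capped))
    alpha = np.clip(alpha, 1e-8, 50.0)

    beta, se, ok = _irls_nb(y, X, offset, alpha)

    flagged = ~ok
    if flagged.any():
        # moment fallback: pseudo-count 0.5 keeps the fit finite when one
        # sex has no reads at all
        beta_f, se_f, ok_f = _irls_nb(y[flagged] + 0.5, X, offset, alpha[flagged])
        beta[flagged] = beta_f
        se[flagged] = se_f

    b_sex = beta[:, sex_idx]
    se_sex = np.maximum(se[:, sex_idx], 1e-12)
    stat = b_sex / se_sex
    pvals = 2.0 * stats.norm.sf(np.abs(stat))
    padj = multipletests(pvals, method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "gene_id": sub.index,
            "stage": stage,
            "baseMean": base_mean,
            "log2fc": b_sex / _LN2,
            "se_log2fc": se_sex / _LN2,
            "stat": stat,
            "p": pvals,
            "padj": padj,
            "flagged": flagged,
        }
    ).set_index("gene_id")


def classify(
    table: pd.DataFrame,
    alpha: float = 0.05,
    min_abs_log2fc: float = 1.0,
    min_basemean: float = 10.0,
) -> pd.DataFrame:
    """Attach bias labels using the FDR / fold-change / baseMean thresholds."""
    if "padj" not in table.columns:
        raise ValueError("classify() needs a padj column; run nb_differential first")
    out = table.copy()
    sig = (out["padj"] < alpha) & (out["baseMean"] > min_basemean)
    out["label"] = "unbiased"
    out.loc[sig & (out["log2fc"] > min_abs_log2fc), "label"] = "male-biased"
    out.loc[sig & (out["log2fc"] < -min_abs_log2fc), "label"] = "female-biased"
    return out


@dataclass
class EnrichmentResult:
    """2x2 Fisher test of a biased gene set against the Z/A split.

    ``table`` rows are (biased, not biased), columns are (Z, A).
    """

    table: np.ndarray
    odds_ratio: float
    p: float

    def as_dict(self) -> dict:
        return {
            "biased_z": int(self.table[0, 0]),
            "biased_a": int(self.table[0, 1]),
            "unbiased_z": int(self.table[1, 0]),
            "unbiased_a": int(self.table[1, 1]),
            "odds_ratio": self.odds_ratio,
            "p": self.p,
        }


def chromosomal_enrichment(
    labels: pd.Series, chrom_class: pd.Series, direction: str = "male"
) -> EnrichmentResult:
    """Fisher's exact test for enrichment of biased genes on Z.

    ``labels`` maps gene -> {male-biased, female-biased, unbiased};
    ``chrom_class`` maps gene -> {A, Z, unassigned}. Unassigned genes are
    dropped. ``direction`` selects which bias direction forms the first row.
    The p-value is the two-sided Fisher probability (sum of hypergeometric
    outcomes no more probable than the observed table); the odds ratio is the
    conditional maximum-likelihood estimate.
    """
    if direction not in ("male", "female"):
        raise ValueError("direction must be 'male' or 'female'")
    target = f"{direction}-biased"
    cls = chrom_class.reindex(labels.index)
    keep = cls.isin(["A", "Z"])
    lab = labels[keep]
    cls = cls[keep]
    biased = lab == target
    is_z = cls == "Z"
    table = np.array(
        [
            [int((biased & is_z).sum()), int((biased & ~is_z).sum())],
            [int((~biased & is_z).sum()), int((~biased & ~is_z).sum())],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return EnrichmentResult(table=table, odds_ratio=float("nan"), p=1.0)
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    try:
        orr = float(stats.contingency.odds_ratio(table, kind="conditional").statistic)
    except Exception:
        orr = float("nan")
    return EnrichmentResult(table=table, odds_ratio=orr, p=min(p, 1.0))
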