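"""Synthetic ZW RNA-seq data generator.

Emulates a whole-body bulk RNA-seq design for a female-heterogametic (ZZ/ZW)
butterfly: three male and three female biological replicates at each of three
developmental stages (larva, pupa, adult), ~13.4k autosomal genes on 20
autosomes and ~400 Z-linked genes, spread over draft-assembly scaffolds.

The generator plants three recoverable signals:

* **dosage** — Z-linked genes are expressed at a configurable multiple of the
  two-copy autosomal baseline in each sex (``d_z_male``, ``d_z_female``; 0.5
  mimics the incomplete-compensation regime where male Z expression is halved
  to the single-copy female level but stays below autosomes);
* **sex bias** — a per-stage fraction of genes gets a planted log2 male/female
  effect, the per-stage sets nested (larva ⊆ pupa ⊆ adult) so bias increases
  across development; male-biased genes preferentially reside on Z
  (``z_malebias_odds``), mimicking Z masculinization;
* **assembly noise** — scaffold-to-reference alignment tables with a tunable
  fraction of off-target mapped bp and a fraction of near-unmapped scaffolds.

Counts are negative-binomial with a mean-dependent dispersion trend and a
multiplicative log-normal family (batch) factor. Everything is deterministic
given ``SimConfig.seed``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

STAGES: tuple[str, ...] = ("larva", "pupa", "adult")
SEXES: tuple[str, ...] = ("F", "M")

__all__ = [
    "SimConfig",
    "SimConfigError",
    "GenomeModel",
    "SimResult",
    "generate_genome",
    "generate_alignment_hits",
    "generate_counts",
    "simulate",
    "write_simulation",
]


class SimConfigError(ValueError):
    """Raised when a :class:`SimConfig` fails validation."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic ZW expression study.

    Defaults reproduce the study conditions the package is designed around:
    20 autosomes, 13,442 autosomal and 405 Z-linked genes, 3 + 3 replicates
    per stage from four families, incomplete dosage compensation
    (``d_z_male = d_z_female = 0.5``) and a stage-increasing sex-bias fraction
    (1.5% / 3.5% / 27% of genes) with male-biased genes enriched on Z.
    """

    n_autosomes: int = 20
    n_autosomal_genes: int = 13442
    n_z_genes: int = 405
    #: mean number of genes per scaffold (sizes are 1 + Poisson(mean - 1))
    genes_per_scaffold: float = 14.0
    gene_length_meanlog: float = math.log(1000.0)
    gene_length_sdlog: float = 0.6
    min_gene_length: int = 100
    stages: tuple[str, ...] = STAGES
    replicates_per_group: int = 3
    #: per-sample relative sequencing depth; scalar or mapping sample_id -> depth
    library_size: float | Mapping[str, float] = 1.0
    #: log-normal baseline expression rate per kb (reads per kb at unit
    #: depth); the default emulates a deep whole-body bulk library
    #: (median ~30 reads/kb, upper tail into the tens of thousands)
    expression_meanlog: float = math.log(30.0)
    expression_sdlog: float = 1.5
    #: asymptotic NB dispersion a0 in the trend alpha(mu) = a0 + a1/mu
    dispersion: float = 0.05
    dispersion_mean_coef: float = 2.0
    #: log-normal sd of per-gene jitter around the dispersion trend
    dispersion_lognorm_sd: float = 0.3
    d_z_male: float = 0.5
    d_z_female: float = 0.5
    #: fraction of genes with a planted sex effect at each stage, in stage order
    sexbias_fraction_per_stage: tuple[float, ...] = (0.015, 0.035, 0.27)
    effect_size_log2: float = 2.0
    male_fraction_of_biased: float = 0.5
    #: odds multiplier for a male-biased gene residing on the Z chromosome;
    #: the default reproduces ~20% of Z genes male-biased in adults at the
    #: default gene counts and per-stage bias fractions
    z_malebias_odds: float = 1.5
    #: log-scale sd of the multiplicative per-(family, gene) batch factor
    batch_effect_sd: float = 0.1
    n_families: int = 4
    #: expected fraction of a scaffold's mapped bp landing on its true chromosome
    alignment_purity: float = 0.98
    #: fraction of scaffolds emitted with < 200 total mapped bp
    min_mapped_fraction: float = 0.2
    mapped_fraction_range: tuple[float, float] = (0.4, 0.95)
    intergenic_factor_range: tuple[float, float] = (2.0, 4.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_autosomes < 1 or self.n_autosomal_genes < 1 or self.n_z_genes < 1:
            raise SimConfigError("chromosome and gene counts must be positive")
        if self.genes_per_scaffold <= 0:
            raise SimConfigError("genes_per_scaffold must be positive")
        if not self.stages:
            raise SimConfigError("stages must be non-empty")
        if len(set(self.stages)) != len(self.stages):
            raise SimConfigError("stages must be unique")
        if self.replicates_per_group < 1:
            raise SimConfigError("replicates_per_group must be >= 1")
        if isinstance(self.library_size, (int, float)):
            if self.library_size <= 0:
                raise SimConfigError("library_size must be positive")
        else:
            if any(v <= 0 for v in self.library_size.values()):
                raise SimConfigError("library sizes must be positive")
        for name in ("d_z_male", "d_z_female", "z_malebias_odds"):
            if getattr(self, name) <= 0:
                raise SimConfigError(f"{name} must be strictly positive")
        if self.dispersion < 0 or self.dispersion_mean_coef < 0:
            raise SimConfigError("dispersion parameters must be non-negative")
        if len(self.sexbias_fraction_per_stage) != len(self.stages):
            raise SimConfigError(
                "sexbias_fraction_per_stage must have one entry per stage"
            )
        for frac in (
            *self.sexbias_fraction_per_stage,
            self.male_fraction_of_biased,
            self.alignment_purity,
            self.min_mapped_fraction,
        ):
            if not 0.0 <= frac <= 1.0:
                raise SimConfigError("fractions must lie in [0, 1]")
        if self.effect_size_log2 < 0:
            raise SimConfigError("effect_size_log2 must be non-negative")
        if self.batch_effect_sd < 0:
            raise SimConfigError("batch_effect_sd must be non-negative")
        if self.n_families < 1:
            raise SimConfigError("n_families must be >= 1")

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return ("Z",) + tuple(f"A{i}" for i in range(1, self.n_autosomes + 1))

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class GenomeModel:
    """Gene and scaffold tables of a simulated draft assembly.

    ``genes``: gene_id, scaffold_id, chromosome, length (bp).
    ``scaffolds``: scaffold_id, chromosome, length (bp).
    """

    genes: pd.DataFrame
    scaffolds: pd.DataFrame


@dataclass
class SimResult:
    """Bundle returned by :func:`simulate`."""

    config: SimConfig
    genome: GenomeModel
    hits: pd.DataFrame
    counts: pd.DataFrame
    samples: pd.DataFrame
    truth: pd.DataFrame


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per generation stage
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _truncated_lognormal(
    rng: np.random.Generator, meanlog: float, sdlog: float, lower: float, size: int
) -> np.ndarray:
    out = rng.lognormal(meanlog, sdlog, size)
    bad = out < lower
    # resample the tail rather than clipping, so the shape stays log-normal
    for _ in range(100):
        n_bad = int(bad.sum())
        if n_bad == 0:
            break
        out[bad] = rng.lognormal(meanlog, sdlog, n_bad)
        bad = out < lower
    out[out < lower] = lower
    return out


def generate_genome(config: SimConfig) -> GenomeModel:
    """Lay out genes on chromosomes and partition them into scaffolds.

    Gene counts per chromosome class match the config exactly; autosomal genes
    are split across autosomes by an equal-probability multinomial. Scaffolds
    never span chromosomes and every gene sits on exactly one scaffold.
    """
    rng = _rng(config, 1)
    per_auto = rng.multinomial(
        config.n_autosomal_genes, np.full(config.n_autosomes, 1.0 / config.n_autosomes)
    )
    # guarantee every autosome carries at least one gene
    while (per_auto == 0).any() and per_auto.max() > 1:
        per_auto[np.argmin(per_auto)] += 1
        per_auto[np.argmax(per_auto)] -= 1

    chrom_sizes = {"Z": config.n_z_genes}
    for i, n in enumerate(per_auto, start=1):
        chrom_sizes[f"A{i}"] = int(n)

    n_total = config.n_z_genes + config.n_autosomal_genes
    lengths = np.rint(
        _truncated_lognormal(
            rng,
            config.gene_length_meanlog,
            config.gene_length_sdlog,
            config.min_gene_length,
            n_total,
        )
    ).astype(np.int64)

    gene_rows: list[tuple[str, str, str, int]] = []
    scaf_rows: list[tuple[str, str, int]] = []
    gi = 0
    si = 0
    for chrom, n_genes in chrom_sizes.items():
        remaining = n_genes
        while remaining > 0:
            size = 1 + int(rng.poisson(max(config.genes_per_scaffold - 1.0, 0.0)))
            size = min(size, remaining)
            scaffold_id = f"scf{si:05d}"
            glen = 0
            for _ in range(size):
                gene_id = f"g{gi:06d}"
                gene_rows.append((gene_id, scaffold_id, chrom, int(lengths[gi])))
                glen += int(lengths[gi])
                gi += 1
            factor = rng.uniform(*config.intergenic_factor_range)
            scaf_rows.append((scaffold_id, chrom, int(round(glen * factor))))
            si += 1
            remaining -= size

    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "scaffold_id", "chromosome", "length"]
    )
    scaffolds = pd.DataFrame(scaf_rows, columns=["scaffold_id", "chromosome", "length"])
    return GenomeModel(genes=genes, scaffolds=scaffolds)


def generate_alignment_hits(genome: GenomeModel, config: SimConfig) -> pd.DataFrame:
    """Emit a scaffold-vs-reference coverage table.

    One or two rows per scaffold (on-target plus at most one off-target
    chromosome). The expected on-target share of mapped bp equals
    ``alignment_purity``; a ``min_mapped_fraction`` share of scaffolds gets
    fewer than 200 total mapped bp and is thus uninformative downstream.
    """
    rng = _rng(config, 2)
    chroms = np.asarray(config.chromosomes)
    rows: list[tuple[str, int, str, int]] = []
    scafs = genome.scaffolds
    n = len(scafs)
    uninformative = rng.random(n) < config.min_mapped_fraction
    frac = rng.uniform(*config.mapped_fraction_range, size=n)
    purity = config.alignment_purity
    c = 300.0  # Beta concentration: sd ~ sqrt(p(1-p)/301) around the purity

    for i, (scaffold_id, chrom, length) in enumerate(
        scafs[["scaffold_id", "chromosome", "length"]].itertuples(index=False)
    ):
        if uninformative[i]:
            total = int(rng.integers(1, 200))
        else:
            total = max(200, int(round(frac[i] * length)))
        if purity >= 1.0:
            rows.append((scaffold_id, int(length), chrom, total))
            continue
        if purity <= 0.0:
            on = 0
        else:
            on = int(round(total * rng.beta(c * purity, c * (1.0 - purity))))
        on = min(max(on, 0), total)
        off = total - on
        if on > 0:
            rows.append((scaffold_id, int(length), chrom, on))
        if off > 0:
            others = chroms[chroms != chrom]
            target = str(rng.choice(others))
            rows.append((scaffold_id, int(length), target, off))

    return pd.DataFrame(
        rows, columns=["scaffold_id", "scaffold_length", "chromosome", "mapped_bp"]
    )


def _sample_table(config: SimConfig) -> pd.DataFrame:
    rows = []
    for s_idx, stage in enumerate(config.stages):
        # two families per stage, crossed with sex so the family covariate
        # stays estimable alongside the sex effect in a 3+3 design
        fam_a = (2 * s_idx) % config.n_families
        fam_b = (2 * s_idx + 1) % config.n_families
        for sex in SEXES:
            for r in range(1, config.replicates_per_group + 1):
                offset = 0 if sex == "F" else 1
                fam = fam_a if (r + offset) % 2 == 0 else fam_b
                rows.append(
                    {
                        "sample_id": f"{stage}_{sex}{r}",
                        "sex": sex,
                        "stage": stage,
                        "family": f"fam{fam}",
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def _weighted_sample_without_replacement(
    rng: np.random.Generator, pool: np.ndarray, weights: np.ndarray, size: int
) -> np.ndarray:
    if size == 0:
        return pool[:0]
    p = weights / weights.sum()
    return rng.choice(pool, size=size, replace=False, p=p)


def _plant_bias(
    config: SimConfig, genome: GenomeModel, rng: np.random.Generator
) -> pd.DataFrame:
    """Pick nested per-stage biased gene sets and signed log2 effects.

    Returns a (gene x stage) frame of true log2(M/F) effects. Male-biased
    genes are drawn with Z genes upweighted by ``z_malebias_odds``.
    """
    genes = genome.genes
    gene_ids = genes["gene_id"].to_numpy()
    is_z = (genes["chromosome"] == "Z").to_numpy()
    n_genes = len(gene_ids)

    targets = [int(round(f * n_genes)) for f in config.sexbias_fraction_per_stage]
    # nesting (earlier ⊆ later stage) requires non-decreasing target sizes
    targets = list(np.maximum.accumulate(targets))

    m_final = targets[-1]
    n_male = int(round(m_final * config.male_fraction_of_biased))
    n_female = m_final - n_male

    weights = np.where(is_z, config.z_malebias_odds, 1.0)
    male_set = _weighted_sample_without_replacement(
        rng, np.arange(n_genes), weights, n_male
    )
    remaining = np.setdiff1d(np.arange(n_genes), male_set, assume_unique=False)
    female_set = rng.choice(remaining, size=n_female, replace=False)

    effects = pd.DataFrame(
        0.0, index=pd.Index(gene_ids, name="gene_id"), columns=list(config.stages)
    )
    male_cur, female_cur = male_set, female_set
    for stage, target in zip(reversed(config.stages), reversed(targets)):
        n_m = int(round(target * config.male_fraction_of_biased))
        n_f = target - n_m
        n_m = min(n_m, len(male_cur))
        n_f = min(n_f, len(female_cur))
        male_cur = rng.choice(male_cur, size=n_m, replace=False) if len(male_cur) else male_cur
        female_cur = (
            rng.choice(female_cur, size=n_f, replace=False) if len(female_cur) else female_cur
        )
        col = np.zeros(n_genes)
        col[male_cur] = config.effect_size_log2
        col[female_cur] = -config.effect_size_log2
        effects[stage] = col
    return effects


def generate_counts(
    genome: GenomeModel, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw the NB count matrix plus sample metadata and the truth table.

    The mean for gene *g* in sample *j* is
    ``s_j * (L_g / 1e3) * q_g * D * B * batch`` with ``q_g`` a log-normal
    baseline rate, ``D`` the sex-specific Z-dose multiplier (1 on autosomes),
    ``B = 2^(±effect/2)`` for genes with a planted effect at the sample's
    stage, and a log-normal per-(family, gene) batch factor.
    """
    rng = _rng(config, 3)
    genes = genome.genes
    gene_ids = genes["gene_id"].to_numpy()
    lengths = genes["length"].to_numpy(dtype=float)
    is_z = (genes["chromosome"] == "Z").to_numpy()
    n_genes = len(gene_ids)

    samples = _sample_table(config)
    if isinstance(config.library_size, (int, float)):
        lib = np.full(len(samples), float(config.library_size))
    else:
        lib = np.array([float(config.library_size[s]) for s in samples.index])

    q = rng.lognormal(config.expression_meanlog, config.expression_sdlog, n_genes)
    effects = _plant_bias(config, genome, rng)

    families = sorted(samples["family"].unique())
    fam_idx = {f: i for i, f in enumerate(families)}
    if config.batch_effect_sd > 0:
        batch = rng.lognormal(0.0, config.batch_effect_sd, (len(families), n_genes))
    else:
        batch = np.ones((len(families), n_genes))

    base_mean = float(np.mean(lib)) * (lengths / 1e3) * q
    trend = config.dispersion + config.dispersion_mean_coef / np.maximum(base_mean, 1e-8)
    if config.dispersion_lognorm_sd > 0:
        alpha = trend * rng.lognormal(0.0, config.dispersion_lognorm_sd, n_genes)
    else:
        alpha = trend

    dose = {
        "M": np.where(is_z, config.d_z_male, 1.0),
        "F": np.where(is_z, config.d_z_female, 1.0),
    }

    counts = np.empty((n_genes, len(samples)), dtype=np.int64)
    for j, (sample_id, row) in enumerate(samples.iterrows()):
        eff = effects[row["stage"]].to_numpy()
        bias = np.exp2(eff / 2.0) if row["sex"] == "M" else np.exp2(-eff / 2.0)
        mu = lib[j] * (lengths / 1e3) * q * dose[row["sex"]] * bias
        mu = mu * batch[fam_idx[row["family"]], :]
        tiny = alpha < 1e-8
        col = np.empty(n_genes, dtype=np.int64)
        if tiny.any():
            col[tiny] = rng.poisson(mu[tiny])
        if (~tiny).any():
            a = alpha[~tiny]
            m = mu[~tiny]
            col[~tiny] = rng.negative_binomial(1.0 / a, 1.0 / (1.0 + a * m))
        counts[:, j] = col

    counts_df = pd.DataFrame(
        counts, index=pd.Index(gene_ids, name="gene_id"), columns=samples.index
    )

    truth_rows = []
    chrom_class = np.where(is_z, "Z", "A")
    for stage in config.stages:
        eff = effects[stage].to_numpy()
        label = np.where(eff > 0, "male-biased", np.where(eff < 0, "female-biased", "unbiased"))
        truth_rows.append(
            pd.DataFrame(
                {
                    "gene_id": gene_ids,
                    "stage": stage,
                    "chromosome": genes["chromosome"].to_numpy(),
                    "chrom_class": chrom_class,
                    "true_log2fc": eff,
                    "label": label,
                }
            )
        )
    truth = pd.concat(truth_rows, ignore_index=True)
    return counts_df, samples.reset_index(), truth


def simulate(config: SimConfig) -> SimResult:
    """Run the full generator: genome, alignment hits, counts, truth."""
    genome = generate_genome(config)
    hits = generate_alignment_hits(genome, config)
    counts, samples, truth = generate_counts(genome, config)
    return SimResult(
        config=config, genome=genome, hits=hits, counts=counts, samples=samples, truth=truth
    )


def write_simulation(result: SimResult, outdir) -> None:
    """Write counts.tsv, genes.tsv, scaffolds.tsv, hits.tsv, samples.tsv, truth.tsv."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.counts.to_csv(out / "counts.tsv", sep="\t")
    result.genome.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    result.genome.scaffolds.to_csv(out / "scaffolds.tsv", sep="\t", index=False)
    result.hits.to_csv(out / "hits.tsv", sep="\t", index=False)
    result.samples.to_csv(out / "samples.tsv", sep="\t", index=False)
    result.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
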