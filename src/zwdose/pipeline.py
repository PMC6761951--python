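"""End-to-end orchestration: simulate/load -> assign -> normalize -> sex bias -> dosage.

A :class:`RunConfig` either embeds a :class:`~zwdose.simulate.SimConfig`
block or points at the four input tables (counts, samples, genes, hits).
:func:`run_pipeline` executes every stage with the study defaults (min
mapped 200 bp, class/chromosome cutoffs 0.95/0.90, top-quartile 0.25,
10,000 bootstrap iterations, FDR 0.05, |log2FC| > 1, baseMean > 10), fans a
single seed out to per-stage child seeds, and returns a
:class:`ReportBundle` whose summary mirrors the point/CI/p layout of a
median-ratio results table. A fixed seed reproduces the bundle exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assign as _assign
from . import dosage as _dosage
from . import normalize as _norm
from . import sexbias as _sexbias
from .simulate import SimConfig, SimResult, simulate

__all__ = [
    "RunConfig",
    "ReportBundle",
    "PipelineError",
    "run_pipeline",
    "summarize",
    "significance_stars",
    "write_bundle",
]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Resolved parameters of one pipeline run (defaults = study values)."""

    sim: SimConfig | None = None
    counts_path: str | None = None
    samples_path: str | None = None
    genes_path: str | None = None
    hits_path: str | None = None
    min_mapped: int = 200
    class_fraction_cutoff: float = 0.95
    chromosome_fraction_cutoff: float = 0.90
    denominator: str = "mapped"
    top_fraction: float = 0.25
    n_boot: int = 10000
    ci: float = 0.95
    alpha: float = 0.05
    min_abs_log2fc: float = 1.0
    min_basemean: float = 10.0
    dunn_p_adjust: str | None = None
    per_chromosome: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_block = raw.pop("sim", None)
        sim = SimConfig(**sim_block) if sim_block is not None else None
        known = {f.name for f in dataclasses.fields(cls)} - {"sim"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(sim=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            d["sim"] = dataclasses.asdict(self.sim)
        return d


@dataclass
class ReportBundle:
    """All per-stage tables plus the run summary."""

    config: RunConfig
    sim: SimResult | None
    counts: pd.DataFrame
    samples: pd.DataFrame
    genes: pd.DataFrame
    hits: pd.DataFrame
    assignment: pd.DataFrame
    gene_labels: pd.DataFrame
    factors: pd.Series
    fpkm: pd.DataFrame
    replicate_qc: pd.DataFrame
    group_means: pd.DataFrame
    sexbias: dict[str, pd.DataFrame]
    filter_reports: dict[str, dict]
    enrichment: pd.DataFrame
    dosage_full: _dosage.DosageResults
    dosage_excluded: _dosage.DosageResults
    summary: pd.DataFrame
    summary_json: dict


def significance_stars(p: float) -> str:
    """Star convention: * P<=0.05, ** P<=0.01, *** P<=0.001."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def _load_inputs(config: RunConfig):
    if config.sim is not None:
        return None
    needed = ("counts_path", "samples_path", "genes_path", "hits_path")
    missing = [n for n in needed if getattr(config, n) is None]
    if missing:
        raise PipelineError("inputs", f"no sim block and missing paths: {missing}")
    counts = pd.read_csv(config.counts_path, sep="\t", index_col=0)
    counts.index.name = "gene_id"
    samples = pd.read_csv(config.samples_path, sep="\t")
    genes = pd.read_csv(config.genes_path, sep="\t")
    hits = pd.read_csv(config.hits_path, sep="\t")
    return counts, samples, genes, hits


def run_pipeline(config: RunConfig, outdir=None) -> ReportBundle:
    """Execute every stage in order; deterministic given ``config.seed``."""
    ss = np.random.SeedSequence(int(config.seed))
    sim_seed, boot_seed = (int(s) & 0x7FFFFFFF for s in ss.generate_state(2))

    sim_result = None
    if config.sim is not None:
        sim_result = simulate(config.sim.replace(seed=sim_seed))
        counts, samples = sim_result.counts, sim_result.samples
        genes, hits = sim_result.genome.genes, sim_result.hits
    else:
        counts, samples, genes, hits = _load_inputs(config)

    stages = list(dict.fromkeys(samples["stage"]))

    try:
        assignment = _assign.assign_scaffolds(
            hits,
            min_mapped=config.min_mapped,
            class_fraction_cutoff=config.class_fraction_cutoff,
            chromosome_fraction_cutoff=config.chromosome_fraction_cutoff,
            denominator=config.denominator,
        )
        gene_labels = _assign.genes_to_chromosomes(assignment, genes).set_index("gene_id")
    except ValueError as exc:
        raise PipelineError("assign", str(exc)) from exc
    chrom_class = gene_labels["chrom_class"]
    chromosome = gene_labels["chromosome"]

    try:
        autosomal = chrom_class.index[chrom_class == "A"]
        factors = _norm.scale_factors(counts, autosomal, config.top_fraction)
        fpkm = _norm.fpkm_matrix(counts, genes.set_index("gene_id")["length"], factors)
        replicate_qc = _norm.replicate_spearman(fpkm, samples)
        group_means = _norm.group_means(fpkm, samples)
    except ValueError as exc:
        raise PipelineError("normalize", str(exc)) from exc

    sexbias_tables: dict[str, pd.DataFrame] = {}
    filter_reports: dict[str, dict] = {}
    enrich_rows = []
    try:
        for stage in stages:
            filtered, report = _sexbias.filter_genes(counts, samples, stage)
            filter_reports[stage] = report
            table = _sexbias.nb_differential(
                filtered, samples, stage, size_factors=factors
            )
            labeled = _sexbias.classify(
                table,
                alpha=config.alpha,
                min_abs_log2fc=config.min_abs_log2fc,
                min_basemean=config.min_basemean,
            )
            sexbias_tables[stage] = labeled
            for direction in ("male", "female"):
                res = _sexbias.chromosomal_enrichment(
                    labeled["label"], chrom_class, direction=direction
                )
                enrich_rows.append({"stage": stage, "direction": direction, **res.as_dict()})
    except ValueError as exc:
        raise PipelineError("sexbias", str(exc)) from exc
    enrichment = pd.DataFrame(enrich_rows)

    labels_by_stage = {stage: t["label"] for stage, t in sexbias_tables.items()}
    try:
        full, excluded = _dosage.exclude_and_rerun(
            group_means,
            chrom_class,
            labels_by_stage,
            chromosome=chromosome if config.per_chromosome else None,
            n_boot=config.n_boot,
            ci=config.ci,
            rng=np.random.default_rng(boot_seed),
            dunn_p_adjust=config.dunn_p_adjust,
        )
    except ValueError as exc:
        raise PipelineError("dosage", str(exc)) from exc

    summary, summary_json = summarize(full, excluded, sexbias_tables, enrichment)

    bundle = ReportBundle(
        config=config,
        sim=sim_result,
        counts=counts,
        samples=samples,
        genes=genes,
        hits=hits,
        assignment=assignment,
        gene_labels=gene_labels.reset_index(),
        factors=factors,
        fpkm=fpkm,
        replicate_qc=replicate_qc,
        group_means=group_means,
        sexbias=sexbias_tables,
        filter_reports=filter_reports,
        enrichment=enrichment,
        dosage_full=full,
        dosage_excluded=excluded,
        summary=summary,
        summary_json=summary_json,
    )
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


def summarize(
    full: _dosage.DosageResults,
    excluded: _dosage.DosageResults,
    sexbias_tables: dict[str, pd.DataFrame],
    enrichment: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """One row per run x comparison x stage cell, plus a JSON mirror.

    The JSON object is built from the same records as the table, so the two
    emissions agree field for field.
    """
    rows = []
    for run_name, res in (("full", full), ("excluded", excluded)):
        for _, r in res.za.iterrows():
            rows.append(
                {
                    "run": run_name,
                    "comparison": "Z:A",
                    "stage": r["stage"],
                    "group": r["sex"],
                    "point": float(r["point"]),
                    "ci_low": float(r["ci_low"]),
                    "ci_high": float(r["ci_high"]),
                    "n": int(r["n_numerator"]),
                    "p": float(r["p_mwu"]),
                    "stars": significance_stars(float(r["p_mwu"])),
                }
            )
        for _, r in res.mf.iterrows():
            rows.append(
                {
                    "run": run_name,
                    "comparison": "M:F",
                    "stage": r["stage"],
                    "group": r["chrom_class"],
                    "point": float(r["point"]),
                    "ci_low": float(r["ci_low"]),
                    "ci_high": float(r["ci_high"]),
                    "n": int(r["n_genes"]),
                    "p": float(r["p_mwu"]),
                    "stars": significance_stars(float(r["p_mwu"])),
                }
            )
    summary = pd.DataFrame(rows)

    bias_counts = {
        stage: {
            "male_biased": int((t["label"] == "male-biased").sum()),
            "female_biased": int((t["label"] == "female-biased").sum()),
            "total_biased": int(t["label"].isin(["male-biased", "female-biased"]).sum()),
        }
        for stage, t in sexbias_tables.items()
    }
    summary_json = {
        "ratios": rows,
        "sex_biased_counts": bias_counts,
        "enrichment": enrichment.to_dict(orient="records"),
    }
    return summary, summary_json


def _write_dosage(res: _dosage.DosageResults, out: Path, tag: str) -> None:
    pd.concat(
        [res.za.rename(columns={"sex": "group"}),
         res.mf.rename(columns={"chrom_class": "group"})],
        ignore_index=True,
    ).to_csv(out / f"dosage_{tag}.tsv", sep="\t", index=False)
    if res.chrom_kw is not None:
        res.chrom_kw.to_csv(out / f"chromtests_{tag}.tsv", sep="\t", index=False)
        res.chrom_dunn.to_csv(out / f"dunn_{tag}.tsv", sep="\t", index=False)
    res.quartiles.to_csv(out / f"quartiles_{tag}.tsv", sep="\t", index=False)


def write_bundle(bundle: ReportBundle, outdir) -> None:
    """Write every stage's table plus summary.tsv/summary.json and the config."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if bundle.sim is not None:
        from .simulate import write_simulation

        write_simulation(bundle.sim, out / "sim")
    bundle.assignment.to_csv(out / "assignment.tsv", sep="\t", index=False)
    bundle.gene_labels.to_csv(out / "gene_labels.tsv", sep="\t", index=False)
    bundle.factors.rename_axis("sample_id").to_csv(out / "factors.tsv", sep="\t")
    bundle.fpkm.to_csv(out / "fpkm.tsv", sep="\t")
    bundle.replicate_qc.to_csv(out / "replicate_qc.tsv", sep="\t", index=False)
    bundle.group_means.to_csv(out / "group_means.tsv", sep="\t")
    for stage, table in bundle.sexbias.items():
        table.to_csv(out / f"sexbias_{stage}.tsv", sep="\t")
    bundle.enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    _write_dosage(bundle.dosage_full, out, "full")
    _write_dosage(bundle.dosage_excluded, out, "excluded")
    bundle.summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(bundle.summary_json, fh, indent=2)
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(bundle.config.to_dict(), fh, sort_keys=False)
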