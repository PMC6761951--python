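"""Scaffold-to-chromosome assignment from homology coverage tables.

A draft-assembly scaffold is assigned to a chromosome class (autosomal vs
Z-linked) and, in a second, less stringent pass, to an individual chromosome,
from the amount of sequence it maps to each reference chromosome:

* scaffolds with fewer than ``min_mapped`` (default 200) bp mapped anywhere
  are uninformative and stay unassigned;
* class A or Z if more than ``class_fraction_cutoff`` (default 0.95) of the
  mapped sequence hits that chromosome group;
* an individual chromosome if more than ``chromosome_fraction_cutoff``
  (default 0.90) hits a single chromosome.

Fractions are computed over total mapped bp by default; pass
``denominator="scaffold_length"`` to divide by the scaffold length instead
(over deep divergence times most of a scaffold does not align, which makes
the mapped-bp denominator the practical default).

Genes inherit the labels of the scaffold that carries them.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["assign_scaffolds", "genes_to_chromosomes", "UNASSIGNED"]

UNASSIGNED = "unassigned"

_REQUIRED_HIT_COLS = ("scaffold_id", "scaffold_length", "chromosome", "mapped_bp")


def assign_scaffolds(
    hits: pd.DataFrame,
    min_mapped: int = 200,
    class_fraction_cutoff: float = 0.95,
    chromosome_fraction_cutoff: float = 0.90,
    denominator: str = "mapped",
    valid_chromosomes: set[str] | None = None,
) -> pd.DataFrame:
    """Assign each scaffold to a chromosome class and individual chromosome.

    Parameters
    ----------
    hits
        One row per (scaffold, target chromosome) alignment aggregate with
        columns scaffold_id, scaffold_length, chromosome, mapped_bp. Multiple
        rows per pair are summed. mapped_bp may exceed scaffold_length in sum
        (local alignments can overlap).
    min_mapped
        Scaffolds with less total mapped sequence are dropped to unassigned.
    class_fraction_cutoff, chromosome_fraction_cutoff
        Strict (>) share thresholds for the two-way A/Z class call and the
        per-chromosome call respectively.
    denominator
        "mapped" (total mapped bp) or "scaffold_length".
    valid_chromosomes
        Optional whitelist of target labels; anything outside raises.

    Returns
    -------
    One row per input scaffold, sorted by scaffold_id, with columns
    scaffold_id, chrom_class, chromosome, total_mapped_bp, class_fraction,
    chromosome_fraction.
    """
    if hits.empty:
        raise ValueError("hits table is empty")
    missing = [c for c in _REQUIRED_HIT_COLS if c not in hits.columns]
    if missing:
        raise ValueError(f"hits table lacks columns: {missing}")
    if not 0 < class_fraction_cutoff <= 1 or not 0 < chromosome_fraction_cutoff <= 1:
        raise ValueError("fraction cutoffs must lie in (0, 1]")
    if denominator not in ("mapped", "scaffold_length"):
        raise ValueError("denominator must be 'mapped' or 'scaffold_length'")
    if (hits["mapped_bp"] < 0).any():
        raise ValueError("negative mapped_bp")
    if hits["chromosome"].isna().any() or (hits["chromosome"].astype(str) == "").any():
        raise ValueError("missing target chromosome label")
    if valid_chromosomes is not None:
        unknown = set(hits["chromosome"].astype(str)) - set(valid_chromosomes)
        if unknown:
            raise ValueError(f"unknown chromosome labels: {sorted(unknown)}")

    lengths = hits.groupby("scaffold_id")["scaffold_length"].first()
    per_target = (
        hits.groupby(["scaffold_id", "chromosome"], sort=True)["mapped_bp"]
        .sum()
        .reset_index()
    )

    rows = []
    for scaffold_id, grp in per_target.groupby("scaffold_id", sort=True):
        total = int(grp["mapped_bp"].sum())
        denom = float(total) if denominator == "mapped" else float(lengths[scaffold_id])
        if total < min_mapped or denom <= 0:
            rows.append((scaffold_id, UNASSIGNED, UNASSIGNED, total, 0.0, 0.0))
            continue
        is_z = grp["chromosome"].astype(str) == "Z"
        z_bp = int(grp.loc[is_z, "mapped_bp"].sum())
        a_bp = total - z_bp
        z_share = z_bp / denom
        a_share = a_bp / denom
        class_fraction = max(z_share, a_share)
        if z_share > class_fraction_cutoff:
            chrom_class = "Z"
        elif a_share > class_fraction_cutoff:
            chrom_class = "A"
        else:
            chrom_class = UNASSIGNED
        # second pass: single best chromosome, ties broken by label for determinism
        grp_sorted = grp.sort_values(
            ["mapped_bp", "chromosome"], ascending=[False, True]
        )
        best = grp_sorted.iloc[0]
        chromosome_fraction = float(best["mapped_bp"]) / denom
        chromosome = (
            str(best["chromosome"])
            if chromosome_fraction > chromosome_fraction_cutoff
            else UNASSIGNED
        )
        rows.append(
            (scaffold_id, chrom_class, chromosome, total, class_fraction, chromosome_fraction)
        )

    return pd.DataFrame(
        rows,
        columns=[
            "scaffold_id",
            "chrom_class",
            "chromosome",
            "total_mapped_bp",
            "class_fraction",
            "chromosome_fraction",
        ],
    )


def genes_to_chromosomes(
    assignment: pd.DataFrame, genes: pd.DataFrame
) -> pd.DataFrame:
    """Propagate scaffold labels to genes.

    ``genes`` needs columns gene_id and scaffold_id. Genes on scaffolds
    absent from the assignment raise; genes on unassigned scaffolds come back
    labeled unassigned (they are excluded from class-based statistics
    downstream but still receive expression values).
    """
    if "gene_id" not in genes.columns or "scaffold_id" not in genes.columns:
        raise ValueError("gene table needs gene_id and scaffold_id columns")
    idx = assignment.set_index("scaffold_id")
    unknown = set(genes["scaffold_id"]) - set(idx.index)
    if unknown:
        raise ValueError(f"genes reference unknown scaffolds: {sorted(unknown)[:5]}")
    out = genes[["gene_id", "scaffold_id"]].copy()
    out["chrom_class"] = idx["chrom_class"].reindex(genes["scaffold_id"]).to_numpy()
    out["chromosome"] = idx["chromosome"].reindex(genes["scaffold_id"]).to_numpy()
    return out
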