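# Methods

This note documents the models, estimators and numerical choices behind
`zwdose`, and what the synthetic data generator does and does not emulate.

## Scaffold-to-chromosome assignment

Input is a coverage table with one or more rows per (scaffold, target
chromosome): scaffold id, scaffold length, target, mapped bp. Rows are
summed per pair; mapped bp may legitimately exceed scaffold length in total
because local alignments overlap.

Rules, in order:

* scaffolds with total mapped bp < `min_mapped` (default **200 bp**) are
  uninformative → class and chromosome `unassigned`;
* **class pass**: the Z share and the pooled-autosome share of the
  denominator are compared against `class_fraction_cutoff` (default
  **0.95**, strict `>`);
* **chromosome pass**: the single best target's share against
  `chromosome_fraction_cutoff` (default **0.90**, strict `>`), ties between
  equally covered targets broken by label so output is order-independent.

The share denominator is **total mapped bp** by default. Dividing by the
full scaffold length is also supported (`denominator="scaffold_length"`),
but over deep divergence between a draft assembly and a reference genome
most scaffold sequence does not align at all, and under the scaffold-length
reading almost nothing clears a 95% bar; the mapped-bp reading is the one
under which realistic assignment rates arise. The two passes are
independent, so a scaffold can have an individual chromosome (share > 0.90)
while its class stays unassigned (share ≤ 0.95).

Genes inherit their scaffold's labels; genes on unassigned scaffolds are
excluded from class-based statistics but still receive expression values.

## Autosome-anchored modified-quantile normalization

Per library, restrict to autosomal genes, drop zero counts, remove the
`ceil(0.25 · n_nonzero)` highest-count genes and return the sum of the
remaining counts as the scale factor `F_j`. Ties at the quartile boundary
are broken by gene id (lexicographically smaller ids removed first), a
deterministic rule chosen because any tie rule is arbitrary and this one is
reproducible across runs and row orders. Anchoring on autosomes only keeps
the factor independent of the sex-asymmetric Z; summing *below* the upper
quartile makes it insensitive to a handful of extremely expressed genes,
which dominate plain per-million scaling in whole-body insect libraries.

`F_j` replaces the per-million term of FPKM:
`FPKM = count · 1e9 / (length_bp · F_j)`. The `1e9` is forced by FPKM
semantics (kb × "per-million-like" factor) once `F_j` takes the place of
total mapped reads. A library whose autosomal counts are all zero (or fewer
than 4 nonzero) cannot be scaled and raises.

Replicate QC is pairwise tie-corrected Spearman correlation within each
sex × stage group (constant columns give a missing rho); replicates are then
collapsed by the arithmetic mean FPKM per gene.

## Dosage statistics

All ratio inference is on **medians** — expression is heavily right-skewed
and medians are robust to the filtering steps; means are reported nowhere
as inferential quantities.

* **Z:A** per sex × stage: genes with zero group-mean FPKM are dropped
  separately for each cell; point = median(Z FPKM) / median(A FPKM).
* **M:F** per class × stage: restricted to genes with positive group-mean
  FPKM in *both* sexes of the stage.
* **CI**: percentile bootstrap, default **10,000** iterations, 2.5/97.5
  percentiles. Genes are the exchangeable units, so the numerator and
  denominator gene sets are resampled independently with replacement at
  their original sizes. For M:F the two sides cover the same genes, and a
  paired scheme would also be defensible; the independent scheme is used
  uniformly so one estimator backs every ratio. Identical seeds give
  identical intervals.
* **Mann–Whitney U**: exact enumeration when both groups have < 8
  observations, otherwise the tie-corrected normal approximation with
  continuity correction. The exact path enumerates the permutation
  distribution of U by dynamic programming on doubled midranks, so it is
  exact under ties too; fully tied data short-circuits to p = 1. The
  two-sided exact p is `min(1, 2·min(P(U ≤ u), P(U ≥ u)))`.
* **Per-chromosome tests**: tie-corrected Kruskal–Wallis over all
  individually assigned chromosomes, then Dunn's z for the Z against each
  autosome using pooled midranks and the tie-corrected variance
  `(N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/n_i + 1/n_j)`. Dunn p-values are
  reported unadjusted by default — the common convention for this post-hoc
  test when each comparison is read against a fixed 0.05 line — with
  optional BH/Holm adjustment.
* **Quartile analysis**: Z genes ranked by their *maximum* group-mean FPKM
  in either sex (ties by gene id), cut into four equal bins with remainders
  to the lower bins; M-vs-F Mann–Whitney within each bin. A chromosome-wide
  dosage mechanism predicts a uniform sex difference across bins, whereas
  saturation-driven dose effects concentrate in the top bins.
* **Exclusion rerun**: every statistic is recomputed after removing, per
  stage, the genes labeled male- or female-biased at that stage. Both runs
  share a bootstrap seed, so an empty exclusion set reproduces the full run
  bit for bit.

## Negative-binomial sex-bias test

Per stage (3 F vs 3 M by default), per gene:

    count[g,j] ~ NB(mu, alpha_g),  Var = mu + alpha·mu²
    log mu = log sf_j + b0 + b_sex·1[male] + family dummies

`sf_j` are the autosome-anchored scale factors rescaled to unit geometric
mean (a baseMean convention; baseMean is the mean of `count/sf` across the
stage's samples). Family enters as a known covariate — the observable batch
structure of a sibling-group design — rather than via latent surrogate
variables; dummy columns that would make the design rank-deficient are
dropped.

Dispersion estimation, the crux at 3 + 3 replication:

1. Poisson pre-fit; residual-df-corrected Pearson moments
   `alpha = (n/(n−p)·Σ(y−mu)² − Σmu) / Σmu²` give provisional values
   (possibly negative; kept unclipped so their conditional mean is
   unbiased).
2. A trend `alpha(mu) = a0 + a1/mu` is fitted by iteratively reweighted
   non-negative least squares with weights `1/trend` (gamma-family-like),
   top 2.5% of values winsorized.
3. NB re-fit at the trend, then per-gene dispersion by **Cox–Reid-adjusted
   profile likelihood** on an 80-point log grid over [1e-5, 30], holding
   fitted means fixed (the CR term `−0.5·logdet(XᵀWX)` corrects the severe
   small-sample downward bias of moment/ML estimates).
4. The trend is re-fitted through the CR estimates and each gene's value is
   shrunk toward it in log space with weight 0.75, its influence capped at
   a factor 8 either side of the trend.

The sex coefficient is tested two-sided against a normal reference
(Wald `z = b_sex/SE`), BH-adjusted over the tested genes. On simulated null
data at 2,000 genes this pipeline keeps the raw P < 0.05 rate at ~4–5%
(the suite asserts 2.5–7.5%); a planted |log2FC| = 2 at mean 500 and
dispersion 0.05 is detected essentially always at 3 + 3.

GLM fitting is batched IRLS across genes (shared design, per-gene weights),
with the linear predictor clipped to ±30. Non-convergent genes — typically
one sex entirely at zero — are re-fitted on `count + 0.5` (pseudo-count
moment fallback) and flagged; their log2FC is finite but conservative.

Low-expression filtering before testing: genes with nonzero counts in at
most one sample of the whole matrix are removed, then genes whose mean
count is below 1 in *every* sex group of the contrasted stage (retaining a
gene if either sex group reaches mean ≥ 1, since genuinely sex-limited
expression should not be discarded).

Labels: male-biased iff padj < 0.05 **and** log2FC > 1 **and**
baseMean > 10; female-biased symmetrically; otherwise unbiased.
Enrichment of a biased set on the Z uses Fisher's exact test on the
2×2 (biased vs not) × (Z vs A) table, with the two-sided p defined as the
sum of hypergeometric outcomes no more probable than the observed one and
the conditional-MLE odds ratio; an empty margin reports p = 1 and a missing
odds ratio.

## Synthetic data generator

The generator emulates a whole-body bulk RNA-seq study of a ZW butterfly.
Defaults (the study conditions): 20 autosomes, 13,442 autosomal and 405
Z-linked genes on Poisson-sized scaffolds (mean 14 genes), gene lengths
log-normal (median 1 kb, sdlog 0.6, floor 100 bp); three stages ×
{3 F, 3 M} from 4 families, two families crossed with sex within each
stage so the family covariate stays estimable; baseline expression rates
log-normal (median 30 reads/kb — a deep library — sdlog 1.5); NB dispersion
`0.05 + 2/mu` with log-normal gene jitter (sd 0.3); Z dose multipliers
`d_z_male = d_z_female = 0.5` (incomplete compensation); per-stage biased
fractions 1.5% / 3.5% / 27% with nested sets (larva ⊆ pupa ⊆ adult),
planted effect |log2FC| = 2 applied symmetrically (`×2^(+e/2)` in the
biased sex, `×2^(−e/2)` in the other) so the true coefficient equals the
nominal effect; male-biased genes drawn with Z odds 1.5, which realizes
~20% of Z genes male-biased in adults at these gene counts; one
multiplicative log-normal batch factor per (family, gene) with log-sd 0.1.
Alignment tables give each scaffold an on-target mapped fraction drawn from
a Beta with mean `alignment_purity` (default 0.98, concentration 300) plus
one off-target row, and 20% of scaffolds fewer than 200 total mapped bp
(mirroring the fraction of uninformative scaffolds typical of a draft
assembly vs distant reference).

Everything is deterministic given the seed, with independent sub-streams
for genome, alignment and counts.

**What it does not emulate**: read-level error, positional/GC bias,
isoforms, gene–gene correlation, tissue composition shifts across
metamorphosis, dominance of gonadal transcripts in adults, or technical
(flow-cell) batch other than the family factor. Passing recovery tests on
this generator therefore demonstrates that the estimators recover the
planted dose, bias and enrichment structure under NB sampling with batch
noise and imperfect chromosome assignment — not that every biological
confound of a real study is handled.

## Pipeline, seeds, problem sizes

`run_pipeline` fans its single seed into per-stage child seeds via
`SeedSequence`, so stage-level reruns are reproducible and any seed placed
inside the sim block is overridden (the resolved config written beside the
outputs records what was used). Exit codes in the CLI: 0 ok, 2 config
error, 3 data error.

The test suite runs its recovery checks at a mixture of scales: the full
13,442 + 405 genome for the dosage-band and complete-compensation checks
(bootstrap scaled to 2,000 iterations there and in `scripts/acceptance.py`;
point estimates are unaffected and CI endpoints stabilize well below that),
2,000-gene simulations for DE calibration, 100-replicate batteries for
enrichment and CI coverage, and 50 replicates for the exclusion-direction
property. `scripts/acceptance.py` runs the default full-scale study
end-to-end and writes every headline quantity it computes.

## Known limitations

* The Wald test, even with CR-profile dispersions, is approximate at 3 + 3;
  the suite pins its null behavior empirically rather than by theory.
* The independent-resampling bootstrap ignores the M:F pairing of genes;
  its CIs for M:F are mildly conservative.
* Scaffold assignment carries no synteny model: a fused or rearranged
  reference chromosome maps cleanly but wrongly, exactly as in real
  homology-based assignment.
* Dunn p-values are unadjusted by default; with 20 autosome comparisons a
  per-family error rate requires the optional BH/Holm flags.
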