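# Methods

This note documents the models, parameters and design choices behind
`ribostate`, in the order the pipeline runs. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Input data and quality control

The pipeline consumes cell × gene UMI count matrices (Matrix Market
directories with barcode/feature sidecars, or dense CSV with an
orientation flag), cell metadata keyed by `cell_id`, and GMT gene-set
collections. Counts must be non-negative integers with unique
identifiers on both axes.

Cell QC removes cells with **strictly fewer than 200 detected genes**
(the one protocol-stated rule; the boundary cell with exactly 200 genes
is kept) and, inclusively, cells above a mitochondrial-fraction cap
(default 0.2, genes identified by the configurable `MT-`/`mt-` prefix),
outside optional total-count bounds, or below an optional
log₁₀(genes)/log₁₀(counts) complexity floor. The extra thresholds are
conventional defaults — the protocols they come from list the criteria
but not the values — and every removal count is reported per criterion.
Filtering is idempotent.

Normalization is library-size scaling to `scale_factor` (default 10,000)
followed by natural log1p, so each cell's pre-log values sum to the
scale factor exactly. Highly variable genes (default 2,000) are ranked
by mean-binned standardized dispersion of the log data: genes are
quantile-binned by mean (20 bins, ≥5 genes per bin) and the dispersion
(variance/mean) z-scored within each bin, preventing highly expressed
genes from dominating. This is a deliberately simple dispersion
criterion implemented in-house; it behaves sensibly on the tiny
matrices the test suite uses, which heavier loess-based selectors do
not.

## Program discovery (per-sample NMF)

Samples with fewer than `min_epithelial_cells` = 200 cells are skipped
(logged). For each remaining sample the log-normalized HVG matrix is
**z-scored per gene within the sample and clipped at 0** before
factorization. Centering removes per-gene baseline expression, so
components capture above-average co-expression rather than absolute
abundance — without it, a handful of highly expressed housekeeping-like
genes loads on every component and later pollutes the frequency-based
signature. This follows established metaprogram practice for per-tumour
NMF.

Factorization is multiplicative-update NMF under the Frobenius
objective, implemented in-house so the per-iteration objective is
available: multiplicative updates make the objective non-increasing,
and the recorded trace lets callers (and the test suite) assert
monotonicity on every factorization. Initialization is uniform random
from a generator seeded by (config seed, rank); convergence is a
relative objective change below `tol` = 1e-4 between evaluations (every
`objective_every` = 10 iterations) or `max_iter` = 200 iterations.
A coordinate-descent reference implementation (scikit-learn) serves as
an independent fit-quality cross-check in the tests, not as the
implementation.

The sweep covers ranks 2–10, emitting Σ₍ᵣ₌₂₎¹⁰ r = 54 programs per
sample. Each program carries its gene-coefficient vector, its cell-score
column of W, the fraction of the sample's cells assigned to it (arg-max
across the rank's programs, ties to the lowest index, all-zero cells to
program 0 with a warning; fractions sum to 1 per rank), and its top
`n_top_genes` = 200 genes by coefficient (ties broken lexicographically).
Program scores are the raw W columns; an analyst can row-normalize
before assignment, but raw scores are kept for the correlation stage.

## Reference scoring and mean-maxed selection

Reference ribosome gene sets (any K ≥ 1; the expected use is the five
published ribosomal signatures) are scored per cell with the rank-based
scorer (below). Because the scorer is invariant to monotone transforms
of a cell's expression vector, reference scoring runs on the QC'd counts
over all genes rather than the lognorm layer — the scores are identical.

Each program's cell scores are Pearson-correlated with each reference
score within the program's own sample; the mean over the K references is
R_mean. Zero-variance program scores get r = 0 with a warning, so
degenerate programs can never win selection. A Spearman option exists;
Pearson is the default.

Per sample, the **mean-maxed program** maximizes R_mean among candidates
satisfying both selection criteria: (1) the program's own rank
decomposition contains at least `min_programs_above_fraction` = 2
programs with cell fraction > `min_cell_fraction` = 0.10 — the candidate
itself need not be one of them, since genuinely small ribosome programs
are reported in the source analyses; (2) R_mean > 0.1 (strict). Ties
break to the lower rank, then lower index. Samples with no qualifying
candidate select nothing.

All programs' K-dimensional correlation profiles are clustered by
Ward-linkage agglomerative clustering (Euclidean metric, default
`n_clusters` = 3: ribosome-like / neutral / anti). The ribosome-related
cluster is the one with the highest mean R_mean, the anti-program
cluster the lowest; they must differ (k = 1 is an error here). The
fraction of mean-maxed programs falling in the ribosome cluster is
logged as a coherence check. Clustering all programs (rather than a
pre-filtered subset) is the pipeline default; the cluster operation
itself accepts whatever profile set it is given.

## Signature assembly

Gene frequency counts membership: the number of source programs whose
top-200 list contains the gene, not coefficient weight. The metagene
("ribosomal state") signature keeps genes at frequency ≥
`metagene_min_frequency` = 10 (inclusive), ordered by decreasing
frequency then gene id. The anti-signature keeps genes in more than two
anti-programs (frequency ≥ 3) and removes any overlap with the metagene
signature, recording the excluded genes; disjointness is asserted on
every run. Raising either threshold can only shrink the signature.

On a null run (no program correlates with the references) the pipeline
completes with the degenerate outcome on record — no mean-maxed
programs, or no gene reaching the frequency floor — rather than
aborting; the standalone assembly functions still raise in those cases.

## Per-cell and bulk scoring

The per-cell scorer ranks genes by decreasing expression within each
cell (average ties by default; `min` available), clips ranks beyond
`max_rank` = 1500 to `max_rank + 1`, and maps the signature's
Mann–Whitney U statistic to [0, 1]:
score = max(0, 1 − U/(n·r_max)). 1500 and average ties are the
published defaults of this scorer family. Signature genes absent from
the matrix are dropped with a warning (silently treating them as
unexpressed would bias scores under symbol-case or cross-species
mismatches); an empty effective signature is an error.

The bulk scorer is a single-sample enrichment walk: genes get ascending
ranks (top gene = G), are traversed in decreasing order, and the score
sums the in-set ECDF weighted by |rank|^α (α = 0.25) minus the uniform
out-of-set ECDF. Raw enrichment is reported; an optional flag min-max
normalizes across samples. A signature covering every gene leaves the
out-of-set ECDF undefined and is rejected.

`scale_scores` z-scales score columns (sample sd, ddof = 1) for the
sign-rule subtype classifier, which labels a cell subtype A when its
up-A and down-B scores are above zero and its up-B and down-A scores
below zero (B symmetric; anything else, including exact zeros, is
unassigned). Inputs whose column means exceed a tolerance are rejected
with a pointer to `scale_scores`. The analogous cluster-level definition
in the source material is ambiguous and is not implemented.

## Tissue prevalence (Ro/e)

Observed cell-type × condition counts are cross-tabulated; expected
counts come from the χ² independence model
(row_total × col_total / grand_total), so observed and expected totals
always agree and Ro/e is invariant to uniform count scaling. Values > 1
indicate enrichment, < 1 depletion. Cells with expected 0 (an empty
level) are flagged undefined rather than propagating infinities.

## Survival stratification

The log-rank statistic is the k-group Mantel–Haenszel sum of observed
minus expected events over event times with hypergeometric covariance;
the statistic is the quadratic form over k−1 groups (generalized inverse)
against χ²ₖ₋₁. Kaplan–Meier curves use the product-limit estimator
(lifelines). Degenerate tables with zero total variance return the null
(statistic 0, p 1).

The optimal-cutoff scan evaluates every **distinct observed score**
within the inclusive 10th–90th percentile window (not a percentile
grid), splitting at score > cutoff (strict). Ties on p break to the more
balanced split, then the lower cutoff. The best cutoff and p, plus the
full scan trace, are returned; the best p is the trace minimum by
construction. Minimum-p selection inflates type-I error — this is a
property of the procedure, acknowledged and *measured* by the null
calibration (the acceptance script reports the fixed-cutoff and
minimum-p rejection rates side by side), not corrected.

The three-group scheme splits subjects at the marker mean (strictly
above = high; ties go low), then applies the optimal score cutoff
computed within the marker-high subgroup alone (which must contain ≥10
subjects, configurable), and reports the three-group log-rank.
Multivariate proportional-hazards modelling is deliberately out of
scope; standard survival-regression packages cover it.

## Synthetic data generator

The generator emulates the statistical structure the discovery pipeline
assumes, with these defaults as the standing study conditions:

| parameter | default | meaning |
|---|---|---|
| n_samples × cells × genes | 5 × 1,000 × 2,000 | cohort dimensions |
| planted programs | 3 × 200 genes | disjoint gene blocks |
| activity law | lognormal(−0.5, 0.8) | per-cell program activity |
| loading_strength | 3.0 | program loading scale (× U(0.5, 1) per gene) |
| baseline | Gamma(0.8, 1) per gene | shared expression floor |
| sample_gene_sd | 0.6 | per-sample lognormal gene-scale jitter |
| baseline_dispersion | 0.3 | NB overdispersion (gamma-Poisson) |
| library_size_mean / sd | 2,500 / 0.35 | lognormal per-cell depth |
| reference sets | 5 × 100 genes, 50% in-program | planted "ribosome" signatures |

A cell's relative expression is baseline plus activity-weighted
loadings, normalized and scaled by a lognormal library size; counts are
gamma-Poisson (negative binomial). One planted program is designated the
ribosome program and each reference set draws half its genes from it
(the rest from background), mirroring the premise that a real
ribosome-biogenesis program correlates with published signatures without
equalling any of them. Program sizes of 200 genes reflect the realistic
scale of the ribosome-biogenesis complement (ribosomal proteins plus
processing/assembly factors) and match the top-200 program
summarization. The per-sample gene-scale jitter encodes inter-tumour
expression heterogeneity; without it, sample-invariant background genes
recur across programs and dilute the frequency-thresholded signature —
with it, only genuinely program-linked genes recur across samples.

Ground truth (per-cell activities, program gene lists, reference sets,
planted low-quality cells) is returned with the data, sufficient to
score any recovery metric without re-simulation. All generators are
pure functions of their configs; a fixed seed reproduces output
bit-for-bit. Optional planted low-quality cells receive a ~100-count
library so they fail the 200-detected-genes rule.

Survival cohorts draw scores from a configurable distribution and give
subjects above `true_cutoff` a hazard multiplied by the configured
ratio; event times are exponential, censoring is an independent
exponential calibrated to the requested overall rate (exact at hazard
ratio 1, approximate otherwise). Tissue tables are multinomial draws
from a cell-type × tissue weight matrix.

What the generator does **not** emulate: ambient RNA, doublets, batch
effects, cell-cycle structure, or non-exponential hazards. Passing
recovery tests therefore demonstrates the pipeline's correctness under
its own model assumptions, not robustness to those artifacts.

## Problem sizes and seeds

The default discovery preset (5 × 1,000 × 2,000, ranks 2–10) runs the
full pipeline in roughly a minute on one CPU and is used directly by
the end-to-end tests and the acceptance script. The null-calibration
pipeline run uses 3 samples × 1,000 cells × 1,000 genes with ranks 2–6:
1,000 cells keeps the null sampling distribution of the program-
reference correlations at the scale the selection thresholds were
designed against, while the reduced gene count and rank range keep the
run brief. Null survival calibration uses 200 replicates (fixed cutoff)
and 100 replicates (minimum-p scan); cutoff recovery uses 100 replicates
at n = 300, hazard ratio 3, true cutoff at the 40th score percentile.

A single global seed fans out to per-stage seeds by hashing
`"{seed}:{stage}"` (blake2s, reduced mod 2³¹), so any stage can be
re-run in isolation reproducibly and adding a stage never perturbs the
others.

## Known limitations

* The NMF is a single seeded run per rank — no consensus restarts or
  automatic rank selection; conclusions about a specific decomposition
  carry the usual local-optimum caveat.
* The frequency thresholds (10 for metagenes, 3 for anti-genes) are
  absolute counts; cohorts much smaller or larger than the intended
  scale may need them rescaled.
* The minimum-p cutoff is reported without multiplicity adjustment, by
  design; its p-values are exploratory.
* Doublet detection, batch integration, clustering/annotation and
  trajectory analysis are out of scope — upstream tools exist for all
  of them.
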