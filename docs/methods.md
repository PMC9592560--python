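# Methods

## The stem cell index

The index places each tumor on the axis between the two intestinal stem-cell
programs: the LGR5⁺ crypt-base columnar (CBC) program and the LGR5⁻
regenerative (RSC) program. Each program is represented as a gene signature,
each sample receives a single-sample enrichment score per signature, and the
index is `RSC score − CBC score`. The key modelling assumption is that a bulk
transcriptome is (approximately) a convex mixture of the two epithelial
archetypes plus non-epithelial tissue, so relative enrichment of one program
over the other is meaningful even when absolute purity is not.

### Single-sample enrichment

Scores are computed with a kernel-CDF rank random-walk estimator. For gene
*i* with expression `x_i1 … x_in` across the cohort:

1. **Kernel CDF.** `z_ij = (1/n) Σ_k K((x_ij − x_ik))`, where K is the
   Gaussian CDF with per-gene bandwidth `sd_i / 4` (continuous data), the
   Poisson CDF with rate `x_ik + 0.5` (integer counts), or the empirical CDF
   (`kernel="none"`). Because the CDF estimate is relative to the cohort,
   *scores depend on cohort composition*; the result object carries a cohort
   fingerprint (n, gene count, content hash) so scores from differently
   normalized cohorts are never silently mixed.
2. **Ranking.** Within each sample genes are ranked by decreasing `z`, ties
   broken by input gene order (stable sort — deterministic), and the
   symmetric rank statistic `r_ij = |p/2 − rank_ij|` is formed (p = number of
   genes). The symmetrization puts extreme genes at either end on an equal
   footing.
3. **Walk.** Down the ranked list, in-set genes add `r^τ / Σ_set r^τ`
   (default τ = 1), out-of-set genes subtract `1/(p − m)` for a set of size
   m. Both step families sum to 1, so the walk — and every score — lies in
   [−1, 1].
4. **Score.** Default is the sum of the maximum positive and minimum
   negative deviations ("diff-of-extremes"); the single largest-magnitude
   deviation ("max-deviation") is available.

A signature must overlap the measured genes by at least `min_set_size`
(default 2, maximum 500) and must not cover all genes (the out-of-set step
would be undefined).

For RNA-seq the default pipeline feeds the Gaussian kernel with
`log2(TMM-CPM + 1)`; scoring raw counts with the Poisson kernel is a
configuration away. Microarray intensities are collapsed to one value per
gene (arithmetic mean over probes) and scored with the Gaussian kernel.

### TMM normalization

Scaling factors follow the trimmed-mean-of-M-values scheme: reference sample
= upper-quartile depth closest to the cohort mean; per sample, genes
expressed in both sample and reference contribute a log-ratio M and
intensity A; 30% (M) and 5% (A) are trimmed on each side by rank; the factor
is 2 to the precision-weighted mean of surviving M values, with weights from
the delta-method variance of M; factors are rescaled to geometric mean 1 and
multiply library sizes before CPM. The implementation is cross-checked in
the test suite against both a literal transcription of the formulas and the
reference R implementation (edgeR `calcNormFactors`).

## Signature refinement

A candidate signature is restricted to genes of predominantly epithelial
origin using single-cell data:

- **Pseudobulk.** Raw counts are summed per (cell type, patient). The
  patient is the replication unit throughout.
- **Specificity rule.** A gene is specific to cell type c iff its
  depth-adjusted total pseudobulk (cell-type totals rescaled to a common
  library size) exceeds every rival cell type by ≥ 1 raw count *and* every
  pairwise Welch t-test of log1p-CPM patient replicates (c vs rival) has
  p < 0.01. The test choice is a design decision: patient-level pseudobulk
  replicates are the only replication structure available, and the unequal-
  variance t-test makes no variance-equality assumption across cell types.
  At most one cell type can win (strict inequalities in all directions).
- **Cluster exclusion.** Signature genes are clustered on z-scored
  cell-type mean log-CPM profiles (distance 1 − Pearson r, average linkage,
  k = min(8, ⌊n/5⌋) flat clusters). A cluster is removed when its centroid
  is stromal-dominant, epithelial but with stromal z > 0.5, flat
  (max z < 0.5), or dominated by any non-epithelial type (the
  `keep_epithelial_only` default, reflecting that only epithelial-origin
  genes belong in a tumor-cell signature). These thresholds replace manual
  cluster inspection with a reproducible rule and are configurable.
  Refinement preserves input order, returns a subset, and is idempotent on
  its own output for a fixed pseudobulk.

Note that per-gene z-scoring makes any single gene's profile full-scale by
construction; flatness is therefore a property of cluster *centroids*, where
incoherent directions average out.

## Single-cell classification

QC follows the standard gates (> 1000 UMI strict, < 30% mitochondrial
strict, 2000–6000 detected genes inclusive — boundary strictness is a
literal reading of the stated rules). Logcounts are `log1p` of counts
depth-normalized to 10,000 per cell (the common single-cell convention; the
target is configurable). A cell's signature value is the mean logcounts over
signature genes present in the matrix. Positivity cutoffs are the 95th
percentile (linear interpolation) of the signature values in the population
— motivated by the prior expectation that ~5% of cells are true CBC cells —
rounded to the nearest 0.05 logcounts with half-up ties; a rounding step of
0 disables rounding. Classification is strict: mixed = both values above
their cutoffs, CBC/RSC = only one above, negative otherwise.

The recovery analyses in the test suite and acceptance script use unrounded
cutoffs: the 0.05 grid is a reporting convention whose effect depends on
where an arbitrary expression scale happens to fall, and at a 95th-percentile
operating point a grid shift of half a step moves a material fraction of
true positives across the boundary. A structural note on double-positive
cells: with 5% CBC + 1% mixed cells all carrying an elevated CBC program,
6% of cells compete for a cutoff that passes 5%, so roughly one in six
elevated cells necessarily falls below it; per-class recovery is therefore
assessed for the CBC and RSC classes, and mixed-class performance is
reported without a hard bound.

## Cohort analytics

- **Polarized deciles** rank samples by the index; the lowest and highest
  10% (round(0.1·n) each) are the CBC- and RSC-enriched deciles. Ties break
  by CBC score (descending) then sample id. The two-signature
  above-median predominance view is emitted as a report, not used for
  selection.
- **CNV categorization**: segment mean < −0.3 → loss (−1), > 0.3 → gain
  (+1), else neutral; strict on both sides; thresholds configurable.
- **Plasticity**: index > 0 → RSC-positive, otherwise CBC-positive (an
  exact zero — a measure-zero event on continuous scores — is classed
  CBC-positive under the strict reading of "positive"); a patient is
  plastic iff the class flips between the pre- and post-treatment sample.
  Responders are patients with moderate or marked histological regression.
  The static/plastic × responder/non-responder table is tested with the
  two-sided Fisher exact test (sum of hypergeometric probabilities not
  exceeding the observed table's); the odds ratio is the sample OR with a
  Haldane 0.5 correction when a cell is zero.
- **Reproducibility**: one-way random-effects ANOVA with the unbalanced
  design coefficient `k0 = (N − Σn_i²/N)/(a − 1)`;
  `σ²_b = max((MSB − MSW)/k0, 0)`, `σ²_w = MSW`, ICC(1,1) =
  σ²_b/(σ²_b + σ²_w) (cross-checked against pingouin). CVs are
  100·σ/|grand mean|. A CV on a signed index is ill-defined near zero mean,
  so CVs are reported as NaN (with a warning) when |grand mean| falls below
  tolerance; the ICC is returned regardless. Zero total variance yields
  ICC 0 with a warning.

## Synthetic data

The generators provide ground truth for every stage; all draws are
deterministic under a top-level seed expanded into per-component streams via
`numpy.random.SeedSequence`.

- **Bulk** (`BulkSimConfig`): expected profile per sample
  `(1−c)·[(1−f)·CBC + f·RSC] + c·stromal`, where the archetypes share a
  lognormal baseline with 100-gene marker blocks elevated 2² = 4-fold
  (default `effect_lfc = 2`), the stromal profile additionally depletes
  both stem blocks, `f` spans a uniform grid over [0, 1] by default, and
  counts are negative binomial with dispersion 0.2 at library sizes
  0.5–2 M. Defaults: 100 samples × 2000 genes — large enough for stable
  kernel CDFs, small enough that a multi-seed recovery run takes seconds.
- **Single cell** (`ScSimConfig`): seven populations (CBC 5%, RSC 5%,
  mixed 1%, other-epithelial 59%, stromal 15%, myeloid 10%, lymphoid 5%)
  across 5 patients × 400 cells, allocated by exact largest-remainder
  counts per patient so planted class balance is exact for recovery
  scoring. Each population has a 30-gene marker block at 2³-fold (mixed
  cells elevate both stem blocks; all epithelial populations share a
  50-gene epithelial block; stroma carries 50 extra markers), 10 mito
  genes carry ~5% of a healthy transcriptome, and counts are multinomial
  at lognormal depth (median 7000 UMI, log-sd 0.2 — placed so that
  healthy cells always satisfy the QC gates, which is part of the
  generator's contract). A planted 5% low-quality fraction has depth
  100–800 UMI and a mito-dominated profile and must fail QC.
- **Paired** (`PairedSimConfig`): 75 patients, 40% plastic, index
  magnitude 0.3 with noise sd 0.05 (separation ≫ noise, so the sign rule
  recovers labels exactly), responder rates 0.6 (static) vs 0.2 (plastic).
- **Biopsies**: tumor effects N(0, ρσ²) plus noise N(0, (1−ρ)σ²) around a
  grand mean; defaults ρ = 0.821, mean 1.0, σ = 0.3, i.e. design CVs of
  ~12.7% within- and ~27.2% between-subject — the reproducibility regime
  of multiregional-biopsy studies of this index.

### What the generators do and do not emulate

They reproduce the *structure* the analyses rely on — mixture composition,
population markers, per-patient replication, planted truth — but not the
full texture of real data: no batch effects, no gene–gene correlation beyond
the block structure, no zero-inflation beyond NB/multinomial sampling, no
ambient RNA or doublets, and human-scale gene counts are down-sampled
(2000 bulk / 8000 single-cell genes). Passing recovery tests therefore
demonstrates correctness and calibration of the algorithms under the stated
generative assumptions, not performance on any particular clinical dataset.

## Numerical choices and degenerate inputs

- Sort-based ties (enrichment ranking, decile boundaries) break by input
  order / sample id — documented and deterministic.
- Zero-variance genes in the Gaussian kernel get a tiny bandwidth (1e-8),
  reducing to a step CDF.
- Percentile-cutoff rounding guards the quotient against binary
  representation error so exact halves genuinely round up.
- Pseudobulk cell types with a single patient raise an error (the pairwise
  test is undefined) rather than silently skipping the significance arm.
- All-zero samples are rejected by TMM; empty QC pass-sets, empty refined
  signatures and degenerate Fisher margins warn instead of failing.

## Known limitations

- The published 265-gene RSC signature is not bundled (it derives from an
  external accession); users supply their own GMT. Small illustrative
  marker sets are used in examples.
- Enrichment scores are cohort-relative; single-sample absolute calls
  across cohorts require a shared normalization frame.
- The specificity test treats patients as exchangeable replicates and
  ignores within-patient cell-count imbalance beyond depth adjustment.
- CV-based reproducibility summaries are only meaningful when the cohort's
  index distribution sits away from zero.
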