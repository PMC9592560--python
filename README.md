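# stemindex

Colorectal tumors harbor two transcriptionally distinct stem-cell
compartments: LGR5⁺ crypt-base columnar cells (CBC), the homeostatic
intestinal stem cell, and LGR5⁻ regenerative stem cells (RSC) expressing a
fetal/repair program (ANXA1, CLU, PLAUR/LY6A). Individual tumors sit on a
continuum between these poles, and their position — and their ability to
shift along it under therapy — carries biological and clinical information.

`stemindex` quantifies that continuum. For a cohort of bulk transcriptomes it
computes the **stem cell index**

```
index_j = ES_RSC(j) − ES_CBC(j)
```

where `ES_S(j)` is a single-sample enrichment score of signature *S* in
sample *j*, computed with a kernel-CDF rank random-walk estimator
(GSVA-style): per-gene kernel CDF estimates across the cohort (Gaussian
kernel, bandwidth s/4, for continuous data; a Poisson mixture kernel for raw
counts), symmetric rank statistics |p/2 − rank|, and a weighted
Kolmogorov–Smirnov-like walk whose in-set steps are proportional to
rank-statistic^τ and whose score is the sum of the maximum positive and
minimum negative deviations (∈ [−1, 1]). A positive index means the tumor is
RSC-skewed; negative means CBC-skewed. RNA-seq counts are first normalized
with TMM scaling factors applied to counts-per-million; microarray probes are
collapsed to genes by the per-gene mean.

Around the index, the package implements the companion analyses:

- **signatures** — GMT IO, pseudobulk aggregation of single-cell counts,
  the cell-type specificity rule (higher than every rival cell type by ≥ 1
  depth-adjusted raw count with all pairwise patient-replicate tests at
  p < 0.01), hierarchical-clustering signature refinement to epithelial
  genes, and mouse/human ortholog mapping.
- **single_cell** — QC gates (> 1000 UMI, < 30% mitochondrial, 2000–6000
  detected genes), per-cell mean-logcounts signature values, 95th-percentile
  positivity cutoffs (rounded to 0.05 logcounts by default), and
  CBC / RSC / mixed (double-positive) / negative classification.
- **cohort** — polarized deciles (10% most CBC- vs RSC-skewed tumors),
  gain/loss categorization of CNV segment means at ±0.3, per-decile pathway
  mutation prevalence, static/plastic classification of paired pre/post
  treatment tumors with a Fisher exact test against histological response,
  and one-way random-effects reproducibility statistics (ICC, within- and
  between-subject CV) for multiregional biopsies.
- **synthetic** — generators for all of the above with known ground truth:
  negative-binomial bulk mixtures of CBC/RSC archetypes with stromal
  contamination, multi-population single-cell cohorts, paired cohorts with
  planted plasticity, and biopsy tables with a design ICC.

Everything is also exposed as a CLI (`stemindex index`, `sc-classify`,
`refine-signature`, `plasticity`, `cohort-cnv`, `pathway-prevalence`,
`repro`, `simulate …`).

## Worked example

Score a synthetic cohort whose ground truth is known:

```python
import stemindex as si
from stemindex import synthetic as syn
from scipy.stats import spearmanr

cfg = syn.BulkSimConfig(n_samples=100, seed=1)   # RSC fraction 0 -> 1 across samples
expr, truth, sigs = syn.simulate_bulk(cfg)        # counts, planted truth, CBC/RSC signatures

logcpm = si.tmm_cpm(expr, log=True)               # TMM-normalized log2(CPM + 1)
scores = si.gsva_scores(logcpm, sigs.values())    # samples x signatures
res = si.stem_cell_index(scores)                  # RSC - CBC per sample

print(res.table.head(3).round(3))
print("Spearman(planted fraction, index):",
      round(spearmanr(truth["rsc_fraction"], res.table["stem_cell_index"]).statistic, 3))
```

prints

```
      cbc_score  rsc_score  stem_cell_index
S000      0.666     -0.688           -1.353
S001      0.574     -0.696           -1.270
S002      0.543     -0.726           -1.269
Spearman(planted fraction, index): 0.996
```

The first samples were simulated as almost pure CBC phenotype (planted RSC
fraction ≈ 0), so their CBC score is strongly positive, their RSC score
negative, and the index deeply negative; across the cohort the index tracks
the planted mixing fraction almost perfectly (ρ = 0.996).

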