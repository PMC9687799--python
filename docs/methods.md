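# Methods

## Model and assumptions

The package treats the *sum of log2 expression over all genes* as a
per-sample summary of global transcriptional activity, min–max scales it
across the cohort to a transcriptomic burden TcB ∈ [0, 1], and interprets
the TcB ordering as a progression axis. This carries two assumptions:

1. **Inputs are harmonized.** Matrices are assumed pre-normalized
   (median-normalized log2 data, or comparable TPM-family counts). The
   package deliberately performs no quantile/TMM normalization; a
   library-size artifact would masquerade as burden.
2. **Global activity is monotone in progression.** The min–max map is
   affine-invariant and order-preserving but says nothing about causality;
   the bands are descriptive strata, not survival-calibrated risk groups.

"Median shift" is implemented literally as the min–max formula
`(value − range minimum) / range`; the word *median* in the name is treated
as nomenclature, not median-centering — the formula is the operation's only
explicit definition.

### Gene shift: two variants

The per-gene analogue of TcB is ambiguous in principle, so both readings are
provided and config-selectable:

- **median-summary** (default, `compute_gene_shift`): each gene is
  summarized by its median across samples, and the summaries are min–max
  scaled jointly across genes. Yields one value per gene; used for abacus
  row ordering.
- **per-value** (`median_shift_per_gene`): each gene's own expression vector
  is min–max scaled across samples, yielding a genes × samples matrix in
  [0, 1]. This scales the whole transcriptome uniformly, so timepoints can
  be compared directly; it feeds the longitudinal kernel densities and, when
  selected for DE, switches the fold-change threshold from 1.25 to 0.25
  (on [0, 1]-scaled values a 1.25 log2 difference is unreachable).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| pseudocount | 1.0 | added before log2 on raw-scale inputs |
| bands | low [0, .25], mid [.375, .625], high [.75, 1] | closed intervals; gaps are guard zones (excluded) |
| DE thresholds | \|log2FC\| > 1.25, p < 0.0005, FDR < 0.05 | conjunctive significance filter |
| screen bounds | r > 0.75 / r < −0.75, p < 1e-4, top 50 | raw-p filter — a hypothesis-generating screen, deliberately not FDR-adjusted |
| enrichment | p < 1e-4 and FDR < 0.05, conjunctive | universe = genes of the analyzed matrix |
| min group size | 3 | smaller bands are skipped in DE with a warning |

Band endpoints are **closed on both ends** so the printed cutoff values
belong to their named bands (0.25 → low, 0.375 → mid). Ordering ties are
broken lexicographically by ID, making all outputs bit-reproducible.

## Statistical choices

- **Between-group DE** uses Welch's *t* on log2 values (Mann–Whitney U as
  the rank alternative), not a count model: inputs are harmonized log-scale
  matrices, not raw counts. A table from edgeR/DESeq2 can be imported
  (`import_external_de`) and passes through the same significance flagging.
  Degenerate genes (zero variance in both groups): p = 1 when the means are
  equal, p = 0 when they differ exactly.
- **Within-group deviation** references each gene to its within-group
  median; the mean deviation is tested by the one-sample Wilcoxon
  signed-rank test; all-zero deviations give p = 1 by convention.
- **BH-FDR** is the only multiplicity procedure, via statsmodels, verified
  against the brute-force step-up definition in tests.
- **Spearman rho** is Pearson on average ranks (tie-aware). p-values use the
  t approximation (df = n − 2) for n > 9 and the exact permutation null over
  all n! pairings for n ≤ 9. Constant genes are reported with rho 0, p 1 and
  a `degenerate` flag rather than dropped, so output rows align with input
  genes.
- **Enrichment** is the exact hypergeometric upper tail
  (`P(overlap ≥ k)`), sets intersected with the universe first; catch-all
  set names (defaults: "disease", "development") are excluded by a
  configurable blacklist because such categories dominate every list without
  mechanistic content.
- **Kernel densities** of gene-shift values use a Gaussian kernel, Silverman
  bandwidth, a 512-point grid on [0, 1], and boundary reflection at 0 and 1
  so the estimate integrates to ~1 despite the hard support bounds.
- **Degenerate min–max ranges** (all-equal vectors) raise an error by
  default; a `zeros` fallback maps everything to 0 for pathological inputs.

## Paired and longitudinal designs

TcB for multi-timepoint designs is always computed on the **pooled matrix**
(all subjects × all timepoints). Scaling each timepoint separately would map
both timepoints onto [0, 1] independently and erase the very shift being
measured. A *TcB shift* is strictly upward band movement; downward moves are
reported via `delta_tcb` but never classified as shifts. Subjects with a
timepoint in a guard gap are labeled indeterminate (not shifted), and
subjects missing a timepoint are dropped with a warning.

## The synthetic generator

The generator emulates the data structure the method targets: a hidden
progression index `x` equally spaced on [0, 1] (equal spacing guarantees
every TcB band is deterministically occupied), planted monotone gene
programs, and Gaussian noise on the log2 scale (noise is modeled where the
method operates, not at count level).

Per gene: programmed genes follow their program,
`value = baseline + sign·slope·x + ε`, while background genes carry the
shared activity drift, `value = baseline + global_gain·x + ε`. Separating
the two keeps the roles clean: the gain term creates the per-sample burden
gradient that TcB measures, and the programs create the band-to-band
fold changes that DE must recover. (Folding the gain into programmed genes
as well would make down-programs nearly flat — gain − slope — and
unrecoverable at the stated defaults, contradicting the generator's own
recovery contract.) Defaults: 120 samples, 2,000 genes, 5% up / 5% down
programs, baseline N(8, 1), slope 2, gain 1, noise sd 0.5, seed 7.

- **Paired mode** anchors to a 41-subject relapse cohort with 24 shifters.
  Subjects start alternately at activity levels 0.10 and 0.45, chosen so
  that after pooled min–max scaling they sit at the centers of the low and
  mid bands; a shifter's second timepoint gains `shift_gain` (strong preset
  0.35 log2 units on every background gene, with matching program
  progression), which moves it up exactly one band. The TcB noise of a
  2,000-gene sum (sd ≈ 0.5·√2000 on the sum, ≈ 0.016 in TcB units) is an
  order of magnitude smaller than the 0.125 margin to the nearest band edge,
  which is why shift classification is near-perfect by construction.
- **Longitudinal mode** mirrors a 6-subject × 3-timepoint treatment course
  (days 0/7/21): each interval lowers every subject's index by
  `reversal_strength` (default 0.25), so global activity and up-programs
  decay while down-programs recover symmetrically — the mirror image of the
  progression plant.

**What passing these tests shows — and does not.** The generator produces
clean monotone programs with homoscedastic Gaussian noise and no batch
effects, dropout, library-size artifacts or correlated gene modules. Recovery
statistics near 1.0 therefore validate the *machinery* (ordering,
stratification, testing, classification), not the method's power on real
cohorts, where signal-to-noise is far less favorable.

## Problem sizes

Tests and the acceptance script run the generator at its stated defaults
(120 × 2,000 cross-sectional; 82 × 2,000 paired; 18 × 2,000 longitudinal;
1,000-gene null calibration). The correlation-screen recall check uses 40
planted genes per direction — below the screen's top-50 truncation, so
recall is well-defined — at noise sd 0.3, inside the regime (≤ 25% of the
2-log2-unit signal amplitude) where the r > 0.75 bound is attainable; at the
bound itself a slope-2 gene's population Spearman is ≈ 0.73 and the screen
cannot, by design, retain it.

## Known limitations

- The within-group "pairwise vs group median" comparison is implemented at
  the gene level (one record per gene, deviations pooled over samples); a
  per-sample reading would multiply records without changing the statistic.
- The exact-permutation correlation p is quadratic in memory for n = 9
  (9! pairings); beyond that the t approximation is used.
- No survival analysis, covariate adjustment, count-model DE or network
  rendering; matrices for heatmaps/networks are emitted as TSV, figures are
  the user's concern.
- Gene IDs are opaque strings; no symbol/Ensembl mapping is attempted.
- Missing values are rejected at read time; impute upstream if needed.
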