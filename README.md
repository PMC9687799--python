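# tcburden

Transcriptomic-burden (TcB) analysis for bulk expression matrices: order a
tumor cohort along a progression axis derived from global transcriptional
activity, stratify it into burden bands, and analyze what biology changes —
and in which direction — along that axis, cross-sectionally and over time.

## Who this is for

Computational biologists with a gene × sample expression matrix (TPM / RPKM /
FPKM / RSEM, raw or already log2) who want a time-axis-free way to study
disease progression: single-cohort snapshots, paired initial/relapse designs,
or short treatment time courses.

## The method

For a log2-scale matrix *X* (genes × samples), define per sample *j*

    S_j  = Σ_g X_gj                    (sum of log2 expression)
    TcB_j = (S_j − min S) / (max S − min S)   ∈ [0, 1]

The min–max map (the method calls it a *median shift*) sends the least
active sample to 0 and the most active to 1. Genes get an analogous *gene
shift* from their median expression across samples. Sorting samples by TcB
and genes by gene shift — *abacus ordering* — linearizes the matrix along a
putative progression axis. Samples are then stratified into

    low = [0, 0.25]   mid = [0.375, 0.625]   high = [0.75, 1]

(closed bands; samples in the gaps are excluded as guard zones), and the
bands are compared by:

- **differential expression** (Welch *t* or Mann–Whitney on log2 values;
  significant ⇔ |log2FC| > 1.25, p < 0.0005, BH-FDR < 0.05; a 0.25
  threshold replaces 1.25 on per-gene min–max-transformed values),
- **Spearman screening** of each gene against TcB (r > 0.75 / r < −0.75,
  p < 0.0001, top 50 per direction),
- **hypergeometric over-representation** of significant genes in local GMT
  gene sets, with collapsing of pathways into higher-order categories
  (translation, TCA/ETC, transcription, cell cycle, ECM),
- **trajectory analysis**: for paired designs, an upward TcB band move
  (low → mid or higher) between timepoints marks a *TcB shift*; for
  longitudinal designs, per-subject TcB courses and per-timepoint kernel
  densities of the globally rescaled transcriptome.

A seeded synthetic-data generator plants a hidden progression index, gene
programs, paired shifters and treatment reversal, so every stage is testable
without external downloads.

## Worked example

```python
from scipy import stats
import tcburden as tb

matrix, truth, sets = tb.generate_progression_dataset(n_samples=60, n_genes=500, seed=7)
tcb = tb.compute_tcb(matrix)
groups = tb.assign_tcb_groups(tcb)
print(stats.spearmanr(tcb["tcb"], truth.samples["progression_index"]).statistic)
print(tb.group_counts(groups))
de = tb.between_group_de(matrix, groups, pair=("low", "high"))
print(int(de["significant"].sum()), "of", len(de), "genes significant")
```

prints

```
0.9973881633787164
{'low': 13, 'mid': 15, 'high': 18, 'excluded': 14}
49 of 500 genes significant
```

TcB recovers the hidden progression ordering almost perfectly (Spearman
0.997); 46 samples land inside the three bands and 14 fall in the guard
gaps; the high-vs-low comparison recovers the planted up/down programs
(49 significant genes vs 50 planted). The `examples/` directory has one
narrative script per capability (ordering, DE + enrichment, correlation
screen, paired shifts, longitudinal courses).

A thin CLI wraps the same calls:

```bash
tcburden simulate progression --seed 7 --out data/
tcburden run --matrix data/matrix.tsv --gmt data/sets.gmt \
             --catmap data/categories.tsv --out results/
```

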