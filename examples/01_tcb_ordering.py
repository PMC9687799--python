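"""Order a cohort by transcriptomic burden (TcB) and stratify it.

Builds a synthetic cohort with a hidden progression axis, computes each
sample's TcB (min-max scaled sum of log2 expression), orders the matrix on
both axes (abacus ordering) and assigns the low/mid/high bands.
"""

from scipy import stats

import tcburden as tb

matrix, truth, _ = tb.generate_progression_dataset(n_samples=60, n_genes=500, seed=7)

tcb = tb.compute_tcb(matrix)
gene_shift = tb.compute_gene_shift(matrix)
ordered = tb.abacus_order(matrix, tcb, gene_shift)
groups = tb.assign_tcb_groups(tcb)

rho = stats.spearmanr(tcb["tcb"], truth.samples["progression_index"]).statistic
print(f"samples: {matrix.n_samples}, genes: {matrix.n_genes}")
print(f"Spearman(TcB, hidden progression index) = {rho:.3f}")
print(f"group counts: {tb.group_counts(groups)}")
print(f"first 3 samples after abacus ordering: {ordered.sample_ids[:3]}")

# The Spearman value near 1 means the TcB score recovered the cohort's
# hidden progression ordering; the group counts show how many samples fall
# in the low/mid/high bands and how many sit in the guard gaps (excluded).
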