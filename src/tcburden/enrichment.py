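"""Gene-set over-representation and higher-order pathway collapsing.

Over-representation is the exact hypergeometric upper-tail test of the
overlap between a significant-gene list and each gene set, within a stated
universe (all genes of the analyzed matrix, so the enrichment universe
matches the differential-testing universe). No web services are involved:
gene sets come from a local GMT file.

"Higher-order collapsing" summarizes broad biological programs
(translation, TCA/electron transport, transcription, cell cycle,
extracellular matrix, ...): pathways are grouped into categories via a
set -> category map, each category is represented by the per-sample mean
log2 expression of the union of its member genes, and TcB groups are
compared by the median of those per-sample means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust
from .errors import ConfigError, ConsistencyError
from .io import ExpressionMatrix, GeneSetCollection
from .stratify import GROUP_ORDER, samples_in_group

DEFAULT_P_MAX = 1e-4
DEFAULT_FDR_MAX = 0.05

#: Set names containing any of these (case-insensitive) substrings are
#: dropped before testing: such catch-all categories dominate every list
#: without saying anything mechanistic.
DEFAULT_NAME_BLACKLIST: tuple[str, ...] = ("disease", "development")


def hypergeometric_enrichment(
    gene_list: Iterable[str],
    universe: Iterable[str],
    sets: GeneSetCollection,
    p_max: float = DEFAULT_P_MAX,
    fdr_max: float = DEFAULT_FDR_MAX,
    name_blacklist: Sequence[str] = DEFAULT_NAME_BLACKLIST,
) -> pd.DataFrame:
    """Exact hypergeometric over-representation of ``gene_list`` in each set.

    Sets are intersected with the universe before testing; sets with zero
    overlap are still reported (p = 1). ``significant`` requires both
    p < p_max and BH-FDR < fdr_max.
    """
    universe_set = set(map(str, universe))
    if not universe_set:
        raise ConfigError("empty universe")
    glist = set(map(str, gene_list))
    outside = glist - universe_set
    if outside:
        raise ConsistencyError(
            f"gene list contains IDs outside the universe: {sorted(outside)[:10]}"
        )
    M = len(universe_set)
    N = len(glist)
    rows = []
    for name, genes in sets.sets.items():
        lname = name.lower()
        if any(b.lower() in lname for b in name_blacklist):
            continue
        members = set(genes) & universe_set
        K = len(members)
        k = len(members & glist)
        # P(overlap >= k) under draws of N from M with K marked
        p = float(stats.hypergeom.sf(k - 1, M, K, N))
        rows.append(
            {
                "set_name": name,
                "overlap": k,
                "set_size": K,
                "list_size": N,
                "universe_size": M,
                "p_value": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows, columns=["set_name", "overlap", "set_size", "list_size",
                                      "universe_size", "p_value"])
    out["fdr"] = bh_adjust(out["p_value"].to_numpy()) if len(out) else []
    out["significant"] = (out["p_value"] < p_max) & (out["fdr"] < fdr_max)
    return out


@dataclass
class HigherOrderSummary:
    """Collapsed higher-order category expression.

    Attributes
    ----------
    sample_means
        categories x samples DataFrame of mean log2 expression over each
        category's member genes.
    group_medians
        categories x TcB-groups DataFrame: median over each group's samples
        of the per-sample means.
    coverage
        Per category: members in the map vs members found in the matrix.
    """

    sample_means: pd.DataFrame
    group_medians: pd.DataFrame
    coverage: pd.DataFrame


def collapse_to_higher_order(
    matrix: ExpressionMatrix,
    sets: GeneSetCollection,
    groups: pd.DataFrame | None = None,
) -> HigherOrderSummary:
    """Collapse the matrix to higher-order category summaries.

    Requires ``sets.category_map``. Genes absent from the matrix are
    ignored (reported in the coverage table); a category with no matched
    gene is dropped with a warning.
    """
    if not sets.category_map:
        raise ConfigError("collapse_to_higher_order requires a non-empty category_map")
    cats = sets.categories()
    means: dict[str, np.ndarray] = {}
    cov_rows = []
    index = set(map(str, matrix.gene_ids))
    for cat, genes in cats.items():
        present = [g for g in genes if str(g) in index]
        cov_rows.append({"category": cat, "n_members": len(genes), "n_matched": len(present)})
        if not present:
            warnings.warn(f"category {cat!r}: no member gene in the matrix; dropped", stacklevel=2)
            continue
        means[cat] = matrix.values.loc[present].mean(axis=0).to_numpy(dtype=float)
    if not means:
        raise ConsistencyError("no category has any member gene in the matrix")
    sample_means = pd.DataFrame(means, index=matrix.sample_ids).T
    sample_means.index.name = "category"

    med_cols = {}
    if groups is not None:
        for g in GROUP_ORDER:
            ids = samples_in_group(groups, g)
            if ids:
                med_cols[g] = sample_means[ids].median(axis=1)
    group_medians = pd.DataFrame(med_cols, index=sample_means.index)
    coverage = pd.DataFrame(cov_rows)
    return HigherOrderSummary(sample_means=sample_means, group_medians=group_medians, coverage=coverage)
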