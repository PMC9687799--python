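"""Spearman screening of genes against TcB.

Every gene is rank-correlated with the per-sample TcB values; genes passing
a raw-p filter and a correlation bound (defaults r > 0.75 / r < -0.75,
p < 0.0001) are ranked by |rho| and truncated to the top N (default 50) per
direction. The screen deliberately uses unadjusted p-values: it is a
hypothesis-generating filter, not an inferential claim per gene.

rho is computed as Pearson correlation of average ranks (the textbook
tie-aware definition). Two-sided p-values use the t approximation with
n - 2 degrees of freedom for n > 9 and the exact permutation null
(all n! pairings) for n <= 9.
"""

from __future__ import annotations

from itertools import permutations
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConsistencyError, DomainError
from .io import ExpressionMatrix

DEFAULT_R_POS = 0.75
DEFAULT_R_NEG = -0.75
DEFAULT_P_MAX = 1e-4
DEFAULT_TOP_N = 50

#: Largest n for which the exact permutation p-value is used.
EXACT_MAX_N = 9


def _rank_rows(arr: np.ndarray) -> np.ndarray:
    return stats.rankdata(arr, axis=-1)


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of a 2-D array ``x`` with vector ``y``."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    xn = np.sqrt((xc**2).sum(axis=1))
    yn = np.sqrt((yc**2).sum())
    denom = xn * yn
    out = np.zeros(x.shape[0])
    ok = denom > 0
    out[ok] = (xc[ok] @ yc) / denom[ok]
    return np.clip(out, -1.0, 1.0)


def _exact_permutation_p(gene_ranks: np.ndarray, tcb_ranks: np.ndarray) -> np.ndarray:
    """Two-sided exact permutation p per gene (all n! pairings of the ranks)."""
    n = tcb_ranks.size
    perms = np.array(list(permutations(range(n))))  # (n!, n)
    null_t = tcb_ranks[perms]  # every pairing of the two rank vectors
    tc = null_t - null_t.mean(axis=1, keepdims=True)
    tn = np.sqrt((tc**2).sum(axis=1))
    gc = gene_ranks - gene_ranks.mean(axis=1, keepdims=True)
    gn = np.sqrt((gc**2).sum(axis=1))
    obs = np.zeros(gene_ranks.shape[0])
    p = np.ones(gene_ranks.shape[0])
    ok = gn > 0
    obs[ok] = (gc[ok] @ tc[0]) / (gn[ok] * tn[0])
    m = factorial(n)
    chunk = max(1, 2_000_000 // m)
    for start in range(0, gene_ranks.shape[0], chunk):
        sl = slice(start, start + chunk)
        idx = ok[sl]
        if not idx.any():
            continue
        rhos = (gc[sl][idx] @ tc.T) / (gn[sl][idx][:, None] * tn[None, :])
        p_block = np.ones(idx.size)
        p_block[idx] = (np.abs(rhos) >= np.abs(obs[sl][idx])[:, None] - 1e-12).mean(axis=1)
        p[sl] = p_block
    return p


def tcb_gene_correlation(matrix: ExpressionMatrix, tcb: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation of every gene's expression with TcB.

    Returns a DataFrame with columns ``gene_id``, ``rho``, ``p_value``,
    ``degenerate`` (True for constant genes, reported with rho 0, p 1) and
    ``selected`` (initialized to ``"none"``; see
    :func:`select_top_correlated`).
    """
    missing = set(matrix.sample_ids) - set(tcb["sample_id"].astype(str))
    if missing:
        raise ConsistencyError(f"TcB profile missing for samples: {sorted(missing)[:10]}")
    n = matrix.n_samples
    if n < 4:
        raise DomainError(f"correlation screen needs >= 4 samples, got {n}")
    t = (
        tcb.set_index(tcb["sample_id"].astype(str))
        .loc[[str(s) for s in matrix.sample_ids], "tcb"]
        .to_numpy(dtype=float)
    )
    if np.ptp(t) == 0:
        raise DomainError("TcB values are constant; correlation undefined")
    arr = matrix.values.to_numpy(dtype=float)
    gene_ranks = _rank_rows(arr)
    tcb_ranks = stats.rankdata(t)
    rho = _pearson_rows(gene_ranks, tcb_ranks)
    degenerate = np.ptp(arr, axis=1) == 0

    if n <= EXACT_MAX_N:
        p = _exact_permutation_p(gene_ranks, tcb_ranks)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = rho * np.sqrt((n - 2) / (1 - rho**2))
        p = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
        p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    p = np.where(degenerate, 1.0, p)
    rho = np.where(degenerate, 0.0, rho)
    return pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "rho": rho,
            "p_value": np.clip(p, 0.0, 1.0),
            "degenerate": degenerate,
            "selected": "none",
        }
    )


def select_top_correlated(
    records: pd.DataFrame,
    r_pos: float = DEFAULT_R_POS,
    r_neg: float = DEFAULT_R_NEG,
    p_max: float = DEFAULT_P_MAX,
    top_n: int = DEFAULT_TOP_N,
) -> pd.DataFrame:
    """Flag the top positively and negatively TcB-correlated genes.

    Positive list: genes with ``rho > r_pos`` and ``p < p_max``, sorted by
    rho descending, truncated to ``top_n`` (ties broken by gene ID so the
    selection is deterministic). Negative list is symmetric (rho ascending).
    Returns a copy of ``records`` with the ``selected`` column set to
    ``positive_top`` / ``negative_top`` / ``none``.
    """
    out = records.copy()
    out["selected"] = "none"
    pos = out[(out["rho"] > r_pos) & (out["p_value"] < p_max)]
    pos = pos.sort_values(["rho", "gene_id"], ascending=[False, True]).head(top_n)
    neg = out[(out["rho"] < r_neg) & (out["p_value"] < p_max)]
    neg = neg.sort_values(["rho", "gene_id"], ascending=[True, True]).head(top_n)
    out.loc[pos.index, "selected"] = "positive_top"
    out.loc[neg.index, "selected"] = "negative_top"
    return out


def top_gene_lists(records: pd.DataFrame) -> tuple[list[str], list[str]]:
    """The ranked (positive, negative) gene ID lists from annotated records."""
    pos = records[records["selected"] == "positive_top"].sort_values(
        ["rho", "gene_id"], ascending=[False, True]
    )
    neg = records[records["selected"] == "negative_top"].sort_values(
        ["rho", "gene_id"], ascending=[True, True]
    )
    return pos["gene_id"].tolist(), neg["gene_id"].tolist()
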