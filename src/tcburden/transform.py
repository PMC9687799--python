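"""The mathematical core: log2 transform, min-max ("median shift") scaling,
TcB and gene-shift computation, and abacus ordering.

TcB (transcriptomic burden) is a per-sample scalar in [0, 1]: the sum of a
sample's log2 expression values over all genes, min-max scaled across
samples. It acts as a proxy for global transcriptional activity and — in
tumor cohorts — for progression along a disease axis. The "gene shift" is
the analogous per-gene quantity used to order the second axis. Sorting
samples by TcB and genes by gene shift linearizes the matrix like beads on
abacus rails, so that group comparisons read along a progression axis.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import DegenerateRangeError, DomainError
from .io import ExpressionMatrix, check_profiles_cover


def median_shift(values, degenerate: str = "error") -> np.ndarray:
    """Min-max scale a vector onto [0, 1]: ``(v - min) / (max - min)``.

    This is the transform the method calls a "median shift"; the name is
    nomenclature, the operation is the plain min-max map. It is
    order-preserving and affine-invariant (``a*v + b`` with ``a > 0`` maps
    to the same output).

    Parameters
    ----------
    values
        Sequence of at least 2 floats.
    degenerate
        What to do when all values are equal (zero range): ``"error"``
        raises :class:`DegenerateRangeError`; ``"zeros"`` maps everything
        to 0.0.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise DomainError(f"median_shift needs a 1-D vector of length >= 2, got shape {v.shape}")
    lo = v.min()
    rng = v.max() - lo
    if rng == 0:
        if degenerate == "zeros":
            return np.zeros_like(v)
        raise DegenerateRangeError("all values equal: min-max range is zero")
    return (v - lo) / rng


def log2_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2-transform a raw-scale matrix: ``log2(value + pseudocount)``.

    A matrix already on the log2 scale is returned unchanged with a warning
    (never double-logged). Any cell with ``value + pseudocount <= 0`` is a
    domain error naming the cell.
    """
    if matrix.scale == "log2":
        warnings.warn("matrix is already log2-scaled; log2_transform is a no-op", stacklevel=2)
        return matrix
    if matrix.scale != "raw":
        raise DomainError(f"log2_transform expects a raw-scale matrix, got scale={matrix.scale!r}")
    if pseudocount < 0:
        raise DomainError("pseudocount must be >= 0")
    arr = matrix.values.to_numpy() + pseudocount
    if (arr <= 0).any():
        gi, si = np.argwhere(arr <= 0)[0]
        raise DomainError(
            f"log2 undefined at gene {matrix.values.index[gi]!r}, "
            f"sample {matrix.values.columns[si]!r}: value + pseudocount <= 0"
        )
    out = pd.DataFrame(np.log2(arr), index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values=out, scale="log2")


def compute_tcb(matrix: ExpressionMatrix, degenerate: str = "error") -> pd.DataFrame:
    """Per-sample TcB profile.

    Returns a DataFrame with columns ``sample_id``, ``raw_sum`` (sum of
    log2 expression over all genes) and ``tcb`` (min-max scaled raw_sum,
    in [0, 1]). TcB order is identical to raw-sum order by construction.
    """
    if matrix.scale != "log2":
        raise DomainError(f"compute_tcb expects a log2-scale matrix, got scale={matrix.scale!r}")
    sums = matrix.values.sum(axis=0).to_numpy(dtype=float)
    tcb = median_shift(sums, degenerate=degenerate)
    return pd.DataFrame(
        {"sample_id": matrix.sample_ids, "raw_sum": sums, "tcb": tcb}
    )


def compute_gene_shift(matrix: ExpressionMatrix, degenerate: str = "error") -> pd.DataFrame:
    """Per-gene shift profile (median-summary mode).

    Each gene is summarized by its median log2 expression across samples;
    the summaries are then min-max scaled jointly across genes so the
    lowest-median gene gets shift 0 and the highest 1. Columns:
    ``gene_id``, ``median_expr``, ``shift``.
    """
    if matrix.scale != "log2":
        raise DomainError(f"compute_gene_shift expects log2 scale, got {matrix.scale!r}")
    med = matrix.values.median(axis=1).to_numpy(dtype=float)
    shift = median_shift(med, degenerate=degenerate)
    return pd.DataFrame({"gene_id": matrix.gene_ids, "median_expr": med, "shift": shift})


def median_shift_per_gene(matrix: ExpressionMatrix, degenerate: str = "error") -> ExpressionMatrix:
    """Per-value gene-shift mode: min-max scale each gene's own expression
    vector across samples, yielding a genes x samples matrix in [0, 1]
    (scale flag ``"shift"``).

    This is the uniform rescaling that makes global expression changes
    directly comparable between timepoints in longitudinal designs, and the
    representation for which a 0.25 fold-change threshold substitutes for
    the usual 1.25 log2 threshold.
    """
    if matrix.scale != "log2":
        raise DomainError(f"median_shift_per_gene expects log2 scale, got {matrix.scale!r}")
    arr = matrix.values.to_numpy(dtype=float)
    lo = arr.min(axis=1, keepdims=True)
    rng = arr.max(axis=1, keepdims=True) - lo
    flat = (rng == 0).ravel()
    if flat.any():
        if degenerate != "zeros":
            raise DegenerateRangeError(
                f"{int(flat.sum())} gene(s) constant across samples, e.g. "
                f"{matrix.values.index[np.argmax(flat)]!r}"
            )
        rng = np.where(rng == 0, 1.0, rng)
        arr = np.where(flat[:, None], lo, arr)
    out = pd.DataFrame((arr - lo) / rng, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values=out, scale="shift")


def abacus_order(
    matrix: ExpressionMatrix, tcb: pd.DataFrame, gene_shift: pd.DataFrame
) -> ExpressionMatrix:
    """Rearrange the matrix: samples ascending by TcB, genes ascending by
    gene shift. Ties are broken lexicographically by ID, so the ordering is
    deterministic and idempotent. The operation is a pure permutation.
    """
    check_profiles_cover(matrix.sample_ids, tcb["sample_id"], "TcB profile")
    check_profiles_cover(matrix.gene_ids, gene_shift["gene_id"], "gene-shift profile")
    tcb_of = dict(zip(tcb["sample_id"].astype(str), tcb["tcb"]))
    shift_of = dict(zip(gene_shift["gene_id"].astype(str), gene_shift["shift"]))
    cols = sorted(matrix.sample_ids, key=lambda s: (tcb_of[str(s)], str(s)))
    rows = sorted(matrix.gene_ids, key=lambda g: (shift_of[str(g)], str(g)))
    return ExpressionMatrix(values=matrix.values.loc[rows, cols], scale=matrix.scale)
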