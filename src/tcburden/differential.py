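"""Between-group and within-group differential expression.

Inputs here are harmonized log2-scale matrices, so the built-in tests are
location tests on log2 values (Welch t by default, Mann-Whitney U as the
rank-based alternative) rather than count models; externally computed DE
tables (edgeR / DESeq2 output) can be imported and pass through the same
significance flagging.

A gene is flagged significant when all three filters hold:
``|log2fc| > fc_threshold``, ``p < p_threshold`` and ``BH-FDR < fdr_threshold``.
Defaults: fc 1.25 (or 0.25 on per-gene min-max-transformed matrices),
p 0.0005, FDR 0.05.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DomainError, FormatError
from .io import ExpressionMatrix, read_table
from .stratify import MIN_GROUP_SIZE, samples_in_group

DEFAULT_P = 0.0005
DEFAULT_FDR = 0.05
DEFAULT_FC_LOG2 = 1.25
#: Fold-change threshold used when the matrix is per-gene min-max transformed
#: (values live in [0, 1], so a 1.25 log2 threshold would be unreachable).
DEFAULT_FC_SHIFT = 0.25


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up FDR)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def _default_fc(matrix: ExpressionMatrix, fc_threshold: float | None) -> float:
    if fc_threshold is not None:
        return fc_threshold
    return DEFAULT_FC_SHIFT if matrix.scale == "shift" else DEFAULT_FC_LOG2


def _flag(df: pd.DataFrame, fc: float, p: float, fdr: float) -> pd.DataFrame:
    df = df.copy()
    df["significant"] = (
        (df["log2fc"].abs() > fc) & (df["p_value"] < p) & (df["fdr"] < fdr)
    )
    return df


def between_group_de(
    matrix: ExpressionMatrix,
    groups: pd.DataFrame,
    pair: tuple[str, str] = ("low", "high"),
    test: str = "welch",
    fc_threshold: float | None = None,
    p_threshold: float = DEFAULT_P,
    fdr_threshold: float = DEFAULT_FDR,
) -> pd.DataFrame:
    """Per-gene differential expression between two TcB groups.

    ``pair = (A, B)`` yields ``log2fc = mean(B) - mean(A)`` per gene and a
    comparison label ``"B_vs_A"``. p-values come from Welch's t-test
    (``test="welch"``) or the Mann-Whitney U test (``test="mannwhitney"``),
    BH-adjusted across all tested genes.
    """
    if matrix.scale == "raw":
        raise DomainError("between_group_de expects log2 (or shift) scale, got raw")
    if test not in ("welch", "mannwhitney"):
        raise ConfigError(f"unknown test {test!r}; use 'welch' or 'mannwhitney'")
    a_name, b_name = pair
    a_ids = samples_in_group(groups, a_name)
    b_ids = samples_in_group(groups, b_name)
    for name, ids in ((a_name, a_ids), (b_name, b_ids)):
        if len(ids) < MIN_GROUP_SIZE:
            warnings.warn(
                f"group {name!r} has {len(ids)} samples (< {MIN_GROUP_SIZE}); skipping comparison",
                stacklevel=2,
            )
            return pd.DataFrame(
                columns=["gene_id", "comparison", "log2fc", "p_value", "fdr", "significant"]
            )
    a = matrix.values[a_ids].to_numpy(dtype=float)
    b = matrix.values[b_ids].to_numpy(dtype=float)
    log2fc = b.mean(axis=1) - a.mean(axis=1)

    if test == "welch":
        res = stats.ttest_ind(b, a, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    else:
        res = stats.mannwhitneyu(b, a, axis=1, alternative="two-sided")
        p = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups: equal means -> no evidence (p=1);
    # different means -> separation is exact (p=0)
    nan = ~np.isfinite(p)
    if nan.any():
        p[nan] = np.where(np.isclose(log2fc[nan], 0.0), 1.0, 0.0)

    out = pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "comparison": f"{b_name}_vs_{a_name}",
            "log2fc": log2fc,
            "p_value": p,
            "fdr": bh_adjust(p),
        }
    )
    return _flag(out, _default_fc(matrix, fc_threshold), p_threshold, fdr_threshold)


def within_group_deviation(
    matrix: ExpressionMatrix,
    group_samples: list[str],
    fc_threshold: float | None = None,
    p_threshold: float = DEFAULT_P,
    fdr_threshold: float = DEFAULT_FDR,
) -> pd.DataFrame:
    """Per-gene deviation from the group median, within one TcB group.

    For each gene the reference is its median within the group; the
    statistic is the mean of per-sample deviations (value - reference),
    tested against zero by the one-sample Wilcoxon signed-rank test.
    """
    if len(group_samples) < MIN_GROUP_SIZE:
        raise ConfigError(f"within-group test needs >= {MIN_GROUP_SIZE} samples")
    sub = matrix.values[list(group_samples)].to_numpy(dtype=float)
    ref = np.median(sub, axis=1, keepdims=True)
    dev = sub - ref
    mean_dev = dev.mean(axis=1)
    p = np.ones(dev.shape[0])
    for i in range(dev.shape[0]):
        d = dev[i]
        if np.allclose(d, 0.0):
            continue  # all deviations zero -> p = 1 by convention
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p[i] = stats.wilcoxon(d, zero_method="wilcox").pvalue
    out = pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "comparison": "vs_group_median",
            "log2fc": mean_dev,
            "p_value": p,
            "fdr": bh_adjust(p),
        }
    )
    return _flag(out, _default_fc(matrix, fc_threshold), p_threshold, fdr_threshold)


def import_external_de(
    path: str,
    fc_threshold: float = DEFAULT_FC_LOG2,
    p_threshold: float = DEFAULT_P,
    fdr_threshold: float = DEFAULT_FDR,
) -> pd.DataFrame:
    """Import a DE table computed elsewhere (edgeR, DESeq2, ...).

    The file must contain columns ``gene_id``, ``log2fc`` and ``p_value``;
    an ``fdr`` column is used if present and recomputed by BH otherwise.
    Records then pass through the same significance flagging as the
    built-in tests.
    """
    df = read_table(path)
    required = ["gene_id", "log2fc", "p_value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    p = df["p_value"].astype(float).to_numpy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise FormatError(f"{path}: p_value outside [0, 1]")
    out = pd.DataFrame(
        {
            "gene_id": df["gene_id"].astype(str),
            "comparison": df["comparison"].astype(str) if "comparison" in df.columns else "external",
            "log2fc": df["log2fc"].astype(float),
            "p_value": p,
        }
    )
    if "fdr" in df.columns:
        fdr = df["fdr"].astype(float).to_numpy()
        if ((fdr < 0) | (fdr > 1)).any() or not np.isfinite(fdr).all():
            raise FormatError(f"{path}: fdr outside [0, 1]")
        out["fdr"] = fdr
    else:
        out["fdr"] = bh_adjust(p)
    return _flag(out, fc_threshold, p_threshold, fdr_threshold)
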