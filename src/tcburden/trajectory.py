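"""Paired and longitudinal TcB trajectory analysis.

For paired designs (e.g. initial diagnosis vs relapse), TcB is always
computed on the pooled two-timepoint matrix so both timepoints share one
min-max scale; computing it per timepoint would rescale each timepoint to
[0, 1] and erase the very shift being measured. A subject "shifts" when its
TcB band moves strictly upward (low -> mid or higher) between timepoints;
downward moves are reported via delta_tcb but never count as a shift.

For longitudinal designs, each subject's TcB course across ordered
timepoints is extracted, and the global distribution of per-gene min-max
("median shift") values is summarized per timepoint by a boundary-corrected
Gaussian kernel density on [0, 1].
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ConfigError, ConsistencyError
from .io import ExpressionMatrix, GeneSetCollection, SampleTable
from .stratify import DEFAULT_BANDS, GROUP_ORDER, assign_tcb_groups
from .transform import compute_tcb, median_shift_per_gene

_RANK = {g: i for i, g in enumerate(GROUP_ORDER)}


def paired_tcb_shift(
    tcb: pd.DataFrame,
    metadata: SampleTable,
    bands: dict[str, tuple[float, float]] | None = None,
    t1: str | None = None,
    t2: str | None = None,
) -> pd.DataFrame:
    """Classify each subject's TcB band movement between two timepoints.

    ``tcb`` must come from :func:`tcburden.transform.compute_tcb` run on the
    pooled matrix containing both timepoints. Subjects missing a timepoint
    are dropped with a warning; subjects with either timepoint excluded
    from the bands are labeled indeterminate (and not shifted).

    Returns one row per subject: ``subject_id, tcb_t1, tcb_t2, group_t1,
    group_t2, delta_tcb, shifted, indeterminate``.
    """
    order = metadata.timepoint_order
    t1 = order[0] if t1 is None else t1
    t2 = order[-1] if t2 is None else t2
    if t1 == t2 or t1 not in order or t2 not in order:
        raise ConfigError(f"invalid timepoint pair ({t1!r}, {t2!r}) for order {order}")
    groups = assign_tcb_groups(tcb, bands=bands or dict(DEFAULT_BANDS))
    info = groups.set_index("sample_id")
    meta = metadata.table
    rows = []
    for subject, sub in meta.groupby("subject_id", sort=True):
        s1 = sub.loc[sub["timepoint"] == t1, "sample_id"]
        s2 = sub.loc[sub["timepoint"] == t2, "sample_id"]
        if len(s1) != 1 or len(s2) != 1:
            warnings.warn(
                f"subject {subject!r} lacks exactly one sample per timepoint; dropped",
                stacklevel=2,
            )
            continue
        sid1, sid2 = str(s1.iloc[0]), str(s2.iloc[0])
        for sid in (sid1, sid2):
            if sid not in info.index:
                raise ConsistencyError(f"no TcB profile for sample {sid!r}")
        g1, g2 = info.loc[sid1, "group"], info.loc[sid2, "group"]
        v1, v2 = float(info.loc[sid1, "tcb"]), float(info.loc[sid2, "tcb"])
        indeterminate = g1 == "excluded" or g2 == "excluded"
        shifted = (not indeterminate) and _RANK[g2] > _RANK[g1]
        rows.append(
            {
                "subject_id": str(subject),
                "tcb_t1": v1,
                "tcb_t2": v2,
                "group_t1": g1,
                "group_t2": g2,
                "delta_tcb": v2 - v1,
                "shifted": shifted,
                "indeterminate": indeterminate,
            }
        )
    return pd.DataFrame(rows)


def directional_foldchange(
    matrix: ExpressionMatrix,
    metadata: SampleTable,
    shifts: pd.DataFrame,
    sets: GeneSetCollection,
    t1: str | None = None,
    t2: str | None = None,
) -> pd.DataFrame:
    """Per-gene log2 fold changes (t2 - t1) for higher-order category genes,
    averaged over subjects, reported separately for the shifted and
    not-shifted subsets (and pooled).

    Output columns: ``category, gene_id, subset, log2fc, n_subjects`` with
    subset in {shifted, not_shifted, all}. Empty subsets are omitted.
    """
    if not sets.category_map:
        raise ConfigError("directional_foldchange requires a category_map")
    order = metadata.timepoint_order
    t1 = order[0] if t1 is None else t1
    t2 = order[-1] if t2 is None else t2
    meta = metadata.table
    pair_of: dict[str, tuple[str, str]] = {}
    for subject, sub in meta.groupby("subject_id", sort=True):
        s1 = sub.loc[sub["timepoint"] == t1, "sample_id"]
        s2 = sub.loc[sub["timepoint"] == t2, "sample_id"]
        if len(s1) == 1 and len(s2) == 1:
            pair_of[str(subject)] = (str(s1.iloc[0]), str(s2.iloc[0]))
    shifted_ids = set(shifts.loc[shifts["shifted"], "subject_id"].astype(str))
    not_shifted_ids = set(
        shifts.loc[~shifts["shifted"] & ~shifts["indeterminate"], "subject_id"].astype(str)
    )
    subsets = {
        "shifted": [s for s in pair_of if s in shifted_ids],
        "not_shifted": [s for s in pair_of if s in not_shifted_ids],
        "all": list(pair_of),
    }
    gene_index = set(map(str, matrix.gene_ids))
    rows = []
    for cat, genes in sets.categories().items():
        present = [g for g in genes if str(g) in gene_index]
        if not present:
            continue
        sub_matrix = matrix.values.loc[present]
        for subset, subjects in subsets.items():
            if not subjects:
                continue
            deltas = np.column_stack(
                [
                    sub_matrix[pair_of[s][1]].to_numpy(dtype=float)
                    - sub_matrix[pair_of[s][0]].to_numpy(dtype=float)
                    for s in subjects
                ]
            )
            fc = deltas.mean(axis=1)
            for g, v in zip(present, fc):
                rows.append(
                    {
                        "category": cat,
                        "gene_id": g,
                        "subset": subset,
                        "log2fc": float(v),
                        "n_subjects": len(subjects),
                    }
                )
    return pd.DataFrame(rows)


def reflected_kde(
    values,
    grid_size: int = 512,
    bandwidth: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density on [0, 1] with boundary reflection.

    Mass that a plain Gaussian kernel would leak past 0 or 1 is folded back
    in, so the estimate integrates to ~1 on the unit interval. Bandwidth
    defaults to Silverman's rule.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2:
        raise ConfigError("kernel density needs >= 2 values")
    if bandwidth is None:
        sd = x.std(ddof=1)
        iqr = np.subtract(*np.percentile(x, [75, 25]))
        scale = min(sd, iqr / 1.34) if iqr > 0 else sd
        if scale == 0:
            scale = max(sd, 1e-3)
        bandwidth = 0.9 * scale * x.size ** (-0.2)
    bandwidth = max(float(bandwidth), 1e-6)
    grid = np.linspace(0.0, 1.0, grid_size)

    def gauss(centers: np.ndarray) -> np.ndarray:
        z = (grid[:, None] - centers[None, :]) / bandwidth
        return np.exp(-0.5 * z**2).sum(axis=1)

    dens = gauss(x) + gauss(-x) + gauss(2.0 - x)
    dens /= x.size * bandwidth * np.sqrt(2 * np.pi)
    return grid, dens


def longitudinal_course(
    matrix: ExpressionMatrix,
    metadata: SampleTable,
    grid_size: int = 512,
    bandwidth: float | None = None,
    degenerate: str = "error",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject TcB course and per-timepoint gene-shift density.

    TcB is computed on the pooled matrix (all subjects x all timepoints).
    Subjects with fewer than 2 timepoints are excluded with a warning.

    Returns
    -------
    course
        ``subject_id, timepoint, sample_id, tcb, delta_tcb`` (delta vs the
        previous timepoint, NaN at the first).
    density
        ``timepoint, grid, density``: boundary-corrected Gaussian KDE of
        the pooled per-gene min-max ("median shift") values of that
        timepoint's samples, on a fixed grid over [0, 1].
    """
    tcb = compute_tcb(matrix)
    info = tcb.set_index("sample_id")
    order = metadata.timepoint_order
    meta = metadata.table
    course_rows = []
    for subject, sub in meta.groupby("subject_id", sort=True):
        sub = sub.set_index("timepoint")
        tps = [t for t in order if t in sub.index]
        if len(tps) < 2:
            warnings.warn(f"subject {subject!r} has < 2 timepoints; excluded", stacklevel=2)
            continue
        prev = None
        for t in tps:
            sid = str(sub.loc[t, "sample_id"])
            v = float(info.loc[sid, "tcb"])
            course_rows.append(
                {
                    "subject_id": str(subject),
                    "timepoint": t,
                    "sample_id": sid,
                    "tcb": v,
                    "delta_tcb": np.nan if prev is None else v - prev,
                }
            )
            prev = v
    course = pd.DataFrame(course_rows)

    shift = median_shift_per_gene(matrix, degenerate=degenerate)
    density_rows = []
    for t in order:
        ids = meta.loc[meta["timepoint"] == t, "sample_id"].astype(str).tolist()
        ids = [s for s in ids if s in shift.values.columns]
        if not ids:
            continue
        grid, dens = reflected_kde(
            shift.values[ids].to_numpy(dtype=float), grid_size=grid_size, bandwidth=bandwidth
        )
        density_rows.append(
            pd.DataFrame({"timepoint": t, "grid": grid, "density": dens})
        )
    density = pd.concat(density_rows, ignore_index=True) if density_rows else pd.DataFrame(
        columns=["timepoint", "grid", "density"]
    )
    return course, density
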