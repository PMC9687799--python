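"""Stratification of samples into low / mid / high TcB bands.

The default bands are low = [0, 0.25], mid = [0.375, 0.625] and
high = [0.75, 1]. The deliberate gaps between bands act as guard zones:
samples falling in a gap are labeled ``excluded`` and dropped from
group-wise comparisons, which sharpens the contrast between bands.
Intervals are closed at both ends, so the printed endpoints belong to
their named bands (0.25 -> low, 0.375 -> mid, ...).
"""

from __future__ import annotations

import warnings

import pandas as pd

from .errors import ConfigError

#: Default TcB cutoff bands, as (lower, upper) closed intervals.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "low": (0.0, 0.25),
    "mid": (0.375, 0.625),
    "high": (0.75, 1.0),
}

GROUP_ORDER = ("low", "mid", "high")

#: Groups smaller than this are skipped in differential testing.
MIN_GROUP_SIZE = 3


def validate_bands(bands: dict[str, tuple[float, float]]) -> None:
    for name in GROUP_ORDER:
        if name not in bands:
            raise ConfigError(f"cutoff bands must define {GROUP_ORDER}, missing {name!r}")
        lo, hi = bands[name]
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigError(f"band {name!r} = ({lo}, {hi}) is not a valid interval in [0, 1]")
    ordered = [bands[g] for g in GROUP_ORDER]
    for (lo1, hi1), (lo2, hi2) in zip(ordered, ordered[1:]):
        if hi1 >= lo2:
            raise ConfigError(
                f"cutoff bands overlap or are unordered: ({lo1}, {hi1}) vs ({lo2}, {hi2})"
            )


def assign_tcb_groups(
    tcb: pd.DataFrame, bands: dict[str, tuple[float, float]] | None = None
) -> pd.DataFrame:
    """Assign each sample to low / mid / high / excluded by its TcB value.

    Parameters
    ----------
    tcb
        DataFrame with columns ``sample_id`` and ``tcb`` (from
        :func:`tcburden.transform.compute_tcb`).
    bands
        Mapping group name -> (lower, upper) closed interval; defaults to
        :data:`DEFAULT_BANDS`.

    Returns
    -------
    DataFrame with columns ``sample_id``, ``tcb``, ``group``. Every sample
    gets exactly one label; samples in no band are ``excluded``.
    """
    bands = dict(DEFAULT_BANDS) if bands is None else bands
    validate_bands(bands)

    def label(x: float) -> str:
        for name in GROUP_ORDER:
            lo, hi = bands[name]
            if lo <= x <= hi:
                return name
        return "excluded"

    out = pd.DataFrame(
        {
            "sample_id": tcb["sample_id"].astype(str),
            "tcb": tcb["tcb"].astype(float),
            "group": [label(x) for x in tcb["tcb"].astype(float)],
        }
    )
    counts = group_counts(out)
    for name in GROUP_ORDER:
        if 0 < counts.get(name, 0) < MIN_GROUP_SIZE:
            warnings.warn(
                f"TcB group {name!r} has only {counts[name]} samples "
                f"(< {MIN_GROUP_SIZE}); it will be skipped in differential tests",
                stacklevel=2,
            )
    return out


def group_counts(groups: pd.DataFrame) -> dict[str, int]:
    """Sample counts per group label (including ``excluded``)."""
    c = groups["group"].value_counts().to_dict()
    return {k: int(c.get(k, 0)) for k in (*GROUP_ORDER, "excluded")}


def samples_in_group(groups: pd.DataFrame, name: str) -> list[str]:
    return groups.loc[groups["group"] == name, "sample_id"].astype(str).tolist()
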