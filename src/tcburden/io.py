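"""Readers, writers and the core in-memory containers.

Expression data travel as an :class:`ExpressionMatrix` — a genes x samples
:class:`pandas.DataFrame` plus an explicit scale flag. The flag is mandatory
because the single most damaging silent error in this kind of pipeline is
log2-transforming data that are already on the log2 scale.

All tabular results are plain :class:`pandas.DataFrame` objects and are
written as TSV.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError

#: Recognised value scales for an expression matrix.
#: "raw"   — non-negative normalized counts (TPM/RPKM/FPKM/RSEM...).
#: "log2"  — log2-transformed expression, the scale the pipeline operates on.
#: "shift" — per-gene min-max ("median shift") transformed values in [0, 1].
SCALES = ("raw", "log2", "shift")


@dataclass
class ExpressionMatrix:
    """A genes x samples expression grid with an explicit value scale.

    Parameters
    ----------
    values
        DataFrame with gene IDs as the index and sample IDs as columns.
    scale
        One of ``"raw"``, ``"log2"`` or ``"shift"``.
    """

    values: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise FormatError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        v = self.values
        if v.shape[0] < 2 or v.shape[1] < 2:
            raise FormatError(
                f"expression matrix must have >= 2 genes and >= 2 samples, got {v.shape}"
            )
        dup_genes = v.index[v.index.duplicated()].unique().tolist()
        if dup_genes:
            raise FormatError(f"duplicate gene IDs: {sorted(map(str, dup_genes))}")
        dup_samples = v.columns[v.columns.duplicated()].unique().tolist()
        if dup_samples:
            raise FormatError(f"duplicate sample IDs: {sorted(map(str, dup_samples))}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = _first_non_numeric(v)
            raise FormatError(f"non-numeric value at gene {bad[0]!r}, sample {bad[1]!r}")
        if not np.isfinite(arr).all():
            gi, si = np.argwhere(~np.isfinite(arr))[0]
            raise FormatError(
                f"non-finite value at gene {v.index[gi]!r}, sample {v.columns[si]!r}"
            )
        if self.scale == "raw" and (arr < 0).any():
            gi, si = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"raw-scale matrix contains negative value at gene {v.index[gi]!r}, "
                f"sample {v.columns[si]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class SampleTable:
    """Per-sample metadata: subject, timepoint and optional diagnosis.

    ``timepoint_order`` declares the ordered set the timepoint labels are
    drawn from (e.g. ``["initial", "relapse"]`` or ``["day0", "day7",
    "day21"]``); it defines the direction of every paired / longitudinal
    comparison.
    """

    table: pd.DataFrame
    timepoint_order: list[str] = field(default_factory=list)

    REQUIRED = ("sample_id", "subject_id", "timepoint")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"sample table missing required columns: {missing}")
        dup = self.table["sample_id"][self.table["sample_id"].duplicated()].tolist()
        if dup:
            raise FormatError(f"duplicate sample IDs in metadata: {sorted(map(str, dup))}")
        if not self.timepoint_order:
            # fall back to order of first appearance
            self.timepoint_order = list(dict.fromkeys(self.table["timepoint"]))
        unknown = set(self.table["timepoint"]) - set(self.timepoint_order)
        if unknown:
            raise FormatError(
                f"timepoint labels {sorted(map(str, unknown))} not in declared order "
                f"{self.timepoint_order}"
            )


@dataclass
class GeneSetCollection:
    """Named gene sets plus an optional pathway -> higher-order category map."""

    sets: dict[str, list[str]]
    category_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise FormatError(f"gene set {name!r} is empty")

    def categories(self) -> dict[str, list[str]]:
        """Union of member genes per higher-order category (order-stable)."""
        out: dict[str, list[str]] = {}
        for set_name, cat in self.category_map.items():
            if set_name not in self.sets:
                continue
            seen = out.setdefault(cat, [])
            for g in self.sets[set_name]:
                if g not in seen:
                    seen.append(g)
        return out


def _first_non_numeric(df: pd.DataFrame) -> tuple[str, str]:
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            return str(df.index[bad.argmax()]), str(col)
    return "?", "?"


def _sep_for(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_expression_matrix(
    path: str,
    scale: str,
    orientation: str = "genes_in_rows",
    delimiter: str | None = None,
) -> ExpressionMatrix:
    """Read a delimited expression table into an :class:`ExpressionMatrix`.

    The file must have one header row and one ID column. ``orientation``
    says whether rows are genes (``genes_in_rows``) or samples
    (``samples_in_rows``); the returned matrix is always genes x samples.
    Missing cells and non-numeric cells are rejected with coordinates.
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise FormatError(f"unknown orientation {orientation!r}")
    sep = _sep_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "samples_in_rows":
        df = df.T
    df.index.name = None
    df.columns.name = None
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise FormatError(f"duplicate gene IDs: {sorted(dup)}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        gi, si = np.argwhere(bad.to_numpy())[0]
        cell = df.iat[gi, si]
        what = "missing" if (pd.isna(cell) or str(cell).strip() == "") else f"non-numeric ({cell!r})"
        raise FormatError(
            f"{what} value at row {df.index[gi]!r}, column {df.columns[si]!r} in {path}"
        )
    return ExpressionMatrix(values=numeric.astype(float), scale=scale)


def write_expression_matrix(matrix: ExpressionMatrix, path: str, delimiter: str | None = None) -> None:
    sep = _sep_for(path, delimiter)
    matrix.values.to_csv(path, sep=sep, index_label="gene_id", float_format="%.10g")


def read_sample_table(
    path: str,
    timepoint_order: Sequence[str] | None = None,
    delimiter: str | None = None,
) -> SampleTable:
    """Read sample metadata (columns sample_id, subject_id, timepoint[, diagnosis])."""
    sep = _sep_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str)
    return SampleTable(table=df, timepoint_order=list(timepoint_order or []))


def read_gmt(path: str) -> GeneSetCollection:
    """Read gene sets in Broad GMT format.

    Each line is ``name<TAB>description<TAB>gene1<TAB>gene2...``. The
    description is discarded; duplicate genes within one set are
    de-duplicated (first occurrence wins); duplicate set names are an error.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields, got {len(fields)}"
                )
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            genes = [g for g in fields[2:] if g.strip()]
            sets[name] = list(dict.fromkeys(genes))
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_category_map(path: str, delimiter: str | None = None) -> dict[str, str]:
    """Read a two-column TSV mapping gene-set name -> higher-order category."""
    sep = _sep_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: category map needs two columns (set_name, category)")
    cols = list(df.columns[:2])
    return dict(zip(df[cols[0]], df[cols[1]]))


def write_table(records: pd.DataFrame, path: str, delimiter: str | None = None) -> None:
    """Write a result table as delimited text with >= 6 significant digits."""
    sep = _sep_for(path, delimiter)
    d = os.path.dirname(path)
    if d:
        os.makedirs(d, exist_ok=True)
    records.to_csv(path, sep=sep, index=False, float_format="%.10g")


def read_table(path: str, delimiter: str | None = None) -> pd.DataFrame:
    sep = _sep_for(path, delimiter)
    return pd.read_csv(path, sep=sep)


def check_profiles_cover(
    ids_needed: Sequence[str], ids_have: Sequence[str], what: str
) -> None:
    """Raise :class:`ConsistencyError` unless every needed ID has a profile."""
    missing = sorted(set(map(str, ids_needed)) - set(map(str, ids_have)))
    if missing:
        raise ConsistencyError(f"missing {what} for: {missing[:10]}")
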