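"""Readers and writers for every tabular artifact in the pipeline.

Formats are plain text throughout: CSV/TSV with a header for feature
tables, labeled CSV/TSV for similarity matrices (first column = test id,
remaining columns labeled by train id), a PDBbind-style whitespace index
for binding affinities, and a long-format TSV for performance curves.
The delimiter is chosen from the file extension (``.csv`` -> comma,
anything else -> tab).  Complex identifiers are lowercased on ingest so
that mixed-case PDB codes from different sources match.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .similarity import SimilarityMatrix

__all__ = [
    "ComplexRecord",
    "FeatureTable",
    "AffinityTable",
    "read_feature_table",
    "write_feature_table",
    "read_pdbbind_index",
    "write_pdbbind_index",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "write_performance_table",
    "read_performance_table",
    "PERFORMANCE_COLUMNS",
]


@dataclass(frozen=True)
class ComplexRecord:
    """One protein-ligand complex: id, measured affinity, named features.

    ``affinity`` is in pK units (-log10 of the molar Kd or Ki) and is the
    regression target of every scoring function here.
    """

    id: str
    affinity: float
    features: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "id", str(self.id).strip().lower())
        if not math.isfinite(self.affinity):
            raise ValueError(f"non-finite affinity for complex {self.id!r}")


class FeatureTable:
    """An ordered id-by-feature numeric table (no missing values allowed)."""

    def __init__(self, ids, columns, values):
        self.ids = [str(i).strip().lower() for i in ids]
        self.columns = [str(c) for c in columns]
        values = np.asarray(values, dtype=float).reshape(len(self.ids), len(self.columns))
        if len(set(self.ids)) != len(self.ids):
            seen, dup = set(), None
            for i in self.ids:
                if i in seen:
                    dup = i
                    break
                seen.add(i)
            raise ValueError(f"duplicate complex id {dup!r} in feature table")
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("duplicate feature column names")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"missing/non-finite value at row {self.ids[i]!r}, column {self.columns[j]!r}"
            )
        self.values = values

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def p(self) -> int:
        return len(self.columns)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.ids, name="id"),
                            columns=self.columns)

    def select_columns(self, columns) -> "FeatureTable":
        missing = [c for c in columns if c not in self.columns]
        if missing:
            raise KeyError(f"feature table lacks column(s) {missing}")
        idx = [self.columns.index(c) for c in columns]
        return FeatureTable(self.ids, list(columns), self.values[:, idx])

    def select_ids(self, ids) -> "FeatureTable":
        pos = {i: k for k, i in enumerate(self.ids)}
        wanted = [str(i).lower() for i in ids]
        missing = [i for i in wanted if i not in pos]
        if missing:
            raise KeyError(f"feature table lacks id(s) {missing[:5]}")
        rows = [pos[i] for i in wanted]
        return FeatureTable(wanted, self.columns, self.values[rows])

    def __eq__(self, other):
        return (
            isinstance(other, FeatureTable)
            and self.ids == other.ids
            and self.columns == other.columns
            and np.array_equal(self.values, other.values)
        )


class AffinityTable:
    """Mapping complex id -> measured binding affinity in pK units."""

    def __init__(self, data: dict):
        self._data = {}
        for key, value in data.items():
            key = str(key).strip().lower()
            value = float(value)
            if not math.isfinite(value):
                raise ValueError(f"non-finite affinity for complex {key!r}")
            if key in self._data:
                raise ValueError(f"duplicate complex id {key!r} in affinity table")
            self._data[key] = value

    def __getitem__(self, key: str) -> float:
        return self._data[str(key).lower()]

    def __contains__(self, key) -> bool:
        return str(key).lower() in self._data

    def __len__(self) -> int:
        return len(self._data)

    def __iter__(self):
        return iter(self._data)

    def items(self):
        return self._data.items()

    def as_dict(self) -> dict:
        return dict(self._data)

    def vector_for(self, ids) -> np.ndarray:
        missing = [i for i in ids if str(i).lower() not in self._data]
        if missing:
            raise KeyError(f"affinity table lacks id(s) {missing[:5]}")
        return np.array([self._data[str(i).lower()] for i in ids], dtype=float)


def _delimiter(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_feature_table(path, expected_columns=()) -> FeatureTable:
    """Read a feature table; first column is the complex id.

    If ``expected_columns`` is non-empty the columns are reordered to
    match it and any absent column raises an error naming it.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter(path), dtype=str)
    if df.shape[1] < 1:
        raise ValueError(f"{path}: no columns found")
    id_col = df.columns[0]
    ids = df[id_col].astype(str).str.strip().str.lower()
    columns = list(df.columns[1:])
    values = np.empty((len(df), len(columns)), dtype=float)
    for j, col in enumerate(columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any() or converted.isna().any():
            row = int(np.argmax((converted.isna()).to_numpy()))
            raise ValueError(
                f"{path}: non-numeric or missing value at row {row + 1} "
                f"(id {ids.iloc[row]!r}), column {col!r}"
            )
        values[:, j] = converted.to_numpy(dtype=float)
    dup = ids[ids.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate complex id {dup.iloc[0]!r}")
    table = FeatureTable(list(ids), columns, values)
    if expected_columns:
        missing = [c for c in expected_columns if c not in table.columns]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
        table = table.select_columns(list(expected_columns))
    return table


def write_feature_table(table: FeatureTable, path) -> None:
    path = Path(path)
    df = table.to_dataframe()
    df.to_csv(path, sep=_delimiter(path), float_format="%.9g")


def read_pdbbind_index(path) -> AffinityTable:
    """Parse a PDBbind-style index file into an affinity table.

    Whitespace-delimited; lines starting with ``#`` are comments.  Column 1
    is the 4-character complex code and column 4 the -logKd/Ki value; the
    remaining columns (resolution, year, affinity string) are ignored.
    """
    data = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(
                    f"{path}: line {lineno}: expected at least 4 columns, got {len(parts)}"
                )
            code = parts[0].lower()
            try:
                affinity = float(parts[3])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric affinity {parts[3]!r}"
                ) from exc
            if code in data:
                raise ValueError(f"{path}: line {lineno}: duplicate complex code {code!r}")
            data[code] = affinity
    return AffinityTable(data)


def write_pdbbind_index(affinities: AffinityTable, path, year: int = 2020) -> None:
    """Write affinities back out in the PDBbind index dialect (round-trippable)."""
    with open(path, "w") as handle:
        handle.write("# code  resolution  year  -logKd/Ki  affinity\n")
        for code, value in affinities.items():
            handle.write(f"{code}  2.00  {year}  {value:.6f}  pK={value:.2f}\n")


def read_similarity_matrix(path, kind: str, metric_name: str = "other") -> SimilarityMatrix:
    """Read a labeled dense similarity/dissimilarity matrix.

    First column holds test ids; the header labels the training ids.
    Values are validated against the declared ``kind``'s range
    ([0, 1] for similarity, [0, +inf) for dissimilarity).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter(path), index_col=0)
    values = df.to_numpy(dtype=float)
    return SimilarityMatrix(
        test_ids=[str(i).strip().lower() for i in df.index],
        train_ids=[str(c).strip().lower() for c in df.columns],
        values=values,
        kind=kind,
        metric_name=metric_name,
    )


def write_similarity_matrix(m: SimilarityMatrix, path) -> None:
    path = Path(path)
    df = pd.DataFrame(m.values, index=pd.Index(m.test_ids, name="id"), columns=m.train_ids)
    df.to_csv(path, sep=_delimiter(path), float_format="%.9g")


PERFORMANCE_COLUMNS = ["sf_name", "metric", "direction", "cutoff", "n_train", "rp", "rs", "rmse"]


def write_performance_table(curves, path) -> None:
    """Serialize performance curves as a long-format TSV (one row per cutoff).

    Missing evaluations (empty or sub-minimal training sets, constant
    predictions) are written as NA.
    """
    rows = []
    for curve in curves:
        for pt in curve.points:
            rows.append({
                "sf_name": curve.sf_name,
                "metric": curve.metric_name,
                "direction": curve.direction,
                "cutoff": f"{pt.cutoff:.6f}",
                "n_train": pt.n_train,
                "rp": "NA" if pt.rp is None or not math.isfinite(pt.rp) else f"{pt.rp:.6f}",
                "rs": "NA" if pt.rs is None or not math.isfinite(pt.rs) else f"{pt.rs:.6f}",
                "rmse": "NA" if pt.rmse is None or not math.isfinite(pt.rmse) else f"{pt.rmse:.6f}",
            })
    df = pd.DataFrame(rows, columns=PERFORMANCE_COLUMNS)
    df.to_csv(path, sep=_delimiter(path), index=False)


def read_performance_table(path) -> pd.DataFrame:
    """Read a performance TSV back into a DataFrame (NA -> NaN)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter(path), na_values=["NA"])
    missing = [c for c in PERFORMANCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing performance column(s) {missing}")
    return df
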