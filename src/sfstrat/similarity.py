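"""Train/test similarity metrics and similarity-matrix containers.

Three complementary views of how much a training complex resembles a test
set are supported:

* protein structure similarity — a TM-score-like value in (0, 1], produced
  by an external structure aligner and ingested as a precomputed matrix;
* ligand fingerprint similarity — the Tanimoto coefficient of circular
  (ECFP4-style) fingerprints, computed here from on-bit sets;
* binding-pocket topology dissimilarity — the city-block (Manhattan)
  distance between fixed-length pocket descriptor vectors, computed here.

The first is a similarity (1 = identical), the last a dissimilarity
(0 = identical, unbounded above); :class:`SimilarityMatrix` records which
convention applies so downstream stratification can treat both uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

SIMILARITY = "similarity"
DISSIMILARITY = "dissimilarity"
_KINDS = (SIMILARITY, DISSIMILARITY)

METRIC_NAMES = ("protein_structure", "ligand_fingerprint", "pocket_topology", "other")

__all__ = [
    "SIMILARITY",
    "DISSIMILARITY",
    "METRIC_NAMES",
    "SimilarityMatrix",
    "Fingerprint",
    "PocketVector",
    "tanimoto",
    "cityblock",
    "build_matrix",
    "skew_histogram",
    "matrix_agreement",
]


@dataclass(frozen=True)
class SimilarityMatrix:
    """Dense test-by-train matrix of pairwise (dis)similarity values.

    Rows are test complexes, columns training complexes.  ``kind`` is
    ``"similarity"`` (values in [0, 1]) or ``"dissimilarity"`` (values
    in [0, +inf)); construction validates the declared range and rejects
    NaN cells.
    """

    test_ids: tuple
    train_ids: tuple
    values: np.ndarray
    kind: str
    metric_name: str = "other"

    def __post_init__(self):
        object.__setattr__(self, "test_ids", tuple(str(i) for i in self.test_ids))
        object.__setattr__(self, "train_ids", tuple(str(i) for i in self.train_ids))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.kind not in _KINDS:
            raise ValueError(f"unknown matrix kind {self.kind!r}; expected one of {_KINDS}")
        if self.metric_name not in METRIC_NAMES:
            raise ValueError(
                f"unknown metric_name {self.metric_name!r}; expected one of {METRIC_NAMES}"
            )
        if values.ndim != 2 or values.shape != (len(self.test_ids), len(self.train_ids)):
            raise ValueError(
                f"matrix shape {values.shape} does not match "
                f"{len(self.test_ids)} test x {len(self.train_ids)} train ids"
            )
        if len(set(self.test_ids)) != len(self.test_ids):
            raise ValueError("duplicate test ids")
        if len(set(self.train_ids)) != len(self.train_ids):
            raise ValueError("duplicate train ids")
        validate_range(values, self.kind)

    @property
    def shape(self) -> tuple:
        return self.values.shape


def validate_range(values: np.ndarray, kind: str) -> None:
    """Raise ValueError (with cell coordinates) on any out-of-range or NaN cell."""
    values = np.asarray(values, dtype=float)
    bad = ~np.isfinite(values)
    bad |= values < 0
    if kind == SIMILARITY:
        bad |= values > 1
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"value {values[i, j]!r} at cell ({i}, {j}) outside the valid range for "
            f"kind={kind!r} ({'[0, 1]' if kind == SIMILARITY else '[0, +inf)'})"
        )


@dataclass(frozen=True)
class Fingerprint:
    """A hashed circular-substructure fingerprint, stored as its set of on bits."""

    on_bits: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        bits = frozenset(int(b) for b in self.on_bits)
        if any(b < 0 for b in bits):
            raise ValueError("fingerprint bits must be non-negative integers")
        object.__setattr__(self, "on_bits", bits)


@dataclass(frozen=True)
class PocketVector:
    """Fixed-length real vector encoding binding-pocket shape and charges."""

    components: np.ndarray

    def __post_init__(self):
        comp = np.asarray(self.components, dtype=float).ravel()
        if not np.all(np.isfinite(comp)):
            raise ValueError("pocket vector components must be finite")
        object.__setattr__(self, "components", comp)

    def __len__(self) -> int:
        return self.components.size


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |a & b| / |a | b| of two fingerprints.

    Two empty fingerprints score 0, not 1: an atom-free ligand carries no
    evidence of similarity.
    """
    union = len(a.on_bits | b.on_bits)
    if union == 0:
        return 0.0
    return len(a.on_bits & b.on_bits) / union


def cityblock(a: PocketVector, b: PocketVector) -> float:
    """City-block (Manhattan) distance between two pocket vectors; 0 iff identical."""
    if len(a) != len(b):
        raise ValueError(f"pocket vector length mismatch: {len(a)} vs {len(b)}")
    return float(np.abs(a.components - b.components).sum())


def _as_bit_matrix(items: list) -> np.ndarray:
    """Pack fingerprints into a dense boolean matrix over the union of bits."""
    all_bits = sorted(set().union(*(fp.on_bits for fp in items)) if items else set())
    index = {b: k for k, b in enumerate(all_bits)}
    mat = np.zeros((len(items), max(len(all_bits), 1)), dtype=bool)
    for row, fp in enumerate(items):
        for b in fp.on_bits:
            mat[row, index[b]] = True
    return mat


def build_matrix(test_items: dict, train_items: dict, metric: str,
                 metric_name: str | None = None) -> SimilarityMatrix:
    """Assemble the dense pairwise matrix between test and train items.

    ``metric`` is ``"tanimoto"`` (fingerprints, yields a similarity matrix)
    or ``"cityblock"`` (pocket vectors, yields a dissimilarity matrix).
    Cell (i, j) equals the pairwise metric between test item i and train
    item j; the Tanimoto path is evaluated as vectorised set algebra on a
    packed bit matrix, which is exactly the element-wise definition.
    """
    test_ids = tuple(test_items)
    train_ids = tuple(train_items)
    test_vals = list(test_items.values())
    train_vals = list(train_items.values())
    modalities = {type(v) for v in test_vals + train_vals}
    if metric == "tanimoto":
        if modalities - {Fingerprint}:
            raise ValueError("tanimoto requires Fingerprint items only")
        kind = SIMILARITY
        if not test_ids or not train_ids:
            values = np.zeros((len(test_ids), len(train_ids)))
        else:
            packed = _as_bit_matrix(test_vals + train_vals)
            a = packed[: len(test_vals)].astype(np.float64)
            b = packed[len(test_vals):].astype(np.float64)
            inter = a @ b.T
            union = a.sum(axis=1)[:, None] + b.sum(axis=1)[None, :] - inter
            with np.errstate(invalid="ignore"):
                values = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
        default_name = "ligand_fingerprint"
    elif metric == "cityblock":
        if modalities - {PocketVector}:
            raise ValueError("cityblock requires PocketVector items only")
        kind = DISSIMILARITY
        lengths = {len(v) for v in test_vals + train_vals}
        if len(lengths) > 1:
            raise ValueError(f"pocket vectors have mixed lengths: {sorted(lengths)}")
        if not test_ids or not train_ids:
            values = np.zeros((len(test_ids), len(train_ids)))
        else:
            values = cdist(
                np.vstack([v.components for v in test_vals]),
                np.vstack([v.components for v in train_vals]),
                metric="cityblock",
            )
        default_name = "pocket_topology"
    else:
        raise ValueError(f"unknown metric {metric!r}; expected 'tanimoto' or 'cityblock'")
    return SimilarityMatrix(
        test_ids=test_ids,
        train_ids=train_ids,
        values=values,
        kind=kind,
        metric_name=metric_name or default_name,
    )


def train_side_statistic(m: SimilarityMatrix) -> np.ndarray:
    """Per-training-complex similarity summary against the whole test set.

    For a similarity matrix this is the maximum over test complexes (the
    value that decides membership of every nested training set); for a
    dissimilarity matrix it is the minimum.  Zero test rows make every
    universally-quantified membership condition vacuously true, which is
    encoded as -inf (similarity) / +inf (dissimilarity).
    """
    if m.values.shape[0] == 0:
        fill = -np.inf if m.kind == SIMILARITY else np.inf
        return np.full(len(m.train_ids), fill)
    if m.kind == SIMILARITY:
        return m.values.max(axis=0)
    return m.values.min(axis=0)


def skew_histogram(m: SimilarityMatrix, schedule) -> list:
    """Histogram of training complexes over the cutoff increments of a schedule.

    Each entry is ``((lo, hi), count)`` for one consecutive cutoff pair of
    the schedule, in sweep order; the count is the number of training
    complexes added to the nested training set when the cutoff moves from
    the earlier to the later grid point in the dissimilar-first direction.
    For a similarity metric the bin is the half-open interval (c_k, c_{k+1}]
    of the per-train max-over-tests similarity; for a dissimilarity metric
    it is [c_{k+1}, c_k) of the min-over-tests distance.  Counts therefore
    sum to the number of training complexes inside the schedule's range.
    """
    stat = train_side_statistic(m)
    cutoffs = schedule.cutoffs()
    bins = []
    for lo, hi in zip(cutoffs[:-1], cutoffs[1:]):
        if m.kind == SIMILARITY:
            count = int(np.sum((stat > lo) & (stat <= hi)))
        else:
            count = int(np.sum((stat >= hi) & (stat < lo)))
        bins.append(((lo, hi), count))
    return bins


def matrix_agreement(a: SimilarityMatrix, b: SimilarityMatrix, threshold: float) -> float:
    """Fraction of cells where the two matrices differ by at most ``threshold``.

    Used to quantify how closely two alternative protein-structure
    alignment protocols agree over all pairwise scores; the comparison is
    inclusive (|a - b| <= threshold counts as agreement).
    """
    if a.test_ids != b.test_ids or a.train_ids != b.train_ids:
        raise ValueError("matrices must share identical test and train id orderings")
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    diff = np.abs(a.values - b.values)
    # thresholds are printed decimals; guard the <= against binary-float
    # representation error (|0.9 - 0.7| evaluates slightly above 0.2)
    return float(np.mean(diff <= threshold + 1e-12))
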