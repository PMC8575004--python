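"""Nested training-set construction stratified by train/test similarity.

Given a fixed test set TS and the original full training set OT, a family
of nested training sets is built over a grid of cutoff values c, in two
sweep directions:

* dissimilar-first (``ds``) — start from the complexes least similar to
  the test set and grow toward the full set.  For a similarity metric s,
  NT(c) = { p in OT : for every q in TS, s(p, q) <= c }, so NT(1) = OT.
  For a dissimilarity metric d, NT(c) = { p : for every q, d(p, q) >= c },
  so NT(0) = OT and the grid is swept downward.
* similar-first (``sd``) — the complementary sets: for similarity,
  NT(c) = { p : there exists q with s(p, q) > c }; for dissimilarity,
  NT(c) = { p : there exists q with d(p, q) < c }.

At every cutoff the ds and sd sets partition OT, and each family is
nested along its sweep.  Membership depends only on each training
complex's extreme similarity over the test set (max for similarity, min
for dissimilarity), so families are built by thresholding that one
per-complex statistic — provably equivalent to evaluating the
quantifiers directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal
from pathlib import Path

import numpy as np

from .similarity import DISSIMILARITY, SIMILARITY, SimilarityMatrix, train_side_statistic

__all__ = [
    "CutoffSchedule",
    "NestedSetFamily",
    "DEFAULT_SCHEDULES",
    "nested_set",
    "build_family",
    "family_sizes",
    "export_family",
    "deposited_counts",
]


@dataclass(frozen=True)
class CutoffSchedule:
    """An exact decimal cutoff grid from ``start`` to ``end`` in steps of ``step``.

    Grid points are generated as integer multiples of the decimal step and
    rounded to the step's decimal places, so a printed cutoff like 0.99 is
    compared exactly as 0.99 rather than accumulating binary-float drift
    across a 61-point sweep.  ``orientation`` follows the sign of
    ``end - start``.
    """

    start: float
    end: float
    step: float

    def __post_init__(self):
        if self.step <= 0:
            raise ValueError("step must be positive")
        span = abs(Decimal(str(self.end)) - Decimal(str(self.start)))
        ratio = span / Decimal(str(self.step))
        if ratio != ratio.to_integral_value():
            raise ValueError(
                f"span |{self.end} - {self.start}| is not an integer multiple of step {self.step}"
            )

    @property
    def orientation(self) -> str:
        return "ascending" if self.end >= self.start else "descending"

    @property
    def n_cutoffs(self) -> int:
        return int(round(abs(self.end - self.start) / self.step)) + 1

    @property
    def decimals(self) -> int:
        return max(0, -Decimal(str(self.step)).as_tuple().exponent)

    def cutoffs(self) -> list:
        sign = 1.0 if self.orientation == "ascending" else -1.0
        return [round(self.start + sign * k * self.step, self.decimals)
                for k in range(self.n_cutoffs)]


#: The grids used throughout: protein-structure TM-score similarity swept
#: 0.40 -> 1.00 in steps of 0.01 (61 cutoffs), ligand-fingerprint Tanimoto
#: similarity 0.50 -> 1.00 in steps of 0.01 (51 cutoffs), and pocket-topology
#: city-block dissimilarity 10.0 -> 0.0 in steps of 0.2 (51 cutoffs).  All
#: three run in the ds sweep order (increasing inclusion).
DEFAULT_SCHEDULES = {
    "protein_structure": CutoffSchedule(0.40, 1.00, 0.01),
    "ligand_fingerprint": CutoffSchedule(0.50, 1.00, 0.01),
    "pocket_topology": CutoffSchedule(10.0, 0.0, 0.2),
}


@dataclass(frozen=True)
class NestedSetFamily:
    """Ordered map cutoff -> training-id set for one metric and one direction."""

    metric_name: str
    kind: str
    direction: str
    cutoffs: tuple
    sets: dict
    full_set: frozenset

    def __post_init__(self):
        if self.direction not in ("ds", "sd"):
            raise ValueError(f"direction must be 'ds' or 'sd', got {self.direction!r}")

    def set_at(self, cutoff: float) -> frozenset:
        return self.sets[cutoff]


def nested_set(m: SimilarityMatrix, c: float, direction: str) -> frozenset:
    """The nested training set at one cutoff, per the quantifier definitions.

    similarity/ds:    every test similarity <= c      (max <= c)
    similarity/sd:    some test similarity  > c       (max >  c)
    dissimilarity/ds: every test distance   >= c      (min >= c)
    dissimilarity/sd: some test distance    <  c      (min <  c)
    """
    if direction not in ("ds", "sd"):
        raise ValueError(f"direction must be 'ds' or 'sd', got {direction!r}")
    stat = train_side_statistic(m)
    if m.kind == SIMILARITY:
        mask = stat <= c if direction == "ds" else stat > c
    else:
        mask = stat >= c if direction == "ds" else stat < c
    return frozenset(np.asarray(m.train_ids, dtype=object)[mask].tolist())


def build_family(m: SimilarityMatrix, schedule: CutoffSchedule, direction: str) -> NestedSetFamily:
    """Build the whole nested family over a cutoff schedule.

    The per-train extreme statistic is computed once and thresholded at
    every grid point.  For a similarity matrix the schedule must lie in
    [0, 1]; a dissimilarity schedule must be non-negative.
    """
    cutoffs = schedule.cutoffs()
    if m.kind == SIMILARITY and (min(cutoffs) < 0 or max(cutoffs) > 1):
        raise ValueError("similarity schedule must lie within [0, 1]")
    if m.kind == DISSIMILARITY and min(cutoffs) < 0:
        raise ValueError("dissimilarity schedule must be non-negative")
    stat = train_side_statistic(m)
    train_ids = np.asarray(m.train_ids, dtype=object)
    sets = {}
    for c in cutoffs:
        if m.kind == SIMILARITY:
            mask = stat <= c if direction == "ds" else stat > c
        else:
            mask = stat >= c if direction == "ds" else stat < c
        sets[c] = frozenset(train_ids[mask].tolist())
    return NestedSetFamily(
        metric_name=m.metric_name,
        kind=m.kind,
        direction=direction,
        cutoffs=tuple(cutoffs),
        sets=sets,
        full_set=frozenset(m.train_ids),
    )


def family_sizes(f: NestedSetFamily) -> list:
    """Ordered (cutoff, n_train) pairs along the family's sweep."""
    return [(c, len(f.sets[c])) for c in f.cutoffs]


def export_family(f: NestedSetFamily, path) -> None:
    """Audit export: one TSV row per cutoff with the member ids joined by ';'."""
    with open(path, "w") as handle:
        handle.write("metric\tdirection\tcutoff\tn_train\tids\n")
        for c in f.cutoffs:
            ids = ";".join(sorted(f.sets[c]))
            handle.write(f"{f.metric_name}\t{f.direction}\t{c}\t{len(f.sets[c])}\t{ids}\n")


def deposited_counts(matrix: SimilarityMatrix, cutoffs, band: tuple | None = None) -> dict:
    """Nested-set sizes (ds direction) at given cutoffs, plus an optional band count.

    Convenience for auditing a deposited protein-structure similarity
    matrix: returns ``{cutoff: |NT_ds(cutoff)|}`` and, when ``band=(lo, hi)``
    is given, the number of training complexes whose max-over-tests
    similarity falls in the half-open interval (lo, hi] under key
    ``"band"``.
    """
    out = {c: len(nested_set(matrix, c, "ds")) for c in cutoffs}
    if band is not None:
        stat = train_side_statistic(matrix)
        lo, hi = band
        out["band"] = int(np.sum((stat > lo) & (stat <= hi)))
    return out
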