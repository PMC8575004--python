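"""Scoring power, cutoff sweeps, crossing points and sharp leaps.

Scoring power is the standard triple used in community benchmarking:
Pearson correlation (Rp) and Spearman correlation (Rs) between predicted
and measured affinities, plus the root-mean-square error (RMSE) in pK
units.  Higher Rp/Rs and lower RMSE are better.

A *sweep* retrains a list of scoring functions on every nested training
set of a family and evaluates each on the fixed held-out test set,
yielding one performance curve per scoring function.  Two curve
diagnostics follow the way results are usually narrated:

* a *crossing point* — the first cutoff at which one scoring function
  becomes strictly better than another (with a flag for whether the
  advantage is sustained over all later cutoffs);
* *leap deltas* — per-step metric increments along a curve, used to spot
  the sharp leap that the heavily populated (0.99, 1] near-duplicate
  similarity band produces in ML-based scoring functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .io_formats import AffinityTable, FeatureTable
from .scoring import ModelSpec, fit_scoring_function, predict
from .stratify import NestedSetFamily

#: Fewest training rows accepted: p + 2 for a p-feature linear fit, 10 for
#: tree ensembles.  Below these a curve point is recorded as missing.
MIN_ROWS_ENSEMBLE = 10

_METRICS = ("rp", "rs", "rmse")

__all__ = [
    "ScoringPower",
    "CurvePoint",
    "PerformanceCurve",
    "CrossingPoint",
    "scoring_power",
    "sweep",
    "find_crossing",
    "leap_deltas",
    "largest_leap",
    "export_scatter",
    "MIN_ROWS_ENSEMBLE",
]


@dataclass(frozen=True)
class ScoringPower:
    rp: float
    rs: float
    rmse: float


@dataclass(frozen=True)
class CurvePoint:
    cutoff: float
    n_train: int
    rp: float = math.nan
    rs: float = math.nan
    rmse: float = math.nan

    def metric(self, name: str) -> float:
        if name not in _METRICS:
            raise ValueError(f"metric must be one of {_METRICS}, got {name!r}")
        return getattr(self, name)


@dataclass(frozen=True)
class PerformanceCurve:
    """Per-cutoff scoring power of one scoring function along one sweep."""

    sf_name: str
    metric_name: str
    direction: str
    points: tuple

    def cutoffs(self) -> tuple:
        return tuple(pt.cutoff for pt in self.points)

    def series(self, metric: str) -> np.ndarray:
        return np.array([pt.metric(metric) for pt in self.points], dtype=float)


@dataclass(frozen=True)
class CrossingPoint:
    sf_a: str
    sf_b: str
    metric: str
    cutoff: float
    n_train: int
    sustained: bool


def scoring_power(pred: dict, obs: dict) -> ScoringPower:
    """Rp, Rs and RMSE over the ids shared by predictions and observations.

    Spearman uses average ranks for ties.  If either side is constant the
    correlations are undefined and returned as NaN; the RMSE is still
    computed.  Fewer than 2 shared ids is an error.
    """
    shared = sorted(set(pred) & set(obs))
    if len(shared) < 2:
        raise ValueError(f"need at least 2 shared ids, got {len(shared)}")
    p = np.array([pred[i] for i in shared], dtype=float)
    o = np.array([obs[i] for i in shared], dtype=float)
    rmse = float(np.sqrt(np.mean((p - o) ** 2)))
    if np.ptp(p) == 0 or np.ptp(o) == 0:
        return ScoringPower(math.nan, math.nan, rmse)
    rp = float(stats.pearsonr(p, o).statistic)
    rs = float(stats.spearmanr(p, o).statistic)
    return ScoringPower(rp, rs, rmse)


def _point_seed(global_seed: int, cutoff_index: int) -> int:
    # distinct, stable, < 2^31 per (seed, grid point)
    return (int(global_seed) * 100003 + 7919 * cutoff_index) % (2**31 - 1)


def sweep(specs, family: NestedSetFamily, X: FeatureTable, y: AffinityTable,
          test_X: FeatureTable, test_y: AffinityTable,
          global_seed: int = 0) -> list:
    """Retrain every spec on every nested training set; score on the test set.

    Training rows are taken from ``X`` restricted to the family's set at
    each cutoff (in ``X``'s row order, so results do not depend on set
    iteration order).  Sets smaller than the model's minimum (p + 2 rows
    for linear fits, 10 for ensembles) yield a missing point.  Each
    ensemble fit is seeded from ``(global_seed, cutoff index)``, making
    the whole sweep reproducible bit-for-bit.
    """
    overlap = set(X.ids) & set(test_X.ids)
    if overlap:
        raise ValueError(f"train/test overlap on id(s) {sorted(overlap)[:5]}")
    test_obs = {i: test_y[i] for i in test_X.ids if i in test_y}
    curves = []
    for spec in specs:
        if not isinstance(spec, ModelSpec):
            spec = ModelSpec(str(spec))
        min_rows = MIN_ROWS_ENSEMBLE if spec.family in ("RF", "XGB") else len(spec.columns) + 2
        points = []
        for idx, c in enumerate(family.cutoffs):
            ids = [i for i in X.ids if i in family.sets[c]]
            if len(ids) < min_rows:
                points.append(CurvePoint(cutoff=c, n_train=len(family.sets[c])))
                continue
            sub = X.select_ids(ids)
            model = fit_scoring_function(spec.with_seed(_point_seed(global_seed, idx)), sub, y)
            power = scoring_power(predict(model, test_X), test_obs)
            points.append(CurvePoint(cutoff=c, n_train=len(family.sets[c]),
                                     rp=power.rp, rs=power.rs, rmse=power.rmse))
        curves.append(PerformanceCurve(
            sf_name=spec.sf_name,
            metric_name=family.metric_name,
            direction=family.direction,
            points=tuple(points),
        ))
    return curves


def find_crossing(a: PerformanceCurve, b: PerformanceCurve, metric: str) -> CrossingPoint | None:
    """First cutoff (in sweep order) where curve ``a`` strictly beats ``b``.

    "Better" means higher for rp/rs and lower for rmse.  Cutoffs where
    either curve is missing are not eligible.  ``sustained`` is True iff
    ``a`` stays at least as good at every later comparable cutoff —
    capturing both the "surpassed at cutoff X" and the "from X onwards"
    readings of a crossing.
    """
    if a.cutoffs() != b.cutoffs():
        raise ValueError("curves are on different cutoff grids")
    sign = -1.0 if metric == "rmse" else 1.0
    va, vb = a.series(metric) * sign, b.series(metric) * sign
    comparable = np.isfinite(va) & np.isfinite(vb)
    for idx in np.flatnonzero(comparable & (va > vb)):
        later = np.flatnonzero(comparable)
        later = later[later > idx]
        sustained = bool(np.all(va[later] >= vb[later]))
        pt = a.points[idx]
        return CrossingPoint(a.sf_name, b.sf_name, metric, pt.cutoff, pt.n_train, sustained)
    return None


def leap_deltas(c: PerformanceCurve, metric: str) -> list:
    """Per-step metric increments: ((cutoff_i, cutoff_{i+1}), value_{i+1} - value_i).

    Steps touching a missing point carry a NaN delta.
    """
    values = c.series(metric)
    if np.sum(np.isfinite(values)) < 2:
        raise ValueError("need at least 2 non-missing points")
    cutoffs = c.cutoffs()
    return [((cutoffs[i], cutoffs[i + 1]), float(values[i + 1] - values[i]))
            for i in range(len(cutoffs) - 1)]


def largest_leap(c: PerformanceCurve, metric: str) -> tuple:
    """The interval with the largest increase (rp/rs) or largest drop (rmse)."""
    deltas = leap_deltas(c, metric)
    key = (lambda d: -d[1]) if metric == "rmse" else (lambda d: d[1])
    finite = [d for d in deltas if math.isfinite(d[1])]
    if not finite:
        raise ValueError("no finite deltas")
    return max(finite, key=key)


def export_scatter(pred: dict, obs: dict, path, plot_path=None) -> None:
    """Write (measured, predicted) pairs as TSV; optionally render a scatter plot."""
    shared = sorted(set(pred) & set(obs))
    if not shared:
        raise ValueError("no shared ids between predictions and observations")
    with open(path, "w") as handle:
        handle.write("id\tmeasured\tpredicted\n")
        for i in shared:
            handle.write(f"{i}\t{obs[i]:.6f}\t{pred[i]:.6f}\n")
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        o = np.array([obs[i] for i in shared])
        p = np.array([pred[i] for i in shared])
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(o, p, s=8, alpha=0.6)
        lo, hi = min(o.min(), p.min()), max(o.max(), p.max())
        ax.plot([lo, hi], [lo, hi], "k--", lw=0.8)
        ax.set_xlabel("measured affinity (pK)")
        ax.set_ylabel("predicted affinity (pK)")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
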