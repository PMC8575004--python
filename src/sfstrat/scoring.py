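"""Classical (MLR) and machine-learning scoring functions on a fit/predict contract.

Eight scoring functions are supported, named ``family::features``:

* ``MLR::Xscore`` — a consensus of three parallel ordinary-least-squares
  fits.  Each constituent uses van der Waals (VDW), hydrogen bonding (HB)
  and rotor/deformation penalty (RT) plus one of three alternative
  hydrophobic-effect terms (HP, HM, HS); the predicted affinity is the
  arithmetic mean of the three constituent predictions.
* ``MLR::Vina`` — a quasi-linear model: the weighted sum of five empirical
  interaction terms is normalized by 1 + w_rot * Nrot, where Nrot is a
  ligand-only conformational-freedom count and w_rot is fixed (the
  published rotor weight), never recalibrated.  Equivalently, each term
  column is divided row-wise by (1 + w_rot * Nrot) and OLS is run on the
  transformed design; the intercept sits outside the normalization.
* ``MLR::Cyscore`` — plain OLS on four intermolecular terms.
* ``RF::Xscore``, ``RF::Vina``, ``RF::Cyscore``, ``RF::XVC`` — random-forest
  regressors on the same feature subsets (XVC = all sixteen combined).
* ``XGB::XVC`` — gradient-boosted trees on the combined sixteen features.

All fits take a FeatureTable and an AffinityTable and return a
TrainedScoringFunction whose predictions are in pK units and reproducible
bit-for-bit given the same spec, data and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import scipy.linalg
from sklearn.ensemble import RandomForestRegressor
from xgboost import XGBRegressor

from .io_formats import AffinityTable, FeatureTable

# ---------------------------------------------------------------------------
# Feature registry
# ---------------------------------------------------------------------------

XSCORE6 = ("VDW", "HB", "RT", "HP", "HM", "HS")
VINA6 = ("gauss1", "gauss2", "repulsion", "hydrophobic", "hbond", "Nrot")
CYSCORE4 = ("hydrophobic_free_energy", "vdw_energy", "hbond_energy", "ligand_entropy")
XVC16 = XSCORE6 + VINA6 + CYSCORE4

FEATURE_REGISTRY = {
    "XSCORE6": XSCORE6,
    "VINA6": VINA6,
    "CYSCORE4": CYSCORE4,
    "XVC16": XVC16,
}

#: The three X-Score constituents share VDW/HB/RT and differ only in the
#: hydrophobic-effect term.
XSCORE_CONSTITUENTS = (
    ("VDW", "HB", "RT", "HP"),
    ("VDW", "HB", "RT", "HM"),
    ("VDW", "HB", "RT", "HS"),
)

#: Published AutoDock Vina rotor weight; adopted without recalibration.
DEFAULT_NROT_WEIGHT = 0.05846

SF_NAMES = (
    "MLR::Xscore", "MLR::Vina", "MLR::Cyscore",
    "RF::Xscore", "RF::Vina", "RF::Cyscore", "RF::XVC",
    "XGB::XVC",
)

_SUBSET_OF = {
    "Xscore": "XSCORE6",
    "Vina": "VINA6",
    "Cyscore": "CYSCORE4",
    "XVC": "XVC16",
}

RF_DEFAULTS = {"n_estimators": 500}
XGB_DEFAULTS = {"n_estimators": 500, "learning_rate": 0.05, "max_depth": 6, "subsample": 0.8}

__all__ = [
    "XSCORE6", "VINA6", "CYSCORE4", "XVC16", "FEATURE_REGISTRY",
    "XSCORE_CONSTITUENTS", "DEFAULT_NROT_WEIGHT", "SF_NAMES",
    "ModelSpec", "TrainedScoringFunction",
    "fit_mlr", "fit_mlr_xscore", "fit_mlr_vina", "fit_tree_ensemble",
    "fit_scoring_function", "predict", "save_model", "load_model",
]


@dataclass(frozen=True)
class ModelSpec:
    """A named scoring function plus hyperparameters and a seed."""

    sf_name: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.sf_name not in SF_NAMES:
            raise ValueError(f"unknown scoring function {self.sf_name!r}; expected one of {SF_NAMES}")

    @property
    def family(self) -> str:
        return self.sf_name.split("::")[0]

    @property
    def feature_subset(self) -> str:
        return _SUBSET_OF[self.sf_name.split("::")[1]]

    @property
    def columns(self) -> tuple:
        return FEATURE_REGISTRY[self.feature_subset]

    def with_seed(self, seed: int) -> "ModelSpec":
        return ModelSpec(self.sf_name, dict(self.hyperparams), int(seed))


@dataclass
class TrainedScoringFunction:
    """A fitted scoring function bound to its feature columns.

    ``parameters`` holds linear coefficients for the MLR kinds (one
    ``(coef, intercept, columns)`` entry per constituent) or is None for
    tree ensembles, whose fitted estimator lives in ``estimator``.
    """

    spec: ModelSpec
    kind: str                     # "mlr" | "mlr_consensus" | "mlr_vina" | "ensemble"
    columns: tuple
    parameters: list | None = None
    estimator: object = None
    nrot_weight: float | None = None
    training_ids: frozenset = frozenset()

    def predict(self, X: FeatureTable) -> dict:
        return predict(self, X)


# ---------------------------------------------------------------------------
# Linear fits
# ---------------------------------------------------------------------------

def _design(X: FeatureTable, columns) -> np.ndarray:
    sub = X.select_columns(list(columns))
    return sub.values


def _ols(design: np.ndarray, y: np.ndarray, columns) -> tuple:
    """OLS with intercept; raises on rank deficiency naming the collinear columns."""
    n, p = design.shape
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} rows to fit {p} coefficients, got {n}")
    A = np.column_stack([np.ones(n), design])
    _, r, piv = scipy.linalg.qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(A.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    if rank < p + 1:
        dependent = sorted(
            ("intercept" if k == 0 else columns[k - 1]) for k in piv[rank:]
        )
        raise ValueError(f"rank-deficient design; collinear column(s): {dependent}")
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return coef[1:], float(coef[0])


def fit_mlr(X: FeatureTable, y: AffinityTable, columns=None,
            spec: ModelSpec | None = None) -> TrainedScoringFunction:
    """Ordinary least squares with intercept on the given feature columns."""
    columns = tuple(columns) if columns is not None else tuple(X.columns)
    design = _design(X, columns)
    target = y.vector_for(X.ids)
    coef, intercept = _ols(design, target, columns)
    # plain fit_mlr is also usable outside the eight named SFs; tag it as the
    # closest strict-MLR spec unless the caller provides one
    return TrainedScoringFunction(
        spec=spec if spec is not None else ModelSpec("MLR::Cyscore"),
        kind="mlr",
        columns=columns,
        parameters=[(coef, intercept, columns)],
        training_ids=frozenset(X.ids),
    )


def fit_mlr_xscore(X: FeatureTable, y: AffinityTable, seed: int = 0) -> TrainedScoringFunction:
    """Consensus-of-three X-Score recalibration.

    Three OLS fits sharing VDW/HB/RT and differing in the hydrophobic term
    (HP, HM or HS); prediction is the mean of the three raw constituent
    predictions.
    """
    target = y.vector_for(X.ids)
    parameters = []
    for cols in XSCORE_CONSTITUENTS:
        design = _design(X, cols)
        coef, intercept = _ols(design, target, cols)
        parameters.append((coef, intercept, cols))
    return TrainedScoringFunction(
        spec=ModelSpec("MLR::Xscore", seed=seed),
        kind="mlr_consensus",
        columns=XSCORE6,
        parameters=parameters,
        training_ids=frozenset(X.ids),
    )


def _vina_transform(X: FeatureTable, nrot_weight: float) -> tuple:
    terms = [c for c in VINA6 if c != "Nrot"]
    sub = X.select_columns(list(VINA6))
    nrot = sub.values[:, list(VINA6).index("Nrot")]
    denom = 1.0 + nrot_weight * nrot
    if np.any(denom <= 0):
        row = int(np.argmax(denom <= 0))
        raise ValueError(
            f"1 + w_rot*Nrot <= 0 at row {X.ids[row]!r} (Nrot={nrot[row]}); "
            "cannot normalize"
        )
    term_idx = [list(VINA6).index(c) for c in terms]
    transformed = sub.values[:, term_idx] / denom[:, None]
    return transformed, tuple(terms)


def fit_mlr_vina(X: FeatureTable, y: AffinityTable,
                 nrot_weight: float = DEFAULT_NROT_WEIGHT,
                 seed: int = 0) -> TrainedScoringFunction:
    """Quasi-MLR Vina recalibration with a fixed (non-fitted) Nrot weight.

    Each of the five empirical term columns is divided row-wise by
    1 + w_rot*Nrot before the OLS; prediction applies the same transform.
    """
    transformed, terms = _vina_transform(X, nrot_weight)
    target = y.vector_for(X.ids)
    coef, intercept = _ols(transformed, target, terms)
    return TrainedScoringFunction(
        spec=ModelSpec("MLR::Vina", seed=seed),
        kind="mlr_vina",
        columns=VINA6,
        parameters=[(coef, intercept, terms)],
        nrot_weight=float(nrot_weight),
        training_ids=frozenset(X.ids),
    )


# ---------------------------------------------------------------------------
# Tree ensembles
# ---------------------------------------------------------------------------

def fit_tree_ensemble(X: FeatureTable, y: AffinityTable, spec: ModelSpec) -> TrainedScoringFunction:
    """Fit the RF or XGB variant named by ``spec.sf_name`` on its feature subset.

    Random forests use 500 bootstrap trees with max(1, floor(p/3)) feature
    candidates per split (the RF-Score convention); gradient boosting uses
    500 rounds at learning rate 0.05, depth 6, subsample 0.8.  Both are
    seeded and single-threaded, so repeated fits are bit-identical.
    """
    if spec.family not in ("RF", "XGB"):
        raise ValueError(f"{spec.sf_name!r} is not a tree-ensemble scoring function")
    columns = spec.columns
    design = _design(X, columns)
    target = y.vector_for(X.ids)
    if len(target) < 2:
        raise ValueError("need at least 2 training rows for a tree ensemble")
    if spec.family == "RF":
        params = {**RF_DEFAULTS, **spec.hyperparams}
        est = RandomForestRegressor(
            n_estimators=params["n_estimators"],
            max_features=max(1, len(columns) // 3),
            bootstrap=True,
            random_state=int(spec.seed),
            n_jobs=1,
        )
    else:
        params = {**XGB_DEFAULTS, **spec.hyperparams}
        est = XGBRegressor(
            n_estimators=params["n_estimators"],
            learning_rate=params["learning_rate"],
            max_depth=params["max_depth"],
            subsample=params["subsample"],
            random_state=int(spec.seed),
            n_jobs=1,
            verbosity=0,
        )
    est.fit(design, target)
    return TrainedScoringFunction(
        spec=spec,
        kind="ensemble",
        columns=columns,
        estimator=est,
        training_ids=frozenset(X.ids),
    )


# ---------------------------------------------------------------------------
# Unified fit / predict
# ---------------------------------------------------------------------------

def fit_scoring_function(spec: ModelSpec, X: FeatureTable, y: AffinityTable) -> TrainedScoringFunction:
    """Train any of the eight named scoring functions."""
    if spec.sf_name == "MLR::Xscore":
        return fit_mlr_xscore(X, y, seed=spec.seed)
    if spec.sf_name == "MLR::Vina":
        weight = spec.hyperparams.get("nrot_weight", DEFAULT_NROT_WEIGHT)
        return fit_mlr_vina(X, y, nrot_weight=weight, seed=spec.seed)
    if spec.sf_name == "MLR::Cyscore":
        model = fit_mlr(X.select_columns(list(CYSCORE4)), y, columns=CYSCORE4)
        model.spec = spec
        return model
    return fit_tree_ensemble(X, y, spec)


def predict(model: TrainedScoringFunction, X: FeatureTable) -> dict:
    """Predicted affinities (pK units) for every row, in row order."""
    missing = [c for c in model.columns if c not in X.columns]
    if missing:
        raise ValueError(
            f"feature table lacks column(s) {missing} required by {model.spec.sf_name}"
        )
    if model.kind == "ensemble":
        values = model.estimator.predict(_design(X, model.columns))
    elif model.kind == "mlr_vina":
        transformed, terms = _vina_transform(X, model.nrot_weight)
        coef, intercept, _ = model.parameters[0]
        values = transformed @ coef + intercept
    else:
        preds = []
        for coef, intercept, cols in model.parameters:
            preds.append(_design(X, cols) @ coef + intercept)
        values = np.mean(preds, axis=0)
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{model.spec.sf_name} produced non-finite predictions")
    return dict(zip(X.ids, values.tolist()))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_model(model: TrainedScoringFunction, path) -> None:
    """Persist a trained scoring function.

    Linear kinds are saved as self-describing JSON; tree ensembles as a
    joblib dump with a JSON sidecar header embedded in the payload.
    """
    path = Path(path)
    if model.kind == "ensemble":
        joblib.dump({
            "spec": {"sf_name": model.spec.sf_name,
                     "hyperparams": model.spec.hyperparams,
                     "seed": model.spec.seed},
            "kind": model.kind,
            "columns": list(model.columns),
            "estimator": model.estimator,
            "training_ids": sorted(model.training_ids),
        }, path)
        return
    payload = {
        "spec": {"sf_name": model.spec.sf_name,
                 "hyperparams": model.spec.hyperparams,
                 "seed": model.spec.seed},
        "kind": model.kind,
        "columns": list(model.columns),
        "nrot_weight": model.nrot_weight,
        "training_ids": sorted(model.training_ids),
        "parameters": [
            {"coef": list(map(float, coef)), "intercept": intercept, "columns": list(cols)}
            for coef, intercept, cols in model.parameters
        ],
    }
    path.write_text(json.dumps(payload, indent=1))


def load_model(path) -> TrainedScoringFunction:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
        binary = False
    except (UnicodeDecodeError, json.JSONDecodeError):
        payload = joblib.load(path)
        binary = True
    spec = ModelSpec(payload["spec"]["sf_name"], payload["spec"]["hyperparams"],
                     payload["spec"]["seed"])
    if binary:
        return TrainedScoringFunction(
            spec=spec, kind=payload["kind"], columns=tuple(payload["columns"]),
            estimator=payload["estimator"],
            training_ids=frozenset(payload["training_ids"]),
        )
    parameters = [
        (np.array(entry["coef"], dtype=float), float(entry["intercept"]), tuple(entry["columns"]))
        for entry in payload["parameters"]
    ]
    return TrainedScoringFunction(
        spec=spec, kind=payload["kind"], columns=tuple(payload["columns"]),
        parameters=parameters, nrot_weight=payload.get("nrot_weight"),
        training_ids=frozenset(payload["training_ids"]),
    )
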