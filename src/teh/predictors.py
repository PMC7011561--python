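"""Pluggable outcome predictors and individual-treatment-effect estimation.

A predictor is any learner of Pr(Y = 1 | X, T) fitted on one half of the
trial.  Two adapters ship with the package:

``glm``
    Unpenalised logistic regression with linear main effects for every
    covariate plus the treatment indicator (categoricals one-hot encoded,
    no interactions).  Its linear predictor Z_i = intercept + X_i beta +
    T_i alpha_treat is the baseline the stacking test compares against.

``random_forest``
    A random-forest classifier (established implementation, wrapped not
    reimplemented) with the conventional classification defaults:
    500 trees, sqrt(d) variables sampled per node, minimum leaf size 1.

Individual treatment effects are estimated with a counterfactual toggle:
one model with T as a feature is evaluated under forced T = 1 and T = 0,

    ite_i = Pr(Y=1 | X_i, T=1) - Pr(Y=1 | X_i, T=0).

With outcome 1 an adverse event, ite < 0 means the experimental arm is
predicted beneficial; ties go to standard of care.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "PredictorSpec",
    "FittedPredictor",
    "GlmFit",
    "register_predictor",
    "fit_predictor",
    "predict_event_probability",
    "estimate_ite",
    "glm_linear_predictor",
    "clip_probability",
    "DegenerateTrainingError",
]


class DegenerateTrainingError(ValueError):
    """Training data cannot support a fit (constant outcome or single arm)."""


@dataclass(frozen=True)
class PredictorSpec:
    """Name + hyperparameters + seed identifying a predictor configuration."""

    name: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "hyperparameters": dict(self.hyperparameters),
            "seed": self.seed,
        }


@dataclass
class GlmFit:
    """Coefficients of the baseline logistic GLM."""

    intercept: float
    beta: np.ndarray
    alpha_treat: float


@dataclass
class FittedPredictor:
    """A fitted predictor plus the design schema it was trained on."""

    spec: PredictorSpec
    columns: list          # design-matrix column names (post one-hot)
    categories: dict       # covariate -> category levels seen in training
    training_info: dict
    backend: object
    glm_fit: GlmFit | None = None


def _encode(X: pd.DataFrame, categories: dict | None = None):
    """One-hot encode categoricals with a fixed category set.

    Returns (matrix DataFrame, categories) so that prediction rows are
    expanded against the training levels.
    """
    X = pd.DataFrame(X).reset_index(drop=True)
    if categories is None:
        categories = {
            c: list(X[c].astype("category").cat.categories)
            for c in X.columns
            if not pd.api.types.is_numeric_dtype(X[c])
        }
    work = X.copy()
    unknown = []
    for c, levels in categories.items():
        if c not in work.columns:
            raise ValueError(f"covariate column {c!r} missing at prediction time")
        col = pd.Categorical(work[c], categories=levels)
        if pd.isna(col).sum() > pd.isna(work[c]).sum():
            unknown.append(c)
        work[c] = col
    if unknown:
        raise ValueError(f"unseen category levels in columns: {unknown}")
    mat = pd.get_dummies(work, columns=list(categories), drop_first=True, dtype=float)
    return mat.astype(float), categories


def _check_training(T: np.ndarray, Y: np.ndarray):
    if len(np.unique(Y)) < 2:
        raise DegenerateTrainingError("degenerate training outcome (Y constant)")
    if len(np.unique(T)) < 2:
        raise DegenerateTrainingError("degenerate training arm (single arm)")


class _GlmBackend:
    def __init__(self, result):
        self.result = result

    def predict_proba(self, design: np.ndarray) -> np.ndarray:
        return np.asarray(self.result.predict(design))

    def linear_predictor(self, design: np.ndarray) -> np.ndarray:
        return design @ np.asarray(self.result.params)


def _fit_glm(spec, Xmat, T, Y):
    design = np.column_stack([np.ones(len(T)), Xmat.to_numpy(), T])
    try:
        with warnings.catch_warnings():
            # convergence is checked below via finiteness of the params
            warnings.simplefilter("ignore")
            res = sm.Logit(Y, design).fit(disp=0, maxiter=200)
        params = np.asarray(res.params)
        if not np.all(np.isfinite(params)):
            raise np.linalg.LinAlgError("non-finite coefficients")
    except Exception as exc:  # separation / singular design on a small half
        raise DegenerateTrainingError(f"GLM fit failed: {exc}") from exc
    fit = GlmFit(
        intercept=float(params[0]),
        beta=params[1:-1].copy(),
        alpha_treat=float(params[-1]),
    )
    return _GlmBackend(res), fit


class _RfBackend:
    def __init__(self, model, classes_pos):
        self.model = model
        self._pos = classes_pos

    def predict_proba(self, design: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(design)[:, self._pos]


def _fit_random_forest(spec, Xmat, T, Y):
    hp = spec.hyperparameters
    model = RandomForestClassifier(
        n_estimators=int(hp.get("n_trees", 500)),
        max_features=hp.get("max_features", "sqrt"),
        min_samples_leaf=int(hp.get("min_leaf", 1)),
        random_state=spec.seed,
        n_jobs=1,
    )
    design = np.column_stack([Xmat.to_numpy(), T])
    model.fit(design, Y)
    pos = int(np.flatnonzero(model.classes_ == 1)[0])
    return _RfBackend(model, pos), None


_REGISTRY = {"glm": _fit_glm, "random_forest": _fit_random_forest}


def register_predictor(name: str, constructor):
    """Register a learner under ``name``.

    ``constructor(spec, Xmat, T, Y)`` must return ``(backend, glm_fit_or_None)``
    where the backend exposes ``predict_proba(design_matrix)`` on the design
    ``[encoded X | T]`` (the GLM design additionally has a leading 1 column,
    handled internally; custom backends see ``[encoded X | T]``).
    """
    _REGISTRY[name] = constructor


def fit_predictor(spec: PredictorSpec, data) -> FittedPredictor:
    """Fit the predictor named by ``spec`` on a trial (half)."""
    if spec.name not in _REGISTRY:
        raise KeyError(
            f"unknown predictor {spec.name!r}; registered: {sorted(_REGISTRY)}"
        )
    _check_training(data.T, data.Y)
    Xmat, categories = _encode(data.X)
    backend, glm_fit = _REGISTRY[spec.name](spec, Xmat, data.T, data.Y)
    return FittedPredictor(
        spec=spec,
        columns=list(Xmat.columns),
        categories=categories,
        training_info={
            "n": int(data.n),
            "n_treated": int(data.n_treated),
            "n_events": int(data.Y.sum()),
        },
        backend=backend,
        glm_fit=glm_fit,
    )


def _design_for(model: FittedPredictor, X: pd.DataFrame, T) -> np.ndarray:
    Xmat, _ = _encode(X, model.categories)
    if list(Xmat.columns) != model.columns:
        raise ValueError(
            "covariate schema mismatch with training: "
            f"expected {model.columns}, got {list(Xmat.columns)}"
        )
    T = np.broadcast_to(np.asarray(T, dtype=float), (len(Xmat),))
    base = np.column_stack([Xmat.to_numpy(), T])
    if isinstance(model.backend, _GlmBackend):
        return np.column_stack([np.ones(len(Xmat)), base])
    return base


def predict_event_probability(model: FittedPredictor, X, T) -> np.ndarray:
    """Pr(Y = 1 | X, T) under a forced (scalar) or per-row treatment ``T``."""
    p = model.backend.predict_proba(_design_for(model, X, T))
    return np.clip(np.asarray(p, dtype=float), 0.0, 1.0)


def estimate_ite(model: FittedPredictor, X) -> np.ndarray:
    """Per-row predicted treatment effect on event probability.

    Negative values mean the experimental arm is predicted to lower the
    adverse-event probability (benefit from switching off standard of care).
    """
    return predict_event_probability(model, X, 1) - predict_event_probability(model, X, 0)


def glm_linear_predictor(model: FittedPredictor, X, T) -> np.ndarray:
    """Out-of-sample linear predictor Z = intercept + X beta + T alpha_treat."""
    if not isinstance(model.backend, _GlmBackend):
        raise TypeError("linear predictor only defined for the glm predictor")
    return model.backend.linear_predictor(_design_for(model, X, T))


def clip_probability(p, epsilon: float = 1e-3):
    """Clamp probabilities into [epsilon, 1 - epsilon] so log-odds are finite."""
    if not 0 < epsilon < 0.5:
        raise ValueError("epsilon must lie in (0, 0.5)")
    return np.clip(p, epsilon, 1.0 - epsilon)
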