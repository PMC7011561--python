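"""Stacking test for the added predictive benefit of an ML model over a GLM.

Within one random split, both the baseline logistic GLM and the ML model
are fitted to each half and evaluated on the opposite half at each
subject's *actual* treatment (this is a risk-prediction stack, not a
counterfactual):

* z_glm_i — out-of-sample GLM linear predictor X_i beta + T_i alpha_treat,
* z_ml_i  — out-of-sample ML log-odds log(p / (1-p)) after clipping.

A second-stage ("stacked") logistic regression of Y on (z_glm, z_ml) over
the full trial then tests theta_ml = 0 with a 1-df likelihood-ratio
(deviance ANOVA) test: if the ML predictions carry no information beyond
the GLM, z_ml is a noisy function of (X, T) independent of the held-out
outcomes given z_glm, and the per-split p value is (asymptotically)
uniform.  K splits are merged with the quantile aggregation rules.

An intercept is included in the stacked model by default: out-of-sample
predictors can be miscalibrated in level, and omitting the intercept can
manufacture spurious significance.  Set ``include_intercept=False`` for
the intercept-free variant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from .aggregation import AggregateResult, aggregate_adaptive, aggregate_fixed_gamma
from .predictors import (
    DegenerateTrainingError,
    PredictorSpec,
    clip_probability,
    fit_predictor,
    glm_linear_predictor,
    predict_event_probability,
)
from .trial_data import SplitPlan, TrialData, make_split_plan

logger = logging.getLogger(__name__)

__all__ = [
    "CrossFitPredictions",
    "StackedFit",
    "AddedBenefitResult",
    "crossfit_predictions",
    "stacked_lrt",
    "run_added_benefit_test",
]


@dataclass
class CrossFitPredictions:
    """Per-subject out-of-sample predictions from one split."""

    z_glm: np.ndarray
    z_ml: np.ndarray
    split_index: int = 1


@dataclass
class StackedFit:
    """Stacked-model coefficients and the 1-df likelihood-ratio test."""

    theta_glm: float
    theta_ml: float
    lrt_statistic: float
    p_value: float
    df: int = 1
    intercept: float | None = None
    penalized: bool = False
    degenerate: bool = False
    reason: str | None = None

    def to_dict(self) -> dict:
        return {
            "theta_glm": self.theta_glm,
            "theta_ml": self.theta_ml,
            "lrt_statistic": self.lrt_statistic,
            "p_value": self.p_value,
            "df": self.df,
            "intercept": self.intercept,
            "penalized": self.penalized,
            "degenerate": self.degenerate,
            "reason": self.reason,
        }


@dataclass
class AddedBenefitResult:
    aggregate: AggregateResult
    splits: list
    warnings: list = field(default_factory=list)


def crossfit_predictions(
    data: TrialData,
    plan: SplitPlan,
    glm_spec: PredictorSpec = PredictorSpec("glm"),
    ml_spec: PredictorSpec = PredictorSpec("random_forest"),
    epsilon: float = 1e-3,
    split_index: int = 1,
) -> CrossFitPredictions:
    """Out-of-sample z_glm and z_ml for every subject at their actual T."""
    z_glm = np.full(data.n, np.nan)
    z_ml = np.full(data.n, np.nan)
    for train_idx, test_idx in ((plan.half_a, plan.half_b), (plan.half_b, plan.half_a)):
        train = data.subset(train_idx)
        glm = fit_predictor(glm_spec, train)
        ml = fit_predictor(ml_spec, train)
        X_test = data.X.iloc[test_idx]
        T_test = data.T[test_idx]
        z_glm[test_idx] = glm_linear_predictor(glm, X_test, T_test)
        p = clip_probability(
            predict_event_probability(ml, X_test, T_test), epsilon
        )
        z_ml[test_idx] = np.log(p / (1.0 - p))
    assert np.isfinite(z_glm).all() and np.isfinite(z_ml).all(), (
        "every subject must receive finite out-of-sample predictions"
    )
    return CrossFitPredictions(z_glm=z_glm, z_ml=z_ml, split_index=split_index)


def _neg_loglik(params, design, y, lam=0.0):
    eta = design @ params
    # log(1+e^eta) computed stably
    ll = y @ eta - np.logaddexp(0.0, eta).sum()
    return -(ll - 0.5 * lam * params @ params)


def _neg_loglik_grad(params, design, y, lam=0.0):
    eta = design @ params
    mu = 1.0 / (1.0 + np.exp(-eta))
    return -(design.T @ (y - mu) - lam * params)


def _fit_ridge_logit(design, y, lam):
    """Ridge-penalised logistic MLE (separation fallback).

    BFGS on the exact gradient; the penalised objective is smooth and
    strictly convex.  Returns (params, penalised log-likelihood).
    """
    res = optimize.minimize(
        _neg_loglik,
        np.zeros(design.shape[1]),
        args=(design, y, lam),
        jac=_neg_loglik_grad,
        method="BFGS",
        options={"gtol": 1e-8, "maxiter": 500},
    )
    return res.x, -res.fun


def _fit_logit(design, y):
    """Unpenalised logistic MLE; returns (params, log-likelihood) or
    (None, None) when the fit fails or diverges (separation)."""
    try:
        with warnings.catch_warnings():
            # separation is detected and handled below, not surfaced here
            warnings.simplefilter("ignore")
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
    except Exception:
        return None, None
    params = np.asarray(res.params)
    # genuine stacked coefficients are O(1) on the log-odds scale; huge
    # values mean the optimiser walked off under (quasi-)separation
    if not np.all(np.isfinite(params)) or np.any(np.abs(params) > 1e3):
        return None, None
    return params, float(res.llf)


def stacked_lrt(
    predictions: CrossFitPredictions,
    Y: np.ndarray,
    include_intercept: bool = True,
    ridge: float = 1e-3,
) -> StackedFit:
    """1-df likelihood-ratio test of theta_ml = 0 in the stacked model.

    On (quasi-)separation — detected as non-finite or extreme coefficients —
    both nested models are refitted with the same small ridge penalty and
    the penalised LRT is reported with ``penalized=True``.
    """
    y = np.asarray(Y, dtype=float)
    z_glm = np.asarray(predictions.z_glm, dtype=float)
    z_ml = np.asarray(predictions.z_ml, dtype=float)
    if not (np.isfinite(z_glm).all() and np.isfinite(z_ml).all()):
        raise ValueError("prediction vectors must be finite")
    if len(y) != len(z_glm) or len(y) != len(z_ml):
        raise ValueError("Y and prediction vectors must share a length")

    cols = [z_glm, z_ml]
    if include_intercept:
        cols = [np.ones_like(y)] + cols
    full = np.column_stack(cols)
    null = full[:, :-1]

    rank = np.linalg.matrix_rank(full)
    if rank < full.shape[1]:
        # z_ml collinear with the null design: no added information
        return StackedFit(
            theta_glm=0.0, theta_ml=0.0, lrt_statistic=0.0, p_value=1.0,
            intercept=None, degenerate=True, reason="collinear predictions",
        )

    params_f, ll_f = _fit_logit(full, y)
    params_n, ll_n = _fit_logit(null, y)
    penalized = params_f is None or params_n is None
    if penalized:
        # identical penalty in both nested models keeps the LRT conservative
        params_f, ll_f = _fit_ridge_logit(full, y, lam=ridge)
        params_n, ll_n = _fit_ridge_logit(null, y, lam=ridge)
        logger.warning("split %d: separation, ridge fallback", predictions.split_index)

    lrt = max(0.0, 2.0 * (ll_f - ll_n))
    p = float(stats.chi2.sf(lrt, df=1))
    off = 1 if include_intercept else 0
    return StackedFit(
        theta_glm=float(params_f[off]),
        theta_ml=float(params_f[off + 1]),
        intercept=float(params_f[0]) if include_intercept else None,
        lrt_statistic=float(lrt),
        p_value=p,
        penalized=penalized,
    )


def run_added_benefit_test(
    data: TrialData,
    glm_spec: PredictorSpec = PredictorSpec("glm"),
    ml_spec: PredictorSpec = PredictorSpec("random_forest"),
    K: int = 1000,
    alpha: float = 0.05,
    gamma: float | None = None,
    master_seed: int = 0,
    epsilon: float = 1e-3,
    include_intercept: bool = True,
) -> AddedBenefitResult:
    """K-split stacking test; split k uses seed ``master_seed + k`` and the
    same partition for both the GLM and the ML model.  Degenerate splits
    (a half that cannot support a fit) contribute p = 1."""
    if K < 1:
        raise ValueError("K must be >= 1")
    splits = []
    warnings = []
    for k in range(1, K + 1):
        plan = make_split_plan(data, seed=master_seed + k)
        try:
            preds = crossfit_predictions(
                data, plan, glm_spec, ml_spec, epsilon, split_index=k
            )
            fit = stacked_lrt(preds, data.Y, include_intercept=include_intercept)
        except DegenerateTrainingError as exc:
            fit = StackedFit(
                theta_glm=0.0, theta_ml=0.0, lrt_statistic=0.0, p_value=1.0,
                degenerate=True, reason=str(exc),
            )
            logger.warning("split %d degenerate: %s", k, exc)
        if fit.degenerate:
            warnings.append(f"split {k}: {fit.reason}")
        elif fit.penalized:
            warnings.append(f"split {k}: separation, penalised LRT")
        splits.append(fit)
    p_values = np.array([s.p_value for s in splits])
    if gamma is not None:
        aggregate = aggregate_fixed_gamma(p_values, gamma)
        aggregate.alpha = alpha
    else:
        aggregate = aggregate_adaptive(p_values, alpha)
    return AddedBenefitResult(aggregate=aggregate, splits=splits, warnings=warnings)
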