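"""Synthetic two-arm trials with known treatment-effect structure.

The generative model is a Bernoulli outcome with a logistic link,

    logit Pr(Y=1) = b0 + X.baseline_coefs + T*treat_main
                    + T*1[subgroup]*teh_magnitude,

with d independent standard-normal covariates, a fair-coin randomised
treatment independent of X, and the subgroup defined by the first
covariate exceeding a population quantile threshold (so the realised
subgroup fraction is binomial around the target prevalence).  This is the
simplest structure that realises all three regimes:

``none``          no heterogeneity (teh_magnitude = 0),
``noncrossover``  the same arm is optimal everywhere but its benefit
                  differs inside the subgroup,
``crossover``     the optimal arm switches inside the subgroup
                  (treat_main and treat_main + teh_magnitude have
                  opposite signs).

A ``smooth_crossover`` preset replaces the step interaction with a spline
shape in the first covariate for a smoothly varying effect.

The intercept b0 is calibrated by Gauss-Hermite quadrature so that the
standard-of-care arm has a target event rate (default 0.2).

Ground truth (per-subject true ITE and subgroup membership) is returned
alongside every generated trial so oracle checks are possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .predictors import PredictorSpec, estimate_ite, fit_predictor
from .trial_data import TrialData, make_ratio_split

__all__ = [
    "SimScenario",
    "scenario_preset",
    "generate_trial",
    "split_ratio_experiment",
    "theoretical_se_curve",
    "calibration_study",
]

_DEFAULT_COEFS = np.array([0.5, -0.5, 0.3, 0.3, 0.0])


@dataclass(frozen=True)
class SimScenario:
    """Parameters of the generative model; see the module docstring."""

    n: int = 500
    d: int = 5
    baseline_coefs: np.ndarray = field(default_factory=lambda: _DEFAULT_COEFS.copy())
    treat_main: float = 0.0
    teh_kind: str = "none"  # none | noncrossover | crossover
    subgroup_prevalence: float = 0.3
    teh_magnitude: float = 0.0
    baseline_event_rate: float = 0.2
    smooth: bool = False
    seed: int = 0

    def __post_init__(self):
        coefs = np.asarray(self.baseline_coefs, dtype=float)
        if coefs.size != self.d:
            raise ValueError(
                f"baseline_coefs has length {coefs.size}, expected d={self.d}"
            )
        object.__setattr__(self, "baseline_coefs", coefs)
        if self.teh_kind not in ("none", "noncrossover", "crossover"):
            raise ValueError(f"unknown teh_kind {self.teh_kind!r}")
        if not 0 < self.subgroup_prevalence < 1:
            raise ValueError("subgroup_prevalence must lie in (0, 1)")
        if self.teh_kind == "none" and self.teh_magnitude != 0.0:
            raise ValueError("teh_kind='none' requires teh_magnitude = 0")
        inside = self.treat_main + self.teh_magnitude
        if self.teh_kind == "crossover" and not (
            self.treat_main != 0 and inside * self.treat_main < 0
        ):
            raise ValueError(
                "crossover requires treat_main + teh_magnitude to have the "
                "opposite sign to treat_main"
            )
        if self.teh_kind == "noncrossover" and inside * self.treat_main <= 0:
            raise ValueError(
                "noncrossover requires the optimal arm to stay the same "
                "inside the subgroup"
            )

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "d": self.d,
            "baseline_coefs": np.asarray(self.baseline_coefs).tolist(),
            "treat_main": self.treat_main,
            "teh_kind": self.teh_kind,
            "subgroup_prevalence": self.subgroup_prevalence,
            "teh_magnitude": self.teh_magnitude,
            "baseline_event_rate": self.baseline_event_rate,
            "smooth": self.smooth,
            "seed": self.seed,
        }


def scenario_preset(name: str, **overrides) -> SimScenario:
    """Named study conditions.

    ``null``             no effect at all (sharp null for calibration),
    ``noncrossover``     experimental beneficial everywhere, more so in
                         the subgroup,
    ``crossover``        experimental harmful outside the subgroup,
                         beneficial inside it (optimum reversed),
    ``smooth_crossover`` crossover with a spline-shaped smooth interaction.
    """
    presets = {
        "null": dict(treat_main=0.0, teh_kind="none", teh_magnitude=0.0),
        "noncrossover": dict(treat_main=-0.5, teh_kind="noncrossover",
                             teh_magnitude=-1.0),
        "crossover": dict(treat_main=0.5, teh_kind="crossover",
                          teh_magnitude=-2.0),
        "smooth_crossover": dict(treat_main=0.5, teh_kind="crossover",
                                 teh_magnitude=-2.0, smooth=True),
    }
    if name not in presets:
        raise KeyError(f"unknown scenario {name!r}; presets: {sorted(presets)}")
    kwargs = dict(presets[name])
    kwargs.update(overrides)
    return SimScenario(**kwargs)


def _calibrate_intercept(scenario: SimScenario) -> float:
    """Solve E[expit(b0 + X.beta)] = baseline_event_rate for b0.

    X.beta is N(0, sigma^2) with sigma = ||beta||; the expectation is a
    64-node Gauss-Hermite quadrature, so the result is deterministic.
    """
    sigma = float(np.linalg.norm(scenario.baseline_coefs))
    target = scenario.baseline_event_rate
    if sigma == 0.0:
        return float(np.log(target / (1 - target)))
    nodes, weights = np.polynomial.hermite_e.hermegauss(64)

    def mean_rate(b0):
        return weights @ expit(b0 + sigma * nodes) / weights.sum() - target

    return float(optimize.brentq(mean_rate, -30, 30))


def _interaction_weight(scenario: SimScenario, x0: np.ndarray) -> np.ndarray:
    """Per-subject multiplier on teh_magnitude: a 0/1 step by default, a
    smooth spline-like ramp saturating inside the subgroup when smooth."""
    threshold = stats.norm.ppf(1 - scenario.subgroup_prevalence)
    if not scenario.smooth:
        return (x0 > threshold).astype(float)
    # cubic smoothstep over one unit below the threshold, saturated above
    u = np.clip((x0 - threshold + 1.0), 0.0, 1.0)
    return u * u * (3 - 2 * u)


def generate_trial(scenario: SimScenario):
    """Draw one trial; returns (TrialData, truth DataFrame).

    The truth table has columns ``in_subgroup``, ``true_ite`` (difference
    in event probability, experimental minus standard of care) and
    ``linear_predictor`` (the logit at the assigned treatment).
    """
    rng = np.random.default_rng(scenario.seed)
    b0 = _calibrate_intercept(scenario)
    X = rng.standard_normal((scenario.n, scenario.d))
    T = rng.integers(0, 2, size=scenario.n)
    w = _interaction_weight(scenario, X[:, 0])
    base = b0 + X @ scenario.baseline_coefs
    effect = scenario.treat_main + w * scenario.teh_magnitude
    eta = base + T * effect
    Y = rng.binomial(1, expit(eta))
    # a degenerate draw cannot feed the pipeline; extremely unlikely at
    # the default event rates but checked loudly
    if Y.min() == Y.max():
        raise RuntimeError("degenerate draw: constant outcome; change seed or n")

    threshold = stats.norm.ppf(1 - scenario.subgroup_prevalence)
    truth = pd.DataFrame(
        {
            "in_subgroup": X[:, 0] > threshold,
            "true_ite": expit(base + effect) - expit(base),
            "linear_predictor": eta,
        }
    )
    data = TrialData(
        subject_id=np.array([f"s{i:05d}" for i in range(scenario.n)]),
        X=pd.DataFrame(X, columns=[f"x{j+1}" for j in range(scenario.d)]),
        T=T,
        Y=Y,
    )
    return data, truth


def theoretical_se_curve(n: int, ratios) -> pd.DataFrame:
    """The 1/(sqrt(n1) + sqrt(n2)) prediction-error scaling for split
    fractions r, with n1 = r*n, n2 = (1-r)*n; minimised at r = 1/2."""
    r = np.asarray(ratios, dtype=float)
    se = 1.0 / (np.sqrt(r * n) + np.sqrt((1 - r) * n))
    return pd.DataFrame({"ratio": r, "theoretical_se": se})


def split_ratio_experiment(
    scenario: SimScenario,
    ratios=(0.3, 0.5, 0.7),
    replicates: int = 50,
    predictor: PredictorSpec | None = None,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Empirical prediction error of cross-fitted ITEs by split ratio.

    Each replicate draws one fresh trial and evaluates *every* ratio on
    it (a paired, common-random-numbers design: the ratio comparison is
    not diluted by between-trial variation).  For each ratio r the trial
    is split r / (1-r) within arms, the predictor is cross-fitted, and
    the RMSE of the held-out ITE estimates against the generative truth
    is recorded.  The mean RMSE should be minimised at r = 0.5.
    """
    if predictor is None:
        predictor = PredictorSpec("random_forest", {"n_trees": 100}, seed=0)
    for ratio in ratios:
        if not 0 < ratio < 1:
            raise ValueError("ratios must lie in (0, 1)")
    errors = {ratio: [] for ratio in ratios}
    excluded = {ratio: 0 for ratio in ratios}
    for rep in range(replicates):
        seed = master_seed + rep
        data, truth = generate_trial(replace(scenario, seed=seed))
        true_ite = truth["true_ite"].to_numpy()
        for ri, ratio in enumerate(ratios):
            plan = make_ratio_split(data, ratio, seed=seed + 1000 * (ri + 1))
            try:
                ite = np.full(data.n, np.nan)
                for tr, te in ((plan.half_a, plan.half_b), (plan.half_b, plan.half_a)):
                    model = fit_predictor(predictor, data.subset(tr))
                    ite[te] = estimate_ite(model, data.X.iloc[te])
                errors[ratio].append(
                    float(np.sqrt(np.mean((ite - true_ite) ** 2)))
                )
            except Exception:  # degenerate half at an extreme ratio
                excluded[ratio] += 1
    return pd.DataFrame(
        [
            {
                "ratio": float(ratio),
                "mean_se": float(np.mean(errors[ratio])) if errors[ratio] else np.nan,
                "replicates": len(errors[ratio]),
                "excluded": excluded[ratio],
            }
            for ratio in ratios
        ]
    )


def calibration_study(
    scenario: SimScenario,
    test: str = "crossover",
    replicates: int = 100,
    K: int = 50,
    alpha: float = 0.05,
    predictor: PredictorSpec | None = None,
    glm_spec: PredictorSpec | None = None,
    master_seed: int = 0,
) -> dict:
    """Monte-Carlo rejection rate of the full pipeline on fresh draws.

    Runs the chosen test (``crossover`` or ``added_benefit``) on
    ``replicates`` independently generated trials and reports the fraction
    with aggregate p <= alpha together with its binomial standard error.
    On a null scenario the fraction must stay at or below alpha.
    """
    from .added_benefit import run_added_benefit_test
    from .crossover import run_crossover_test

    if test not in ("crossover", "added_benefit"):
        raise ValueError("test must be 'crossover' or 'added_benefit'")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if predictor is None:
        predictor = PredictorSpec("random_forest", {"n_trees": 100}, seed=0)
    if glm_spec is None:
        glm_spec = PredictorSpec("glm")

    p_aggregates = []
    for rep in range(replicates):
        gen_seed = master_seed + 7919 * (rep + 1)  # spaced, < 2**31 for sane inputs
        data, _ = generate_trial(replace(scenario, seed=gen_seed))
        run_alpha = min(alpha, 0.9999)
        if test == "crossover":
            res = run_crossover_test(
                data, predictor, K=K, alpha=run_alpha, master_seed=gen_seed + 1
            )
        else:
            res = run_added_benefit_test(
                data, glm_spec, predictor, K=K, alpha=run_alpha,
                master_seed=gen_seed + 1,
            )
        p_aggregates.append(res.aggregate.p_aggregate)
    p_aggregates = np.asarray(p_aggregates)
    frac = float(np.mean(p_aggregates <= alpha))
    se = float(np.sqrt(frac * (1 - frac) / replicates))
    return {
        "test": test,
        "alpha": alpha,
        "replicates": replicates,
        "K": K,
        "rejection_fraction": frac,
        "mc_standard_error": se,
        "p_aggregates": p_aggregates.tolist(),
    }
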