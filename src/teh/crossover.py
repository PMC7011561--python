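"""Omnibus test for crossover treatment-effect heterogeneity (subgroups).

One iteration: randomly split the trial into two arm-balanced halves, fit
the predictor to each half, and score every subject with the model trained
on the *other* half (twofold cross-prediction, so each score is strictly
out-of-sample).  Subjects whose predicted individual treatment effect is
strictly negative — predicted to benefit from the experimental arm rather
than standard of care — form the held-out subgroup of size n_s.  Because
treatment was randomised, roughly half of that subgroup actually received
each arm; a one-sided two-sample test (default: Fisher exact on the 2x2
table of received arm x event) asks whether subgroup members who received
the experimental treatment fared better.  Under the null of no benefitting
subgroup the resulting p value is uniform (conservative), and K iterations
are merged with the quantile aggregation rules.

n_s / n averaged over splits estimates the subgroup prevalence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .aggregation import AggregateResult, aggregate_adaptive, aggregate_fixed_gamma
from .predictors import (
    DegenerateTrainingError,
    PredictorSpec,
    estimate_ite,
    fit_predictor,
)
from .trial_data import SplitPlan, TrialData, make_split_plan

logger = logging.getLogger(__name__)

__all__ = [
    "TestStatisticSpec",
    "SplitResult",
    "CrossoverTestResult",
    "register_test_statistic",
    "split_pvalue",
    "run_crossover_test",
]


def _fisher_exact_one_sided(table: np.ndarray) -> float:
    """One-sided Fisher exact p; alternative = experimental arm has fewer
    events.  Row 0 = received experimental, row 1 = received standard of
    care; column 0 = event, column 1 = no event."""
    return float(stats.fisher_exact(table, alternative="less")[1])


def _proportions_z_one_sided(table: np.ndarray) -> float:
    """One-sided difference-in-proportions z test, same orientation.

    Registrable alternative to the exact test for large subgroups."""
    e1, f1 = table[0]
    e0, f0 = table[1]
    n1, n0 = e1 + f1, e0 + f0
    p_pool = (e1 + e0) / (n1 + n0)
    if p_pool in (0.0, 1.0):
        return 1.0
    se = np.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n0))
    z = (e1 / n1 - e0 / n0) / se
    return float(stats.norm.cdf(z))


_STAT_REGISTRY = {
    "fisher_exact_one_sided": _fisher_exact_one_sided,
    "proportions_z_one_sided": _proportions_z_one_sided,
}


def register_test_statistic(name: str, func):
    """Register ``func(table_2x2) -> p`` as a subgroup test statistic."""
    _STAT_REGISTRY[name] = func


@dataclass(frozen=True)
class TestStatisticSpec:
    """Named two-sample test on the subgroup's received-arm x event table.

    Direction is fixed: evidence means better outcomes in the experimental
    arm within the subgroup predicted to benefit from it.
    """

    name: str = "fisher_exact_one_sided"

    __test__ = False  # not a pytest collection target

    def resolve(self):
        if self.name not in _STAT_REGISTRY:
            raise KeyError(
                f"unknown test statistic {self.name!r}; "
                f"registered: {sorted(_STAT_REGISTRY)}"
            )
        return _STAT_REGISTRY[self.name]


@dataclass
class SplitResult:
    """Outcome of one random split of the crossover test."""

    split_index: int
    plan: SplitPlan
    subgroup_ids: np.ndarray
    n_s: int
    arm_counts: np.ndarray  # 2x2: received exp / soc  x  event / no event
    p_value: float
    degenerate: bool = False
    reason: str | None = None

    def to_dict(self) -> dict:
        return {
            "split_index": self.split_index,
            "seed": int(self.plan.seed),
            "subgroup_ids": np.asarray(self.subgroup_ids).tolist(),
            "n_s": int(self.n_s),
            "arm_counts": np.asarray(self.arm_counts).tolist(),
            "p_value": float(self.p_value),
            "degenerate": bool(self.degenerate),
            "reason": self.reason,
        }


@dataclass
class CrossoverTestResult:
    aggregate: AggregateResult
    splits: list
    prevalence_estimate: float
    warnings: list = field(default_factory=list)


def _degenerate(split_index, plan, reason, subgroup_idx=None, data=None):
    logger.warning("split %d degenerate: %s", split_index, reason)
    if subgroup_idx is None:
        ids = np.array([])
        counts = np.zeros((2, 2), dtype=int)
    else:
        ids = data.subject_id[subgroup_idx]
        counts = _table(data, subgroup_idx)
    return SplitResult(
        split_index=split_index,
        plan=plan,
        subgroup_ids=ids,
        n_s=len(ids),
        arm_counts=counts,
        p_value=1.0,
        degenerate=True,
        reason=reason,
    )


def _table(data: TrialData, subgroup_idx: np.ndarray) -> np.ndarray:
    t = data.T[subgroup_idx]
    y = data.Y[subgroup_idx]
    return np.array(
        [
            [int(np.sum((t == 1) & (y == 1))), int(np.sum((t == 1) & (y == 0)))],
            [int(np.sum((t == 0) & (y == 1))), int(np.sum((t == 0) & (y == 0)))],
        ]
    )


def cross_predict_ite(
    data: TrialData, plan: SplitPlan, predictor: PredictorSpec
) -> np.ndarray:
    """Out-of-sample ITE for every subject: each half is scored by the
    model trained on the opposite half."""
    ite = np.full(data.n, np.nan)
    for train_idx, test_idx in ((plan.half_a, plan.half_b), (plan.half_b, plan.half_a)):
        model = fit_predictor(predictor, data.subset(train_idx))
        ite[test_idx] = estimate_ite(model, data.X.iloc[test_idx])
    assert not np.isnan(ite).any(), "every subject must be scored exactly once"
    return ite


def split_pvalue(
    data: TrialData,
    plan: SplitPlan,
    predictor: PredictorSpec,
    stat: TestStatisticSpec = TestStatisticSpec(),
    split_index: int = 1,
) -> SplitResult:
    """One split of the crossover test: cross-predict, pool the held-out
    subgroup, and test it.  Degenerate configurations give p = 1."""
    test_func = stat.resolve()
    try:
        ite = cross_predict_ite(data, plan, predictor)
    except DegenerateTrainingError as exc:
        return _degenerate(split_index, plan, f"training half degenerate: {exc}")

    subgroup_idx = np.flatnonzero(ite < 0)  # strict benefit; ties -> soc
    if subgroup_idx.size == 0:
        return _degenerate(split_index, plan, "empty subgroup", subgroup_idx, data)

    t = data.T[subgroup_idx]
    y = data.Y[subgroup_idx]
    if len(np.unique(t)) < 2:
        return _degenerate(
            split_index, plan, "subgroup within a single received arm",
            subgroup_idx, data,
        )
    if len(np.unique(y)) < 2:
        return _degenerate(
            split_index, plan, "no outcome variation in subgroup",
            subgroup_idx, data,
        )

    table = _table(data, subgroup_idx)
    p = float(np.clip(test_func(table), 0.0, 1.0))
    return SplitResult(
        split_index=split_index,
        plan=plan,
        subgroup_ids=data.subject_id[subgroup_idx],
        n_s=int(subgroup_idx.size),
        arm_counts=table,
        p_value=p,
    )


def run_crossover_test(
    data: TrialData,
    predictor: PredictorSpec,
    stat: TestStatisticSpec = TestStatisticSpec(),
    K: int = 1000,
    alpha: float = 0.05,
    gamma: float | None = None,
    master_seed: int = 0,
) -> CrossoverTestResult:
    """Run K random splits and aggregate their p values.

    Split k uses seed ``master_seed + k`` (k = 1..K).  Aggregation uses the
    adaptive rule at ``alpha`` unless a fixed ``gamma`` is given.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    splits = []
    warnings = []
    for k in range(1, K + 1):
        plan = make_split_plan(data, seed=master_seed + k)
        res = split_pvalue(data, plan, predictor, stat, split_index=k)
        if res.degenerate:
            warnings.append(f"split {k}: {res.reason}")
        splits.append(res)
    p_values = np.array([s.p_value for s in splits])
    if gamma is not None:
        aggregate = aggregate_fixed_gamma(p_values, gamma)
        aggregate.alpha = alpha
    else:
        aggregate = aggregate_adaptive(p_values, alpha)
    if all(s.degenerate for s in splits):
        warnings.append("all splits degenerate; aggregate p = 1")
        logger.warning("all %d splits degenerate; aggregate p = 1", K)
    prevalence = float(np.mean([s.n_s for s in splits]) / data.n)
    return CrossoverTestResult(
        aggregate=aggregate,
        splits=splits,
        prevalence_estimate=prevalence,
        warnings=warnings,
    )
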