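import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from teh import (
    PredictorSpec,
    TestStatisticSpec,
    TrialData,
    make_split_plan,
    register_predictor,
    run_crossover_test,
    scenario_preset,
    split_pvalue,
)
from teh.crossover import _fisher_exact_one_sided, cross_predict_ite
from teh.synthetic import generate_trial


def hypergeom_tail_oracle(table):
    """Exhaustive one-sided p: probability, over all 2x2 tables with the
    observed margins, of at most the observed events in the experimental
    row (independent enumeration with exact binomial coefficients)."""
    e1, f1 = int(table[0][0]), int(table[0][1])
    e0, f0 = int(table[1][0]), int(table[1][1])
    n1, n0 = e1 + f1, e0 + f0
    m = e1 + e0  # total events
    total = math.comb(n1 + n0, m)
    acc = 0
    for k in range(0, min(m, n1) + 1):
        if m - k > n0:
            continue
        if k <= e1:
            acc += math.comb(n1, k) * math.comb(n0, m - k)
    return acc / total


def _register_constant_ite(name, value):
    class _Backend:
        def predict_proba(self, design):
            T = design[:, -1]
            return 0.5 + value * T  # ITE == value for every row

    register_predictor(name, lambda *a: (_Backend(), None))
    return PredictorSpec(name)


class TestFisherEngine:
    def test_specific_table_against_enumeration(self):
        table = np.array([[1, 19], [8, 12]])
        assert _fisher_exact_one_sided(table) == pytest.approx(
            hypergeom_tail_oracle(table), abs=1e-12
        )

    def test_random_tables_against_enumeration(self, rng):
        for _ in range(20):
            n1, n0 = rng.integers(2, 40, size=2)
            e1 = int(rng.integers(0, n1 + 1))
            e0 = int(rng.integers(0, n0 + 1))
            table = np.array([[e1, n1 - e1], [e0, n0 - e0]])
            assert _fisher_exact_one_sided(table) == pytest.approx(
                hypergeom_tail_oracle(table), abs=1e-12
            )

    def test_direction_is_experimental_benefit(self):
        benefit = np.array([[1, 19], [8, 12]])   # exp arm has fewer events
        harm = np.array([[8, 12], [1, 19]])
        assert _fisher_exact_one_sided(benefit) < 0.05
        assert _fisher_exact_one_sided(harm) > 0.5


class TestSplitPvalue:
    def test_null_predictor_empty_subgroup(self, null_trial):
        spec = _register_constant_ite("_never_benefit", 0.0)
        plan = make_split_plan(null_trial, 3)
        res = split_pvalue(null_trial, plan, spec)
        assert res.n_s == 0
        assert res.degenerate and res.p_value == 1.0

    def test_out_of_sample_guarantee(self, null_trial):
        """No subject is scored by a model trained on a half containing it."""
        # identify training rows through a covariate smuggled as an id
        data = null_trial
        probe = TrialData(
            subject_id=np.arange(data.n),
            X=data.X.assign(rowid=np.arange(data.n, dtype=float)),
            T=data.T,
            Y=data.Y,
        )

        captured = []

        class _Probe2:
            def __init__(self, train_rowids):
                self.train_rowids = set(train_rowids)

            def predict_proba(self, design):
                test_rowids = set(design[:, -2].astype(int))  # rowid column
                captured.append((self.train_rowids, test_rowids))
                return np.full(design.shape[0], 0.4)

        register_predictor(
            "_probe", lambda spec, Xmat, T, Y: (_Probe2(Xmat["rowid"].astype(int)), None)
        )
        plan = make_split_plan(probe, 5)
        cross_predict_ite(probe, plan, PredictorSpec("_probe"))
        assert len(captured) >= 2
        scored = set()
        for train_ids, test_ids in captured:
            assert not (train_ids & test_ids)
            scored |= test_ids
        assert scored == set(range(probe.n))  # everyone scored exactly once

    def test_degenerate_training_half_gives_p_one(self):
        rng = np.random.default_rng(4)
        n = 40
        data = TrialData(
            subject_id=np.arange(n),
            X=pd.DataFrame({"x": rng.standard_normal(n)}),
            T=rng.permutation([0, 1] * (n // 2)),
            Y=np.array([1] + [0] * (n - 1)),  # one event: some half all-zero
        )
        plan = make_split_plan(data, 2)
        res = split_pvalue(data, plan, PredictorSpec("glm"))
        assert res.degenerate and res.p_value == 1.0

    def test_strong_crossover_mostly_significant(self, crossover_trial):
        """Oracle-like predictor on a strong reversed effect at n=2000:
        the per-split p is below 0.05 in >= 90% of splits."""
        data, _ = crossover_trial
        glm_interact = PredictorSpec("_glm_interact")

        from scipy.special import expit as _expit
        import statsmodels.api as sm

        class _InteractBackend:
            def __init__(self, params, thr):
                self.params, self.thr = params, thr

            def predict_proba(self, design):
                X, T = design[:, :-1], design[:, -1]
                s = (X[:, 0] > self.thr).astype(float)
                D = np.column_stack([np.ones(len(T)), X, T, T * s])
                return _expit(D @ self.params)

        def constructor(spec, Xmat, T, Y):
            thr = stats.norm.ppf(0.7)
            X = Xmat.to_numpy()
            s = (X[:, 0] > thr).astype(float)
            D = np.column_stack([np.ones(len(T)), X, T, T * s])
            params = sm.Logit(Y, D).fit(disp=0).params
            return _InteractBackend(np.asarray(params), thr), None

        register_predictor("_glm_interact", constructor)
        hits = 0
        n_splits = 40
        for seed in range(n_splits):
            plan = make_split_plan(data, seed)
            res = split_pvalue(data, plan, glm_interact)
            hits += (not res.degenerate) and res.p_value < 0.05
        assert hits / n_splits >= 0.90


class TestRunCrossoverTest:
    def test_aggregate_contract(self, null_trial):
        res = run_crossover_test(
            null_trial, PredictorSpec("glm"), K=8, master_seed=100
        )
        agg = res.aggregate
        assert 0 <= agg.p_aggregate <= 1
        assert agg.trace[-1] == agg.p_aggregate
        assert len(res.splits) == 8
        assert [s.plan.seed for s in res.splits] == list(range(101, 109))
        assert 0 <= res.prevalence_estimate <= 1

    def test_k1_adaptive_closed_form(self, null_trial):
        res = run_crossover_test(
            null_trial, PredictorSpec("glm"), K=1, alpha=0.05, master_seed=7
        )
        p1 = res.splits[0].p_value
        assert res.aggregate.p_aggregate == pytest.approx(
            min(1.0, (1 - math.log(0.05)) * p1)
        )

    def test_all_degenerate_aggregates_to_one(self, null_trial):
        spec = _register_constant_ite("_never_benefit2", 0.0)
        res = run_crossover_test(null_trial, spec, K=5, master_seed=1)
        assert res.aggregate.p_aggregate == 1.0
        assert any("degenerate" in w or "empty" in w for w in res.warnings)

    def test_fixed_gamma_aggregation_used_when_requested(self, null_trial):
        res = run_crossover_test(
            null_trial, PredictorSpec("glm"), K=5, gamma=0.5, master_seed=50
        )
        assert res.aggregate.method == "fixed_gamma"


class TestNullUniformity:
    def test_permuted_outcomes_give_conservative_pvalues(self, null_trial):
        """Permuting Y within arms breaks any covariate link; the split
        p values must then be stochastically >= uniform (one-sided KS)."""
        rng = np.random.default_rng(77)
        data = null_trial
        y = data.Y.copy()
        for arm in (0, 1):
            idx = np.flatnonzero(data.T == arm)
            y[idx] = rng.permutation(y[idx])
        permuted = TrialData(
            subject_id=data.subject_id, X=data.X, T=data.T, Y=y
        )
        pvals = []
        for seed in range(500):
            plan = make_split_plan(permuted, seed)
            pvals.append(split_pvalue(permuted, plan, PredictorSpec("glm")).p_value)
        # 'greater' alternative = ECDF above uniform = anti-conservative
        ks = stats.kstest(pvals, "uniform", alternative="greater")
        assert ks.pvalue > 0.01

    def test_power_monotone_in_effect_size(self):
        """Across nested crossover scenarios at matched seeds, stronger
        generative effects give no fewer rejections of the per-split test."""
        rejections = []
        for mag in (-1.0, -2.5, -4.0):
            hits = 0
            for seed in range(12):
                data, _ = generate_trial(
                    scenario_preset(
                        "crossover", n=700, teh_magnitude=mag, seed=1000 + seed
                    )
                )
                res = run_crossover_test(
                    data,
                    PredictorSpec("random_forest", {"n_trees": 50}, seed=1),
                    K=8,
                    master_seed=seed,
                )
                hits += res.aggregate.p_aggregate <= 0.05
            rejections.append(hits)
        assert rejections[0] <= rejections[1] <= rejections[2]
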