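import numpy as np
import pandas as pd
import pytest

import hallmarknet as hn
from hallmarknet.survival import (RiskModel, _cox_loglik, cox_coefficient,
                                  fit_risk_model, ggi_score, logrank_test,
                                  stratified_split, stratify_and_test)


def make_clinical(times, events, prefix="p"):
    return pd.DataFrame({
        "sample_id": [f"{prefix}{i}" for i in range(len(times))],
        "time": list(map(float, times)),
        "event": list(events),
    })


class TestStratifiedSplit:
    def test_even_patients_even_events(self):
        clin = make_clinical(range(1, 11), [1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        train, test = stratified_split(clin, seed=0)
        assert len(train) == len(test) == 5
        by_id = clin.set_index("sample_id")["event"]
        assert by_id[train].sum() == by_id[test].sum() == 2

    def test_odd_patients_odd_events(self):
        clin = make_clinical(range(1, 12), [1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        train, test = stratified_split(clin, seed=3)
        assert sorted((len(train), len(test))) == [5, 6]
        by_id = clin.set_index("sample_id")["event"]
        assert sorted((by_id[train].sum(), by_id[test].sum())) == [2, 3]

    def test_all_censored(self):
        clin = make_clinical(range(1, 9), [0] * 8)
        train, test = stratified_split(clin, seed=1)
        assert len(train) == len(test) == 4

    def test_partition_covers_all_samples(self):
        clin = make_clinical(range(1, 14), [1, 0] * 6 + [1])
        train, test = stratified_split(clin, seed=9)
        assert sorted(train + test) == sorted(clin["sample_id"])
        assert not set(train) & set(test)

    def test_reproducible_and_seed_sensitive(self):
        clin = make_clinical(range(1, 21), [1, 0] * 10)
        assert stratified_split(clin, seed=4) == stratified_split(clin, seed=4)
        splits = {tuple(stratified_split(clin, seed=s)[0]) for s in range(5)}
        assert len(splits) > 1

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            stratified_split(make_clinical([1, 2, 3], [1, 0, 1]), seed=0)


class TestCoxCoefficient:
    def test_constant_gene_flagged(self):
        assert cox_coefficient([2.0] * 6, [1, 2, 3, 4, 5, 6], [1, 1, 1, 0, 0, 1]) is None

    def test_fewer_than_two_events_flagged(self):
        assert cox_coefficient([1, 2, 3, 4], [1, 2, 3, 4], [1, 0, 0, 0]) is None

    def test_perfectly_concordant_toy_diverges(self):
        # spec-style 4-patient toy: highest expression dies first, so the
        # partial likelihood is monotone in beta (no finite maximizer); the
        # grid-search oracle confirms the maximum sits on the grid boundary
        x = np.array([4.0, 3.0, 2.0, 1.0])
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 1, 1])
        grid = np.linspace(-5, 5, 201)
        lls = [_cox_loglik(b, x, t, e) for b in grid]
        assert int(np.argmax(lls)) == len(grid) - 1  # boundary maximum
        assert cox_coefficient(x, t, e) is None  # flagged as non-convergent

    def test_matches_grid_search_oracle_on_converging_toy(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        t = np.array([4.0, 3.0, 1.0, 2.0])
        e = np.array([1, 1, 1, 1])
        beta = cox_coefficient(x, t, e)
        grid = np.linspace(-5, 5, 2001)
        lls = np.array([_cox_loglik(b, x, t, e) for b in grid])
        assert beta == pytest.approx(grid[int(np.argmax(lls))], abs=0.01)
        assert _cox_loglik(beta, x, t, e) >= lls.max() - 1e-9

    def test_matches_lifelines_with_ties_and_censoring(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(1)
        for seed in range(3):
            rng = np.random.default_rng(seed)
            n = 60
            x = rng.normal(size=n)
            t = np.round(rng.exponential(np.exp(-0.7 * x)), 1) + 0.1  # induces ties
            e = (rng.random(n) < 0.7).astype(int)
            cph = lifelines.CoxPHFitter().fit(
                pd.DataFrame({"x": x, "t": t, "e": e}), "t", "e")
            assert cox_coefficient(x, t, e) == pytest.approx(cph.params_["x"], abs=1e-4)

    def test_sign_convention_positive_means_higher_hazard(self):
        rng = np.random.default_rng(0)
        n = 100
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-x))  # high x -> high hazard -> short time
        e = np.ones(n, dtype=int)
        assert cox_coefficient(x, t, e) > 0


class TestGgiScore:
    def model(self, pos, neg):
        coeffs = {g: 1.0 for g in pos} | {g: -1.0 for g in neg}
        return RiskModel(coefficients=coeffs)

    def test_direct_sum(self):
        expr = pd.DataFrame({"s1": [2.0, 3.0, 1.0]}, index=["a", "b", "c"])
        assert ggi_score(self.model(["a", "b"], ["c"]), expr)["s1"] == 4.0

    def test_empty_negative_set(self):
        expr = pd.DataFrame({"s1": [2.0, 3.0]}, index=["a", "b"])
        assert ggi_score(self.model(["a", "b"], []), expr)["s1"] == 5.0

    def test_all_flagged_model_scores_zero(self):
        model = RiskModel(coefficients={"a": None, "b": None})
        expr = pd.DataFrame({"s1": [2.0, 3.0]}, index=["a", "b"])
        assert (ggi_score(model, expr) == 0.0).all()

    def test_positive_scaling_linearity(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.normal(size=(4, 6)), index=list("abcd"))
        model = self.model(["a", "c"], ["b"])
        base = ggi_score(model, expr)
        for a in (0.5, 2.0, 7.3):
            scaled = ggi_score(model, a * expr)
            assert np.allclose(scaled, a * base)

    def test_missing_model_genes_dropped_with_warning(self):
        expr = pd.DataFrame({"s1": [2.0]}, index=["a"])
        with pytest.warns(UserWarning, match="missing"):
            score = ggi_score(self.model(["a", "ghost"], []), expr)
        assert score["s1"] == 2.0


class TestLogrankAndStratification:
    def test_identical_groups_give_null_statistic(self):
        time = [5, 6, 7, 8, 5, 6, 7, 8]
        event = [1, 1, 0, 1, 1, 1, 0, 1]
        group = [True] * 4 + [False] * 4
        stat, p = logrank_test(time, event, group)
        assert stat == 0.0 and p == 1.0

    def test_hand_computed_eight_patient_table(self):
        # group 1: times 1,3,5,7 events 1,1,0,1; group 0: times 2,4,6,8 events 1,0,1,1
        # accumulating O-E and V over event times 1,2,3,6,7,8 by hand gives
        # O-E = 1/2 - 3/7 + 1/2 - 1/3 + 1/2 + 0 = 31/42
        # V   = 1/4 + 12/49 + 1/4 + 2/9 + 1/4     = 2147/1764
        # statistic = (31/42)^2 / (2147/1764) = 961/2147
        stat, p = logrank_test([1, 3, 5, 7, 2, 4, 6, 8],
                               [1, 1, 0, 1, 1, 0, 1, 1],
                               [1, 1, 1, 1, 0, 0, 0, 0])
        assert stat == pytest.approx(961 / 2147, rel=1e-12)

    def test_matches_lifelines_on_random_data(self):
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        rng = np.random.default_rng(7)
        t = rng.exponential(1, size=40)
        e = (rng.random(40) < 0.8).astype(int)
        g = rng.random(40) < 0.5
        stat, p = logrank_test(t, e, g)
        ref = lifelines_stats.logrank_test(t[g], t[~g], e[g], e[~g])
        assert stat == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_degenerate_stratification_rejected(self):
        model = RiskModel(coefficients={"a": 1.0})
        expr = pd.DataFrame([[1.0, 1.0, 1.0, 1.0]], index=["a"],
                            columns=[f"p{i}" for i in range(4)])
        clin = make_clinical([1, 2, 3, 4], [1, 1, 1, 1])
        with pytest.raises(ValueError, match="degenerate"):
            stratify_and_test(model, expr, clin)

    def test_median_split_halves_even_cohort(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.normal(size=(2, 10)), index=["a", "b"],
                            columns=[f"p{i}" for i in range(10)])
        clin = make_clinical(rng.exponential(1, 10), [1] * 10)
        strat = stratify_and_test(RiskModel(coefficients={"a": 1.0, "b": -1.0}),
                                  expr, clin)
        assert (strat.groups == "high").sum() == 5
        assert (strat.groups == "low").sum() == 5

    def test_flipping_coefficients_swaps_groups_same_p(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(rng.normal(size=(3, 20)), index=["a", "b", "c"],
                            columns=[f"p{i}" for i in range(20)])
        clin = make_clinical(rng.exponential(1, 20), (rng.random(20) < 0.8).astype(int))
        model = RiskModel(coefficients={"a": 0.8, "b": -0.5, "c": 1.2})
        flipped = RiskModel(coefficients={g: -b for g, b in model.coefficients.items()})
        s1 = stratify_and_test(model, expr, clin)
        s2 = stratify_and_test(flipped, expr, clin)
        assert s1.p_value == pytest.approx(s2.p_value, rel=1e-9)
        swap = {"high": "low", "low": "high"}
        assert (s2.groups == s1.groups.map(swap)).all()

    def test_planted_risk_module_separates_and_hr_above_one(self):
        config = hn.SyntheticConfig(n_cohorts=1, samples_per_cohort=(200,),
                                    shared_modules=((8, 0.8),),
                                    cohort_specific_modules=(), beta=1.5, seed=21)
        ds = hn.generate_cohorts(config)
        expr, clin = ds.cohorts["cohort0"]
        genes = ds.module_genes("shared0")
        train, test = stratified_split(clin, seed=1)
        model = fit_risk_model(expr[train], clin[clin["sample_id"].isin(train)], genes)
        strat = stratify_and_test(model, expr[test], clin[clin["sample_id"].isin(test)])
        assert strat.p_value < 0.05
        assert strat.hazard_ratio > 1.0


class TestFitRiskModel:
    def test_partitions_by_sign_and_flags(self, default_dataset):
        expr, clin = default_dataset.cohorts["cohort0"]
        genes = list(default_dataset.module_genes("shared0"))[:4]
        expr = expr.copy()
        expr.loc["flat"] = 1.0
        with pytest.warns(UserWarning, match="absent"):
            model = fit_risk_model(expr, clin, genes + ["flat", "ghost"])
        assert "flat" in model.flagged_genes
        assert "ghost" in model.flagged_genes
        assert set(model.positive_genes) | set(model.negative_genes) <= set(genes)
        assert not set(model.positive_genes) & set(model.negative_genes)
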