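"""Cutpoint search methods: grid construction, argmax/argmin contracts,
oracle identities, determinism, and recovery of the true cutpoint."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import survcut.cutpoints as cp
from survcut import (GASettings, Scenario, SurvivalDataset, candidate_grid,
                     crossval_effect, dichotomise, estimate_all,
                     estimate_concordance_addfor, estimate_concordance_genetic,
                     estimate_maxchi2, estimate_minaic, estimate_minp_logrank,
                     estimate_splitsample, fit_cox, harrell_cindex,
                     logrank_test, simulate_dataset)

from conftest import random_survival_data


class TestCandidateGrid:
    def test_integer_ladder(self):
        g = candidate_grid(np.arange(1.0, 101.0), min_prop=0.1)
        np.testing.assert_array_equal(g.values, np.arange(10.0, 91.0))

    def test_tight_bound(self):
        g = candidate_grid(np.arange(1.0, 101.0), min_prop=0.49)
        np.testing.assert_array_equal(g.values, [49.0, 50.0, 51.0])

    def test_constant_and_few_values_rejected(self):
        with pytest.raises(ValueError):
            candidate_grid(np.ones(50))
        with pytest.raises(ValueError):
            candidate_grid(np.tile(np.arange(5.0), 10))

    def test_group_proportions_bounded(self, weibull_data):
        x = weibull_data.biomarker
        g = candidate_grid(x, min_prop=0.1)
        for v in (g.values[0], g.values[-1]):
            prop = (x <= v).mean()
            assert 0.1 - 1e-12 <= prop <= 0.9 + 1e-12


class TestDichotomise:
    def test_boundary_belongs_to_low_group(self):
        np.testing.assert_array_equal(dichotomise([1, 2, 3], 2.0), [0, 0, 1])

    def test_extremes(self):
        x = np.array([1.0, 2.0, 3.0])
        assert dichotomise(x, 0.0).sum() == 3
        assert dichotomise(x, 3.0).sum() == 0

    def test_nonfinite_cutpoint_rejected(self):
        with pytest.raises(ValueError):
            dichotomise([1.0, 2.0], np.nan)


class TestChiSquareMethods:
    def test_maxchi2_equals_minaic(self):
        # analytic identity: argmax LRT chi2 == argmin AIC at fixed k
        for seed in range(6):
            sc = Scenario(["weibull", "exponential", "gompertz"][seed % 3],
                          theta=0.7, n_obs=150, pc_t=0.5, pc_f=0.25, seed=seed)
            data = simulate_dataset(sc)
            a = estimate_maxchi2(data)
            e1 = estimate_minaic(data)
            assert a.cutpoint == e1.cutpoint

    def test_single_candidate_grid(self, weibull_data):
        g = candidate_grid(weibull_data.biomarker, 0.1)
        single = cp.CandidateGrid(g.values[[5]], 0.1)
        res = estimate_maxchi2(weibull_data, single)
        assert res.cutpoint == g.values[5]

    def test_recovery_of_true_cutpoint(self):
        sc = Scenario("weibull", theta=0.2, n_obs=5_000, pc_t=0.2, pc_f=0.25,
                      seed=101)
        data = simulate_dataset(sc)
        res = estimate_maxchi2(data)
        assert res.cutpoint == pytest.approx(0.2, abs=0.1)

    def test_crossval_effect_recovers_hazard_ratio(self):
        sc = Scenario("weibull", theta=0.2, n_obs=4_000, pc_t=0.2, pc_f=0.25,
                      seed=102)
        data = simulate_dataset(sc)
        hr, p = crossval_effect(data, seed=7)
        assert hr == pytest.approx(3.0, abs=0.5)
        assert p < 0.001
        assert (hr, p) == crossval_effect(data, seed=7)  # deterministic

    def test_splitsample_determinism_and_grid_membership(self, weibull_data):
        a = estimate_splitsample(weibull_data, seed=5)
        b = estimate_splitsample(weibull_data, seed=5)
        assert (a.cutpoint, a.hazard_ratio, a.p_value) == \
               (b.cutpoint, b.hazard_ratio, b.p_value)
        assert a.hazard_ratio is not None and a.p_value is not None

    def test_splitsample_needs_forty_subjects(self):
        rng = np.random.default_rng(3)
        data = random_survival_data(rng, 30)
        with pytest.raises(ValueError):
            estimate_splitsample(data)

    def test_stratified_half_split_partitions(self):
        rng = np.random.default_rng(4)
        event = rng.integers(0, 2, 101)
        first = cp._stratified_half_split(event, rng)
        assert first.sum() + (~first).sum() == 101
        n_ev = event.sum()
        assert abs(event[first].sum() - n_ev / 2) <= 1


class TestConcordanceMethods:
    def test_addfor_is_argmax_over_grid(self, weibull_data):
        res = estimate_concordance_addfor(weibull_data, criterion="cindex")
        # re-score every candidate independently via public functions
        g = candidate_grid(weibull_data.biomarker, 0.1)
        best = -np.inf
        frame = weibull_data.data
        for v in g.values:
            f2 = frame.copy()
            f2["XD"] = dichotomise(weibull_data.biomarker, v)
            fit = fit_cox(SurvivalDataset(f2), ["XD", "Z1", "Z2", "Z3"])
            c = harrell_cindex(fit.linear_predictors, weibull_data.time,
                               weibull_data.event)
            best = max(best, c)
        assert res.criterion_value == pytest.approx(best, abs=1e-12)
        assert res.cutpoint in g.values

    def test_cpe_recovery(self):
        sc = Scenario("weibull", theta=0.2, n_obs=1_500, pc_t=0.2, pc_f=0.25,
                      seed=103)
        data = simulate_dataset(sc)
        res = estimate_concordance_addfor(data, criterion="cpe")
        assert res.cutpoint == pytest.approx(0.2, abs=0.15)

    def test_genetic_matches_exhaustive_optimum(self):
        # 1-D fitness is piecewise constant on ~50 pieces: the GA should find
        # the exhaustive-grid optimum in nearly every seeded run
        rng = np.random.default_rng(105)
        sc = Scenario("weibull", theta=0.5, n_obs=200, pc_t=0.3, pc_f=0.25,
                      seed=105)
        base = simulate_dataset(sc)
        frame = base.data.copy()
        frame["X"] = np.round(frame["X"], 1)  # ~50 distinct candidate pieces
        data = SurvivalDataset(frame)
        exact = estimate_concordance_addfor(data, criterion="cindex")
        hits = 0
        for seed in range(100):
            ga = estimate_concordance_genetic(data, criterion="cindex", seed=seed)
            assert ga.cutpoint >= ga.diagnostics["bounds"][0]
            assert ga.cutpoint <= ga.diagnostics["bounds"][1]
            if ga.criterion_value >= exact.criterion_value - 1e-6:
                hits += 1
        assert hits >= 95

    def test_genetic_deterministic(self, weibull_data):
        a = estimate_concordance_genetic(weibull_data, criterion="cpe", seed=11)
        b = estimate_concordance_genetic(weibull_data, criterion="cpe", seed=11)
        assert a.cutpoint == b.cutpoint
        assert a.criterion_value == b.criterion_value


class TestAICMethods:
    def test_e1_recovery_far_cutpoint(self):
        sc = Scenario("weibull", theta=1.2, n_obs=5_000, pc_t=0.2, pc_f=0.25,
                      seed=106)
        data = simulate_dataset(sc)
        res = estimate_minaic(data)
        assert res.cutpoint == pytest.approx(1.2, abs=0.15)

    def test_e2_attracted_to_median_under_null_biomarker(self):
        # biomarker unrelated to survival: the strata AIC favours balanced
        # splits, so E2 estimates pile up near the biomarker median
        cuts = []
        for seed in range(120):
            sc = Scenario("weibull", theta=0.7, n_obs=200, pc_t=0.3, pc_f=0.25,
                          betas=(0.0, np.log(2), np.log(0.5), np.log(2)),
                          seed=200 + seed)
            data = simulate_dataset(sc)
            res = estimate_minaic(data, as_strata=True)
            if not res.failed:
                cuts.append(res.cutpoint - np.median(data.biomarker))
        assert len(cuts) > 100
        assert abs(np.mean(cuts)) < 0.2

    def test_e2_skips_eventless_strata(self, weibull_data):
        res = estimate_minaic(weibull_data, as_strata=True)
        assert not res.failed
        assert "n_infeasible" in res.diagnostics


class TestMinPLogrank:
    def test_scan_equals_per_candidate_brute_force(self, weibull_data):
        res = estimate_minp_logrank(weibull_data)
        g = candidate_grid(weibull_data.biomarker, 0.1)
        pvals = [logrank_test(weibull_data.time, weibull_data.event,
                              weibull_data.biomarker > v).p_value
                 for v in g.values]
        assert res.p_value == pytest.approx(min(pvals), abs=1e-12)
        assert res.p_value <= min(pvals) + 1e-15
        assert res.cutpoint == g.values[int(np.argmin(pvals))]

    def test_recovery(self):
        sc = Scenario("weibull", theta=0.7, n_obs=5_000, pc_t=0.2, pc_f=0.25,
                      seed=107)
        data = simulate_dataset(sc)
        res = estimate_minp_logrank(data)
        assert res.cutpoint == pytest.approx(0.7, abs=0.15)


class TestEstimateAll:
    def test_deterministic_batch(self, weibull_data):
        a = estimate_all(weibull_data, methods=["E1"], seed=9)
        b = estimate_all(weibull_data, methods=["E1"], seed=9)
        assert a[0].cutpoint == b[0].cutpoint

    def test_all_nine_methods(self, weibull_data):
        results = estimate_all(weibull_data, seed=9)
        assert [r.method for r in results] == list(cp.METHODS)
        by = {r.method: r for r in results}
        assert by["A"].cutpoint == by["E1"].cutpoint
        assert not any(r.failed for r in results)
        g = candidate_grid(weibull_data.biomarker, 0.1)
        for m in ("A", "B", "C1", "D1", "E1", "E2", "F"):
            if m == "B":
                continue  # B's grid comes from its own half
            assert by[m].cutpoint in g.values
        lo, hi = g.bounds
        for m in ("C2", "D2"):
            assert lo <= by[m].cutpoint <= hi

    def test_method_failure_is_isolated(self, weibull_data, monkeypatch):
        def boom(*args, **kwargs):
            raise ValueError("forced failure")
        monkeypatch.setattr(cp, "estimate_concordance_genetic", boom)
        results = estimate_all(weibull_data, methods=["C2", "E1"], seed=1)
        by = {r.method: r for r in results}
        assert by["C2"].failed and np.isnan(by["C2"].cutpoint)
        assert not by["E1"].failed

    def test_unknown_or_empty_methods_rejected(self, weibull_data):
        with pytest.raises(ValueError):
            estimate_all(weibull_data, methods=[])
        with pytest.raises(ValueError):
            estimate_all(weibull_data, methods=["Z9"])
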