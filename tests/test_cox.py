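"""Partial-likelihood fitting and model criteria, cross-checked against
lifelines and brute-force pair counting."""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as lifelines_logrank
from lifelines.utils import concordance_index

from survcut import (SurvivalDataset, fit_cox, gonen_heller_cpe, harrell_cindex,
                     logrank_test)
from survcut.cox import PartialLikelihood

from conftest import random_survival_data


def brute_force_cindex(pred, time, event):
    """Independent double loop over ordered pairs."""
    num = den = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shorter = time[i] < time[j] or (
                time[i] == time[j] and event[i] == 1 and event[j] == 0)
            if shorter and event[i] == 1:
                den += 1
                if pred[i] > pred[j]:
                    num += 1
                elif pred[i] == pred[j]:
                    num += 0.5
    return num / den


def brute_force_cpe(beta, x):
    n = x.shape[0]
    total = pairs = 0.0
    for i in range(n):
        for j in range(n):
            if i >= j:
                continue
            d_ij = float((x[j] - x[i]) @ beta)
            d_ji = -d_ij
            term = 0.0
            if d_ij < 0:
                term += 1.0 / (1.0 + math.exp(d_ij))
            if d_ji < 0:
                term += 1.0 / (1.0 + math.exp(d_ji))
            if d_ij == 0:
                term = 0.5
            total += term
            pairs += 1
    return total / pairs


class TestFitCox:
    @pytest.mark.parametrize("with_ties", [False, True])
    def test_matches_lifelines(self, with_ties):
        rng = np.random.default_rng(8)
        data = random_survival_data(rng, 300, n_covariates=2, with_ties=with_ties)
        fit = fit_cox(data, ["X", "Z1", "Z2"])
        cph = CoxPHFitter().fit(
            data.data[["time", "event", "X", "Z1", "Z2"]], "time", "event")
        np.testing.assert_allclose(fit.coef, cph.params_.values, atol=1e-6)
        assert fit.log_pl == pytest.approx(cph.log_likelihood_, abs=1e-6)
        np.testing.assert_allclose(fit.se(), cph.standard_errors_.values, atol=1e-5)

    def test_stratified_matches_lifelines(self):
        rng = np.random.default_rng(9)
        data = random_survival_data(rng, 300, n_covariates=2)
        frame = data.data.copy()
        frame["g"] = (rng.random(300) < 0.4).astype(int)
        ds = SurvivalDataset(frame, covariate_cols=("Z1", "Z2"))
        fit = fit_cox(ds, ["Z1", "Z2"], strata="g")
        cph = CoxPHFitter().fit(frame[["time", "event", "Z1", "Z2", "g"]],
                                "time", "event", strata=["g"])
        np.testing.assert_allclose(fit.coef, cph.params_.values, atol=1e-6)
        assert fit.log_pl == pytest.approx(cph.log_likelihood_, abs=1e-6)
        assert fit.k == 2  # strata contribute no coefficients

    def test_single_stratum_equals_unstratified(self):
        rng = np.random.default_rng(10)
        data = random_survival_data(rng, 200, n_covariates=1)
        frame = data.data.copy()
        frame["one"] = 1
        ds = SurvivalDataset(frame, covariate_cols=("Z1",))
        a = fit_cox(ds, ["X", "Z1"])
        b = fit_cox(ds, ["X", "Z1"], strata="one")
        np.testing.assert_allclose(a.coef, b.coef, atol=1e-10)
        assert a.log_pl == pytest.approx(b.log_pl, abs=1e-10)

    def test_parameter_recovery(self):
        from survcut import Scenario, simulate_dataset, dichotomise
        betas = (math.log(3), math.log(2), math.log(0.5), math.log(2))
        sc = Scenario("weibull", theta=0.2, n_obs=10_000, pc_t=0.2, pc_f=0.25,
                      seed=3)
        data = simulate_dataset(sc)
        frame = data.data.copy()
        frame["XD"] = dichotomise(data.biomarker, 0.2)
        fit = fit_cox(SurvivalDataset(frame), ["XD", "Z1", "Z2", "Z3"])
        assert fit.converged
        np.testing.assert_allclose(fit.coef, betas, atol=0.1)

    def test_aic_identity_and_chi2_scale_invariance(self):
        rng = np.random.default_rng(12)
        data = random_survival_data(rng, 250, n_covariates=2)
        fit = fit_cox(data, ["X", "Z1", "Z2"])
        assert fit.aic == -2.0 * fit.log_pl + 2 * fit.k
        rescaled = data.data.copy()
        rescaled["Z1"] = rescaled["Z1"] * 10 + 3
        fit2 = fit_cox(SurvivalDataset(rescaled, covariate_cols=("Z1", "Z2")),
                       ["X", "Z1", "Z2"])
        assert fit2.chi_square == pytest.approx(fit.chi_square, abs=1e-6)

    def test_constant_covariate_rejected(self):
        rng = np.random.default_rng(13)
        data = random_survival_data(rng, 50)
        frame = data.data.copy()
        frame["c"] = 1.0
        with pytest.raises(ValueError):
            fit_cox(SurvivalDataset(frame, covariate_cols=()), ["X", "c"])

    def test_empty_stratum_rejected(self):
        rng = np.random.default_rng(14)
        data = random_survival_data(rng, 60)
        frame = data.data.copy()
        frame["g"] = 0
        frame.loc[frame.index[frame["event"] == 0][:5], "g"] = 1  # eventless stratum
        with pytest.raises(ValueError):
            fit_cox(SurvivalDataset(frame, covariate_cols=()), ["X"], strata="g")

    def test_compiled_and_numpy_paths_agree(self):
        rng = np.random.default_rng(15)
        data = random_survival_data(rng, 150, n_covariates=2, with_ties=True)
        X = data.data[["X", "Z1", "Z2"]].to_numpy()
        beta = np.array([0.4, -0.3, 0.2])
        auto = PartialLikelihood(data.time, data.event)
        ref = PartialLikelihood(data.time, data.event, engine="numpy")
        la, ga, ha = auto.loglik(X, beta)
        lb, gb, hb = ref.loglik(X, beta)
        assert la == pytest.approx(lb, abs=1e-9)
        np.testing.assert_allclose(ga, gb, atol=1e-9)
        np.testing.assert_allclose(ha, hb, atol=1e-8)


class TestHarrellCindex:
    def test_perfectly_reversed_predictor(self):
        time = np.arange(1.0, 21.0)
        event = np.ones(20)
        assert harrell_cindex(-time, time, event) == 1.0

    def test_independent_predictor_near_half(self):
        rng = np.random.default_rng(16)
        time = rng.exponential(1, 2000)
        event = rng.integers(0, 2, 2000)
        pred = rng.standard_normal(2000)
        assert harrell_cindex(pred, time, event) == pytest.approx(0.5, abs=0.03)

    def test_matches_brute_force_and_lifelines(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            n = int(rng.integers(8, 26))
            time = rng.exponential(1, n)
            event = rng.integers(0, 2, n)
            event[0] = 1
            pred = np.round(rng.standard_normal(n), 1)  # induce predictor ties
            c = harrell_cindex(pred, time, event)
            assert c == pytest.approx(brute_force_cindex(pred, time, event),
                                      abs=1e-12)
            assert c == pytest.approx(concordance_index(time, -pred, event),
                                      abs=1e-12)

    def test_negation_flips_concordance(self):
        rng = np.random.default_rng(18)
        time = rng.exponential(1, 100)  # tie-free
        event = rng.integers(0, 2, 100)
        event[0] = 1
        pred = rng.standard_normal(100)
        c = harrell_cindex(pred, time, event)
        assert harrell_cindex(-pred, time, event) == pytest.approx(1 - c, abs=1e-12)


class TestCPE:
    def test_zero_coefficients_give_exactly_half(self):
        rng = np.random.default_rng(19)
        x = rng.standard_normal((30, 3))
        assert gonen_heller_cpe(np.zeros(3), x) == 0.5

    def test_two_subjects_far_apart_approach_one(self):
        x = np.array([[100.0], [-100.0]])
        assert gonen_heller_cpe(np.array([1.0]), x) == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(20)
        x = rng.standard_normal((20, 3))
        beta = rng.standard_normal(3)
        assert gonen_heller_cpe(beta, x) == pytest.approx(
            brute_force_cpe(beta, x), abs=1e-12)

    def test_invariances(self):
        rng = np.random.default_rng(21)
        x = rng.standard_normal((25, 2))
        beta = np.array([0.7, -0.4])
        base = gonen_heller_cpe(beta, x)
        perm = rng.permutation(25)
        assert gonen_heller_cpe(beta, x[perm]) == pytest.approx(base, abs=1e-12)
        # constant covariate shifts every linear predictor equally: no effect
        x_aug = np.c_[x, np.ones(25)]
        assert gonen_heller_cpe(np.r_[beta, 2.5], x_aug) == pytest.approx(
            base, abs=1e-12)


class TestLogRank:
    def test_identical_groups_give_zero(self):
        time = np.r_[np.arange(1.0, 11.0), np.arange(1.0, 11.0)]
        event = np.r_[np.ones(10), np.ones(10)]
        group = np.r_[np.zeros(10), np.ones(10)]
        res = logrank_test(time, event, group)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_six_subject_hand_tabulation(self):
        # times 1..6, all events, group = [1,1,1,0,0,0]:
        # O1-E1 per event time: .5, .6, .75, 0, 0, 0 (sum 1.85)
        # V per event time:    .25, .24, .1875, 0, 0, 0 (sum .6775)
        res = logrank_test([1, 2, 3, 4, 5, 6], [1] * 6, [1, 1, 1, 0, 0, 0])
        assert res.statistic == pytest.approx(1.85 ** 2 / 0.6775, abs=1e-12)

    def test_matches_lifelines(self):
        rng = np.random.default_rng(22)
        time = rng.exponential(1, 150)
        event = rng.integers(0, 2, 150)
        event[0] = 1
        group = rng.random(150) < 0.4
        res = logrank_test(time, event, group)
        ref = lifelines_logrank(time[group], time[~group],
                                event[group], event[~group])
        assert res.statistic == pytest.approx(ref.test_statistic, abs=1e-9)
        assert res.p_value == pytest.approx(ref.p_value, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], [1, 1])
        with pytest.raises(ValueError):
            logrank_test([1, 2], [0, 0], [1, 0])
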