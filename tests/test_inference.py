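"""Type determination and the Rogers binomial MLE."""

import math

import numpy as np
import pytest
from scipy import optimize

from frfit import (FRParams, SimConfig, Trial, binomial_loglik, classify_fr_type,
                   fit_rogers, rogers_expected, simulate_trials, summarize_fit)
from frfit.errors import DegenerateDataError

EXT = (2, 4, 8, 16, 32, 64, 128, 256)


def _trials(pairs, **kw):
    return [Trial(n_initial=n0, n_eaten=ne, replicate=i + 1, **kw)
            for i, (n0, ne) in enumerate(pairs)]


class TestLikelihood:
    def test_matches_hand_summed_binomial_logpmf(self):
        """3-trial toy dataset: the model log-likelihood equals a fully
        hand-rolled sum of binomial log-pmfs (math.comb, math.log)."""
        trials = _trials([(8, 3), (16, 7), (32, 10)])
        params = FRParams(0.7, 0.05, 1.0)
        hand = 0.0
        for t in trials:
            p = rogers_expected(float(t.n_initial), params) / t.n_initial
            hand += (math.log(math.comb(t.n_initial, t.n_eaten))
                     + t.n_eaten * math.log(p)
                     + (t.n_initial - t.n_eaten) * math.log(1 - p))
        assert binomial_loglik(trials, params) == pytest.approx(hand, abs=1e-10)


class TestClassify:
    def test_typeii_on_rogers_simulated_data(self):
        cfg = SimConfig(attack_rate=2.0, handling_time=0.04, densities=EXT,
                        replicates=10, seed=2)
        res = classify_fr_type(simulate_trials(cfg))
        assert res.inferred_type == "TypeII"
        assert res.first_order_coef < 0
        assert res.p_value < 0.05

    def test_flat_proportion_is_ambiguous(self):
        trials = _trials([(n0, n0 // 2) for n0 in (2, 4, 8, 16, 32, 64)] * 3)
        res = classify_fr_type(trials)
        assert abs(res.first_order_coef) < 0.02
        assert res.inferred_type == "ambiguous"

    def test_typeiii_sigmoidal_data(self):
        """Data generated with a density-dependent attack rate a(N)=b*N
        (low proportional consumption at low density) must classify as
        Type III, and the coefficient must agree with an independent
        hand-rolled logistic MLE."""
        rng = np.random.default_rng(7)
        trials = []
        b, h = 0.004, 0.02
        for n0 in (2, 4, 8, 16, 32, 64):
            a_n = b * n0
            pe = min(0.95, a_n * n0 / (1 + a_n * h * n0) / n0)
            for rep in range(1, 11):
                trials.append(Trial(n_initial=n0, n_eaten=int(rng.binomial(n0, pe)),
                                    replicate=rep))
        res = classify_fr_type(trials)
        assert res.inferred_type == "TypeIII"
        assert res.first_order_coef > 0

        # independent oracle: maximize the binomial-logit likelihood directly
        n0s = np.array([t.n_initial for t in trials], float)
        nes = np.array([t.n_eaten for t in trials], float)

        def nll(beta):
            eta = beta[0] + beta[1] * n0s
            p = 1 / (1 + np.exp(-eta))
            p = np.clip(p, 1e-12, 1 - 1e-12)
            return -np.sum(nes * np.log(p) + (n0s - nes) * np.log(1 - p))

        fit = optimize.minimize(nll, [0.0, 0.0], method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12})
        assert res.first_order_coef == pytest.approx(fit.x[1], rel=1e-3)

    def test_separation_raises(self):
        with pytest.raises(DegenerateDataError, match="separation"):
            classify_fr_type(_trials([(n0, n0) for n0 in (2, 4, 8)] * 3))


class TestFitRogers:
    def test_recovers_truth_within_wald_interval(self, typeii_trials):
        fit = fit_rogers(typeii_trials)
        assert fit.converged
        ci = fit.wald_ci()
        assert ci["a"][0] <= 1.5 <= ci["a"][1]
        assert ci["h"][0] <= 0.08 <= ci["h"][1]
        assert fit.se_a > 0 and fit.se_h > 0
        assert fit.p_a < 0.05 and fit.p_h < 0.05

    def test_single_density_unidentifiable(self):
        with pytest.raises(DegenerateDataError):
            fit_rogers(_trials([(16, k) for k in (3, 5, 4, 6)]))

    def test_no_feeding_raises(self):
        with pytest.raises(DegenerateDataError):
            fit_rogers(_trials([(n0, 0) for n0 in (2, 4, 8, 16)] * 3))

    def test_all_depleted_raises(self):
        with pytest.raises(DegenerateDataError):
            fit_rogers(_trials([(n0, n0) for n0 in (2, 4, 8, 16)] * 3))

    def test_predictions_respect_depletion_bound(self, small_group):
        fit = fit_rogers(small_group)
        for n0 in sorted({t.n_initial for t in small_group}):
            pred = rogers_expected(float(n0), fit.params)
            assert 0 <= pred < n0

    def test_time_unit_consistency(self, small_group):
        """Relabelling the trial duration (hours -> half-days) rescales
        a and h but leaves the fitted consumption curve unchanged."""
        fit1 = fit_rogers(small_group)
        relabelled = [Trial(n_initial=t.n_initial, n_eaten=t.n_eaten,
                            replicate=t.replicate, duration_h=2.0)
                      for t in small_group]
        fit2 = fit_rogers(relabelled)
        assert fit2.params.a == pytest.approx(fit1.params.a / 2, rel=1e-3)
        assert fit2.params.h == pytest.approx(fit1.params.h * 2, rel=1e-3)
        for n0 in (2.0, 16.0, 64.0):
            p1 = rogers_expected(n0, fit1.params)
            p2 = rogers_expected(n0, fit2.params)
            assert p2 == pytest.approx(p1, rel=1e-3)


class TestSummarize:
    def test_summary_round_trip(self, small_group):
        fit = fit_rogers(small_group)
        s = summarize_fit(fit)
        assert s["a"] == fit.params.a
        assert s["h"] == fit.params.h
        assert s["max_feeding_rate"] == pytest.approx(
            1.0 / (fit.params.h * fit.params.T))

    @pytest.mark.parametrize("h,expected", [(0.025, 40.0), (0.2, 5.0)])
    def test_max_feeding_rate_values(self, small_group, h, expected):
        fit = fit_rogers(small_group)
        forced = type(fit)(**{**fit.__dict__, "params": FRParams(fit.params.a, h, 1.0)})
        assert summarize_fit(forced)["max_feeding_rate"] == pytest.approx(expected)
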