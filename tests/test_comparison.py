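"""Juliano indicator-variable tests and bootstrap confidence bands."""

import math

import numpy as np
import pytest

from frfit import (BootstrapBand, SimConfig, bootstrap_fr, fit_rogers,
                   juliano_compare, overlap_verdict, pairwise_compare,
                   rogers_expected, simulate_trials)
from frfit.comparison import _pooled_nll
from frfit.letters import GREEK, compact_letters


class TestJuliano:
    def test_self_comparison_is_null(self, small_group):
        res = juliano_compare(small_group, small_group)
        assert res.delta_a == pytest.approx(0.0, abs=1e-4)
        assert res.delta_h == pytest.approx(0.0, abs=1e-5)
        assert res.p_delta_a > 0.5 and res.p_delta_h > 0.5

    def test_swap_symmetry(self, small_group):
        other = simulate_trials(SimConfig(attack_rate=1.3, handling_time=0.07,
                                          replicates=10, seed=8))
        r12 = juliano_compare(small_group, other)
        r21 = juliano_compare(other, small_group)
        assert r12.delta_a == pytest.approx(-r21.delta_a, abs=1e-4)
        assert r12.delta_h == pytest.approx(-r21.delta_h, abs=1e-5)
        assert r12.p_delta_a == pytest.approx(r21.p_delta_a, abs=1e-6)
        assert r12.p_delta_h == pytest.approx(r21.p_delta_h, abs=1e-6)

    def test_detects_halved_handling_time(self):
        """Group 2 handles prey twice as fast: Δh (group2-group1) must be
        negative and significant on a well-replicated design."""
        g1 = simulate_trials(SimConfig(attack_rate=1.0, handling_time=0.2,
                                       replicates=10, seed=21))
        g2 = simulate_trials(SimConfig(attack_rate=1.0, handling_time=0.1,
                                       replicates=10, seed=22))
        res = juliano_compare(g1, g2)
        assert res.delta_h < 0
        assert res.p_delta_h < 0.05

    def test_pooled_null_equals_concatenated_fit(self, small_group):
        other = simulate_trials(SimConfig(attack_rate=1.0, handling_time=0.1,
                                          replicates=10, seed=13))
        pooled_fit = fit_rogers(list(small_group) + list(other))
        nll = _pooled_nll(small_group, other)
        at_null = -nll(np.array([pooled_fit.params.a, pooled_fit.params.h, 0.0, 0.0]))
        assert at_null == pytest.approx(pooled_fit.log_likelihood, abs=1e-8)

    def test_non_overlapping_designs_flagged(self):
        g1 = simulate_trials(SimConfig(attack_rate=1.0, handling_time=0.1,
                                       densities=(2, 4, 8, 16), replicates=8,
                                       seed=3))
        g2 = simulate_trials(SimConfig(attack_rate=1.0, handling_time=0.1,
                                       densities=(32, 64, 128, 256), replicates=8,
                                       seed=4))
        res = juliano_compare(g1, g2)
        assert res.design_overlap is False

    def test_pairwise_reports_raw_and_holm(self, small_group):
        groups = {
            "g1": small_group,
            "g2": simulate_trials(SimConfig(attack_rate=1.0, handling_time=0.1,
                                            replicates=10, seed=31)),
            "g3": simulate_trials(SimConfig(attack_rate=1.0, handling_time=0.4,
                                            replicates=10, seed=32)),
        }
        out = pairwise_compare(groups)
        assert set(out["letters_h"]) == {"g1", "g2", "g3"}
        for rec in out["pairs"].values():
            assert rec["p_delta_h_holm"] >= rec["p_delta_h"] - 1e-12
        # the slow handler must be lettered apart from the two fast ones
        assert out["letters_h"]["g1"] == out["letters_h"]["g2"]
        assert out["letters_h"]["g3"] != out["letters_h"]["g1"]


class TestBootstrap:
    def test_percentiles_ordered_even_at_n2(self, small_group):
        band = bootstrap_fr(small_group, n_boot=2, seed=1)
        assert all(l <= u for l, u in zip(band.lower95, band.upper95))

    def test_seed_determinism_bitwise(self, small_group):
        b1 = bootstrap_fr(small_group, n_boot=25, seed=9)
        b2 = bootstrap_fr(small_group, n_boot=25, seed=9)
        assert b1 == b2

    def test_bounds_within_depletion_limits(self, small_group):
        band = bootstrap_fr(small_group, n_boot=40, seed=2)
        for n0, lo, hi in zip(band.grid, band.lower95, band.upper95):
            assert 0.0 <= lo <= hi < n0

    def test_band_narrows_with_replication(self):
        widths = []
        for reps in (3, 30):
            tr = simulate_trials(SimConfig(attack_rate=1.0, handling_time=0.1,
                                           replicates=reps, seed=17))
            b = bootstrap_fr(tr, n_boot=150, seed=5)
            widths.append(np.mean(np.array(b.upper95) - np.array(b.lower95)))
        assert widths[1] < widths[0]


class TestOverlap:
    def test_identical_bands_overlap_everywhere(self, small_group):
        b = bootstrap_fr(small_group, n_boot=30, seed=3)
        v = overlap_verdict(b, b)
        assert all(v["overlaps"])
        assert v["fraction_non_overlapping"] == 0.0

    def test_disjoint_synthetic_bands(self, small_group):
        b = bootstrap_fr(small_group, n_boot=30, seed=3)
        shifted = BootstrapBand(
            grid=b.grid, mean_curve=b.mean_curve, point_curve=b.point_curve,
            lower95=tuple(x + 1000 for x in b.lower95),
            upper95=tuple(x + 1000 for x in b.upper95),
            n_boot=b.n_boot, n_failed=0, seed=0)
        v = overlap_verdict(b, shifted)
        assert not any(v["overlaps"])
        assert v["fraction_non_overlapping"] == 1.0

    def test_separated_asymptotes_do_not_overlap_at_high_density(self):
        slow = simulate_trials(SimConfig(attack_rate=1.0, handling_time=0.5,
                                         replicates=20, seed=41))
        fast = simulate_trials(SimConfig(attack_rate=1.0, handling_time=0.01,
                                         replicates=20, seed=42))
        b1 = bootstrap_fr(slow, n_boot=150, seed=6)
        b2 = bootstrap_fr(fast, n_boot=150, seed=6)
        v = overlap_verdict(b1, b2)
        assert v["overlaps"][-1] is False  # density 64: asymptotes 2 vs 100

    def test_mismatched_grids_rejected(self, small_group):
        b1 = bootstrap_fr(small_group, n_boot=10, seed=1)
        b2 = bootstrap_fr(small_group, n_boot=10, seed=1, grid=[2, 64])
        with pytest.raises(ValueError):
            overlap_verdict(b1, b2)


class TestLetters:
    def test_all_different(self):
        p = {("x", "y"): 0.001, ("y", "z"): 0.001, ("x", "z"): 0.001}
        letters = compact_letters(["x", "y", "z"], p)
        assert len({letters[g] for g in "xyz"}) == 3

    def test_middle_group_bridges(self):
        p = {("x", "y"): 0.5, ("y", "z"): 0.5, ("x", "z"): 0.01}
        letters = compact_letters(["x", "y", "z"], p)
        assert set(letters["x"]) & set(letters["y"])
        assert set(letters["y"]) & set(letters["z"])
        assert not set(letters["x"]) & set(letters["z"])

    def test_greek_alphabet_option(self):
        letters = compact_letters(["p", "q"], {("p", "q"): 0.001}, alphabet=GREEK)
        assert letters["p"] == "α" and letters["q"] == "β"
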