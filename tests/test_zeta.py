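"""Zeta decline: closed form vs enumeration, schemes, and model selection."""

import numpy as np
import pandas as pd
import pytest

from zetacomm import (
    SchemeConfig, ZetaDecline, compare_fits, fit_decline,
    group_retention_curves, zeta_brute_force, zeta_decline, zeta_exact_all,
    zeta_mc,
)
from zetacomm.simulate import (
    generate_niche_incidence, generate_random_incidence,
)


class TestExactZeta:
    def test_hand_enumerated_four_plot_case(self, toy_incidence):
        # occupancies 3,2,2,1: zeta_1 = 8/4, zeta_2 = (3+1+1+0)/6
        assert zeta_exact_all(toy_incidence, 1) == pytest.approx(2.0)
        assert zeta_exact_all(toy_incidence, 2) == pytest.approx(5 / 6)

    def test_all_ones_matrix_is_flat(self):
        inc = pd.DataFrame(np.ones((6, 9), dtype=int))
        for i in range(1, 7):
            assert zeta_exact_all(inc, i) == pytest.approx(9.0)

    def test_full_order_counts_ubiquitous_species(self, toy_incidence):
        assert zeta_exact_all(toy_incidence, 4) == 0.0
        inc = toy_incidence.copy()
        inc["s5"] = 1
        assert zeta_exact_all(inc, 4) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 11))
        inc = generate_random_incidence(n, 25, 0.4, seed=seed)
        for i in range(1, n + 1):
            assert zeta_exact_all(inc, i) == pytest.approx(
                zeta_brute_force(inc, i), abs=1e-12)

    def test_monotone_decline(self):
        inc = generate_random_incidence(12, 60, 0.4, seed=8)
        z = [zeta_exact_all(inc, i) for i in range(1, 13)]
        assert all(a >= b - 1e-12 for a, b in zip(z, z[1:]))

    def test_order_out_of_range(self, toy_incidence):
        with pytest.raises(ValueError):
            zeta_exact_all(toy_incidence, 5)


class TestMonteCarlo:
    def test_enumeration_branch_is_exact(self):
        inc = generate_random_incidence(8, 30, 0.4, seed=0)
        cfg = SchemeConfig(scheme="ALL", sam=5000, seed=1)
        est, _ = zeta_mc(inc, 3, cfg)
        assert est == pytest.approx(zeta_exact_all(inc, 3), abs=1e-12)

    def test_sampling_error_within_three_se(self):
        inc = generate_random_incidence(30, 100, 0.4, seed=2)
        cfg = SchemeConfig(scheme="ALL", sam=5000, seed=3)
        for i in (5, 8):
            est, sd = zeta_mc(inc, i, cfg)
            assert abs(est - zeta_exact_all(inc, i)) < 3 * sd / np.sqrt(5000)

    def test_seeded_determinism(self):
        inc = generate_random_incidence(30, 50, 0.3, seed=4)
        cfg = SchemeConfig(scheme="ALL", sam=200, seed=9)
        assert zeta_mc(inc, 6, cfg) == zeta_mc(inc, 6, cfg)

    def test_nn_pairs_on_collinear_plots(self):
        # 5 equally spaced plots on a line: each focal's nearest neighbour
        # is the adjacent plot (ties to the lower index), so the NN pairs
        # are (0,1),(0,1),(1,2),(2,3),(3,4)
        inc = pd.DataFrame(
            [[1, 1, 0],
             [1, 0, 1],
             [0, 1, 1],
             [1, 1, 1],
             [1, 0, 0]], columns=list("abc"))
        coords = np.column_stack([np.arange(5.0), np.zeros(5)])
        cfg = SchemeConfig(scheme="NN", sam=5000, seed=0, coords=coords)
        est, _ = zeta_mc(inc, 2, cfg)
        pairs = [(0, 1), (0, 1), (1, 2), (2, 3), (3, 4)]
        expected = np.mean([
            (inc.iloc[a].to_numpy() & inc.iloc[b].to_numpy()).sum()
            for a, b in pairs])
        assert est == pytest.approx(expected)

    def test_nn_requires_coordinates(self):
        inc = generate_random_incidence(6, 10, 0.5, seed=0)
        with pytest.raises(ValueError):
            zeta_mc(inc, 2, SchemeConfig(scheme="NN", sam=10, seed=0))


class TestDeclineAndRatios:
    def test_all_ones_ratios_are_one(self):
        inc = pd.DataFrame(np.ones((6, 4), dtype=int))
        dec = zeta_decline(inc, 6)
        assert np.allclose(dec.ratios, 1.0)

    def test_bernoulli_retention_tracks_occupancy_probability(self):
        # independent presences: P(shared by i+1 | shared by i) = p
        inc = generate_random_incidence(25, 800, 0.4, seed=6)
        dec = zeta_decline(inc, 8)
        assert np.allclose(dec.ratios, 0.4, atol=0.05)

    def test_ratio_flagged_where_zeta_zero(self):
        inc = pd.DataFrame([[1, 0], [0, 1], [0, 0]])
        dec = zeta_decline(inc, 3)
        assert np.isnan(dec.ratios[1])

    def test_niche_retention_rises_with_order(self):
        # niche-assembled communities keep their generalists: the
        # retention rate climbs with order instead of staying flat
        rises = 0
        for s in range(10):
            inc = generate_niche_incidence(56, 300, 0.08, seed=s)
            dec = zeta_decline(inc, 12)
            r = dec.ratios[~np.isnan(dec.ratios)]
            if len(r) >= 4 and np.mean(r[-3:]) > np.mean(r[:2]):
                rises += 1
        assert rises >= 8


class TestFits:
    @staticmethod
    def _decline(zeta):
        orders = np.arange(1, len(zeta) + 1)
        return ZetaDecline(orders=orders, zeta=np.asarray(zeta, float),
                           sd=np.zeros(len(zeta)),
                           n_combinations=np.ones(len(zeta), int))

    def test_exact_power_series_recovers_exponent(self):
        orders = np.arange(1, 11)
        dec = self._decline(10.0 * orders ** -1.5)
        fit = fit_decline(dec, "power-law")
        assert fit.slope == pytest.approx(1.5, abs=1e-9)
        assert fit.perfect_fit and fit.aic == -np.inf
        form, _, _ = compare_fits(dec)
        assert form == "power-law"

    def test_exact_exponential_series_recovers_rate(self):
        orders = np.arange(1, 11)
        dec = self._decline(10.0 * np.exp(-0.5 * orders))
        fit = fit_decline(dec, "exponential")
        assert fit.slope == pytest.approx(0.5, abs=1e-9)
        assert compare_fits(dec)[0] == "exponential"

    def test_noisy_series_prefers_generating_form(self):
        rng = np.random.default_rng(0)
        orders = np.arange(1, 13)
        z = 10.0 * orders ** -1.2 * np.exp(rng.normal(0, 0.05, 12))
        assert compare_fits(self._decline(z))[0] == "power-law"

    def test_too_few_points_rejected(self):
        dec = self._decline([5.0, 3.0, 2.0])  # only orders 2,3 usable
        with pytest.raises(ValueError):
            fit_decline(dec, "exponential")

    def test_zero_zeta_truncates_fit_range(self):
        dec = self._decline([8, 5, 3, 2, 0, 0, 0, 0])
        fit = fit_decline(dec, "exponential")
        assert fit.n_points == 3  # orders 2..4

    def test_tie_is_reported(self):
        # constant zeta: both forms fit perfectly (slope 0), AIC -inf both
        dec = self._decline([4.0] * 8)
        form, delta, _ = compare_fits(dec)
        assert form == "tie" and delta == 0.0


class TestGroupCurves:
    def test_whole_group_equals_category_mean(self):
        inc = generate_random_incidence(12, 40, 0.4, seed=1)
        cats = {"all": list(inc.index)}
        out = group_retention_curves(
            inc, {"everything": list(inc.columns)}, cats,
            SchemeConfig(scheme="ALL", sam=10_000, seed=0), i_max=6)
        g = out[out["group"] == "everything"].set_index("order")["zeta"]
        ref = out[out["group"] == "__all__"].set_index("order")["zeta"]
        assert np.allclose(g, ref)

    def test_absent_group_flagged_undefined(self):
        inc = generate_random_incidence(8, 10, 0.5, seed=2)
        ghost = ["nothere"]
        out = group_retention_curves(
            inc, {"ghost": ghost}, {"all": list(inc.index)},
            SchemeConfig(scheme="ALL", sam=100, seed=0), i_max=4)
        sub = out[out["group"] == "ghost"]
        assert (sub["zeta"] == 0).all() and (~sub["defined"]).all()

    def test_planted_core_group_retains_fully(self):
        inc = generate_random_incidence(10, 20, 0.3, seed=3)
        inc["core1"] = 1
        inc["core2"] = 1
        out = group_retention_curves(
            inc, {"core": ["core1", "core2"]}, {"all": list(inc.index)},
            SchemeConfig(scheme="ALL", sam=5000, seed=0), i_max=5)
        sub = out[out["group"] == "core"]
        assert np.allclose(sub["ratio"].dropna(), 1.0)

    def test_tiny_category_rejected(self):
        inc = generate_random_incidence(6, 10, 0.5, seed=0)
        with pytest.raises(ValueError):
            group_retention_curves(
                inc, {}, {"one": [inc.index[0]]},
                SchemeConfig(scheme="ALL", sam=10, seed=0))
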