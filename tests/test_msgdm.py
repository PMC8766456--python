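"""I-spline basis, dissimilarity design, constrained fit and partition."""

import numpy as np
import pandas as pd
import pytest

from zetacomm import (
    IsplineBasis, SchemeConfig, SimulationConfig, average_rounds,
    combination_design, fit_msgdm, generate_dataset, ispline_transform,
    variance_partition,
)
from zetacomm.msgdm import MsgdmDesign


@pytest.fixture(scope="module")
def niche_dataset():
    return generate_dataset(SimulationConfig(
        seed=21, niche_strength=2.0, n_species=200,
        occupancy_model="geometric"))


def plot_incidence(ds):
    return ds.truth["presence_plot"]


class TestIspline:
    def test_anchors_at_zero_and_one(self):
        b = IsplineBasis()
        assert np.allclose(ispline_transform([0.0], b), 0.0)
        assert np.allclose(ispline_transform([1.0], b), 1.0)
        assert b.n_basis == 3

    def test_each_basis_function_is_monotone(self):
        grid = np.linspace(0, 1, 201)
        for basis in (IsplineBasis(), IsplineBasis(order=3, n_knots=2)):
            vals = ispline_transform(grid, basis)
            assert vals.shape == (201, basis.n_basis)
            assert (np.diff(vals, axis=0) >= -1e-12).all()
            assert ((vals >= -1e-12) & (vals <= 1 + 1e-12)).all()

    def test_domain_is_enforced(self):
        with pytest.raises(ValueError):
            ispline_transform([1.2])


class TestDesign:
    def test_identical_communities_give_unit_response(self):
        inc = pd.DataFrame(np.ones((6, 5), dtype=int),
                           index=[f"P{i}" for i in range(6)])
        meta = _meta(inc.index)
        d = combination_design(inc, meta, 3,
                               SchemeConfig(scheme="ALL", sam=100, seed=0),
                               variables=("altitude",))
        assert np.allclose(d.frame["response"], 1.0)

    def test_disjoint_communities_give_zero_response(self):
        inc = pd.DataFrame(np.eye(6, dtype=int),
                           index=[f"P{i}" for i in range(6)])
        meta = _meta(inc.index)
        d = combination_design(inc, meta, 2,
                               SchemeConfig(scheme="ALL", sam=100, seed=0),
                               variables=("altitude",))
        assert np.allclose(d.frame["response"], 0.0)

    def test_mean_pairwise_difference_arithmetic(self):
        inc = pd.DataFrame(np.ones((3, 4), dtype=int),
                           index=["P0", "P1", "P2"])
        meta = _meta(inc.index)
        meta["altitude"] = [0.0, 0.5, 1.0]
        d = combination_design(inc, meta, 3,
                               SchemeConfig(scheme="ALL", sam=10, seed=0),
                               variables=("altitude",))
        assert d.frame["altitude"].iloc[0] == pytest.approx(2 / 3)

    def test_empty_combinations_dropped(self):
        inc = pd.DataFrame([[1, 1], [0, 0], [0, 0]],
                           index=["P0", "P1", "P2"])
        meta = _meta(inc.index)
        d = combination_design(inc, meta, 2,
                               SchemeConfig(scheme="ALL", sam=10, seed=0),
                               variables=("altitude",))
        assert d.n_dropped == 1  # the (P1, P2) pair has no species at all
        assert len(d.frame) == 2

    def test_order_one_rejected(self):
        inc = pd.DataFrame(np.ones((3, 2), dtype=int),
                           index=["P0", "P1", "P2"])
        with pytest.raises(ValueError):
            combination_design(inc, _meta(inc.index), 1,
                               SchemeConfig(scheme="ALL", sam=10, seed=0))


def _meta(index):
    rng = np.random.default_rng(0)
    n = len(index)
    return pd.DataFrame({
        "plot_id": list(index),
        "x": rng.uniform(0, 10, n), "y": rng.uniform(0, 10, n),
        "altitude": rng.uniform(800, 1500, n),
    })


def _toy_design(n=300, signal="v1", noise=0.02, seed=0):
    rng = np.random.default_rng(seed)
    x1, x2 = rng.uniform(0, 1, n), rng.uniform(0, 1, n)
    dist = rng.uniform(0, 1, n)
    y = 0.9 - 0.6 * np.where(signal == "v1", x1, x2) ** 2
    y = np.clip(y + rng.normal(0, noise, n), 0, 1)
    frame = pd.DataFrame({"response": y, "distance": dist,
                          "v1": x1, "v2": x2})
    return MsgdmDesign(frame=frame, variables=("v1", "v2"), order=2)


class TestFit:
    def test_constant_response_gives_null_model(self):
        with pytest.warns(UserWarning):
            fit_msgdm(_toy_design(n=30))  # thin design warns
        d = _toy_design(noise=0.0)
        d.frame["response"] = 0.5
        m = fit_msgdm(d)
        assert m.r2 == pytest.approx(0.0, abs=1e-9)
        assert all(np.allclose(c, 0, atol=1e-5) for c in m.coefs.values())

    def test_recovers_the_driving_variable(self):
        wins = 0
        for s in range(20):
            m = fit_msgdm(_toy_design(signal="v1", seed=s))
            amp = m.amplitudes
            wins += amp["v1"] > max(amp["v2"], amp["distance"])
        assert wins >= 18

    def test_fitted_curves_monotone_and_bounded_by_amplitude(self):
        m = fit_msgdm(_toy_design())
        for v in ("v1", "v2", "distance"):
            curve = m.curve(v)["contribution"].to_numpy()
            assert (np.diff(curve) >= -1e-10).all()
            assert curve.max() <= m.amplitudes[v] + 1e-10

    def test_duplicate_predictor_never_hurts_fit(self):
        d = _toy_design()
        r2_single = fit_msgdm(d, predictors=("v1",)).r2
        r2_dup = fit_msgdm(d, predictors=("v1", "v1")).r2
        assert r2_dup >= r2_single - 1e-10


class TestRounds:
    def test_single_round_equals_single_fit(self, niche_dataset):
        ds = niche_dataset
        inc = plot_incidence(ds)
        cfg = SchemeConfig(scheme="ALL", sam=300, seed=5)
        av = average_rounds(inc, ds.metadata, 2, cfg, n_rounds=1)
        single = fit_msgdm(combination_design(inc, ds.metadata, 2, cfg))
        pd.testing.assert_series_equal(av.amplitude_mean,
                                       single.amplitudes, atol=1e-12)

    def test_exact_enumeration_regime_has_zero_spread(self):
        ds = generate_dataset(SimulationConfig(
            n_plots=8, n_species=50, seed=13))
        inc = plot_incidence(ds)
        cfg = SchemeConfig(scheme="ALL", sam=100, seed=0)  # C(8,2)=28 <= sam
        av = average_rounds(inc, ds.metadata, 2, cfg, n_rounds=4)
        assert (av.amplitude_sd < 1e-12).all()

    def test_spread_shrinks_with_sample_size(self, niche_dataset):
        ds = niche_dataset
        inc = plot_incidence(ds)
        spreads = {}
        for sam in (100, 2000):
            cfg = SchemeConfig(scheme="ALL", sam=sam, seed=1)
            av = average_rounds(inc, ds.metadata, 2, cfg, n_rounds=6)
            spreads[sam] = av.amplitude_sd.mean()
        assert spreads[2000] < spreads[100]


class TestPartition:
    def test_arithmetic_identity(self):
        d = _toy_design()
        vp = variance_partition(d)
        assert vp.as_series().sum() == pytest.approx(1.0, abs=1e-9)

    def test_irrelevant_distance_contributes_nothing(self):
        d = _toy_design(noise=0.01)
        vp = variance_partition(d)
        assert vp.distance == pytest.approx(0.0, abs=0.02)
        assert vp.environment > 0.5

    def test_noise_response_explains_nothing(self):
        rng = np.random.default_rng(7)
        d = _toy_design()
        d.frame["response"] = rng.uniform(0, 1, len(d.frame))
        vp = variance_partition(d)
        assert vp.unexplained > 0.9
        assert vp.environment + vp.distance + vp.shared < 0.1

    def test_partition_on_simulated_community(self, niche_dataset):
        ds = niche_dataset
        d = combination_design(plot_incidence(ds), ds.metadata, 2,
                               SchemeConfig(scheme="ALL", sam=500, seed=2))
        vp = variance_partition(d)
        assert vp.as_series().sum() == pytest.approx(1.0, abs=1e-9)
        assert vp.environment > vp.distance  # turnover planted on a covariate
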