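"""Rasterization, CNN regressor, RBF baseline and error metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pigback as pb
from pigback.errors import ConfigError, DivergenceError, ParameterError
from pigback.weightnet import CNNConfig, CNNWeightRegressor, RBFWeightRegressor

from reference_tables import WEIGH_RESULTS


class TestRasterize:
    def test_single_point_occupies_one_cell_at_zero_height(self):
        raster = pb.rasterize_back(pb.PointCloud([[1, 2, 3]]), 8, 8)
        assert raster.counts.sum() == 1
        assert raster.heights.max() == 0  # height relative to itself

    def test_same_cell_mean_rule(self):
        cloud = pb.PointCloud([[0, 0, 0.0], [0.001, 0.001, 0.4],
                               [0.001, 0.0, 0.6], [1, 1, 0.0]])
        raster = pb.rasterize_back(cloud, 4, 4)
        assert raster.heights[0, 0] == pytest.approx((0 + 0.4 + 0.6) / 3)

    def test_occupancy_matches_brute_binning(self, rng):
        pts = rng.uniform(0, 1, (500, 3))
        H = W = 16
        raster = pb.rasterize_back(pb.PointCloud(pts), H, W)

        def bins(c, n):
            span = c.max() - c.min()
            return np.minimum(((c - c.min()) / span * n).astype(int), n - 1)

        ix, iy = bins(pts[:, 0], W), bins(pts[:, 1], H)
        brute = np.zeros((H, W), dtype=int)
        np.add.at(brute, (iy, ix), 1)
        np.testing.assert_array_equal(raster.counts, brute)

    def test_minimum_size(self):
        with pytest.raises(ParameterError):
            pb.rasterize_back(pb.PointCloud([[0, 0, 0]]), 2, 8)


class TestCnnForward:
    def test_zero_weights_give_zero_output(self, rng):
        cfg = CNNConfig(conv_filters=(2,), fc_widths=(4,), raster_hw=(8, 8))
        model = CNNWeightRegressor(cfg)
        model._init_params(6)
        params = {k: np.zeros_like(v) for k, v in model.params.items()}
        out = pb.cnn_forward(rng.random((8, 8)), rng.random(6), cfg, params)
        assert out == 0.0

    def test_hand_computed_tiny_forward_pass(self):
        # 1x1 conv (weight 2, bias 1), pool 1, beta 3, B 0.5, linear
        # activation, one FC layer of width 1 with unit weights
        cfg = CNNConfig(conv_filters=(1,), kernel_size=1, pool_size=1,
                        fc_widths=(1,), activation="linear", raster_hw=(3, 3))
        model = CNNWeightRegressor(cfg)
        model._init_params(1)
        raster = np.arange(9, dtype=float).reshape(3, 3)
        feat = np.array([0.5])
        P = model.params
        P["W0"][:] = 2.0
        P["b0"][:] = 1.0
        P["beta0"][:] = 3.0
        P["B0"][:] = 0.5
        P["FW0"][:] = 1.0
        P["Fb0"][:] = 0.0
        P["OW"][:] = 1.0
        P["Ob"][:] = 0.0
        # per cell: 3*(2x + 1) + 0.5; FC sums the 9 cells plus the feature
        expected = (3 * (2 * raster + 1) + 0.5).sum() + 0.5
        out = pb.cnn_forward(raster, feat, cfg, P)
        assert out == pytest.approx(expected, rel=1e-6)

    def test_beta_homogeneity_with_linear_activation(self, rng):
        cfg = CNNConfig(conv_filters=(1,), kernel_size=3, pool_size=2,
                        fc_widths=(2,), activation="linear", raster_hw=(8, 8))
        model = CNNWeightRegressor(cfg)
        model._init_params(2)
        for key in ("b0", "B0", "Fb0", "Ob"):
            model.params[key][:] = 0.0
        raster, feat = rng.random((8, 8)), np.zeros(2)
        out1 = pb.cnn_forward(raster, feat, cfg, model.params)
        model.params["beta0"] *= 2.0
        out2 = pb.cnn_forward(raster, feat, cfg, model.params)
        assert out2 == pytest.approx(2 * out1, rel=1e-5)


class TestCnnTraining:
    def test_constant_target_learned(self, rng):
        rasters = rng.random((16, 16, 16)).astype(np.float32) * 0.1
        feats = rng.random((16, 6))
        y = np.full(16, 250.0)
        cfg = CNNConfig(epochs=80, raster_hw=(16, 16))
        model = CNNWeightRegressor(cfg).fit(rasters, feats, y)
        np.testing.assert_allclose(model.predict(rasters, feats), 250.0,
                                   rtol=0.01)

    def test_linear_rule_recovered_features_only(self, rng):
        F = rng.uniform(0.5, 1.5, (100, 6))
        y = 300 * F[:, 0]
        cfg = CNNConfig(features_only=True, epochs=8000, learning_rate=0.1)
        model = CNNWeightRegressor(cfg).fit(F[:70], F[:70], y[:70])
        pred = model.predict(F[70:], F[70:])
        mape = np.mean(np.abs(pred - y[70:]) / y[70:]) * 100
        assert mape < 2.0
        assert model.loss_history_[-1] < model.loss_history_[0]

    def test_seeded_determinism(self, rng):
        rasters = rng.random((10, 16, 16)).astype(np.float32)
        feats = rng.random((10, 6))
        y = rng.uniform(200, 300, 10)
        cfg = CNNConfig(epochs=15, raster_hw=(16, 16), seed=5)
        m1 = CNNWeightRegressor(cfg).fit(rasters, feats, y)
        m2 = CNNWeightRegressor(cfg).fit(rasters, feats, y)
        assert m1.loss_history_ == m2.loss_history_
        cfg3 = CNNConfig(epochs=15, raster_hw=(16, 16), seed=6)
        m3 = CNNWeightRegressor(cfg3).fit(rasters, feats, y)
        assert m1.loss_history_ != m3.loss_history_

    def test_divergent_learning_rate_reported(self, rng):
        F = rng.uniform(0.5, 1.5, (20, 6))
        y = 300 * F[:, 0]
        cfg = CNNConfig(features_only=True, epochs=500, learning_rate=1e4)
        with pytest.raises(DivergenceError, match="learning rate"):
            CNNWeightRegressor(cfg).fit(F, F, y)

    def test_save_load_round_trip(self, tmp_path, rng):
        rasters = rng.random((8, 16, 16)).astype(np.float32)
        feats = rng.random((8, 6))
        y = rng.uniform(200, 300, 8)
        cfg = CNNConfig(epochs=5, raster_hw=(16, 16))
        model = CNNWeightRegressor(cfg).fit(rasters, feats, y)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = CNNWeightRegressor.load(path)
        np.testing.assert_allclose(loaded.predict(rasters, feats),
                                   model.predict(rasters, feats), rtol=1e-6)

    def test_unfitted_model_cannot_save_or_predict(self, tmp_path):
        model = CNNWeightRegressor(CNNConfig())
        with pytest.raises(ConfigError):
            model.save(tmp_path / "x.npz")
        with pytest.raises(ConfigError):
            model.predict(np.zeros((1, 64, 64)), np.zeros((1, 6)))

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            CNNWeightRegressor(CNNConfig(epochs=0))
        with pytest.raises(ConfigError):
            CNNWeightRegressor(CNNConfig(fc_widths=()))
        with pytest.raises(ConfigError):
            CNNWeightRegressor(CNNConfig(activation="tanh"))


class TestRbf:
    def test_sine_interpolation(self):
        x = np.linspace(0, 2 * np.pi, 50)[:, None]
        y = np.sin(x[:, 0])
        model = RBFWeightRegressor(n_centers=10, seed=0).fit(x, y)
        dense = np.linspace(0, 2 * np.pi, 300)[:, None]
        err = np.abs(model.predict(dense) - np.sin(dense[:, 0]))
        assert err.max() < 0.1

    def test_full_centers_interpolate_training_points(self, rng):
        X = rng.uniform(0, 1, (15, 3))
        y = rng.uniform(100, 300, 15)
        model = RBFWeightRegressor(n_centers=15, seed=1).fit(X, y)
        np.testing.assert_allclose(model.predict(X), y, atol=1e-3)

    def test_seeded_center_determinism(self, rng):
        X = rng.uniform(0, 1, (30, 4))
        y = rng.uniform(0, 1, 30)
        m1 = RBFWeightRegressor(8, seed=3).fit(X, y)
        m2 = RBFWeightRegressor(8, seed=3).fit(X, y)
        np.testing.assert_array_equal(m1.centers_, m2.centers_)

    def test_needs_enough_records(self):
        with pytest.raises(ParameterError):
            RBFWeightRegressor(10).fit(np.zeros((5, 2)), np.zeros(5))


class TestMetrics:
    def test_hand_computed_example(self):
        m = pb.evaluate([110, 190], [100, 200])
        assert m.mae == pytest.approx(10.0)
        assert m.mape == pytest.approx(7.5)
        assert m.rmse == pytest.approx(10.0)

    def test_perfect_predictions(self):
        m = pb.evaluate([100, 200], [100, 200])
        assert (m.mae, m.mape, m.rmse) == (0, 0, 0)

    def test_reference_test_set_mae(self):
        actual = [a for a, _ in WEIGH_RESULTS]
        est = [e for _, e in WEIGH_RESULTS]
        m = pb.evaluate(est, actual)
        assert m.mae == pytest.approx(10.845, abs=1e-3)

    def test_zero_actual_rejected(self):
        with pytest.raises(ParameterError):
            pb.evaluate([1.0], [0.0])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.floats(1, 500), st.floats(1, 500)),
                    min_size=1, max_size=30))
    def test_rmse_at_least_mae(self, pairs):
        est = [p for p, _ in pairs]
        act = [r for _, r in pairs]
        m = pb.evaluate(est, act)
        assert m.rmse >= m.mae - 1e-9
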