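"""Density regressor: losses, gradients, Monte Carlo dropout, training."""

import numpy as np
import pytest

from probcell import AnnotationSet, render_density_map
from probcell.nn import (
    DensityRegressor,
    RegressorConfig,
    aleatoric_loss,
    l2_loss,
    predict,
    train_regressor,
    load_model,
    save_model,
)
from probcell.nn.unet import _loss_and_grad


class TestLosses:
    def test_l2_zero_for_identical(self, rng):
        y = rng.random((5, 5, 5))
        assert l2_loss(y, y) == 0.0

    def test_l2_single_unit_residual(self):
        assert l2_loss(np.array([1.0, 0, 0]), np.zeros(3)) == 1.0

    def test_l2_matches_loop_oracle(self, rng):
        y, y_hat = rng.random((6, 6, 6)), rng.random((6, 6, 6))
        oracle = 0.0
        for a in range(6):
            for b in range(6):
                for c in range(6):
                    oracle += (y[a, b, c] - y_hat[a, b, c]) ** 2
        assert l2_loss(y, y_hat) == pytest.approx(oracle, rel=1e-10)

    def test_l2_shape_mismatch(self):
        with pytest.raises(ValueError):
            l2_loss(np.zeros(3), np.zeros(4))

    def test_aleatoric_reduces_to_l2_at_unit_variance(self, rng):
        y, y_hat = rng.random((4, 4, 4)), rng.random((4, 4, 4))
        u = np.ones_like(y)
        assert aleatoric_loss(y, y_hat, u) == pytest.approx(l2_loss(y, y_hat))

    def test_aleatoric_hand_value(self):
        # one voxel, residual 1, variance 2
        got = aleatoric_loss(np.array([1.0]), np.array([0.0]), np.array([2.0]))
        assert got == pytest.approx(0.5 + 0.5 * np.log(2), rel=1e-12)

    def test_aleatoric_minimizer_is_twice_squared_residual(self):
        # dense grid search over u at fixed residual r: argmin = 2 r^2
        for r in (0.3, 1.0, 2.5):
            grid = np.linspace(1e-3, 20, 40000)
            losses = r ** 2 / grid + 0.5 * np.log(grid)
            u_star = grid[np.argmin(losses)]
            assert u_star == pytest.approx(2 * r ** 2, rel=2e-3)
            got = aleatoric_loss(
                np.array([r]), np.array([0.0]), np.array([2 * r ** 2])
            )
            assert got <= losses.min() + 1e-6

    def test_aleatoric_clamps_with_warning(self):
        with pytest.warns(UserWarning):
            v = aleatoric_loss(np.array([1.0]), np.array([0.0]), np.array([0.0]))
        assert np.isfinite(v)


class TestBackprop:
    def test_gradients_match_finite_differences(self):
        for bayes in (False, True):
            cfg = RegressorConfig(
                base_channels=2, bayes=bayes, dropout_rate=0.0, conv_margin=2, seed=3
            )
            m = DensityRegressor(cfg)
            m.params = {k: v.astype(np.float64) for k, v in m.params.items()}
            rng = np.random.default_rng(0)
            x = 0.1 * rng.normal(size=(8, 8, 8))
            y = 0.1 * rng.random((4, 4, 4))
            _, cache, dout = _loss_and_grad(m, x, y, None)
            grads = m.backward(dout, cache)
            for name, g in grads.items():
                p = m.params[name]
                idx = tuple(np.unravel_index(np.argmax(np.abs(g)), g.shape))
                eps, orig = 1e-6, p[idx]
                p[idx] = orig + eps
                lp, _, _ = _loss_and_grad(m, x, y, None)
                p[idx] = orig - eps
                lm, _, _ = _loss_and_grad(m, x, y, None)
                p[idx] = orig
                fd = (lp - lm) / (2 * eps)
                assert g[idx] == pytest.approx(fd, rel=1e-5), name


class TestPredict:
    @pytest.fixture(scope="class")
    def tiny_model(self):
        return DensityRegressor(
            RegressorConfig(base_channels=2, bayes=True, conv_margin=4, seed=7)
        )

    def test_output_shape_is_input_minus_margin(self, tiny_model):
        dm, unc = predict(tiny_model, np.zeros((24, 24, 24), np.float32))
        assert dm.values.shape == (16, 16, 16)
        assert unc.aleatoric.shape == (16, 16, 16)

    def test_deterministic_pass_zero_epistemic(self, tiny_model, rng):
        x = rng.normal(size=(16, 16, 16)).astype(np.float32)
        _, unc = predict(tiny_model, x, mc=False)
        assert (unc.epistemic == 0).all()

    def test_zero_dropout_rate_zero_epistemic(self, rng):
        m = DensityRegressor(
            RegressorConfig(base_channels=2, bayes=True, dropout_rate=0.0,
                            conv_margin=4, seed=7)
        )
        x = rng.normal(size=(16, 16, 16)).astype(np.float32)
        _, unc = predict(m, x, mc=True, mc_samples=4, seed=0)
        assert np.allclose(unc.epistemic, 0)

    def test_seeded_mc_is_bit_identical(self, tiny_model, rng):
        x = rng.normal(size=(16, 16, 16)).astype(np.float32)
        a = predict(tiny_model, x, mc=True, mc_samples=6, seed=42)
        b = predict(tiny_model, x, mc=True, mc_samples=6, seed=42)
        np.testing.assert_array_equal(a[0].values, b[0].values)
        np.testing.assert_array_equal(a[1].aleatoric, b[1].aleatoric)
        np.testing.assert_array_equal(a[1].epistemic, b[1].epistemic)

    def test_aleatoric_nonnegative(self, tiny_model, rng):
        x = rng.normal(size=(16, 16, 16)).astype(np.float32)
        _, unc = predict(tiny_model, x, mc=True, mc_samples=4, seed=1)
        assert (unc.aleatoric >= 0).all()

    def test_mc_requires_two_samples(self, tiny_model):
        with pytest.raises(ValueError):
            predict(tiny_model, np.zeros((16, 16, 16)), mc=True, mc_samples=1)

    def test_epistemic_converges_with_sample_count(self, tiny_model, rng):
        # SD of the u_e estimate across independent runs shrinks with n
        x = rng.normal(size=(16, 16, 16)).astype(np.float32)
        def spread(n, seeds):
            maps = [predict(tiny_model, x, mc=True, mc_samples=n, seed=s)[1].epistemic
                    for s in seeds]
            return np.std(np.stack(maps), axis=0).mean()
        few = spread(4, (1, 2, 3, 4))
        many = spread(32, (1, 2, 3, 4))
        assert many < few


class TestTraining:
    def test_overfits_single_patch(self):
        rng = np.random.default_rng(5)
        ann = AnnotationSet(np.array([[8.2, 9.5, 8.1], [4.0, 12.3, 11.2],
                                      [12.8, 4.1, 5.4]]), (16, 16, 16))
        dm = render_density_map(ann, 4.0, "K_max")
        x = (dm.values * 3.0 + rng.normal(0, 0.05, dm.shape)).astype(np.float32)
        y = dm.values[4:12, 4:12, 4:12]
        cfg = RegressorConfig(base_channels=4, bayes=False, dropout_rate=0.0,
                              epochs=400, seed=0, learning_rate=3e-3,
                              conv_margin=4)
        model, log = train_regressor(cfg, [(x, y)])
        assert log[-1]["loss"] < 0.01 * log[0]["loss"]

    def test_bayes_loss_decreases_smoothed(self):
        rng = np.random.default_rng(6)
        ann = AnnotationSet(np.array([[8.0, 10.5, 9.1], [12.0, 4.3, 10.2]]),
                            (16, 16, 16))
        dm = render_density_map(ann, 4.0, "K_max")
        x = (dm.values + rng.normal(0, 0.05, dm.shape)).astype(np.float32)
        y = dm.values[4:12, 4:12, 4:12]
        cfg = RegressorConfig(base_channels=4, bayes=True, dropout_rate=0.0,
                              epochs=120, seed=0, learning_rate=3e-3,
                              conv_margin=4)
        model, log = train_regressor(cfg, [(x, y)])
        losses = np.array([e["loss"] for e in log])
        smooth = np.convolve(losses, np.ones(10) / 10, mode="valid")
        assert smooth[-1] < smooth[0]

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_regressor(RegressorConfig(), [])

    def test_aleatoric_map_tracks_spatially_varying_noise(self):
        """With depth-varying synthetic noise (0.5x..1.5x along axis 0), the
        trained variance head predicts larger u_a where the noise is larger."""
        from probcell import SynthConfig, render_density_map, sample_coordinates
        from probcell.pipeline import training_patches
        from probcell.synthetic import render_volume
        from probcell.tiling import normalize_and_resample

        cfg = SynthConfig(shape=(48, 48, 48), n_cells=15, noise_sd=0.3,
                          noise_spatial=True, n_tubes=0, seed=31)
        ann = sample_coordinates(cfg)
        vol = render_volume(ann, cfg)
        dm = render_density_map(ann, 4.0, "K_max")
        rng = np.random.default_rng(0)
        norm = normalize_and_resample(vol, (1, 1, 1), (8, 8, 8))
        pairs = training_patches(norm, dm.values, 8, 32, 10, rng)
        rcfg = RegressorConfig(base_channels=4, bayes=True, epochs=40,
                               warmup_epochs=10, seed=0)
        model, _ = train_regressor(rcfg, pairs)
        held_out = SynthConfig(**{**vars(cfg), "seed": 32})
        ann2 = sample_coordinates(held_out)
        vol2 = render_volume(ann2, held_out)
        norm2 = normalize_and_resample(vol2, (1, 1, 1), (12, 12, 12))
        _, unc = predict(model, norm2, mc=False)
        third = unc.aleatoric.shape[0] // 3
        assert unc.aleatoric[-third:].mean() > unc.aleatoric[:third].mean()


def test_model_save_load_roundtrip(tmp_path, rng):
    m = DensityRegressor(RegressorConfig(base_channels=2, bayes=True, conv_margin=4,
                                         seed=11))
    save_model(m, tmp_path / "model.npz")
    back = load_model(tmp_path / "model.npz")
    x = rng.normal(size=(16, 16, 16)).astype(np.float32)
    np.testing.assert_array_equal(m.output(x)[0], back.output(x)[0])
    assert back.config.bayes
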