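"""Architecture contracts, receptive field, composite loss, gradients, checkpoints."""

import numpy as np
import pytest

import atacdenoise.nn as nn_mod
from atacdenoise import (
    LossWeights,
    ModelConfig,
    build_model,
    composite_loss,
    load_model,
    receptive_field,
)
from atacdenoise.model import composite_loss_grad
from atacdenoise.nn import Conv1d, ResidualBlock

TINY = ModelConfig(
    in_channels=1, filters=4, kernel=9, dilation=2,
    n_blocks_regression=1, n_blocks_classification=1, seed=3,
)


@pytest.fixture
def float64_nn(monkeypatch):
    """Run the network in float64 so finite differences are meaningful."""
    monkeypatch.setattr(nn_mod, "DTYPE", np.float64)


class TestReceptiveField:
    def test_single_layer_kernel_one(self):
        cfg = ModelConfig(filters=1, kernel=1, dilation=1,
                          n_blocks_regression=1, n_blocks_classification=1)
        # one block = 3 layers of kernel 1: field stays 1
        assert receptive_field(cfg) == 1

    def test_scaling_with_kernel_and_dilation(self):
        # 3 layers of kernel 51 dilation 8 -> 1 + 3*50*8
        cfg = ModelConfig(n_blocks_regression=1)
        assert receptive_field(cfg) == 1 + 3 * 50 * 8

    def test_default_regression_stage_is_six_kb(self):
        """15 stacked dilated convolutions (kernel 51, dilation 8) see 6001 bp."""
        assert receptive_field(ModelConfig()) == 6001

    def test_classification_stage_reported_separately(self):
        assert receptive_field(ModelConfig(), "classification") == 1 + 6 * 50 * 8


class TestForwardContract:
    def test_output_shapes_and_ranges(self):
        model = build_model(TINY)
        x = np.random.default_rng(0).random((3, 1, 256)).astype(np.float32)
        sig, prob = model.forward(x)
        assert sig.shape == (3, 256) and prob.shape == (3, 256)
        assert np.all(sig >= 0)  # ReLU regression output
        assert np.all((prob > 0) & (prob < 1))

    def test_seed_determinism(self):
        x = np.random.default_rng(1).random((2, 1, 128)).astype(np.float32)
        s1, p1 = build_model(TINY).forward(x)
        s2, p2 = build_model(TINY).forward(x)
        assert np.array_equal(s1, s2) and np.array_equal(p1, p2)

    def test_translation_covariance_interior(self):
        """Shifting the input shifts both outputs over the unaffected interior."""
        model = build_model(TINY)
        rng = np.random.default_rng(2)
        x = rng.random((1, 1, 400)).astype(np.float32)
        shift = 16
        xs = np.roll(x, -shift, axis=2)
        s, p = model.forward(x)
        ss, ps = model.forward(xs)
        # interior: away from both windows' boundary effects
        half = (receptive_field(TINY) - 1) // 2 + (
            receptive_field(TINY, "classification") - 1
        ) // 2
        lo, hi = half + shift, 400 - half - shift
        assert np.allclose(s[0, lo:hi], ss[0, lo - shift : hi - shift], atol=1e-5)
        assert np.allclose(p[0, lo:hi], ps[0, lo - shift : hi - shift], atol=1e-5)

    def test_invalid_hyperparameters(self):
        with pytest.raises(ValueError):
            ModelConfig(kernel=50)
        with pytest.raises(ValueError):
            ModelConfig(filters=0)


class TestCheckpoint:
    def test_save_load_bit_identical_forward(self, tmp_path):
        model = build_model(TINY)
        x = np.random.default_rng(5).random((2, 1, 200)).astype(np.float32)
        s1, p1 = model.forward(x)
        path = tmp_path / "model.ckpt"
        model.save(path)
        reloaded = load_model(path)
        s2, p2 = reloaded.forward(x)
        assert np.array_equal(s1, s2) and np.array_equal(p1, p2)
        assert reloaded.config == TINY

    def test_magic_header_rejects_foreign_files(self, tmp_path):
        path = tmp_path / "not_a_model.npz"
        with open(path, "wb") as fh:
            np.savez(fh, header=np.frombuffer(b'{"magic": "nope"}', dtype=np.uint8))
        with pytest.raises(ValueError, match="not an atacdenoise checkpoint"):
            load_model(path)


class TestCompositeLoss:
    def test_perfect_prediction(self):
        rng = np.random.default_rng(0)
        ts = rng.random(100)
        tl = (rng.random(100) < 0.4).astype(float)
        probs = np.where(tl == 1, 1.0 - 1e-7, 1e-7)
        total, mse, pl, bce = composite_loss(ts, probs, ts, tl)
        assert mse == 0 and pl == pytest.approx(0, abs=1e-8)
        assert bce == pytest.approx(0, abs=1e-5)

    def test_anticorrelated_pearson_loss_is_two(self):
        ts = np.arange(50, dtype=float)
        _, _, pl, _ = composite_loss(-ts, np.full(50, 0.5), ts, np.zeros(50))
        assert pl == pytest.approx(2.0, rel=1e-9)

    def test_constant_vector_defines_r_zero(self):
        ts = np.arange(50, dtype=float)
        _, _, pl, _ = composite_loss(np.zeros(50), np.full(50, 0.5), ts, np.zeros(50))
        assert pl == pytest.approx(1.0)

    def test_matches_direct_formulas(self):
        """All three components agree with an independent textbook evaluation."""
        rng = np.random.default_rng(12)
        for _ in range(50):
            ps, ts = rng.normal(size=(2, 100))
            pp = rng.uniform(0.01, 0.99, size=100)
            tl = (rng.random(100) < 0.5).astype(float)
            w = LossWeights(0.7, 1.3, 2.0)
            total, mse, pl, bce = composite_loss(ps, pp, ts, tl, w)
            mse_ref = np.mean((ps - ts) ** 2)
            r_ref = np.corrcoef(ps, ts)[0, 1]
            bce_ref = -np.mean(tl * np.log(pp) + (1 - tl) * np.log(1 - pp))
            assert mse == pytest.approx(mse_ref, rel=1e-9)
            assert pl == pytest.approx(1 - r_ref, rel=1e-6)
            assert bce == pytest.approx(bce_ref, rel=1e-9)
            assert total == pytest.approx(
                0.7 * mse_ref + 1.3 * (1 - r_ref) + 2.0 * bce_ref, rel=1e-6
            )

    def test_nonnegative_with_nonnegative_weights(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            total, *_ = composite_loss(
                rng.normal(size=64), rng.uniform(0.01, 0.99, 64),
                rng.normal(size=64), (rng.random(64) < 0.3).astype(float),
            )
            assert total >= 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            composite_loss(np.zeros(5), np.full(6, 0.5), np.zeros(5), np.zeros(5))

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(0, 0, 0)


class TestGradients:
    """Finite-difference validation of the hand-written backward passes."""

    def test_conv_gradients_exhaustive(self, float64_nn):
        rng = np.random.default_rng(0)
        conv = Conv1d(2, 3, 5, dilation=2, rng=rng)
        x = rng.random((2, 2, 30))
        t = rng.random((2, 3, 30))

        def loss():
            return float(((conv.forward(x) - t) ** 2).sum())

        for p in conv.params():
            p["grad"][...] = 0
        y = conv.forward(x, train=True)
        dx = conv.backward(2 * (y - t))
        eps = 1e-6
        for prm in conv.params():
            V, G = prm["value"], prm["grad"]
            it = np.nditer(V, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                old = V[idx]
                V[idx] = old + eps
                lp = loss()
                V[idx] = old - eps
                lm = loss()
                V[idx] = old
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(G[idx], rel=1e-5, abs=1e-7)
        # input gradient at sampled coordinates
        for _ in range(20):
            idx = tuple(rng.integers(0, d) for d in x.shape)
            old = x[idx]
            x[idx] = old + eps
            lp = loss()
            x[idx] = old - eps
            lm = loss()
            x[idx] = old
            assert (lp - lm) / (2 * eps) == pytest.approx(dx[idx], rel=1e-5, abs=1e-7)

    @pytest.mark.parametrize("in_ch", [3, 2])
    def test_residual_block_gradients(self, float64_nn, in_ch):
        """Identity skip (in_ch == channels) and projection skip both backprop."""
        rng = np.random.default_rng(1)
        block = ResidualBlock(in_ch, 3, 5, 2, rng)
        x = rng.random((1, in_ch, 20))
        t = rng.random((1, 3, 20))

        def loss():
            return float(((block.forward(x) - t) ** 2).sum())

        for p in block.params():
            p["grad"][...] = 0
        y = block.forward(x, train=True)
        block.backward(2 * (y - t))
        eps = 1e-6
        for prm in block.params():
            V, G = prm["value"], prm["grad"]
            it = np.nditer(V, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                old = V[idx]
                V[idx] = old + eps
                lp = loss()
                V[idx] = old - eps
                lm = loss()
                V[idx] = old
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(G[idx], rel=1e-4, abs=1e-7)

    def test_full_model_gradients_smooth_regime(self, float64_nn):
        """End-to-end backprop check with all ReLU units active (kinks removed):
        weights made positive and biases lifted so every pre-activation is
        strictly positive, making the network locally smooth."""
        rng = np.random.default_rng(2)
        cfg = ModelConfig(in_channels=2, filters=3, kernel=5, dilation=2,
                          n_blocks_regression=2, n_blocks_classification=1, seed=9)
        model = build_model(cfg)
        for prm in model.params():
            v = prm["value"]
            v[...] = np.abs(v) * 0.2 + 0.05
        x = rng.random((2, 2, 25)) + 0.5
        ts = rng.random((2, 25)) * 2
        tl = (rng.random((2, 25)) < 0.3).astype(float)
        w = LossWeights(1.0, 1.0, 1.0)

        def loss():
            s, p = model.forward(x)
            return composite_loss(s, p, ts, tl, w)[0]

        for prm in model.params():
            prm["grad"][...] = 0
        s, p = model.forward(x, train=True)
        assert np.all(s > 0), "smooth-regime precondition"
        ds, dp = composite_loss_grad(s, p, ts, tl, w)
        model.backward(ds, dp)
        eps = 1e-6
        rng_idx = np.random.default_rng(3)
        for prm in model.params():
            V, G = prm["value"], prm["grad"]
            for _ in range(min(6, V.size)):
                idx = tuple(rng_idx.integers(0, d) for d in V.shape)
                old = V[idx]
                V[idx] = old + eps
                lp = loss()
                V[idx] = old - eps
                lm = loss()
                V[idx] = old
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(G[idx], rel=1e-4, abs=1e-8)

    def test_loss_grad_matches_numeric(self):
        rng = np.random.default_rng(4)
        ps = rng.random(40) * 3 + 0.1
        pp = rng.uniform(0.05, 0.95, 40)
        ts = rng.random(40) * 3
        tl = (rng.random(40) < 0.4).astype(float)
        w = LossWeights(0.5, 1.5, 0.8)
        ds, dp = composite_loss_grad(ps, pp, ts, tl, w)
        eps = 1e-7
        for i in range(0, 40, 7):
            for vec, grad in ((ps, ds), (pp, dp)):
                old = vec[i]
                vec[i] = old + eps
                lp = composite_loss(ps, pp, ts, tl, w)[0]
                vec[i] = old - eps
                lm = composite_loss(ps, pp, ts, tl, w)[0]
                vec[i] = old
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(grad[0, i], rel=1e-4, abs=1e-10)
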