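import numpy as np
import pytest

from hyenaselect import (
    GenomeSequence,
    HyenaConfig,
    HyenaModel,
    embed_window,
    embed_windows,
    evaluate_xent,
    fft_causal_conv,
    forward_lm,
    hyena_operator,
    implicit_filter,
    positional_features,
    segment_all,
    train_lm,
)
from hyenaselect.hyena_lm import init_block_params
from hyenaselect.windowing import Mode, Window
from tests.conftest import make_windows


def toeplitz_conv(u, h):
    """Brute-force oracle: per-channel lower-triangular Toeplitz multiply."""
    L, D = u.shape
    out = np.zeros_like(u)
    for c in range(D):
        T = np.zeros((L, L))
        for i in range(L):
            for j in range(i + 1):
                T[i, j] = h[i - j, c]
        out[:, c] = T @ u[:, c]
    return out


class TestPositionalFeatures:
    def test_single_row_boundary(self):
        feats = positional_features(1, 5)
        assert feats.shape == (1, 5)
        assert feats[0, 0] == 0.0

    def test_purely_functional(self):
        a = positional_features(16, 9)
        b = positional_features(16, 9)
        np.testing.assert_array_equal(a, b)

    def test_fixed_scale_gives_absolute_rows(self):
        a = positional_features(8, 9, scale=64)
        b = positional_features(16, 9, scale=64)
        np.testing.assert_array_equal(a, b[:8])


class TestImplicitFilter:
    def test_extension_property(self, tiny_config, rng):
        params = init_block_params(tiny_config, rng)
        h8 = implicit_filter(params, 8, tiny_config)
        h16 = implicit_filter(params, 16, tiny_config)
        np.testing.assert_allclose(h8, h16[:8], rtol=0, atol=0)

    def test_large_decay_kills_tail(self, tiny_config, rng):
        params = init_block_params(tiny_config, rng)
        params["decay_raw"].data[:] = 1e4
        h = implicit_filter(params, tiny_config.l_in, tiny_config)
        assert np.abs(h[-1]).max() < 1e-12
        assert np.abs(h[0]).max() > 0

    def test_parameter_count_independent_of_length(self):
        cfg_a = HyenaConfig(l_in=512, d_model=16, n_layer=2)
        cfg_b = HyenaConfig(l_in=4096, d_model=16, n_layer=2)
        assert HyenaModel(cfg_a).parameter_count() == HyenaModel(cfg_b).parameter_count()


class TestFftCausalConv:
    def test_identity_filter(self, rng):
        u = rng.normal(size=(16, 4))
        h = np.zeros((16, 4))
        h[0] = 1.0
        np.testing.assert_allclose(fft_causal_conv(u, h), u, atol=1e-12)

    def test_shift_filter(self, rng):
        u = rng.normal(size=(16, 4))
        h = np.zeros((16, 4))
        h[1] = 1.0
        y = fft_causal_conv(u, h)
        np.testing.assert_allclose(y[1:], u[:-1], atol=1e-12)
        np.testing.assert_allclose(y[0], 0.0, atol=1e-12)

    def test_matches_toeplitz_oracle(self, rng):
        u = rng.normal(size=(64, 3))
        h = rng.normal(size=(64, 3))
        ref = toeplitz_conv(u, h)
        y = fft_causal_conv(u, h)
        rel = np.abs(y - ref).max() / np.abs(ref).max()
        assert rel < 1e-8

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            fft_causal_conv(rng.normal(size=(8, 3)), rng.normal(size=(9, 3)))


def explicit_params(config, rng):
    """Block params wired so x1 = v = u (identity) and x2 = 1, h = impulse."""
    p = init_block_params(config, rng)
    d = config.d_model
    eye = np.eye(d)
    ident_kernel = np.zeros((config.short_conv_width, d))
    ident_kernel[0] = 1.0
    for w, b, k, val in [("wx1", "bx1", "kx1", eye), ("wv", "bv", "kv", eye)]:
        p[w].data = val.copy()
        p[b].data[:] = 0.0
        p[k].data = ident_kernel.copy()
    p["wx2"].data[:] = 0.0
    p["bx2"].data[:] = 1.0
    p["kx2"].data = ident_kernel.copy()
    # filter MLP -> constant 1, huge decay -> lag-0 impulse
    p["fm_w2"].data[:] = 0.0
    p["fm_b2"].data[:] = 1.0
    p["decay_raw"].data[:] = 1e4
    return p


class TestHyenaOperator:
    def test_zero_gate_annihilates(self, tiny_config, rng):
        p = init_block_params(tiny_config, rng)
        p["wx1"].data[:] = 0.0
        p["bx1"].data[:] = 0.0
        u = rng.normal(size=(tiny_config.l_in, tiny_config.d_model))
        np.testing.assert_allclose(hyena_operator(u, p, tiny_config), 0.0, atol=1e-12)

    def test_gating_identity_with_impulse_filter(self, tiny_config, rng):
        p = explicit_params(tiny_config, rng)
        u = rng.normal(size=(tiny_config.l_in, tiny_config.d_model))
        # x2 == 1 and h == lag-0 impulse  =>  output == x1 * v == u * u
        np.testing.assert_allclose(hyena_operator(u, p, tiny_config), u * u, atol=1e-9)

    def test_causality_of_operator(self, tiny_config, rng):
        p = init_block_params(tiny_config, rng)
        u = rng.normal(size=(tiny_config.l_in, tiny_config.d_model))
        v = u.copy()
        t = 10
        v[t + 1 :] += rng.normal(size=v[t + 1 :].shape)
        a = hyena_operator(u, p, tiny_config)
        b = hyena_operator(v, p, tiny_config)
        np.testing.assert_allclose(a[: t + 1], b[: t + 1], atol=1e-10)


class TestForwardLm:
    def test_end_to_end_causality(self, tiny_model, rng):
        L = tiny_model.config.l_in
        ids = rng.integers(0, 4, L)
        ids2 = ids.copy()
        t = 12
        ids2[t + 1 :] = (ids2[t + 1 :] + 1) % 4
        la = tiny_model.forward_logits(ids).data[0]
        lb = tiny_model.forward_logits(ids2).data[0]
        np.testing.assert_allclose(la[: t + 1], lb[: t + 1], atol=1e-10)
        assert np.abs(la[t + 1 :] - lb[t + 1 :]).max() > 1e-8

    def test_deterministic_eval(self, tiny_model, periodic_windows):
        a = forward_lm(tiny_model, periodic_windows[0])
        b = forward_lm(tiny_model, periodic_windows[0])
        np.testing.assert_array_equal(a, b)
        assert a.shape == (tiny_model.config.l_in, tiny_model.config.vocab_size)

    def test_all_pad_input_finite(self, tiny_model):
        L = tiny_model.config.l_in
        w = Window("s", "c", 0, 0, np.full(L, 4, np.uint8), np.zeros(L, bool),
                   Mode.ALL_SEQUENCE)
        assert np.isfinite(forward_lm(tiny_model, w)).all()

    def test_too_long_window_rejected(self, tiny_model, rng):
        ids = rng.integers(0, 4, tiny_model.config.l_in + 1)
        with pytest.raises(ValueError, match="exceeds"):
            tiny_model.forward_logits(ids)


class TestTraining:
    def test_empty_corpus_rejected(self, tiny_config):
        with pytest.raises(ValueError, match="empty"):
            train_lm([], tiny_config)

    def test_loss_decreases_on_learnable_corpus(self, tiny_config, periodic_windows):
        model = train_lm(periodic_windows, tiny_config)
        log = [e["train_loss"] for e in model.training_log]
        assert len(log) == tiny_config.max_epochs
        assert log[-1] < log[0]

    def test_fixed_seed_reproducible(self, tiny_config, periodic_windows):
        m1 = train_lm(periodic_windows, tiny_config)
        m2 = train_lm(periodic_windows, tiny_config)
        for (_, a), (_, b) in zip(m1.named_parameters(), m2.named_parameters()):
            np.testing.assert_array_equal(a.data, b.data)

    def test_special_token_targets_excluded(self, tiny_config):
        # corpus whose only targets are PAD: training must refuse
        L = tiny_config.l_in
        ids = np.full(L, 4, np.uint8)
        ids[0] = 0
        w = Window("s", "c", 0, 1, ids, np.arange(L) < 1, Mode.ALL_SEQUENCE)
        with pytest.raises(ValueError, match="targets"):
            train_lm([w], tiny_config)


class TestEmbedding:
    def test_shape_and_determinism(self, tiny_model, periodic_windows):
        v1 = embed_window(tiny_model, periodic_windows[0])
        v2 = embed_window(tiny_model, periodic_windows[0])
        assert v1.shape == (tiny_model.config.d_model,)
        np.testing.assert_array_equal(v1, v2)

    def test_masked_pooling_ignores_trailing_pads(self, tiny_model):
        """Same real bases with longer padding give the identical vector."""
        short = make_windows("ACGTACGT", 8)[0]
        padded = make_windows("ACGTACGT", 16)[0]
        a = embed_window(tiny_model, short)
        b = embed_window(tiny_model, padded)
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_all_pad_window_rejected(self, tiny_model):
        L = tiny_model.config.l_in
        w = Window("s", "c", 0, 0, np.full(L, 4, np.uint8), np.zeros(L, bool),
                   Mode.ALL_SEQUENCE)
        with pytest.raises(ValueError, match="padding"):
            embed_window(tiny_model, w)

    def test_batched_equals_single(self, tiny_model, periodic_windows):
        batch = embed_windows(tiny_model, periodic_windows[:4], batch_size=2)
        singles = np.stack([embed_window(tiny_model, w) for w in periodic_windows[:4]])
        np.testing.assert_allclose(batch, singles, atol=1e-12)


class TestCheckpoint:
    def test_round_trip_bit_exact(self, tiny_config, periodic_windows, tmp_path):
        model = train_lm(periodic_windows[:4], tiny_config)
        path = tmp_path / "ckpt.npz"
        model.save(path)
        back = HyenaModel.load(path)
        for (na, a), (nb, b) in zip(model.named_parameters(), back.named_parameters()):
            assert na == nb
            np.testing.assert_array_equal(a.data, b.data)
        assert back.training_log == model.training_log
        assert back.config == model.config

    def test_loaded_model_same_xent(self, tiny_config, periodic_windows, tmp_path):
        model = train_lm(periodic_windows[:4], tiny_config)
        path = tmp_path / "ckpt.npz"
        model.save(path)
        back = HyenaModel.load(path)
        assert evaluate_xent(model, periodic_windows[4:6]) == evaluate_xent(
            back, periodic_windows[4:6]
        )
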