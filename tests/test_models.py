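"""Classifier mechanics: windowing, forward/backward, training harness."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from capnea.models import (
    Adam,
    BiLSTM,
    BiLSTMConfig,
    MixerConfig,
    MLPMixer,
    TrainConfig,
    bce_loss,
    load_weights,
    make_model,
    predict_night,
    save_weights,
    train_model,
    window_recording,
    window_starts,
)


def _tiny_mixer(**kw):
    defaults = dict(n_patches=8, n_channels=3, hidden_dim=6, n_blocks=2,
                    dropout=0.0, seed=1)
    defaults.update(kw)
    return MLPMixer(MixerConfig(**defaults))


def _tiny_bilstm(**kw):
    defaults = dict(n_channels=3, hidden_dim=5, n_layers=2, seed=2)
    defaults.update(kw)
    return BiLSTM(BiLSTMConfig(**defaults))


class TestWindowing:
    def test_exact_multiple(self):
        assert window_starts(1500, 500, 500) == [0, 500, 1000]

    def test_end_anchored_remainder(self):
        assert window_starts(1400, 500, 500) == [0, 500, 900]

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="shorter than one window"):
            window_starts(400, 500)

    @given(st.integers(500, 5000), st.integers(100, 500))
    def test_every_sample_covered(self, n, stride):
        covered = np.zeros(n, dtype=bool)
        for s in window_starts(n, 500, stride):
            covered[s:s + 500] = True
        assert covered.all()

    def test_window_recording_shapes(self, rng):
        feats = rng.normal(size=(1234, 4))
        labs = rng.integers(0, 2, size=1234).astype(float)
        starts, X, Y = window_recording(feats, labs, window=500, stride=500)
        assert X.shape == (len(starts), 500, 4)
        assert Y.shape == (len(starts), 500)


class TestForward:
    @pytest.mark.parametrize("factory", [_tiny_mixer, _tiny_bilstm])
    def test_probabilities_shape_and_range(self, factory, rng):
        model = factory()
        X = rng.normal(size=(3, 8, 3))
        p, _ = model.forward(X)
        assert p.shape == (3, 8)
        assert np.all((p > 0) & (p < 1))

    def test_500_patches_yield_500_probabilities(self, rng):
        model = MLPMixer(MixerConfig(n_patches=500, n_channels=4, hidden_dim=8,
                                     n_blocks=1, seed=0))
        p, _ = model.forward(rng.normal(size=(1, 500, 4)))
        assert p.shape == (1, 500)

    @pytest.mark.parametrize("factory", [_tiny_mixer, _tiny_bilstm])
    def test_eval_mode_deterministic(self, factory, rng):
        model = factory()
        X = rng.normal(size=(2, 8, 3))
        p1, _ = model.forward(X, train=False)
        p2, _ = model.forward(X, train=False)
        np.testing.assert_array_equal(p1, p2)

    @pytest.mark.parametrize("factory", [_tiny_mixer, _tiny_bilstm])
    def test_dimension_mismatch_rejected(self, factory, rng):
        with pytest.raises(ValueError, match="expected input"):
            factory().forward(rng.normal(size=(2, 8, 7)))


class TestGradients:
    """Backprop validated against central finite differences."""

    @pytest.mark.parametrize("factory", [_tiny_mixer, _tiny_bilstm])
    def test_matches_finite_differences(self, factory, rng):
        model = factory()
        X = rng.normal(size=(2, 8, 3))
        y = rng.integers(0, 2, size=(2, 8)).astype(float)
        p, cache = model.forward(X)
        grads = model.backward(cache, (p - y) / p.size)

        def loss():
            q, _ = model.forward(X)
            return bce_loss(q, y)

        for name, w in model.params.items():
            for _ in range(4):
                idx = tuple(rng.integers(0, s) for s in w.shape)
                old = w[idx]
                eps = 1e-6
                w[idx] = old + eps
                lp = loss()
                w[idx] = old - eps
                lm = loss()
                w[idx] = old
                num = (lp - lm) / (2 * eps)
                assert grads[name][idx] == pytest.approx(num, abs=1e-7, rel=1e-4)


def test_bilstm_palindrome_symmetry(rng):
    """With one layer, tied direction weights and a symmetric head, a
    palindromic window must produce a palindromic probability sequence — a
    numerical check that the two directions run over the same time axis.
    (With stacked layers the concatenated halves swap under reversal, so
    the symmetry holds only for the single tied layer.)"""
    model = _tiny_bilstm(n_layers=1)
    H = model.config.hidden_dim
    for l in range(model.config.n_layers):
        for nm in ("W", "U", "b"):
            model.params[f"{nm}b{l}"] = model.params[f"{nm}f{l}"].copy()
    model.params["w_out"][H:] = model.params["w_out"][:H]
    half = rng.normal(size=(1, 5, 3))
    X = np.concatenate([half, half[:, ::-1]], axis=1)  # palindrome, T=10
    p, _ = model.forward(X)
    np.testing.assert_allclose(p[0], p[0][::-1], atol=1e-10)


def _separable_datasets(n_rec=4, n=600, rng_seed=0):
    """Synthetic features where the gap channel alone determines the label."""
    rng = np.random.default_rng(rng_seed)
    out = []
    for _ in range(n_rec):
        labs = (rng.random(n) < 0.3).astype(float)
        # strong margin: gap 0.1 during apnea, 1.0 otherwise
        gap = np.where(labs == 1, 0.1, 1.0) + rng.normal(0, 0.02, n)
        feats = np.column_stack([
            rng.normal(size=n), np.ones(n), gap, np.full(n, 0.25),
        ])
        out.append((feats, labs))
    return out


class TestTraining:
    def test_loss_decreases_and_is_reproducible(self):
        data = _separable_datasets()
        tc = TrainConfig(batch_size=4, iterations=60, k_folds=2, window=100, seed=3)
        fit1 = train_model("mixer", data, tc, hidden_dim=8, n_blocks=1)
        fit2 = train_model("mixer", data, tc, hidden_dim=8, n_blocks=1)
        for fold1, fold2 in zip(fit1.folds, fit2.folds):
            assert fold1.losses[-1] < fold1.losses[0]
            assert fold1.losses[-1] == fold2.losses[-1]

    def test_oof_series_full_length_for_all_recordings(self):
        data = _separable_datasets()
        tc = TrainConfig(batch_size=4, iterations=10, k_folds=2, window=100, seed=3)
        fit = train_model("mixer", data, tc, hidden_dim=8, n_blocks=1)
        assert len(fit.oof_probs) == len(data)
        for (feats, _), probs in zip(data, fit.oof_probs):
            assert probs.shape == (feats.shape[0],)
            assert np.all((probs >= 0) & (probs <= 1))

    def test_fewer_recordings_than_folds_raises(self):
        data = _separable_datasets(n_rec=2)
        with pytest.raises(ValueError, match="k_folds"):
            train_model("mixer", data, TrainConfig(k_folds=5, window=100))

    @pytest.mark.parametrize("kind,kw,iters", [
        ("mixer", dict(n_blocks=2), 250),
        ("bilstm", dict(n_layers=3), 700),
    ])
    def test_separable_features_reach_low_bce(self, kind, kw, iters):
        """Both architectures drive training BCE below 0.1 when the gap
        channel alone determines the label."""
        data = _separable_datasets(n_rec=2, n=400)
        tc = TrainConfig(batch_size=4, iterations=iters, k_folds=2,
                         window=50, seed=4)
        fit = train_model(kind, data, tc, hidden_dim=8, **kw)
        for fold in fit.folds:
            assert fold.losses[-10:].mean() < 0.1


class TestInference:
    def test_stitched_series_matches_split_prediction(self, rng):
        """Splitting a recording at a window boundary and predicting the
        halves separately must reproduce the full stitched series."""
        model = _tiny_mixer(n_patches=100, n_channels=4)
        feats = rng.normal(size=(730, 4))
        full = predict_night(model, feats, window=100)
        left = predict_night(model, feats[:300], window=100)
        right = predict_night(model, feats[300:], window=100)
        np.testing.assert_allclose(full, np.concatenate([left, right]), atol=1e-12)

    def test_output_aligned_and_bounded(self, rng):
        model = _tiny_mixer(n_patches=100, n_channels=4)
        feats = rng.normal(size=(512, 4))
        p = predict_night(model, feats, window=100)
        assert p.shape == (512,)
        assert np.all((p > 0) & (p < 1))


class TestParameterAudit:
    def test_mixer_count_closed_form_and_size_independent(self):
        P, C, H, B = 500, 4, 16, 3
        model = MLPMixer(MixerConfig(n_patches=P, n_channels=C, hidden_dim=H,
                                     n_blocks=B, seed=0))
        per_block = (P * H + H) + (H * P + P) + 2 * (H * H + H)
        expected = (C * H + H) + B * per_block + (H + 1)
        assert model.n_parameters() == expected
        # parameter count depends only on the architecture config
        p1, _ = model.forward(np.zeros((1, P, C)))
        p7, _ = model.forward(np.zeros((7, P, C)))
        assert model.n_parameters() == expected


def test_checkpoint_roundtrip(tmp_path, rng):
    model = _tiny_mixer()
    X = rng.normal(size=(2, 8, 3))
    p_before, _ = model.forward(X)
    save_weights(model, tmp_path / "ckpt.npz")
    back = load_weights(tmp_path / "ckpt.npz")
    p_after, _ = back.forward(X)
    np.testing.assert_array_equal(p_before, p_after)
    assert back.config == model.config


def test_make_model_rejects_unknown_kind():
    with pytest.raises(ValueError, match="unknown model kind"):
        make_model("transformer")
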