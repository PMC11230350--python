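"""Latent models: KL/ELBO arithmetic, encode/decode contracts, training
behaviour, model-family identities, checkpointing and the random search."""

import numpy as np
import pytest

from ctxmotif.data import extract_windows
from ctxmotif.models import (
    DSVAE, IDSVAE, ConvContextAutoencoder, LocalVAE, elbo_terms,
    kl_standard_normal, load_model, random_search, save_model, train,
)
from ctxmotif.synth import SyntheticParams, generate_cohort


class TestKL:
    def test_standard_normal_has_zero_kl(self):
        assert kl_standard_normal(np.zeros(3), np.zeros(3)) == 0.0

    def test_unit_mean_closed_form(self):
        assert kl_standard_normal(np.array([1.0]), np.array([0.0])) == pytest.approx(0.5)

    def test_matches_monte_carlo_estimate(self):
        """KL(q||p) = E_q[log q - log p] by simulation, d=3, 10^6 samples."""
        rng = np.random.default_rng(7)
        mean = np.array([0.3, -1.1, 0.8])
        logvar = np.array([0.4, -0.6, 0.1])
        sd = np.exp(0.5 * logvar)
        z = mean + sd * rng.standard_normal((1_000_000, 3))
        log_q = -0.5 * (((z - mean) / sd) ** 2 + logvar + np.log(2 * np.pi)).sum(axis=1)
        log_p = -0.5 * (z**2 + np.log(2 * np.pi)).sum(axis=1)
        mc = float(np.mean(log_q - log_p))
        closed = kl_standard_normal(mean, logvar)
        assert closed == pytest.approx(mc, rel=0.01)

    def test_nonnegative_and_rejects_nonfinite(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            assert kl_standard_normal(rng.normal(size=4), rng.normal(size=4)) >= 0
        with pytest.raises(ValueError):
            kl_standard_normal(np.array([np.nan]), np.array([0.0]))


class TestElbo:
    def test_perfect_reconstruction_with_zero_weights_gives_zero(self):
        x = np.random.default_rng(0).standard_normal((2, 3, 4))
        out = elbo_terms(x, x, np.ones((2, 4, 2)), np.zeros((2, 4, 2)),
                         np.ones((2, 2)), np.zeros((2, 2)), beta=0.0, gamma=0.0)
        assert out["total"] == 0.0 and out["recon"] == 0.0

    def test_standard_normal_posteriors_contribute_no_kl(self):
        x = np.random.default_rng(0).standard_normal((2, 3, 4))
        out = elbo_terms(x, x + 1.0, np.zeros((2, 4, 2)), np.zeros((2, 4, 2)),
                         np.zeros((2, 2)), np.zeros((2, 2)), beta=5.0, gamma=5.0)
        assert out["kl_local"] == 0.0 and out["kl_context"] == 0.0
        assert out["total"] == out["recon"]

    def test_hand_summed_single_window_case(self):
        # one window, N=1, W=2: x=[1, -1], x_hat=[0.5, 0];
        # recon = (1/2) * 0.5 * ((1-0.5)^2 + (-1-0)^2) = 0.3125
        # local KLs: t0 (mu=1, lv=0) -> 0.5; t1 (mu=0, lv=ln 2) -> 0.5*(2-1-ln2)
        # kl_local = (0.5 + 0.5*(1 - np.log(2))) / 2
        # context KL: mu=(1,1), lv=0 -> 1.0
        x = np.array([[[1.0, -1.0]]])
        x_hat = np.array([[[0.5, 0.0]]])
        lm = np.array([[[1.0], [0.0]]])
        lv = np.array([[[0.0], [np.log(2.0)]]])
        cm_, cv = np.array([[1.0, 1.0]]), np.array([[0.0, 0.0]])
        out = elbo_terms(x, x_hat, lm, lv, cm_, cv, beta=2.0, gamma=0.5)
        kl_local = (0.5 + 0.5 * (2 - 1 - np.log(2.0))) / 2
        assert out["recon"] == pytest.approx(0.3125)
        assert out["kl_local"] == pytest.approx(kl_local)
        assert out["kl_context"] == pytest.approx(1.0)
        assert out["total"] == pytest.approx(0.3125 + 2.0 * kl_local + 0.5 * 1.0)


class TestEncode:
    def test_shapes_and_alignment(self, toy_dsvae, toy_windows):
        emb = toy_dsvae.encode(toy_windows)
        m = len(toy_windows)
        assert emb.context_mean.shape == (m, 2)
        assert emb.context_logvar.shape == (m, 2)
        assert emb.local_means.shape == (m, 10, 2)
        assert emb.index == toy_windows.index
        assert np.all(np.isfinite(emb.context_mean))

    def test_inference_is_deterministic(self, toy_dsvae, toy_windows):
        a = toy_dsvae.encode(toy_windows)
        b = toy_dsvae.encode(toy_windows)
        np.testing.assert_array_equal(a.context_mean, b.context_mean)
        np.testing.assert_array_equal(a.local_means, b.local_means)

    def test_idsvae_embedding_is_window_local(self, toy_windows):
        model = IDSVAE(local_size=2, context_size=2, hidden_widths=(16,),
                       epochs=2, seed=0).fit(toy_windows)
        X = toy_windows.windows.copy()
        base = model.encode(X)
        X2 = X.copy()
        X2[5] += 10.0
        pert = model.encode(X2)
        changed = np.any(pert.local_means != base.local_means, axis=(1, 2))
        assert changed[5]
        assert not changed[np.arange(len(X)) != 5].any()

    def test_shape_mismatch_rejected(self, toy_dsvae):
        with pytest.raises(ValueError, match="fitted with"):
            toy_dsvae.encode(np.zeros((2, 5, 10)))

    def test_lvae_context_is_temporal_mean_of_local_means(self, toy_windows):
        model = LocalVAE(local_size=3, hidden_widths=(16,), epochs=2, seed=0).fit(toy_windows)
        emb = model.encode(toy_windows)
        np.testing.assert_array_equal(emb.context_mean, emb.local_means.mean(axis=1))

    def test_co_embeds_without_local_pathway(self, toy_windows):
        model = ConvContextAutoencoder(context_size=3, epochs=2, seed=0).fit(toy_windows)
        emb = model.encode(toy_windows)
        assert emb.context_mean.shape == (len(toy_windows), 3)
        assert emb.local_means is None
        with pytest.raises(ValueError, match="no local embeddings"):
            model.local_trajectory(np.zeros((6, 20)))


class TestModelFamilyIdentities:
    def test_dsvae_with_zeroed_context_conditioning_equals_idsvae(self, toy_windows):
        """The two variants differ only in the local encoder's context input:
        zeroing those weight columns must reproduce IDSVAE encodings."""
        ds = DSVAE(local_size=2, context_size=2, hidden_widths=(16,),
                   epochs=2, seed=3).fit(toy_windows)
        ids = IDSVAE(local_size=2, context_size=2, hidden_widths=(16,),
                     epochs=2, seed=3).fit(toy_windows)
        # context encoder and decoder copied verbatim
        for src, dst in [(ds.context_encoder_, ids.context_encoder_),
                         (ds.decoder_, ids.decoder_)]:
            dst.load_state_dict(src.state_dict())
        # local encoder: first Dense has rows [x_t ; z_c]; drop the z_c rows
        n = ds.n_channels_
        ds_state = ds.local_encoder_.state_dict()
        ds_state["0.W"] = ds_state["0.W"][:n]
        ids.local_encoder_.load_state_dict(ds_state)
        # now zero the context rows in the DSVAE and compare encodings
        ds.local_encoder_.layers[0].params["W"][n:] = 0.0
        a = ds.encode(toy_windows)
        b = ids.encode(toy_windows)
        np.testing.assert_allclose(a.local_means, b.local_means, atol=1e-12)
        np.testing.assert_allclose(a.context_mean, b.context_mean, atol=1e-12)


class TestDecode:
    def test_pure_function_and_shapes(self, toy_dsvae):
        out1 = toy_dsvae.decode(np.zeros(2), np.zeros(2))
        out2 = toy_dsvae.decode(np.zeros(2), np.zeros(2))
        assert out1.shape == (6,)
        np.testing.assert_array_equal(out1, out2)
        assert np.all(np.isfinite(out1))

    def test_length_mismatch_rejected(self, toy_dsvae):
        with pytest.raises(ValueError, match="decode expects"):
            toy_dsvae.decode(np.zeros(3), np.zeros(2))

    def test_overfits_noise_free_toy_cohort(self):
        """With observation noise off and no KL pressure the model should
        reconstruct almost exactly; records the achievable MSE."""
        params = SyntheticParams(n_subjects_per_group=3, n_components=6,
                                 n_timesteps=40, window_length=10,
                                 obs_noise_sd=0.0, cohort_seed=2)
        records, _ = generate_cohort(params)
        # block-aligned windows: the true context is constant within a window
        ws = extract_windows(records, 10, 10)
        model = DSVAE(local_size=2, context_size=2, hidden_widths=(64, 64),
                      beta=0.0, gamma=0.0, epochs=500, batch_size=8,
                      learning_rate=3e-3, seed=0, validation_fraction=0.25).fit(ws)
        assert model.reconstruction_mse(ws) < 0.05


class TestTraining:
    def test_identical_config_reproduces_training_bit_for_bit(self, toy_windows):
        kw = dict(local_size=2, context_size=2, hidden_widths=(16,), epochs=4, seed=11)
        a = DSVAE(**kw).fit(toy_windows)
        b = DSVAE(**kw).fit(toy_windows)
        assert a.training_curve_ == b.training_curve_
        np.testing.assert_array_equal(
            a.encode(toy_windows).context_mean, b.encode(toy_windows).context_mean)

    def test_validation_mse_halves_on_toy_cohort(self, toy_dsvae):
        curve = toy_dsvae.training_curve_
        assert curve[-1]["val_mse"] <= 0.5 * curve[0]["val_mse"]
        assert toy_dsvae.best_val_mse_ == min(r["val_mse"] for r in curve)

    def test_dominant_kl_collapses_posterior_means(self, toy_windows):
        model = DSVAE(local_size=2, context_size=2, hidden_widths=(16,),
                      beta=1e6, gamma=1e6, epochs=30, batch_size=16,
                      learning_rate=0.02, seed=0).fit(toy_windows)
        emb = model.encode(toy_windows)
        assert np.mean(np.abs(emb.context_mean)) < 0.05
        assert np.mean(np.abs(emb.local_means)) < 0.05

    def test_divergence_raises_with_epoch(self, toy_windows):
        with np.errstate(over="ignore", invalid="ignore"):
            with pytest.raises(RuntimeError, match="diverged.*epoch"):
                DSVAE(hidden_widths=(16,), learning_rate=1e100, epochs=3,
                      seed=0).fit(toy_windows)

    def test_stronger_context_regularization_weakly_shrinks_context_kl(self, toy_windows):
        kw = dict(local_size=2, context_size=2, hidden_widths=(16,), epochs=20, seed=4)
        lo = DSVAE(gamma=1e-3, **kw).fit(toy_windows)
        hi = DSVAE(gamma=1.0, **kw).fit(toy_windows)
        kl_lo = lo.loss_terms(toy_windows.windows)["kl_context"]
        kl_hi = hi.loss_terms(toy_windows.windows)["kl_context"]
        assert kl_hi <= kl_lo


class TestCheckpoint:
    def test_save_load_round_trip_reproduces_encodings(self, toy_dsvae, toy_windows, tmp_path):
        path = tmp_path / "model.npz"
        save_model(toy_dsvae, path)
        loaded = load_model(path)
        a = toy_dsvae.encode(toy_windows)
        b = loaded.encode(toy_windows)
        np.testing.assert_array_equal(a.context_mean, b.context_mean)
        np.testing.assert_array_equal(a.local_logvars, b.local_logvars)
        assert loaded.get_params()["hidden_widths"] == (32,)

    @pytest.mark.parametrize("kind,cls", [("IDSVAE", IDSVAE), ("LVAE", LocalVAE),
                                          ("CO", ConvContextAutoencoder)])
    def test_train_entry_point_builds_each_kind(self, toy_windows, kind, cls, tmp_path):
        model = train({"model_kind": kind, "hidden_widths": (8,), "epochs": 1, "seed": 0},
                      toy_windows, toy_windows)
        assert isinstance(model, cls)
        save_model(model, tmp_path / "m.npz")
        reloaded = load_model(tmp_path / "m.npz")
        np.testing.assert_array_equal(model.transform(toy_windows),
                                      reloaded.transform(toy_windows))

    def test_unknown_model_kind_rejected(self, toy_windows):
        with pytest.raises(ValueError, match="unknown model_kind"):
            train({"model_kind": "GAN"}, toy_windows, toy_windows)


class TestRandomSearch:
    def test_single_trial_returns_that_config(self, toy_windows):
        model, log = random_search(toy_windows, toy_windows,
                                   {"beta": (1e-4, 1e-2, "log")}, n_trials=1,
                                   seed=0, hidden_widths=(8,), epochs=1)
        assert len(log) == 1
        assert model.beta == log[0]["beta"]

    def test_selects_the_trainable_learning_rate(self, toy_windows):
        model, log = random_search(
            toy_windows, toy_windows, {"learning_rate": [10.0, 1e-3]},
            n_trials=6, seed=1, hidden_widths=(16,), epochs=5)
        assert model.learning_rate == 1e-3
        assert {row["learning_rate"] for row in log} == {10.0, 1e-3}

    def test_same_seed_samples_same_configs(self, toy_windows):
        space = {"beta": (1e-4, 1e-1, "log"), "hidden_widths": [(8,), (16,)]}
        _, log_a = random_search(toy_windows, toy_windows, space, n_trials=3,
                                 seed=5, epochs=1)
        _, log_b = random_search(toy_windows, toy_windows, space, n_trials=3,
                                 seed=5, epochs=1)
        assert [r["beta"] for r in log_a] == [r["beta"] for r in log_b]
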