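"""Disentangled sequential VAEs for windowed multivariate timeseries.

Four estimators over window arrays ``[M windows, N channels, W timesteps]``:

``DSVAE``
    Two encoders — a *context* encoder mapping the whole window to one latent
    ``z_c``, and a *local* encoder mapping each timestep (concatenated with
    ``z_c``) to a per-timestep latent ``z_t`` — plus an MLP decoder
    reconstructing each timestep from ``[z_c; z_t]``.
``IDSVAE``
    Identical except the local encoder sees only the timestep, not ``z_c``
    (the independent/factorized variant).
``LocalVAE``
    Local-only baseline (LVAE); its window summary is the time-average of the
    local posterior means.
``ConvContextAutoencoder``
    Context-only baseline (CO): a deterministic 1-D convolutional
    autoencoder producing a single embedding per window.

Training maximises an evidence lower bound with a fixed-unit-variance
Gaussian likelihood, so the reconstruction term reduces to ½·MSE per timestep
(additive constants dropped) and hyperparameters are comparable on validation
MSE.  Two KL terms to a standard-normal prior are weighted by ``beta`` (local)
and ``gamma`` (context).  All estimators follow the scikit-learn protocol:
``fit`` / ``transform`` (context means) / ``get_params``; fitted attributes
carry a trailing underscore.  All randomness (init, shuffling, reparameterized
sampling) flows from ``seed``; inference uses posterior means only, so
``transform``/``encode`` are deterministic.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ._nn import Adam, Conv1d, ConvTranspose1d, Dense, Relu, Sequential
from .data import WindowSet

__all__ = [
    "LatentEmbedding", "kl_standard_normal", "elbo_terms",
    "DSVAE", "IDSVAE", "LocalVAE", "ConvContextAutoencoder",
    "MODEL_KINDS", "train", "random_search", "save_model", "load_model",
]

DEFAULT_SEEDS = (42, 1337, 1212, 9999)


@dataclasses.dataclass
class LatentEmbedding:
    """Per-window posterior parameters, aligned with a WindowSet.

    ``context_mean``/``context_logvar`` are ``[M, CS]``; ``local_means``/
    ``local_logvars`` are ``[M, W, LS]`` (None for the context-only model).
    ``index`` carries the (subject_id, start) provenance when encoded from a
    WindowSet.
    """

    context_mean: np.ndarray
    context_logvar: np.ndarray
    local_means: np.ndarray | None
    local_logvars: np.ndarray | None
    index: list[tuple[str, int]] | None = None


def kl_standard_normal(mean: np.ndarray, logvar: np.ndarray) -> np.ndarray | float:
    """KL(N(mean, diag exp(logvar)) || N(0, I)) in nats, summed over the last axis.

    Closed form: ``0.5 * sum_d(exp(logvar_d) + mean_d^2 - 1 - logvar_d)``;
    non-negative, zero iff mean=0 and logvar=0.
    """
    mean = np.asarray(mean, dtype=float)
    logvar = np.asarray(logvar, dtype=float)
    if not (np.all(np.isfinite(mean)) and np.all(np.isfinite(logvar))):
        raise ValueError("kl_standard_normal requires finite inputs")
    kl = 0.5 * np.sum(np.exp(logvar) + mean**2 - 1.0 - logvar, axis=-1)
    return float(kl) if np.ndim(kl) == 0 else kl


def elbo_terms(
    x: np.ndarray,
    x_hat: np.ndarray,
    local_mean: np.ndarray | None,
    local_logvar: np.ndarray | None,
    context_mean: np.ndarray | None,
    context_logvar: np.ndarray | None,
    beta: float,
    gamma: float,
) -> dict[str, float]:
    """Negative ELBO pieces for a batch of windows (pure function).

    ``recon`` is the per-timestep negative Gaussian log-likelihood at unit
    variance with constants dropped, i.e. ``(1/W) sum_t 0.5 ||x_t - x̂_t||²``,
    averaged over the batch.  ``kl_local`` averages the per-timestep KL over
    the W timesteps; ``kl_context`` is one KL per window.  ``total = recon +
    beta·kl_local + gamma·kl_context``.
    """
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise ValueError("x and x_hat must have matching [B, N, W] shapes")
    b, _, w = x.shape
    recon = float(0.5 * np.sum((x - x_hat) ** 2) / (b * w))
    kl_local = 0.0
    if local_mean is not None:
        kl_local = float(np.sum(kl_standard_normal(local_mean, local_logvar)) / (b * w))
    kl_context = 0.0
    if context_mean is not None:
        kl_context = float(np.sum(kl_standard_normal(context_mean, context_logvar)) / b)
    total = recon + beta * kl_local + gamma * kl_context
    return {"total": total, "recon": recon, "kl_local": kl_local, "kl_context": kl_context}


def _kl_sum(mean: np.ndarray, logvar: np.ndarray) -> float:
    # unvalidated KL for the training loop: a non-finite value must surface as
    # a divergence error, not an input-validation error
    return 0.5 * np.sum(np.exp(logvar) + mean**2 - 1.0 - logvar)


def _as_window_array(X) -> tuple[np.ndarray, list | None]:
    if isinstance(X, WindowSet):
        return X.windows, X.index
    X = np.asarray(X, dtype=float)
    if X.ndim != 3:
        raise ValueError("windows must be a WindowSet or an array [M, N, W]")
    return X, None


def _mlp(sizes: Sequence[int], rng: np.random.Generator) -> Sequential:
    layers = []
    for i in range(len(sizes) - 1):
        layers.append(Dense(sizes[i], sizes[i + 1], rng))
        if i < len(sizes) - 2:
            layers.append(Relu())
    return Sequential(*layers)


class _BaseWindowModel(BaseEstimator, TransformerMixin):
    """Shared training loop, checkpointing and encode/decode plumbing."""

    _has_context = True
    _has_local = True

    def __init__(
        self,
        local_size: int = 2,
        context_size: int = 2,
        beta: float = 1e-3,
        gamma: float = 1e-3,
        hidden_widths: tuple[int, ...] = (128, 128),
        learning_rate: float = 1e-3,
        batch_size: int = 128,
        epochs: int = 200,
        seed: int = 42,
        logvar_clip: float = 8.0,
        validation_fraction: float = 0.2,
    ) -> None:
        self.local_size = local_size
        self.context_size = context_size
        self.beta = beta
        self.gamma = gamma
        self.hidden_widths = hidden_widths
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.seed = seed
        self.logvar_clip = logvar_clip
        self.validation_fraction = validation_fraction

    # -- architecture hooks -------------------------------------------------
    def _build(self, rng: np.random.Generator) -> None:
        raise NotImplementedError

    def _forward_backward(self, xb: np.ndarray, rng: np.random.Generator | None,
                          compute_grads: bool = True) -> dict[str, float]:
        raise NotImplementedError

    def _nets(self) -> list[Sequential]:
        raise NotImplementedError

    # -- training -----------------------------------------------------------
    def fit(self, X, y=None, *, validation=None):
        """Train on windows ``X``; select weights at the best validation MSE.

        ``validation`` takes held-out windows (a WindowSet or array); without
        it, a trailing ``validation_fraction`` of a seeded window shuffle is
        held out.  Subject-level splits should be made by the caller.
        """
        Xtr, _ = _as_window_array(X)
        if Xtr.shape[0] == 0:
            raise ValueError("empty training window set")
        self.n_channels_ = Xtr.shape[1]
        self.window_length_ = Xtr.shape[2]
        rng = np.random.default_rng(self.seed)

        if validation is not None:
            Xval, _ = _as_window_array(validation)
        else:
            order = rng.permutation(Xtr.shape[0])
            n_val = max(1, int(round(self.validation_fraction * Xtr.shape[0])))
            Xval, Xtr = Xtr[order[-n_val:]], Xtr[order[:-n_val]]
            if Xtr.shape[0] == 0:
                raise ValueError("validation split left no training windows")
        if Xval.shape[0] == 0:
            raise ValueError("empty validation window set")

        self._build(rng)
        opt = Adam([l for net in self._nets() for l in net.parameter_layers()],
                   lr=self.learning_rate)
        m = Xtr.shape[0]
        curve: list[dict[str, float]] = []
        best = (np.inf, None, -1)
        for epoch in range(self.epochs):
            order = rng.permutation(m)
            ep = {"total": 0.0, "recon": 0.0, "kl_local": 0.0, "kl_context": 0.0}
            n_batches = 0
            for start in range(0, m, self.batch_size):
                xb = Xtr[order[start : start + self.batch_size]]
                opt.zero_grad()
                terms = self._forward_backward(xb, rng)
                if not np.isfinite(terms["total"]):
                    raise RuntimeError(
                        f"training diverged (non-finite loss) at epoch {epoch}"
                    )
                opt.step()
                for k in ep:
                    ep[k] += terms[k]
                n_batches += 1
            val_mse = self.reconstruction_mse(Xval)
            if not np.isfinite(val_mse):
                raise RuntimeError(f"training diverged (non-finite validation MSE) "
                                   f"at epoch {epoch}")
            row = {k: v / n_batches for k, v in ep.items()}
            row.update(epoch=epoch, val_mse=val_mse)
            curve.append(row)
            if val_mse < best[0]:
                best = (val_mse, [net.state_dict() for net in self._nets()], epoch)
        if best[1] is not None:
            for net, state in zip(self._nets(), best[1]):
                net.load_state_dict(state)
        self.best_epoch_ = best[2]
        self.best_val_mse_ = best[0]
        self.training_curve_ = curve
        return self

    def reconstruction_mse(self, X) -> float:
        """Per-element MSE of the deterministic (posterior-mean) reconstruction."""
        Xa, _ = _as_window_array(X)
        total, count = 0.0, 0
        for start in range(0, Xa.shape[0], 1024):
            xb = Xa[start : start + 1024]
            xh = self._reconstruct(xb)
            total += float(np.sum((xb - xh) ** 2))
            count += xb.size
        return total / count

    def score(self, X, y=None) -> float:
        """Negative validation-style MSE (higher is better, sklearn convention)."""
        return -self.reconstruction_mse(X)

    # -- inference ----------------------------------------------------------
    def _check_fitted(self) -> None:
        if not hasattr(self, "n_channels_"):
            raise ValueError("model is not fitted")

    def _check_windows(self, Xa: np.ndarray) -> None:
        if Xa.shape[1] != self.n_channels_ or Xa.shape[2] != self.window_length_:
            raise ValueError(
                f"windows have shape [*, {Xa.shape[1]}, {Xa.shape[2]}] but the model "
                f"was fitted with N={self.n_channels_}, W={self.window_length_}"
            )

    def encode(self, X) -> LatentEmbedding:
        """Posterior parameters for every window (deterministic, no sampling)."""
        self._check_fitted()
        Xa, index = _as_window_array(X)
        self._check_windows(Xa)
        parts = [self._encode_batch(Xa[s : s + 1024]) for s in range(0, Xa.shape[0], 1024)]
        stack = [np.concatenate([p[i] for p in parts]) if parts[0][i] is not None else None
                 for i in range(4)]
        return LatentEmbedding(*stack, index=index)

    def transform(self, X) -> np.ndarray:
        """Context embedding (one vector per window)."""
        return self.encode(X).context_mean

    def local_trajectory(self, timecourses: np.ndarray) -> np.ndarray:
        """Local posterior means along non-overlapping windows of one subject.

        Covers the prefix of length ``floor(T/W)*W`` so every timestep appears
        exactly once; returns ``[T', LS]``.
        """
        self._check_fitted()
        if not self._has_local:
            raise ValueError("this model has no local embeddings")
        n, t = timecourses.shape
        w = self.window_length_
        n_win = t // w
        if n_win < 1:
            raise ValueError("timecourse shorter than one window")
        wins = np.stack([timecourses[:, i * w : (i + 1) * w] for i in range(n_win)])
        emb = self.encode(wins)
        return emb.local_means.reshape(n_win * w, self.local_size)

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | Path) -> None:
        save_model(self, path)


# ---------------------------------------------------------------------------
# DSVAE / IDSVAE / LVAE
# ---------------------------------------------------------------------------

class DSVAE(_BaseWindowModel):
    """Disentangled sequential VAE: local encoder conditioned on the context.

    The context encoder reads the full window; its latent ``z_c`` is
    concatenated with every timestep as local-encoder input, and the decoder
    reconstructs each timestep from ``[z_c; z_t]``.  During training the local
    encoder receives a reparameterized *sample* of ``z_c``; at inference it
    receives the posterior mean.
    """

    _condition_local = True

    def _build(self, rng: np.random.Generator) -> None:
        n, w = self.n_channels_, self.window_length_
        h = list(self.hidden_widths)
        cs, ls = self.context_size, self.local_size
        self.context_encoder_ = _mlp([n * w, *h, 2 * cs], rng)
        loc_in = n + cs if self._condition_local else n
        self.local_encoder_ = _mlp([loc_in, *h, 2 * ls], rng)
        self.decoder_ = _mlp([cs + ls, *h, n], rng)

    def _nets(self) -> list[Sequential]:
        return [self.context_encoder_, self.local_encoder_, self.decoder_]

    def _split_clip(self, out: np.ndarray, d: int):
        mean, raw = out[:, :d], out[:, d:]
        c = self.logvar_clip
        logvar = np.clip(raw, -c, c)
        mask = (raw > -c) & (raw < c)
        return mean, logvar, mask

    def _forward_backward(self, xb, rng, compute_grads=True):
        b, n, w = xb.shape
        cs, ls = self.context_size, self.local_size
        flat = xb.reshape(b, n * w)
        mu_c, lv_c, mask_c = self._split_clip(self.context_encoder_.forward(flat), cs)
        if rng is not None:
            eps_c = rng.standard_normal(mu_c.shape)
            z_c = mu_c + np.exp(0.5 * lv_c) * eps_c
        else:
            eps_c, z_c = None, mu_c

        xt = np.transpose(xb, (0, 2, 1)).reshape(b * w, n)  # per-timestep rows
        if self._condition_local:
            zc_rep = np.repeat(z_c, w, axis=0)
            loc_in = np.concatenate([xt, zc_rep], axis=1)
        else:
            loc_in = xt
        mu_l, lv_l, mask_l = self._split_clip(self.local_encoder_.forward(loc_in), ls)
        if rng is not None:
            eps_l = rng.standard_normal(mu_l.shape)
            z_l = mu_l + np.exp(0.5 * lv_l) * eps_l
        else:
            eps_l, z_l = None, mu_l

        dec_in = np.concatenate([np.repeat(z_c, w, axis=0), z_l], axis=1)
        x_hat = self.decoder_.forward(dec_in)  # [b*w, n]
        diff = x_hat - xt

        terms = {
            "recon": float(0.5 * np.sum(diff**2) / (b * w)),
            "kl_local": float(_kl_sum(mu_l, lv_l) / (b * w)),
            "kl_context": float(_kl_sum(mu_c, lv_c) / b),
        }
        terms["total"] = (terms["recon"] + self.beta * terms["kl_local"]
                          + self.gamma * terms["kl_context"])
        if not compute_grads:
            return terms

        ddec_in = self.decoder_.backward(diff / (b * w))
        dz_c = ddec_in[:, :cs].reshape(b, w, cs).sum(axis=1)
        dz_l = ddec_in[:, cs:]

        dmu_l = dz_l + self.beta * mu_l / (b * w)
        dlv_l = self.beta * (np.exp(lv_l) - 1.0) / (2 * b * w)
        if eps_l is not None:
            dlv_l = dlv_l + dz_l * eps_l * 0.5 * np.exp(0.5 * lv_l)
        dloc_in = self.local_encoder_.backward(
            np.concatenate([dmu_l, dlv_l * mask_l], axis=1)
        )
        if self._condition_local:
            dz_c = dz_c + dloc_in[:, n:].reshape(b, w, cs).sum(axis=1)

        dmu_c = dz_c + self.gamma * mu_c / b
        dlv_c = self.gamma * (np.exp(lv_c) - 1.0) / (2 * b)
        if eps_c is not None:
            dlv_c = dlv_c + dz_c * eps_c * 0.5 * np.exp(0.5 * lv_c)
        self.context_encoder_.backward(np.concatenate([dmu_c, dlv_c * mask_c], axis=1))
        return terms

    def loss_terms(self, X, sample: bool = False, seed: int | None = None) -> dict[str, float]:
        """Negative-ELBO terms on a window batch (deterministic unless sampling)."""
        Xa, _ = _as_window_array(X)
        self._check_windows(Xa)
        rng = np.random.default_rng(self.seed if seed is None else seed) if sample else None
        return self._forward_backward(Xa, rng, compute_grads=False)

    def _encode_batch(self, xb):
        b, n, w = xb.shape
        cs, ls = self.context_size, self.local_size
        mu_c, lv_c, _ = self._split_clip(self.context_encoder_.forward(xb.reshape(b, n * w)), cs)
        xt = np.transpose(xb, (0, 2, 1)).reshape(b * w, n)
        loc_in = (np.concatenate([xt, np.repeat(mu_c, w, axis=0)], axis=1)
                  if self._condition_local else xt)
        mu_l, lv_l, _ = self._split_clip(self.local_encoder_.forward(loc_in), ls)
        return (mu_c, lv_c, mu_l.reshape(b, w, ls), lv_l.reshape(b, w, ls))

    def _reconstruct(self, xb):
        b, n, w = xb.shape
        mu_c, _, mu_l, _ = self._encode_batch(xb)
        dec_in = np.concatenate(
            [np.repeat(mu_c, w, axis=0), mu_l.reshape(b * w, self.local_size)], axis=1
        )
        return self.decoder_.forward(dec_in).reshape(b, w, n).transpose(0, 2, 1)

    def decode(self, context: np.ndarray, local: np.ndarray) -> np.ndarray:
        """Reconstruct one timestep (or a batch) from [context; local] latents."""
        self._check_fitted()
        context = np.atleast_2d(np.asarray(context, dtype=float))
        local = np.atleast_2d(np.asarray(local, dtype=float))
        if context.shape[1] != self.context_size or local.shape[1] != self.local_size:
            raise ValueError(
                f"decode expects context of length {self.context_size} and local of "
                f"length {self.local_size}, got {context.shape[1]} and {local.shape[1]}"
            )
        out = self.decoder_.forward(np.concatenate([context, local], axis=1))
        return out[0] if out.shape[0] == 1 else out


class IDSVAE(DSVAE):
    """Independent (factorized) variant: the local encoder sees only the
    timestep, never the context vector.  This is the single difference from
    DSVAE, so each window's local embedding depends on that window alone.
    """

    _condition_local = False


class LocalVAE(DSVAE):
    """Local-only baseline (LVAE): no context pathway at all.

    The decoder reconstructs each timestep from ``z_t`` alone, and the derived
    context embedding of a window is the time-average of its local posterior
    means (exact identity, tested).
    """

    _condition_local = False
    _has_context = False

    def _build(self, rng: np.random.Generator) -> None:
        n, w = self.n_channels_, self.window_length_
        h = list(self.hidden_widths)
        ls = self.local_size
        self.local_encoder_ = _mlp([n, *h, 2 * ls], rng)
        self.decoder_ = _mlp([ls, *h, n], rng)

    def _nets(self):
        return [self.local_encoder_, self.decoder_]

    def _forward_backward(self, xb, rng, compute_grads=True):
        b, n, w = xb.shape
        ls = self.local_size
        xt = np.transpose(xb, (0, 2, 1)).reshape(b * w, n)
        mu_l, lv_l, mask_l = self._split_clip(self.local_encoder_.forward(xt), ls)
        if rng is not None:
            eps_l = rng.standard_normal(mu_l.shape)
            z_l = mu_l + np.exp(0.5 * lv_l) * eps_l
        else:
            eps_l, z_l = None, mu_l
        x_hat = self.decoder_.forward(z_l)
        diff = x_hat - xt
        terms = {
            "recon": float(0.5 * np.sum(diff**2) / (b * w)),
            "kl_local": float(_kl_sum(mu_l, lv_l) / (b * w)),
            "kl_context": 0.0,
        }
        terms["total"] = terms["recon"] + self.beta * terms["kl_local"]
        if not compute_grads:
            return terms
        dz_l = self.decoder_.backward(diff / (b * w))
        dmu_l = dz_l + self.beta * mu_l / (b * w)
        dlv_l = self.beta * (np.exp(lv_l) - 1.0) / (2 * b * w)
        if eps_l is not None:
            dlv_l = dlv_l + dz_l * eps_l * 0.5 * np.exp(0.5 * lv_l)
        self.local_encoder_.backward(np.concatenate([dmu_l, dlv_l * mask_l], axis=1))
        return terms

    def _encode_batch(self, xb):
        b, n, w = xb.shape
        ls = self.local_size
        xt = np.transpose(xb, (0, 2, 1)).reshape(b * w, n)
        mu_l, lv_l, _ = self._split_clip(self.local_encoder_.forward(xt), ls)
        mu_l = mu_l.reshape(b, w, ls)
        lv_l = lv_l.reshape(b, w, ls)
        # derived context: time-average of local posterior means
        return (mu_l.mean(axis=1), lv_l.mean(axis=1), mu_l, lv_l)

    def _reconstruct(self, xb):
        b, n, w = xb.shape
        _, _, mu_l, _ = self._encode_batch(xb)
        out = self.decoder_.forward(mu_l.reshape(b * w, self.local_size))
        return out.reshape(b, w, n).transpose(0, 2, 1)

    def decode(self, context: np.ndarray, local: np.ndarray) -> np.ndarray:
        self._check_fitted()
        local = np.atleast_2d(np.asarray(local, dtype=float))
        if local.shape[1] != self.local_size:
            raise ValueError(f"decode expects local of length {self.local_size}")
        out = self.decoder_.forward(local)
        return out[0] if out.shape[0] == 1 else out

    @property
    def context_size(self):  # derived context has the local dimensionality
        return self.local_size

    @context_size.setter
    def context_size(self, value):
        self._context_size_unused = value

    def get_params(self, deep=True):
        params = super().get_params(deep=deep)
        params["context_size"] = getattr(self, "_context_size_unused", self.local_size)
        return params


class ConvContextAutoencoder(_BaseWindowModel):
    """Context-only baseline (CO): deterministic convolutional autoencoder.

    A stack of strided 1-D convolutions over time compresses the window to a
    single bottleneck embedding of size ``context_size``; a mirrored
    transposed-convolution stack reconstructs the full ``[N, W]`` block.
    There is no local pathway and no KL term — the embedding is the
    bottleneck activation itself (``context_logvar`` is reported as zeros).
    """

    _has_local = False
    _conv_channels = 32
    _kernel = 5
    _stride = 2

    def _build(self, rng: np.random.Generator) -> None:
        n, w = self.n_channels_, self.window_length_
        c, k, s = self._conv_channels, self._kernel, self._stride
        p = k // 2
        l1 = Conv1d.out_length(w, k, s, p)
        l2 = Conv1d.out_length(l1, k, s, p)
        if l2 < 1:
            raise ValueError(f"window length {w} too short for the conv encoder")
        self._l1, self._l2 = l1, l2
        self.encoder_conv_ = Sequential(
            Conv1d(n, c, k, s, p, rng), Relu(), Conv1d(c, c, k, s, p, rng), Relu()
        )
        self.encoder_head_ = Dense(c * l2, self.context_size, rng)
        self.decoder_head_ = Dense(self.context_size, c * l2, rng)
        self.decoder_conv_ = Sequential(
            Relu(),
            ConvTranspose1d(c, c, k, s, p, out_length=l1, rng=rng), Relu(),
            ConvTranspose1d(c, n, k, s, p, out_length=w, rng=rng),
        )

    def _nets(self):
        return [self.encoder_conv_, Sequential(self.encoder_head_),
                Sequential(self.decoder_head_), self.decoder_conv_]

    def _embed(self, xb):
        b = xb.shape[0]
        feats = self.encoder_conv_.forward(xb)  # [b, c, l2]
        return self.encoder_head_.forward(feats.reshape(b, -1))

    def _decode_embedding(self, z):
        b = z.shape[0]
        h = self.decoder_head_.forward(z).reshape(b, self._conv_channels, self._l2)
        return self.decoder_conv_.forward(h)

    def _forward_backward(self, xb, rng, compute_grads=True):
        b, n, w = xb.shape
        z = self._embed(xb)
        x_hat = self._decode_embedding(z)
        diff = x_hat - xb
        recon = float(0.5 * np.sum(diff**2) / (b * w))
        terms = {"total": recon, "recon": recon, "kl_local": 0.0, "kl_context": 0.0}
        if not compute_grads:
            return terms
        dh = self.decoder_conv_.backward(diff / (b * w))
        dz = self.decoder_head_.backward(dh.reshape(b, -1))
        dfeats = self.encoder_head_.backward(dz)
        self.encoder_conv_.backward(dfeats.reshape(b, self._conv_channels, self._l2))
        return terms

    def loss_terms(self, X, sample: bool = False, seed: int | None = None):
        Xa, _ = _as_window_array(X)
        self._check_windows(Xa)
        return self._forward_backward(Xa, None, compute_grads=False)

    def _encode_batch(self, xb):
        z = self._embed(xb)
        return (z, np.zeros_like(z), None, None)

    def _reconstruct(self, xb):
        return self._decode_embedding(self._embed(xb))

    def decode(self, context: np.ndarray, local=None) -> np.ndarray:
        """Reconstruct a full [N, W] window from a bottleneck embedding."""
        self._check_fitted()
        context = np.atleast_2d(np.asarray(context, dtype=float))
        if context.shape[1] != self.context_size:
            raise ValueError(f"decode expects context of length {self.context_size}")
        out = self._decode_embedding(context)
        return out[0] if out.shape[0] == 1 else out


MODEL_KINDS = {
    "DSVAE": DSVAE,
    "IDSVAE": IDSVAE,
    "LVAE": LocalVAE,
    "CO": ConvContextAutoencoder,
}


def train(config: dict, train_windows, val_windows) -> _BaseWindowModel:
    """Build the model named by ``config['model_kind']`` and fit it.

    Remaining config keys are estimator parameters (local_size, context_size,
    beta, gamma, epochs, seed, ...).  Returns the fitted estimator with
    weights from the best-validation-MSE epoch.
    """
    config = dict(config)
    kind = config.pop("model_kind", "DSVAE")
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model_kind {kind!r}; expected one of {sorted(MODEL_KINDS)}")
    model = MODEL_KINDS[kind](**config)
    return model.fit(train_windows, validation=val_windows)


def random_search(
    train_windows,
    val_windows,
    space: dict,
    n_trials: int = 10,
    seed: int = 0,
    model_kind: str = "DSVAE",
    **fixed,
) -> tuple[_BaseWindowModel, list[dict]]:
    """Small random hyperparameter search selecting by validation MSE.

    ``space`` maps a parameter name to either a list of choices or a tuple
    ``(low, high)`` / ``(low, high, "log")`` for uniform or log-uniform
    sampling.  Diverged trials are recorded with infinite validation MSE; if
    every trial diverges an error is raised.  Deterministic given ``seed``
    (trial configs) and each trial's own model seed in ``fixed``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    trials: list[dict] = []
    best_model, best_mse = None, np.inf
    for i in range(n_trials):
        params = dict(fixed)
        for name, spec in space.items():
            if isinstance(spec, list):
                params[name] = spec[rng.integers(len(spec))]
            else:
                low, high = float(spec[0]), float(spec[1])
                if len(spec) > 2 and spec[2] == "log":
                    params[name] = float(np.exp(rng.uniform(np.log(low), np.log(high))))
                else:
                    params[name] = float(rng.uniform(low, high))
        entry = {"trial": i, **params}
        try:
            model = train({"model_kind": model_kind, **params}, train_windows, val_windows)
            entry["val_mse"] = model.best_val_mse_
        except RuntimeError as exc:
            entry["val_mse"] = np.inf
            entry["error"] = str(exc)
            model = None
        trials.append(entry)
        if model is not None and entry["val_mse"] < best_mse:
            best_model, best_mse = model, entry["val_mse"]
    if best_model is None:
        raise RuntimeError("all random-search trials diverged")
    return best_model, trials


def save_model(model: _BaseWindowModel, path: str | Path) -> None:
    """Single-file checkpoint: weights plus the config needed to rebuild."""
    kind = next(k for k, cls in MODEL_KINDS.items() if cls is type(model))
    config = {k: (list(v) if isinstance(v, tuple) else v)
              for k, v in model.get_params().items()}
    meta = {
        "model_kind": kind,
        "config": config,
        "n_channels": model.n_channels_,
        "window_length": model.window_length_,
        "best_epoch": getattr(model, "best_epoch_", -1),
        "best_val_mse": getattr(model, "best_val_mse_", float("nan")),
    }
    arrays = {}
    for i, net in enumerate(model._nets()):
        for k, v in net.state_dict().items():
            arrays[f"net{i}/{k}"] = v
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_model(path: str | Path) -> _BaseWindowModel:
    """Rebuild a checkpointed model; encodings reproduce bit-identically."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arrays = {k: data[k] for k in data.files if k != "__meta__"}
    config = {k: (tuple(v) if isinstance(v, list) else v)
              for k, v in meta["config"].items()}
    model = MODEL_KINDS[meta["model_kind"]](**config)
    model.n_channels_ = meta["n_channels"]
    model.window_length_ = meta["window_length"]
    model.best_epoch_ = meta["best_epoch"]
    model.best_val_mse_ = meta["best_val_mse"]
    model._build(np.random.default_rng(model.seed))
    for i, net in enumerate(model._nets()):
        prefix = f"net{i}/"
        state = {k[len(prefix):]: v for k, v in arrays.items() if k.startswith(prefix)}
        net.load_state_dict(state)
    model.training_curve_ = []
    return model
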