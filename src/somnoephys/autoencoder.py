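"""Stacked sparse autoencoder for spectral feature reduction.

A compact, dependency-free numpy implementation of the mirror-symmetric
dense autoencoder used for dimensionality reduction of per-bin normalized
PSD features: encoder layers of 256/128/64 units (each Linear -> batch
norm -> ReLU) into a 32-unit latent layer, with a mirrored decoder and a
linear output.  The loss is mean squared reconstruction error plus an L1
sparsity penalty on the encoder activations, optimized with Adam on
shuffled minibatches.  Training is deterministic given the config seed.
"""

from __future__ import annotations

import numpy as np
from numpy.random import default_rng

from ._kernels import (adam_update, add_l1_subgradient, bn_relu_backward,
                       bn_relu_forward)
from .config import AutoencoderConfig

__all__ = ["Autoencoder", "train_autoencoder", "encode_features"]

_F32 = np.float32
_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1   # running = (1-m)*running + m*batch


class _Dense:
    """Linear layer, optionally followed by batch norm + ReLU."""

    def __init__(self, n_in: int, n_out: int, rng, activated: bool = True):
        self.W = (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)).astype(_F32)
        self.b = np.zeros(n_out, dtype=_F32)
        self.activated = activated
        if activated:
            self.gamma = np.ones(n_out, dtype=_F32)
            self.beta = np.zeros(n_out, dtype=_F32)
            self.run_mean = np.zeros(n_out, dtype=_F32)
            self.run_var = np.ones(n_out, dtype=_F32)

    def params(self):
        if self.activated:
            return [self.W, self.b, self.gamma, self.beta]
        return [self.W, self.b]

    def forward(self, X: np.ndarray, training: bool) -> np.ndarray:
        Z = X @ self.W + self.b
        if not self.activated:
            self._X = X
            return Z
        if training:
            A, xhat, inv_std, mu, var = bn_relu_forward(Z, self.gamma, self.beta)
            self.run_mean += _BN_MOMENTUM * (mu - self.run_mean)
            self.run_var += _BN_MOMENTUM * (var - self.run_var)
            self._X, self._xhat, self._inv_std, self._A = X, xhat, inv_std, A
            return A
        inv_std = 1.0 / np.sqrt(self.run_var + _BN_EPS)
        xhat = (Z - self.run_mean) * inv_std
        return np.maximum(self.gamma * xhat + self.beta, 0.0)

    def backward(self, dA: np.ndarray, gout: list | None = None):
        """Return dX; gradients go into ``gout`` (params order) when given,
        else are returned as a list.  forward(training=True) first."""
        if not self.activated:
            if gout is None:
                return dA @ self.W.T, [self._X.T @ dA, dA.sum(axis=0)]
            np.matmul(self._X.T, dA, out=gout[0])
            np.sum(dA, axis=0, out=gout[1])
            return dA @ self.W.T
        dZ, dgamma, dbeta = bn_relu_backward(
            np.ascontiguousarray(dA), self._A, self._xhat, self._inv_std, self.gamma)
        if gout is None:
            return dZ @ self.W.T, [self._X.T @ dZ, np.zeros_like(self.b),
                                   dgamma, dbeta]
        np.matmul(self._X.T, dZ, out=gout[0])
        # dZ.sum(0) vanishes identically under batch norm (the batch-mean
        # subtraction absorbs the linear bias), so gout[1] stays zero
        gout[2][...] = dgamma
        gout[3][...] = dbeta
        return dZ @ self.W.T


class Autoencoder:
    """Mirror-symmetric dense autoencoder; ``encode`` runs batch norm in
    inference mode (running statistics), so encoding is deterministic."""

    def __init__(self, n_features: int, cfg: AutoencoderConfig | None = None):
        self.cfg = cfg or AutoencoderConfig()
        self.cfg.validate()
        self.n_features = n_features
        rng = default_rng(self.cfg.seed)
        widths = list(self.cfg.encoder_widths)
        enc_dims = [n_features] + widths + [self.cfg.latent_width]
        dec_dims = enc_dims[::-1]
        bottleneck_bn = getattr(self.cfg, "bottleneck", "bn_relu") == "bn_relu"
        self.encoder = [_Dense(a, b, rng) for a, b in zip(enc_dims[:-1], enc_dims[1:-1])]
        self.encoder.append(_Dense(enc_dims[-2], enc_dims[-1], rng,
                                   activated=bottleneck_bn))
        self.decoder = [_Dense(a, b, rng) for a, b in zip(dec_dims[:-1], dec_dims[1:-1])]
        self.decoder.append(_Dense(dec_dims[-2], dec_dims[-1], rng, activated=False))
        self.loss_history: list[float] = []
        self._adam_state = None

    # -- inference ----------------------------------------------------------

    def _check(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=_F32)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected (n, {self.n_features}) features, got {X.shape}")
        if not np.all(np.isfinite(X)):
            raise ValueError("features must be finite")
        return X

    def encode(self, X: np.ndarray) -> np.ndarray:
        X = self._check(X)
        for layer in self.encoder:
            X = layer.forward(X, training=False)
        return X

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        Z = self.encode(X)
        for layer in self.decoder:
            Z = layer.forward(Z, training=False)
        return Z

    # -- training -----------------------------------------------------------

    def fit(self, X: np.ndarray) -> "Autoencoder":
        cfg = self.cfg
        X = self._check(X)
        rng = default_rng(cfg.seed + 1)
        layers = self.encoder + self.decoder
        # flatten all parameters into one buffer so the Adam update is four
        # vector operations instead of dozens of small-array ones
        shapes = [p.shape for l in layers for p in l.params()]
        sizes = [int(np.prod(s)) for s in shapes]
        offsets = np.concatenate(([0], np.cumsum(sizes)))
        flat = np.empty(offsets[-1], dtype=_F32)
        views = []
        i = 0
        for l in layers:
            for p in l.params():
                view = flat[offsets[i]:offsets[i + 1]].reshape(p.shape)
                view[...] = p
                views.append(view)
                i += 1
        # rebind layer parameters to the flat-buffer views
        i = 0
        for l in layers:
            names = ["W", "b", "gamma", "beta"] if l.activated else ["W", "b"]
            for name in names:
                setattr(l, name, views[i])
                i += 1
        gflat = np.zeros_like(flat)
        gviews = [gflat[offsets[i]:offsets[i + 1]].reshape(shapes[i])
                  for i in range(len(shapes))]
        # per-layer slices of the gradient views, in params order
        gslices = []
        i = 0
        for l in layers:
            np_ = len(l.params())
            gslices.append(gviews[i:i + np_])
            i += np_
        m = np.zeros_like(flat)
        v = np.zeros_like(flat)
        t = 0
        n = X.shape[0]
        lam = _F32(cfg.l1_weight)
        b1, b2 = _F32(1 - cfg.beta1), _F32(1 - cfg.beta2)
        for _epoch in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for s in range(0, n, cfg.batch_size):
                xb = X[order[s:s + cfg.batch_size]]
                # forward
                acts = []          # post-ReLU encoder activations (penalized)
                h = xb
                for layer in self.encoder:
                    h = layer.forward(h, training=True)
                    acts.append(h)
                for layer in self.decoder:
                    h = layer.forward(h, training=True)
                err = h - xb
                mse = float(np.mean(err * err))
                l1 = float(sum(np.abs(a).mean() for a in acts))
                epoch_loss += mse + cfg.l1_weight * l1
                n_batches += 1
                # backward
                n_enc = len(self.encoder)
                d = _F32(2.0 / err.size) * err
                for li in range(len(self.decoder) - 1, -1, -1):
                    d = self.decoder[li].backward(d, gout=gslices[n_enc + li])
                for li in range(n_enc - 1, -1, -1):
                    a = acts[li]
                    d = add_l1_subgradient(np.ascontiguousarray(d), a,
                                           _F32(lam / a.size))
                    d = self.encoder[li].backward(d, gout=gslices[li])
                # fused Adam update on the flat buffers
                t += 1
                lr_t = _F32(cfg.learning_rate
                            * np.sqrt(1 - cfg.beta2**t) / (1 - cfg.beta1**t))
                adam_update(flat, gflat, m, v, lr_t, b1, b2, _F32(cfg.eps))
            self.loss_history.append(epoch_loss / max(1, n_batches))
        return self


def train_autoencoder(features: np.ndarray,
                      cfg: AutoencoderConfig | None = None) -> Autoencoder:
    """Train a fresh autoencoder on (bins x freqs) feature vectors."""
    features = np.asarray(features)
    ae = Autoencoder(features.shape[1], cfg)
    return ae.fit(features)


def encode_features(encoder: Autoencoder, features: np.ndarray) -> np.ndarray:
    """Deterministic 32-d latent per bin (batch norm in inference mode)."""
    return encoder.encode(features)
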