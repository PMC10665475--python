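"""Minimal seeded CNN engine for snippet classification.

A model is a set of convolutional branches over subsets of the input
channels, concatenated into a single sigmoid dense head:

    branch:  conv1d(n_filters x filter_len, valid) -> ReLU -> dropout
             -> non-overlapping max-pool -> flatten
    head:    concat(branches) -> dense(1) -> sigmoid

Training is plain mini-batch Adam on (optionally class-weighted) binary
cross-entropy.  Everything — initialization, dropout masks, shuffling — draws
from one ``numpy.random.Generator``, so a fixed seed gives bit-reproducible
training on CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import RespFusionError


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _Adam:
    """Adam optimizer state over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class _Branch:
    channels: tuple[int, ...]   # indices into the snippet channel axis
    W: np.ndarray               # (n_filters, len(channels), filter_len)
    b: np.ndarray               # (n_filters,)


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)


class CNNModel:
    """Branched 1-D CNN with a single sigmoid output.

    Parameters
    ----------
    branch_channels : list of tuple of int
        One entry per branch: the input-channel indices that branch convolves
        jointly.  ``[(0, 1, 2, 3)]`` is early fusion over four channels;
        ``[(0,), (1,), (2,), (3,)]`` one branch per channel.
    """

    def __init__(
        self,
        branch_channels: list[tuple[int, ...]],
        n_channels: int,
        snippet_len: int = 201,
        n_filters: int = 4,
        filter_len: int = 20,
        pool_size: int = 4,
        dropout: float = 0.5,
        seed: int = 0,
    ):
        if not branch_channels:
            raise RespFusionError("model needs at least one branch")
        if snippet_len < filter_len:
            raise RespFusionError("snippet shorter than the conv filter")
        self.n_channels = n_channels
        self.snippet_len = snippet_len
        self.n_filters = n_filters
        self.filter_len = filter_len
        self.pool_size = pool_size
        self.dropout = dropout
        self.seed = seed
        self.conv_len = snippet_len - filter_len + 1
        self.pooled_len = self.conv_len // pool_size
        if self.pooled_len < 1:
            raise RespFusionError("pool size larger than the conv output")

        rng = np.random.default_rng(seed)
        self.branches: list[_Branch] = []
        for chans in branch_channels:
            chans = tuple(int(c) for c in chans)
            if any(c < 0 or c >= n_channels for c in chans):
                raise RespFusionError(f"branch channels {chans} out of range")
            fan_in = len(chans) * filter_len
            W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(n_filters, len(chans), filter_len))
            self.branches.append(_Branch(chans, W, np.zeros(n_filters)))
        dense_in = len(self.branches) * n_filters * self.pooled_len
        self.dense_W = rng.normal(0.0, np.sqrt(1.0 / dense_in), size=dense_in)
        self.dense_b = np.zeros(1)
        self.trained = False

    # ------------------------------------------------------------------ API

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    @property
    def n_params(self) -> int:
        conv = sum(br.W.size + br.b.size for br in self.branches)
        return conv + self.dense_W.size + self.dense_b.size

    def _params(self) -> list[np.ndarray]:
        out = []
        for br in self.branches:
            out += [br.W, br.b]
        out += [self.dense_W, self.dense_b]
        return out

    # ------------------------------------------------------------- forward

    def _forward(self, x: np.ndarray, drop_rng: np.random.Generator | None):
        """Forward pass; returns (scores, cache for backward).

        ``drop_rng`` enables inverted dropout (training mode) when given.
        """
        B = x.shape[0]
        feats, cache = [], []
        for br in self.branches:
            xc = np.ascontiguousarray(x[:, br.channels, :])
            xw = np.lib.stride_tricks.sliding_window_view(xc, self.filter_len, axis=2)
            z = np.einsum("bclk,fck->bfl", xw, br.W, optimize=True) + br.b[None, :, None]
            a = np.maximum(z, 0.0)
            if drop_rng is not None and self.dropout > 0:
                keep = 1.0 - self.dropout
                mask = (drop_rng.random(a.shape) < keep) / keep
                a = a * mask
            else:
                mask = None
            crop = self.pooled_len * self.pool_size
            ar = a[:, :, :crop].reshape(B, self.n_filters, self.pooled_len, self.pool_size)
            arg = ar.argmax(axis=3)
            pooled = np.take_along_axis(ar, arg[..., None], axis=3)[..., 0]
            feats.append(pooled.reshape(B, -1))
            cache.append((xw, z, mask, arg))
        h = np.concatenate(feats, axis=1)
        scores = sigmoid(h @ self.dense_W + self.dense_b[0])
        return scores, (h, cache)

    def predict_scores(self, x: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        """Sigmoid outputs in [0, 1], evaluated in inference mode."""
        x = np.asarray(x)
        out = np.empty(x.shape[0])
        for i in range(0, x.shape[0], batch_size):
            out[i : i + batch_size] = self._forward(x[i : i + batch_size], None)[0]
        return out

    # ------------------------------------------------------------ training

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        *,
        epochs: int = 20,
        batch_size: int = 64,
        learning_rate: float = 1e-3,
        class_weighting: bool = True,
        seed: int | None = None,
    ) -> TrainHistory:
        """Mini-batch Adam on binary cross-entropy; deterministic given seed."""
        x = np.asarray(x)
        y = np.asarray(y, dtype=float)
        n = x.shape[0]
        if n == 0:
            raise RespFusionError("empty training set")
        n_pos = int(y.sum())
        if n_pos == 0 or n_pos == n:
            raise RespFusionError("training set must contain both classes")
        if class_weighting:
            w_pos = n / (2.0 * n_pos)
            w_neg = n / (2.0 * (n - n_pos))
        else:
            w_pos = w_neg = 1.0
        sample_w = np.where(y == 1, w_pos, w_neg)

        rng = np.random.default_rng(self.seed if seed is None else seed)
        opt = _Adam(self._params(), learning_rate)
        history = TrainHistory()
        for _ in range(epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for i in range(0, n, batch_size):
                idx = order[i : i + batch_size]
                xb, yb, wb = x[idx], y[idx], sample_w[idx]
                loss = self._step(xb, yb, wb, opt, rng)
                epoch_loss += loss * len(idx)
            history.loss.append(epoch_loss / n)
        self.trained = True
        return history

    def _step(self, xb, yb, wb, opt: _Adam, rng) -> float:
        B = xb.shape[0]
        scores, (h, cache) = self._forward(xb, rng)
        eps = 1e-12
        loss = -np.mean(wb * (yb * np.log(scores + eps) + (1 - yb) * np.log(1 - scores + eps)))
        # d loss / d logit, with the sigmoid folded in
        dlogit = wb * (scores - yb) / B
        g_dense_W = h.T @ dlogit
        g_dense_b = np.array([dlogit.sum()])
        dh = np.outer(dlogit, self.dense_W)

        grads: list[np.ndarray] = []
        width = self.n_filters * self.pooled_len
        for bi, (br, (xw, z, mask, arg)) in enumerate(zip(self.branches, cache)):
            dpool = dh[:, bi * width : (bi + 1) * width].reshape(
                B, self.n_filters, self.pooled_len
            )
            crop = self.pooled_len * self.pool_size
            da = np.zeros((B, self.n_filters, self.pooled_len, self.pool_size))
            np.put_along_axis(da, arg[..., None], dpool[..., None], axis=3)
            da_full = np.zeros_like(z)
            da_full[:, :, :crop] = da.reshape(B, self.n_filters, crop)
            if mask is not None:
                da_full *= mask
            dz = da_full * (z > 0)
            gW = np.einsum("bclk,bfl->fck", xw, dz, optimize=True)
            gb = dz.sum(axis=(0, 2))
            grads += [gW, gb]
        grads += [g_dense_W, g_dense_b]
        opt.step(self._params(), grads)
        return float(loss)
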