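"""A small convolutional network for 5-class frame scoring, in pure numpy.

Architecture (fixed shape, configurable widths): three 3x3 same-padded
conv blocks with ReLU and 2x2 max pooling, global average pooling, one
dense layer and a softmax over the five cleansing scores.  Optimisation
is RMSProp on the categorical cross-entropy.  At 64x64 input this trains
in minutes on a single CPU, which is the design point.

Convolutions are evaluated as matrix products over im2col patches so the
heavy lifting is a BLAS GEMM; the backward pass mirrors the forward
exactly, so the network is fully deterministic under a fixed seed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["SmallCNN"]

_K = 3  # conv kernel side, same padding


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N, H, W, C*9) patches of the 1-padded input."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (_K, _K), axis=(2, 3))
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n, h, w, c * _K * _K
    )


def _col2im(dcols: np.ndarray, n: int, c: int, h: int, w: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter patch gradients back."""
    d = dcols.reshape(n, h, w, c, _K, _K)
    dxp = np.zeros((n, c, h + 2, w + 2), dtype=dcols.dtype)
    for i in range(_K):
        for j in range(_K):
            dxp[:, :, i : i + h, j : j + w] += d[:, :, :, :, i, j].transpose(
                0, 3, 1, 2
            )
    return dxp[:, :, 1 : h + 1, 1 : w + 1]


def _maxpool(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2x2 max pooling; returns output and flat argmax for the backward."""
    n, c, h, w = x.shape
    xr = (
        x.reshape(n, c, h // 2, 2, w // 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, h // 2, w // 2, 4)
    )
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _maxpool_backward(dout: np.ndarray, idx: np.ndarray, h: int, w: int) -> np.ndarray:
    n, c, h2, w2 = dout.shape
    dxr = np.zeros((n, c, h2, w2, 4), dtype=dout.dtype)
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
    return (
        dxr.reshape(n, c, h2, w2, 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, h, w)
    )


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


class SmallCNN:
    """Three conv blocks (3x3, ReLU, 2x pool), GAP, dense, softmax."""

    def __init__(
        self,
        in_channels: int = 3,
        channels: Sequence[int] = (16, 32, 64),
        n_classes: int = 5,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ) -> None:
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_channels = int(in_channels)
        self.channels = tuple(int(c) for c in channels)
        self.n_classes = int(n_classes)
        self.dtype = np.dtype(dtype)
        self.params: dict[str, np.ndarray] = {}
        c_prev = self.in_channels
        for i, c_out in enumerate(self.channels):
            fan_in = c_prev * _K * _K
            self.params[f"W{i}"] = (
                rng.standard_normal((c_out, fan_in)) * np.sqrt(2.0 / fan_in)
            ).astype(self.dtype)
            self.params[f"b{i}"] = np.zeros(c_out, dtype=self.dtype)
            c_prev = c_out
        self.params["Wd"] = (
            rng.standard_normal((c_prev, self.n_classes)) * np.sqrt(2.0 / c_prev)
        ).astype(self.dtype)
        self.params["bd"] = np.zeros(self.n_classes, dtype=self.dtype)

    # ---- forward / backward -------------------------------------------

    def _forward(self, x: np.ndarray) -> tuple[np.ndarray, dict]:
        cache: dict = {"x_shape": x.shape, "cols": [], "relu": [], "pool": []}
        # channels arrive in [0, 1]; centre them for better conditioning
        a = x.astype(self.dtype, copy=False) - self.dtype.type(0.5)
        for i in range(len(self.channels)):
            n, c, h, w = a.shape
            cols = _im2col(a)
            z = cols @ self.params[f"W{i}"].T + self.params[f"b{i}"]
            z = z.transpose(0, 3, 1, 2)
            relu_mask = z > 0
            a = z * relu_mask
            a, pool_idx = _maxpool(a)
            cache["cols"].append((cols, (n, c, h, w)))
            cache["relu"].append(relu_mask)
            cache["pool"].append((pool_idx, (h, w)))
        cache["gap_in_shape"] = a.shape
        feat = a.mean(axis=(2, 3))
        cache["feat"] = feat
        logits = feat @ self.params["Wd"] + self.params["bd"]
        return logits, cache

    def _backward(self, probs: np.ndarray, targets: np.ndarray, cache: dict):
        n = probs.shape[0]
        grads: dict[str, np.ndarray] = {}
        dlogits = ((probs - targets) / n).astype(self.dtype)
        grads["Wd"] = cache["feat"].T @ dlogits
        grads["bd"] = dlogits.sum(axis=0)
        dfeat = dlogits @ self.params["Wd"].T
        nb, cb, hb, wb = cache["gap_in_shape"]
        da = np.broadcast_to(
            dfeat[:, :, None, None] / (hb * wb), (nb, cb, hb, wb)
        ).astype(self.dtype)
        for i in reversed(range(len(self.channels))):
            pool_idx, (h, w) = cache["pool"][i]
            dz = _maxpool_backward(da, pool_idx, h, w)
            dz *= cache["relu"][i]
            cols, (n_, c_, h_, w_) = cache["cols"][i]
            dz_flat = dz.transpose(0, 2, 3, 1).reshape(-1, self.channels[i])
            cols_flat = cols.reshape(-1, cols.shape[-1])
            grads[f"W{i}"] = dz_flat.T @ cols_flat
            grads[f"b{i}"] = dz_flat.sum(axis=0)
            if i > 0:
                dcols = dz_flat @ self.params[f"W{i}"]
                da = _col2im(dcols.reshape(n_, h_, w_, -1), n_, c_, h_, w_)
        return grads

    # ---- training / inference -----------------------------------------

    def loss_and_grads(self, x: np.ndarray, targets: np.ndarray):
        """Cross-entropy loss and parameter gradients for one batch."""
        logits, cache = self._forward(x)
        probs = _softmax(logits.astype(np.float64))
        eps = 1e-12
        loss = float(-(targets * np.log(probs + eps)).sum() / x.shape[0])
        grads = self._backward(probs.astype(self.dtype), targets.astype(self.dtype), cache)
        return loss, grads

    def fit(
        self,
        x: np.ndarray,
        targets: np.ndarray,
        lr: float,
        epochs: int,
        batch_size: int,
        rng: np.random.Generator,
        head_only: bool = False,
        rho: float = 0.9,
        eps: float = 1e-8,
        verbose: bool = False,
    ) -> list[float]:
        """RMSProp training for one phase; returns per-epoch mean losses."""
        n = x.shape[0]
        trainable = (
            ["Wd", "bd"]
            if head_only
            else list(self.params.keys())
        )
        sq = {k: np.zeros_like(self.params[k], dtype=np.float32) for k in trainable}
        history: list[float] = []
        for epoch in range(epochs):
            perm = rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                sel = perm[start : start + batch_size]
                loss, grads = self.loss_and_grads(x[sel], targets[sel])
                losses.append(loss)
                for k in trainable:
                    g = grads[k].astype(np.float32)
                    sq[k] = rho * sq[k] + (1 - rho) * g * g
                    self.params[k] -= (lr * g / (np.sqrt(sq[k]) + eps)).astype(
                        self.dtype
                    )
            history.append(float(np.mean(losses)))
            if verbose:
                print(f"epoch {epoch + 1}/{epochs} loss {history[-1]:.4f}")
        return history

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Softmax probabilities, shape (n, n_classes)."""
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.shape[1]}"
            )
        out = np.empty((x.shape[0], self.n_classes))
        for start in range(0, x.shape[0], batch_size):
            logits, _ = self._forward(x[start : start + batch_size])
            out[start : start + logits.shape[0]] = _softmax(
                logits.astype(np.float64)
            )
        return out

    # ---- persistence ---------------------------------------------------

    def describe(self) -> str:
        blocks = " -> ".join(
            f"conv3x3({c})/relu/pool2" for c in self.channels
        )
        return f"{blocks} -> gap -> dense({self.n_classes}) -> softmax"

    def save(self, path: str | Path) -> None:
        meta = np.array(
            [self.in_channels, self.n_classes, len(self.channels), *self.channels]
        )
        np.savez(Path(path).with_suffix(".npz"), _meta=meta, **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "SmallCNN":
        data = np.load(Path(path).with_suffix(".npz"))
        meta = data["_meta"]
        in_channels, n_classes, n_blocks = int(meta[0]), int(meta[1]), int(meta[2])
        channels = tuple(int(c) for c in meta[3 : 3 + n_blocks])
        net = cls(in_channels=in_channels, channels=channels, n_classes=n_classes)
        for k in net.params:
            net.params[k] = data[k]
        net.dtype = net.params["Wd"].dtype
        return net
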