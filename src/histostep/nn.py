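"""Minimal deterministic NumPy CNN backend.

A small 4-conv-block network (3x3 conv -> ReLU -> 2x2 max-pool, repeated,
then global average pooling and a linear classification head).  Everything is
plain float32 NumPy, single-threaded and bit-reproducible for a fixed seed,
which is what the training orchestration relies on.  Heavy backbones are out
of scope here; the architecture is pluggable at the training layer.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["SmallCNN", "softmax", "cross_entropy_losses"]

_CHANNELS = (8, 16, 32, 32)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_losses(probs: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-sample negative log-likelihood."""
    n = probs.shape[0]
    return -np.log(np.maximum(probs[np.arange(n), labels], 1e-12))


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """3x3 same-padding convolution.  x: (N, C, H, W); w: (F, C, 3, 3)."""
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    out = np.einsum("nchwij,fcij->nfhw", win, w, optimize=True) + b[None, :, None, None]
    return out, win


def _conv_backward(win: np.ndarray, w: np.ndarray, dout: np.ndarray):
    dw = np.einsum("nchwij,nfhw->fcij", win, dout, optimize=True)
    db = dout.sum(axis=(0, 2, 3))
    dp = np.pad(dout, ((0, 0), (0, 0), (1, 1), (1, 1)))
    dwin = np.lib.stride_tricks.sliding_window_view(dp, (3, 3), axis=(2, 3))
    dx = np.einsum("nfhwij,fcij->nchw", dwin, w[:, :, ::-1, ::-1], optimize=True)
    return dx, dw, db


def _pool_forward(x: np.ndarray):
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
    out = xr.max(axis=(3, 5))
    mask = xr == out[:, :, :, None, :, None]
    # Split gradient evenly across ties to keep backward deterministic.
    mask = mask / np.maximum(mask.sum(axis=(3, 5), keepdims=True), 1)
    return out, mask.astype(np.float32)


def _pool_backward(mask: np.ndarray, dout: np.ndarray):
    n, c, h2, _, w2, _ = mask.shape
    d = mask * dout[:, :, :, None, :, None]
    return d.reshape(n, c, h2 * 2, w2 * 2)


class SmallCNN:
    """4-conv-block CNN with a swappable linear head.

    Parameters live in ``self.params`` keyed ``conv{i}_w/b`` and
    ``head_w/head_b``; the head is everything the class-count swap touches.
    """

    def __init__(self, n_classes: int, input_channels: int = 3, seed: int = 0):
        if n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        self.n_classes = n_classes
        self.input_channels = input_channels
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        c_in = input_channels
        for i, c_out in enumerate(_CHANNELS):
            scale = np.sqrt(2.0 / (c_in * 9))
            self.params[f"conv{i}_w"] = (
                rng.normal(0, scale, (c_out, c_in, 3, 3)).astype(np.float32)
            )
            self.params[f"conv{i}_b"] = np.zeros(c_out, dtype=np.float32)
            c_in = c_out
        self._feature_dim = c_in
        self._init_head(rng)

    def _init_head(self, rng: np.random.Generator) -> None:
        scale = np.sqrt(2.0 / self._feature_dim)
        self.params["head_w"] = rng.normal(
            0, scale, (self.n_classes, self._feature_dim)
        ).astype(np.float32)
        self.params["head_b"] = np.zeros(self.n_classes, dtype=np.float32)

    # -- head management -------------------------------------------------
    HEAD_KEYS = ("head_w", "head_b")

    def reinit_head(self, n_classes: int, seed: int) -> None:
        """Re-initialize the head for ``n_classes`` outputs (never a no-op)."""
        if n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        self.n_classes = n_classes
        self._init_head(np.random.default_rng(seed))

    def backbone_checksum(self) -> str:
        """SHA-256 over all non-head parameters, in key order."""
        digest = hashlib.sha256()
        for key in sorted(self.params):
            if key in self.HEAD_KEYS:
                continue
            digest.update(key.encode())
            digest.update(np.ascontiguousarray(self.params[key]).tobytes())
        return digest.hexdigest()

    def copy(self) -> "SmallCNN":
        clone = SmallCNN.__new__(SmallCNN)
        clone.n_classes = self.n_classes
        clone.input_channels = self.input_channels
        clone._feature_dim = self._feature_dim
        clone.params = {k: v.copy() for k, v in self.params.items()}
        return clone

    # -- forward / backward ---------------------------------------------
    def forward(self, x: np.ndarray, cache: dict | None = None) -> np.ndarray:
        """Logits for a (N, H, W, 3) float batch; H and W divisible by 16."""
        a = np.ascontiguousarray(np.moveaxis(x, -1, 1), dtype=np.float32)
        if cache is not None:
            cache["blocks"] = []
        for i in range(len(_CHANNELS)):
            z, win = _conv_forward(a, self.params[f"conv{i}_w"], self.params[f"conv{i}_b"])
            relu_mask = z > 0
            a = z * relu_mask
            a, pool_mask = _pool_forward(a)
            if cache is not None:
                cache["blocks"].append((win, relu_mask, pool_mask))
        feats = a.mean(axis=(2, 3))
        if cache is not None:
            cache["feats"] = feats
            cache["spatial"] = a.shape[2:]
        return feats @ self.params["head_w"].T + self.params["head_b"]

    def backward(self, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        feats = cache["feats"]
        grads["head_w"] = (dlogits.T @ feats).astype(np.float32)
        grads["head_b"] = dlogits.sum(axis=0).astype(np.float32)
        dfeats = dlogits @ self.params["head_w"]
        h, w = cache["spatial"]
        da = np.broadcast_to(
            dfeats[:, :, None, None] / (h * w),
            (dfeats.shape[0], dfeats.shape[1], h, w),
        ).astype(np.float32)
        for i in reversed(range(len(_CHANNELS))):
            win, relu_mask, pool_mask = cache["blocks"][i]
            dz = _pool_backward(pool_mask, da) * relu_mask
            da, grads[f"conv{i}_w"], grads[f"conv{i}_b"] = _conv_backward(
                win, self.params[f"conv{i}_w"], dz
            )
        return grads

    def sgd_step(self, grads: dict[str, np.ndarray], lr: float) -> None:
        for key, g in grads.items():
            self.params[key] -= np.float32(lr) * g

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            out.append(softmax(self.forward(x[i : i + batch_size])))
        return np.concatenate(out, axis=0)
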