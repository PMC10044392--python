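"""Minimal NumPy convolutional-network engine for the U-Net segmenter.

A deliberately small, fully deterministic engine: same-padded 3x3
convolutions, ReLU, 2x2 max-pooling, nearest-neighbour upsampling with
skip concatenation, a 1x1 sigmoid head, hand-derived backpropagation and
an Adam optimizer.  Everything is float32 NumPy; given the same seed and
inputs, forward passes, gradients and updates are bit-identical across
runs, which the pipeline's reproducibility contract relies on.

Tensors are NHWC.  Convolution is computed as nine shifted matrix
products (one per kernel tap), which keeps peak memory low at the sizes
this engine targets (tens of pixels per side, tens of channels).
"""

from __future__ import annotations

import numpy as np

__all__ = ["UNetCore", "Adam", "focal_loss_and_grad"]

_EPS = 1e-7


# ---------------------------------------------------------------------------
# primitive ops


def _conv3x3(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padded 3x3 convolution; x (N,H,W,Ci), w (3,3,Ci,Co)."""
    n, h, wd, _ = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    out = np.broadcast_to(b, (n, h, wd, b.shape[0])).copy()
    for i in range(3):
        for j in range(3):
            out += xp[:, i : i + h, j : j + wd, :] @ w[i, j]
    return out


def _conv3x3_backward(
    x: np.ndarray, w: np.ndarray, dout: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, h, wd, ci = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    dxp = np.zeros_like(xp)
    dw = np.zeros_like(w)
    for i in range(3):
        for j in range(3):
            patch = xp[:, i : i + h, j : j + wd, :]
            dw[i, j] = np.tensordot(patch, dout, axes=([0, 1, 2], [0, 1, 2]))
            dxp[:, i : i + h, j : j + wd, :] += dout @ w[i, j].T
    db = dout.sum(axis=(0, 1, 2))
    return dxp[:, 1:-1, 1:-1, :], dw, db


def _maxpool2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, h, w, c = x.shape
    xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
    out = xr.max(axis=(2, 4))
    # tie-splitting mask (gradient shared among tied maxima)
    mask = xr == out[:, :, None, :, None, :]
    mask = mask / mask.sum(axis=(2, 4), keepdims=True)
    return out, mask.reshape(x.shape).astype(np.float32)


def _maxpool2_backward(dout: np.ndarray, mask: np.ndarray) -> np.ndarray:
    n, hh, ww, c = dout.shape
    up = np.repeat(np.repeat(dout, 2, axis=1), 2, axis=2)
    return up * mask


def _upsample2(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)


def _upsample2_backward(dout: np.ndarray) -> np.ndarray:
    n, h, w, c = dout.shape
    return dout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


# ---------------------------------------------------------------------------
# loss


def focal_loss_and_grad(
    y: np.ndarray, z: np.ndarray, alpha: float, gamma: float
) -> tuple[float, np.ndarray]:
    """Mean binary focal loss and its gradient w.r.t. the logit ``z``.

    ``gamma=0`` reduces to alpha-weighted binary cross-entropy.
    """
    y = y.astype(np.float64)
    p = 1.0 / (1.0 + np.exp(-z.astype(np.float64)))
    p = np.clip(p, _EPS, 1.0 - _EPS)
    omp = 1.0 - p
    log_p, log_omp = np.log(p), np.log(omp)
    loss = -alpha * y * omp**gamma * log_p - (1.0 - alpha) * (1.0 - y) * p**gamma * log_omp
    # dL/dp, then chain through the sigmoid; the clip keeps the gamma-1
    # powers finite, and they are multiplied by gamma (= 0 when gamma=0)
    dldp = alpha * y * (gamma * omp ** (gamma - 1.0) * log_p - omp**gamma / p) + (
        1.0 - alpha
    ) * (1.0 - y) * (p**gamma / omp - gamma * p ** (gamma - 1.0) * log_omp)
    dz = dldp * p * omp / y.size
    return float(loss.mean()), dz.astype(np.float32)


# ---------------------------------------------------------------------------
# network


class UNetCore:
    """Encoder-decoder with skip connections and a single-logit head.

    depth : number of 2x downsampling stages (resolution levels = depth+1)
    base_width : channels at full resolution; doubled per level
    """

    def __init__(self, in_channels: int = 3, base_width: int = 8, depth: int = 2,
                 seed: int = 0) -> None:
        if depth < 1:
            raise ValueError("depth must be >= 1")
        self.in_channels = in_channels
        self.base_width = base_width
        self.depth = depth
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}

        def add_conv(name: str, ci: int, co: int, k: int = 3) -> None:
            fan_in = k * k * ci
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(k, k, ci, co))
            self.params[f"{name}_w"] = w.astype(np.float32)
            self.params[f"{name}_b"] = np.zeros(co, dtype=np.float32)

        w0 = base_width
        ci = in_channels
        for level in range(depth):
            co = w0 * (2**level)
            add_conv(f"enc{level}_c1", ci, co)
            add_conv(f"enc{level}_c2", co, co)
            ci = co
        cb = w0 * (2**depth)
        add_conv("bot_c1", ci, cb)
        add_conv("bot_c2", cb, cb)
        ci = cb
        for level in reversed(range(depth)):
            skip = w0 * (2**level)
            add_conv(f"dec{level}_c1", ci + skip, skip)
            add_conv(f"dec{level}_c2", skip, skip)
            ci = skip
        add_conv("head", ci, 1, k=1)

    # -- parameter plumbing -------------------------------------------------

    def n_parameters(self) -> int:
        return sum(int(p.size) for p in self.params.values())

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        if set(weights) != set(self.params):
            raise ValueError("weight keys do not match this architecture")
        for k, v in weights.items():
            if v.shape != self.params[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            self.params[k] = v.astype(np.float32).copy()

    # -- forward / backward -------------------------------------------------

    def _block(self, name: str, x: np.ndarray, cache: list) -> np.ndarray:
        for conv in (f"{name}_c1", f"{name}_c2"):
            pre = _conv3x3(x, self.params[f"{conv}_w"], self.params[f"{conv}_b"])
            out = np.maximum(pre, 0.0)
            cache.append((conv, x, pre > 0))
            x = out
        return x

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """Logits (N,H,W) for images (N,H,W,3) in [0,1] float32."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        n, h, w, _ = x.shape
        div = 2**self.depth
        if h % div or w % div:
            raise ValueError(f"input size must be divisible by {div}, got {h}x{w}")
        cache: list = []
        skips = []
        for level in range(self.depth):
            x = self._block(f"enc{level}", x, cache)
            skips.append(x)
            x, mask = _maxpool2(x)
            cache.append(("pool", mask, None))
        x = self._block("bot", x, cache)
        for level in reversed(range(self.depth)):
            x = _upsample2(x)
            skip = skips[level]
            x = np.concatenate([skip, x], axis=-1)
            cache.append(("concat", skip.shape[-1], None))
            x = self._block(f"dec{level}", x, cache)
        hw = self.params["head_w"][0, 0]
        z = (x @ hw + self.params["head_b"]).squeeze(-1)
        cache.append(("head", x, None))
        if want_cache:
            return z, cache
        return z

    def backward(self, cache: list, dz: np.ndarray) -> dict[str, np.ndarray]:
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        tag, x_head, _ = cache.pop()
        assert tag == "head"
        dhead = dz[..., None].astype(np.float32)
        grads["head_w"][0, 0] = np.tensordot(x_head, dhead, axes=([0, 1, 2], [0, 1, 2]))
        grads["head_b"][:] = dhead.sum(axis=(0, 1, 2))
        dx = dhead @ self.params["head_w"][0, 0].T

        # skip-connection gradients accumulate as the decoder unwinds
        pending_skip: list[np.ndarray] = []
        while cache:
            tag, a, b = cache.pop()
            if tag == "pool":
                dskip = pending_skip.pop()
                dx = _maxpool2_backward(dx, a) + dskip
            elif tag == "concat":
                skip_ch = a
                pending_skip.append(dx[..., :skip_ch].copy())
                dx = _upsample2_backward(dx[..., skip_ch:])
            else:  # conv layer inside a block
                conv, x_in, relu_mask = tag, a, b
                dpre = dx * relu_mask
                dx, dw, db = _conv3x3_backward(x_in, self.params[f"{conv}_w"], dpre)
                grads[f"{conv}_w"] = dw
                grads[f"{conv}_b"] = db
        return grads


class Adam:
    """Adam with bias correction; state keyed by parameter name."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for k, p in params.items():
            g = grads[k]
            m = self.m.setdefault(k, np.zeros_like(p))
            v = self.v.setdefault(k, np.zeros_like(p))
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)
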