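"""Minimal CPU convolutional network: im2col conv blocks, AdamW, CE and L1 losses.

A deliberately small, fully deterministic NumPy implementation sized for
desk-scale experiments: stride-2 3x3 conv blocks with ReLU, global
mean+max pooling, and a linear head. The conv stack is the "base" (the transferable
representation); the head is task-specific and can be swapped, so the same
backbone supports taxonomic classification and, after fine-tuning with an
optionally frozen base, biomass regression.

Shapes follow the (N, C, H, W) convention; input sizes must be divisible by
2**n_blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray, stride: int = 2):
    """3x3 conv, pad 1, given stride. Returns output and backward cache."""
    n, c, h, w = x.shape
    cout = W.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))[:, :, ::stride, ::stride]
    ho, wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * 9)
    out = cols @ W.reshape(cout, -1).T + b
    cache = (cols, x.shape, W, stride, ho, wo)
    return np.ascontiguousarray(out.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)), cache


def _conv_backward(dy: np.ndarray, cache):
    cols, xshape, W, stride, ho, wo = cache
    n, c, h, w = xshape
    cout = W.shape[0]
    dyf = dy.transpose(0, 2, 3, 1).reshape(-1, cout)
    dW = (dyf.T @ cols).reshape(W.shape)
    db = dyf.sum(axis=0)
    dcols = (dyf @ W.reshape(cout, -1)).reshape(n, ho, wo, c, 3, 3)
    dxp = np.zeros((n, c, h + 2, w + 2), dtype=dy.dtype)
    for ki in range(3):
        for kj in range(3):
            dxp[:, :, ki : ki + stride * ho : stride, kj : kj + stride * wo : stride] += (
                dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
            )
    return dxp[:, :, 1 : h + 1, 1 : w + 1], dW, db


@dataclass
class ConvNet:
    """Stride-2 conv backbone + linear head over pooled (mean ++ max) features."""

    input_size: int
    n_out: int
    channels: tuple[int, ...] = (8, 16, 32)
    params: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def init(cls, input_size: int, n_out: int, channels: tuple[int, ...], seed: int) -> "ConvNet":
        if input_size % (2 ** len(channels)) != 0:
            raise ValueError(
                f"input size {input_size} must be divisible by 2**{len(channels)}"
            )
        rng = np.random.default_rng(seed)
        params: dict[str, np.ndarray] = {}
        cin = 1
        for i, cout in enumerate(channels):
            fan_in = cin * 9
            params[f"conv{i}_W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, cin, 3, 3)).astype(np.float32)
            params[f"conv{i}_b"] = np.zeros(cout, dtype=np.float32)
            cin = cout
        params["head_W"] = rng.normal(0.0, np.sqrt(1.0 / (2 * cin)), (2 * cin, n_out)).astype(np.float32)
        params["head_b"] = np.zeros(n_out, dtype=np.float32)
        return cls(input_size=input_size, n_out=n_out, channels=tuple(channels), params=params)

    @property
    def base_keys(self) -> list[str]:
        return [k for k in self.params if k.startswith("conv")]

    @property
    def head_keys(self) -> list[str]:
        return ["head_W", "head_b"]

    def replace_head(self, n_out: int, seed: int) -> "ConvNet":
        """New task head over the same base (transfer-learning step)."""
        rng = np.random.default_rng(seed)
        cin = self.channels[-1]
        params = {k: v.copy() for k, v in self.params.items() if k.startswith("conv")}
        params["head_W"] = rng.normal(0.0, np.sqrt(1.0 / (2 * cin)), (2 * cin, n_out)).astype(np.float32)
        params["head_b"] = np.zeros(n_out, dtype=np.float32)
        return ConvNet(self.input_size, n_out, self.channels, params)

    def forward(self, x: np.ndarray, want_cache: bool = False):
        caches = []
        h = x
        for i in range(len(self.channels)):
            h, cache = _conv_forward(h, self.params[f"conv{i}_W"], self.params[f"conv{i}_b"])
            mask = h > 0
            h = h * mask
            caches.append((cache, mask))
        # global mean + max pooling: the mean carries bulk/size, the max the
        # presence of distinctive local parts wherever they landed
        n, c, hh, ww = h.shape
        flat = h.reshape(n, c, hh * ww)
        amax = flat.argmax(axis=2)
        feat = np.concatenate([flat.mean(axis=2), np.take_along_axis(flat, amax[:, :, None], 2)[:, :, 0]], axis=1)
        out = feat @ self.params["head_W"] + self.params["head_b"]
        if want_cache:
            return out, (caches, feat, h.shape, amax)
        return out

    def backward(self, dout: np.ndarray, cache, trainable: set[str]) -> dict[str, np.ndarray]:
        """Gradients for the trainable parameter subset given d(loss)/d(logits)."""
        caches, feat, hshape, amax = cache
        grads: dict[str, np.ndarray] = {}
        if "head_W" in trainable:
            grads["head_W"] = feat.T @ dout
            grads["head_b"] = dout.sum(axis=0)
        if not any(k.startswith("conv") for k in trainable):
            return grads
        n, c, hh, ww = hshape
        dfeat = dout @ self.params["head_W"].T
        dmean, dmax = dfeat[:, :c], dfeat[:, c:]
        dflat = np.broadcast_to(dmean[:, :, None] / (hh * ww), (n, c, hh * ww)).copy()
        np.put_along_axis(
            dflat, amax[:, :, None], np.take_along_axis(dflat, amax[:, :, None], 2) + dmax[:, :, None], 2
        )
        dh = dflat.reshape(hshape)
        for i in reversed(range(len(self.channels))):
            conv_cache, mask = caches[i]
            dh = dh * mask
            dh, dW, db = _conv_backward(dh, conv_cache)
            grads[f"conv{i}_W"] = dW
            grads[f"conv{i}_b"] = db
        return grads

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        outs = [self.forward(x[i : i + batch_size]) for i in range(0, len(x), batch_size)]
        return np.concatenate(outs) if outs else np.empty((0, self.n_out))

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}


class AdamW:
    """Decoupled weight decay Adam over a named parameter subset."""

    def __init__(
        self,
        keys: list[str],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-4,
    ) -> None:
        self.keys = list(keys)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.betas
        for k in self.keys:
            g = grads[k]
            self.m[k] = b1 * self.m.get(k, 0.0) + (1 - b1) * g
            self.v[k] = b2 * self.v.get(k, 0.0) + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * params[k])


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean CE loss and gradient w.r.t. logits; y holds integer class ids."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = len(y)
    loss = -np.log(np.maximum(p[np.arange(n), y], 1e-12)).mean()
    grad = p
    grad[np.arange(n), y] -= 1.0
    return float(loss), grad / n


def l1_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute deviation and gradient w.r.t. predictions (column vectors)."""
    diff = pred - target
    return float(np.abs(diff).mean()), np.sign(diff) / diff.size


def augment_batch(
    x: np.ndarray, rng: np.random.Generator, policy: str = "flips_rotations"
) -> np.ndarray:
    """One randomly chosen lattice transform per image (aspect preserved).

    ``flips_rotations`` samples from the square's eight symmetries — the
    augmentation set used for biomass fine-tuning, where apparent size must
    be preserved. ``trivial`` draws one op per image from symmetries, small
    cyclic translations, or mild rescaling, following the
    trivial-augmentation recipe; the rescale op deliberately breaks the
    absolute-size cue so classifiers must rely on shape.
    """
    if policy not in ("flips_rotations", "trivial"):
        raise ValueError(f"unknown augmentation policy {policy!r}")
    out = x.copy()
    ops = rng.integers(0, 8, size=len(x))
    kinds = (
        rng.integers(0, 3, size=len(x))
        if policy == "trivial"
        else np.zeros(len(x), dtype=int)
    )
    for i, op in enumerate(ops):
        img = out[i]
        if kinds[i] == 1:
            dy, dx = rng.integers(-6, 7, size=2)
            img = np.roll(img, (int(dy), int(dx)), axis=(1, 2))
        elif kinds[i] == 2:
            img = _rescale_center(img, float(rng.uniform(0.7, 1.35)))
        else:
            if op >= 4:
                img = img[:, :, ::-1]  # horizontal flip
            img = np.rot90(img, k=op % 4, axes=(1, 2))
        out[i] = img
    return out


def _rescale_center(img: np.ndarray, f: float) -> np.ndarray:
    """Zoom a (1, H, W) image about its center, crop or pad back to H x W."""
    from scipy.ndimage import zoom

    _, h, w = img.shape
    z = zoom(img[0], f, order=1)
    out = np.full((h, w), img[0, 0, 0], dtype=img.dtype)
    zh, zw = z.shape
    if zh >= h:
        top, left = (zh - h) // 2, (zw - w) // 2
        out[:, :] = z[top : top + h, left : left + w]
    else:
        top, left = (h - zh) // 2, (w - zw) // 2
        out[top : top + zh, left : left + zw] = z
    return out[None]
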