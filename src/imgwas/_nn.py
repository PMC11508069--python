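"""Minimal numpy implementation of the reference CNN.

Layers: three valid-padded 3x3 convolution blocks (ReLU + 2x2 max pooling),
flatten, dense-128 ReLU, dropout, dense-2 output. Forward/backward passes
are hand-derived; optimization is Adam. The implementation also exposes the
post-activation feature maps of the last convolutional layer together with
the gradient of a class score with respect to them, which is what
Grad-CAM++ saliency needs.

Everything is deterministic given the seeds of the generators passed in.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Valid 2-D correlation. x: (N,H,W,C), w: (k,k,C,F) -> (N,H-k+1,W-k+1,F)."""
    k = w.shape[0]
    cols = sliding_window_view(x, (k, k), axis=(1, 2))  # (N,Ho,Wo,C,k,k)
    out = np.einsum("nxycij,ijcf->nxyf", cols, w, optimize=True) + b
    return out, cols


def conv_backward(dout, cols, w, x_shape):
    k = w.shape[0]
    db = dout.sum(axis=(0, 1, 2))
    dw = np.einsum("nxycij,nxyf->ijcf", cols, dout, optimize=True)
    dx = np.zeros(x_shape, dtype=dout.dtype)
    ho, wo = dout.shape[1], dout.shape[2]
    for i in range(k):
        for j in range(k):
            dx[:, i : i + ho, j : j + wo, :] += np.einsum(
                "nxyf,cf->nxyc", dout, w[i, j], optimize=True
            )
    return dx, dw, db


def maxpool_forward(x: np.ndarray):
    """2x2/stride-2 max pooling; odd trailing rows/columns are dropped."""
    n, h, w, c = x.shape
    ho, wo = h // 2, w // 2
    xc = x[:, : ho * 2, : wo * 2, :]
    r = xc.reshape(n, ho, 2, wo, 2, c).transpose(0, 1, 3, 5, 2, 4).reshape(n, ho, wo, c, 4)
    arg = r.argmax(axis=-1)
    out = np.take_along_axis(r, arg[..., None], axis=-1)[..., 0]
    return out, (arg, x.shape)


def maxpool_backward(dout, cache):
    arg, x_shape = cache
    n, h, w, c = x_shape
    ho, wo = h // 2, w // 2
    dr = np.zeros((n, ho, wo, c, 4), dtype=dout.dtype)
    np.put_along_axis(dr, arg[..., None], dout[..., None], axis=-1)
    dxc = dr.reshape(n, ho, wo, c, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(n, ho * 2, wo * 2, c)
    dx = np.zeros(x_shape, dtype=dout.dtype)
    dx[:, : ho * 2, : wo * 2, :] = dxc
    return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SmallCNNNet:
    """The 8/16/32-filter CNN with dense-128 head and dropout."""

    def __init__(self, input_shape, conv_filters=(8, 16, 32), kernel=3,
                 dense_units=128, dropout=0.5, n_classes=2, rng=None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.conv_filters = tuple(conv_filters)
        self.kernel = int(kernel)
        self.dropout = float(dropout)
        h, w = input_shape
        c = 1
        self.params: dict[str, np.ndarray] = {}
        for li, f in enumerate(self.conv_filters, start=1):
            fan_in = self.kernel * self.kernel * c
            self.params[f"W{li}"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=(self.kernel, self.kernel, c, f)
            ).astype(np.float64)
            self.params[f"b{li}"] = np.zeros(f)
            h = (h - self.kernel + 1) // 2
            w = (w - self.kernel + 1) // 2
            if h < 1 or w < 1:
                raise ValueError("input image too small for three conv/pool blocks")
            c = f
        self.feature_shape = (h, w, c)
        flat = h * w * c
        self.params["Wd"] = rng.normal(0.0, np.sqrt(2.0 / flat), size=(flat, dense_units))
        self.params["bd"] = np.zeros(dense_units)
        self.params["Wo"] = rng.normal(0.0, np.sqrt(2.0 / dense_units), size=(dense_units, n_classes))
        self.params["bo"] = np.zeros(n_classes)

    # -- forward -----------------------------------------------------------

    def _forward(self, x: np.ndarray, train: bool, drop_rng=None):
        """x: (N,H,W) grayscale. Returns logits and the cache for backprop."""
        a = x[..., None].astype(np.float64)
        cache: dict[str, object] = {"x0": a.shape}
        for li in range(1, len(self.conv_filters) + 1):
            z, cols = conv_forward(a, self.params[f"W{li}"], self.params[f"b{li}"])
            r = np.maximum(z, 0.0)
            p, pc = maxpool_forward(r)
            cache[f"cols{li}"] = cols
            cache[f"ashape{li}"] = a.shape
            cache[f"relu{li}"] = z > 0
            cache[f"act{li}"] = r
            cache[f"pool{li}"] = pc
            a = p
        n = a.shape[0]
        flat = a.reshape(n, -1)
        zd = flat @ self.params["Wd"] + self.params["bd"]
        hd = np.maximum(zd, 0.0)
        if train and self.dropout > 0.0:
            mask = (drop_rng.random(hd.shape) >= self.dropout) / (1.0 - self.dropout)
            hd = hd * mask
            cache["drop"] = mask
        cache["flat"] = flat
        cache["zd"] = zd
        cache["hd"] = hd
        cache["pooled_shape"] = a.shape
        logits = hd @ self.params["Wo"] + self.params["bo"]
        return logits, cache

    def predict_logits(self, x: np.ndarray) -> np.ndarray:
        logits, _ = self._forward(x, train=False)
        return logits

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.predict_logits(x))

    # -- training ----------------------------------------------------------

    def loss(self, x: np.ndarray, y: np.ndarray) -> float:
        proba = self.predict_proba(x)
        eps = 1e-12
        return float(-np.mean(np.log(proba[np.arange(len(y)), y] + eps)))

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray, drop_rng):
        logits, cache = self._forward(x, train=True, drop_rng=drop_rng)
        n = len(y)
        proba = softmax(logits)
        eps = 1e-12
        loss = float(-np.mean(np.log(proba[np.arange(n), y] + eps)))
        dlogits = proba.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grads: dict[str, np.ndarray] = {}
        grads["Wo"] = cache["hd"].T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        dhd = dlogits @ self.params["Wo"].T
        if "drop" in cache:
            dhd = dhd * cache["drop"]
        dzd = dhd * (cache["zd"] > 0)
        grads["Wd"] = cache["flat"].T @ dzd
        grads["bd"] = dzd.sum(axis=0)
        dflat = dzd @ self.params["Wd"].T
        da = dflat.reshape(cache["pooled_shape"])
        for li in range(len(self.conv_filters), 0, -1):
            dr = maxpool_backward(da, cache[f"pool{li}"])
            dz = dr * cache[f"relu{li}"]
            da, grads[f"W{li}"], grads[f"b{li}"] = conv_backward(
                dz, cache[f"cols{li}"], self.params[f"W{li}"], cache[f"ashape{li}"]
            )
        return loss, grads

    # -- saliency hooks ----------------------------------------------------

    def last_conv_maps_and_grads(self, x: np.ndarray, class_index: int):
        """Post-ReLU feature maps A of the last conv layer and dS/dA, where S
        is the pre-softmax (linear) score of ``class_index``."""
        logits, cache = self._forward(x, train=False)
        n = len(x)
        last = len(self.conv_filters)
        a_maps = cache[f"act{last}"]
        dlogits = np.zeros_like(logits)
        dlogits[:, class_index] = 1.0
        dhd = dlogits @ self.params["Wo"].T
        dzd = dhd * (cache["zd"] > 0)
        dflat = dzd @ self.params["Wd"].T
        da = dflat.reshape(cache["pooled_shape"])
        d_amaps = maxpool_backward(da, cache[f"pool{last}"])
        return a_maps, d_amaps


class Adam:
    """Adam optimizer over a parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
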