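"""A compact seeded NumPy convolutional network for image classification.

Architecture (config-driven): a stack of valid 2-D convolution layers with
ReLU, each followed by 2x2 max pooling, then one fully connected hidden
layer and a softmax output.  Training is full-gradient Adam on the
cross-entropy loss.  All weights are drawn from a seeded generator, so
training is deterministic for a fixed configuration and seed.

The implementation favours clarity over throughput; it is intended for the
small inputs (tens of pixels per side) used in the segmented-thermogram
classification experiments.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import DegenerateTrainingError, ParameterError


def _conv_forward(x, w, b):
    """Valid correlation. x: (N,H,W,C), w: (kh,kw,C,F) -> (N,H',W',F)."""
    kh, kw = w.shape[:2]
    patches = sliding_window_view(x, (kh, kw), axis=(1, 2))  # N,H',W',C,kh,kw
    out = np.einsum("nhwckl,klcf->nhwf", patches, w, optimize=True) + b
    return out, patches


def _conv_backward(dout, patches, w, x_shape):
    dw = np.einsum("nhwckl,nhwf->klcf", patches, dout, optimize=True)
    db = dout.sum(axis=(0, 1, 2))
    n, h, wd, c = x_shape
    kh, kw = w.shape[:2]
    dx = np.zeros(x_shape)
    # scatter the kernel-weighted gradients back onto the input
    contrib = np.einsum("nhwf,klcf->nhwklc", dout, w,
                        optimize=True)  # N,H',W',kh,kw,C
    hh, ww = dout.shape[1], dout.shape[2]
    for ki in range(kh):
        for kj in range(kw):
            dx[:, ki:ki + hh, kj:kj + ww, :] += contrib[:, :, :, ki, kj, :]
    return dx, dw, db


def _pool_forward(x):
    """2x2 max pool, stride 2 (odd trailing row/col dropped)."""
    n, h, w, c = x.shape
    h2, w2 = h // 2, w // 2
    xc = x[:, : h2 * 2, : w2 * 2, :].reshape(n, h2, 2, w2, 2, c)
    out = xc.max(axis=(2, 4))
    mask = xc == out[:, :, None, :, None, :]
    return out, (mask, x.shape)


def _pool_backward(dout, cache):
    mask, x_shape = cache
    n, h, w, c = x_shape
    h2, w2 = h // 2, w // 2
    dxc = mask * dout[:, :, None, :, None, :]
    dx = np.zeros(x_shape)
    dx[:, : h2 * 2, : w2 * 2, :] = dxc.reshape(n, h2 * 2, w2 * 2, c)
    return dx


class SmallCNN:
    """Small conv-pool-dense classifier.

    Parameters
    ----------
    input_side : images are expected as (N, side, side, 3) float in [0, 1]
    conv_channels : filters per convolution layer (each followed by ReLU
        and 2x2 max pooling)
    kernel : square convolution kernel size
    hidden : width of the fully connected hidden layer
    global_pool : reduce the final feature maps by global max+mean pooling
        instead of flattening; far fewer dense weights, which curbs
        overfitting on small training sets and keys on localized activation
        peaks (the hot-spot signature) regardless of position
    epochs, lr, batch_size : Adam training schedule
    seed : seed for weight initialization and batch shuffling
    """

    def __init__(self, input_side: int = 32, conv_channels=(8, 16),
                 kernel: int = 3, hidden: int = 32, n_classes: int = 2,
                 global_pool: bool = True,
                 epochs: int = 100, lr: float = 3e-3, batch_size: int = 10,
                 seed: int = 0):
        if kernel % 2 == 0 or kernel < 1:
            raise ParameterError("kernel must be odd and positive")
        self.input_side = int(input_side)
        self.conv_channels = tuple(int(c) for c in conv_channels)
        self.kernel = int(kernel)
        self.hidden = int(hidden)
        self.n_classes = int(n_classes)
        self.global_pool = bool(global_pool)
        self.epochs = int(epochs)
        self.lr = float(lr)
        self.batch_size = int(batch_size)
        self.seed = int(seed)
        self.params_ = None
        self.classes_ = None

    # -- architecture -------------------------------------------------
    def _init_params(self, rng):
        params = {}
        side = self.input_side
        c_in = 3
        for li, c_out in enumerate(self.conv_channels):
            fan_in = self.kernel * self.kernel * c_in
            params[f"Wc{li}"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in),
                size=(self.kernel, self.kernel, c_in, c_out))
            params[f"bc{li}"] = np.zeros(c_out)
            side = (side - self.kernel + 1) // 2
            if side < 1:
                raise ParameterError("input side too small for the conv stack")
            c_in = c_out
        flat = 2 * c_in if self.global_pool else side * side * c_in
        params["W1"] = rng.normal(0.0, np.sqrt(2.0 / flat),
                                  size=(flat, self.hidden))
        params["b1"] = np.zeros(self.hidden)
        params["W2"] = rng.normal(0.0, np.sqrt(2.0 / self.hidden),
                                  size=(self.hidden, self.n_classes))
        params["b2"] = np.zeros(self.n_classes)
        return params

    def _forward(self, x, params):
        caches = []
        out = x
        for li in range(len(self.conv_channels)):
            z, patches = _conv_forward(out, params[f"Wc{li}"], params[f"bc{li}"])
            relu_mask = z > 0
            a = z * relu_mask
            pooled, pool_cache = _pool_forward(a)
            caches.append((patches, relu_mask, pool_cache, out.shape))
            out = pooled
        n = out.shape[0]
        if self.global_pool:
            gmax = out.max(axis=(1, 2))
            gmean = out.mean(axis=(1, 2))
            flat = np.concatenate([gmax, gmean], axis=1)
            head_cache = (out == gmax[:, None, None, :])
        else:
            flat = out.reshape(n, -1)
            head_cache = None
        h_pre = flat @ params["W1"] + params["b1"]
        h_mask = h_pre > 0
        h = h_pre * h_mask
        logits = h @ params["W2"] + params["b2"]
        return logits, (caches, out.shape, flat, h_mask, h, head_cache)

    def _backward(self, dlogits, cache, params):
        caches, conv_out_shape, flat, h_mask, h, head_cache = cache
        grads = {}
        grads["W2"] = h.T @ dlogits
        grads["b2"] = dlogits.sum(axis=0)
        dh = (dlogits @ params["W2"].T) * h_mask
        grads["W1"] = flat.T @ dh
        grads["b1"] = dh.sum(axis=0)
        dflat = dh @ params["W1"].T
        if self.global_pool:
            n, hh, ww, c = conv_out_shape
            dmax = dflat[:, :c]
            dmean = dflat[:, c:]
            max_mask = head_cache
            counts = max_mask.sum(axis=(1, 2), keepdims=True)
            dout = max_mask * (dmax[:, None, None, :] / counts)
            dout = dout + dmean[:, None, None, :] / (hh * ww)
        else:
            dout = dflat.reshape(conv_out_shape)
        for li in reversed(range(len(self.conv_channels))):
            patches, relu_mask, pool_cache, x_shape = caches[li]
            da = _pool_backward(dout, pool_cache)
            dz = da * relu_mask
            dout, grads[f"Wc{li}"], grads[f"bc{li}"] = _conv_backward(
                dz, patches, params[f"Wc{li}"], x_shape)
        return grads

    # -- API -----------------------------------------------------------
    def fit(self, images: np.ndarray, labels) -> "SmallCNN":
        x = np.asarray(images, dtype=np.float64)
        if x.ndim != 4 or x.shape[1] != self.input_side or x.shape[3] != 3:
            raise ParameterError(
                f"expected images of shape (N, {self.input_side}, "
                f"{self.input_side}, 3), got {x.shape}")
        labels = np.asarray(labels)
        self.classes_, y = np.unique(labels, return_inverse=True)
        if len(self.classes_) < 2:
            raise DegenerateTrainingError("training set has a single class")
        rng = np.random.default_rng(self.seed)
        params = self._init_params(rng)
        m = {k: np.zeros_like(v) for k, v in params.items()}
        v2 = {k: np.zeros_like(v) for k, v in params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        n = len(x)
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                sel = order[start:start + self.batch_size]
                xb, yb = x[sel], y[sel]
                logits, cache = self._forward(xb, params)
                shifted = logits - logits.max(axis=1, keepdims=True)
                expd = np.exp(shifted)
                probs = expd / expd.sum(axis=1, keepdims=True)
                dlogits = probs.copy()
                dlogits[np.arange(len(yb)), yb] -= 1.0
                dlogits /= len(yb)
                grads = self._backward(dlogits, cache, params)
                t += 1
                for k in params:
                    m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                    v2[k] = beta2 * v2[k] + (1 - beta2) * grads[k] ** 2
                    mhat = m[k] / (1 - beta1**t)
                    vhat = v2[k] / (1 - beta2**t)
                    params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)
        self.params_ = params
        return self

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        if self.params_ is None:
            raise ParameterError("model is not fitted")
        x = np.asarray(images, dtype=np.float64)
        if len(x) == 0:
            return np.zeros((0, self.n_classes))
        logits, _ = self._forward(x, self.params_)
        shifted = logits - logits.max(axis=1, keepdims=True)
        expd = np.exp(shifted)
        return expd / expd.sum(axis=1, keepdims=True)

    def predict(self, images: np.ndarray):
        probs = self.predict_proba(images)
        if len(probs) == 0:
            return np.asarray([], dtype=self.classes_.dtype if
                              self.classes_ is not None else float)
        return self.classes_[np.argmax(probs, axis=1)]
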