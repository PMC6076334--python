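"""Small encoder-decoder network for focus classification and cell search.

The network mirrors the architecture used throughout the toolkit: three
stride-2 convolution stages followed by three stride-2 deconvolution
(transposed convolution) stages, rectified-linear hidden activations and a
sigmoid on the final layer so every output pixel is a probability in (0, 1).
Everything — the im2col convolutions, backpropagation and the Adam
optimizer — is implemented on top of numpy so training runs in seconds on a
CPU for the image sizes this toolkit works with.

The quality score used for both training assessment and model comparison is
the average residual square (ARS): the root-mean-square per-pixel residual
between the network's probability map and a binary target mask.  An
untrained network scores about 0.5 against balanced binary masks; a perfect
prediction scores 0.
"""

from __future__ import annotations

import io
import json

import numpy as np

__all__ = [
    "Conv2D",
    "ConvTranspose2D",
    "EncoderDecoderNet",
    "TrainingDiverged",
    "ars",
    "train_adam",
    "cross_validate_training_size",
    "save_net",
    "load_net",
]


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


# ---------------------------------------------------------------------------
# im2col / col2im primitives (stride-2, pad-1, 3x3 by default)

def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, ho * wo)
    return np.ascontiguousarray(cols), (ho, wo)


def _col2im(cols: np.ndarray, xshape, k: int, stride: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add back to image layout)."""
    n, c, h, w = xshape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    cols6 = cols.reshape(n, c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            xp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += cols6[:, :, i, j]
    return xp[:, :, pad:pad + h, pad:pad + w]


class Conv2D:
    """3x3 stride-2 convolution, He-initialized."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 2,
                 pad: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        scale = np.sqrt(2.0 / (cin * k * k))
        self.W = rng.normal(0.0, scale, (cout, cin * k * k))
        self.b = np.zeros(cout)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, (ho, wo) = _im2col(x, self.k, self.stride, self.pad)
        self._cols, self._xshape = cols, x.shape
        y = np.einsum("kc,ncl->nkl", self.W, cols) + self.b[None, :, None]
        return y.reshape(x.shape[0], self.cout, ho, wo)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n = dy.shape[0]
        dyf = dy.reshape(n, self.cout, -1)
        self.dW = np.einsum("nkl,ncl->kc", dyf, self._cols)
        self.db = dyf.sum(axis=(0, 2))
        dcols = np.einsum("kc,nkl->ncl", self.W, dyf)
        return _col2im(dcols, self._xshape, self.k, self.stride, self.pad)

    def params(self):
        return [("W", self), ("b", self)]


class ConvTranspose2D:
    """3x3 stride-2 transposed convolution (doubles the spatial size)."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 2,
                 pad: int = 1, outpad: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.cin, self.cout, self.k = cin, cout, k
        self.stride, self.pad, self.outpad = stride, pad, outpad
        scale = np.sqrt(2.0 / (cin * k * k))
        self.W = rng.normal(0.0, scale, (cin, cout * k * k))
        self.b = np.zeros(cout)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def _out_size(self, h: int) -> int:
        return (h - 1) * self.stride - 2 * self.pad + self.k + self.outpad

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, cin, h, w = x.shape
        ho, wo = self._out_size(h), self._out_size(w)
        self._xf = x.reshape(n, cin, h * w)
        cols = np.einsum("cm,ncl->nml", self.W, self._xf)
        y = _col2im(cols, (n, self.cout, ho, wo), self.k, self.stride, self.pad)
        return y + self.b[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n = dy.shape[0]
        cols_dy, _ = _im2col(dy, self.k, self.stride, self.pad)
        self.dW = np.einsum("ncl,nml->cm", self._xf, cols_dy)
        self.db = dy.sum(axis=(0, 2, 3))
        dxf = np.einsum("cm,nml->ncl", self.W, cols_dy)
        n_, cin, _ = dxf.shape
        side_h = (dy.shape[2] + 2 * self.pad - self.k) // self.stride + 1
        side_w = (dy.shape[3] + 2 * self.pad - self.k) // self.stride + 1
        return dxf.reshape(n_, cin, side_h, side_w)

    def params(self):
        return [("W", self), ("b", self)]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask

    def params(self):
        return []


class _Sigmoid:
    def forward(self, x):
        self._y = 0.5 * (1.0 + np.tanh(0.5 * x))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)

    def params(self):
        return []


class EncoderDecoderNet:
    """Three convolution stages, three deconvolution stages, sigmoid output.

    Parameters
    ----------
    in_channels : input image channels (1 for all toolkit uses).
    widths : encoder channel widths; the decoder mirrors them.
    seed : initialization seed; two nets built with the same seed are
        identical.

    Input images must have height and width divisible by ``2**len(widths)``
    (8 for the default three-stage net); the output probability map has the
    same shape as the input.
    """

    def __init__(self, in_channels: int = 1, widths: tuple[int, ...] = (8, 16, 32),
                 seed: int | None = 0):
        rng = np.random.default_rng(seed)
        self.in_channels = in_channels
        self.widths = tuple(widths)
        self.layers: list = []
        cin = in_channels
        for wdt in widths:
            self.layers += [Conv2D(cin, wdt, rng=rng), _ReLU()]
            cin = wdt
        dec = list(widths[:-1][::-1]) + [in_channels]
        for i, wdt in enumerate(dec):
            self.layers.append(ConvTranspose2D(cin, wdt, rng=rng))
            self.layers.append(_Sigmoid() if i == len(dec) - 1 else _ReLU())
            cin = wdt

    # -- shape handling ----------------------------------------------------
    def _as_batch(self, image: np.ndarray) -> np.ndarray:
        x = np.asarray(image, dtype=np.float64)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        if x.ndim != 4:
            raise ValueError(f"expected 2-D, 3-D or 4-D input, got shape {image.shape}")
        div = 2 ** len(self.widths)
        if x.shape[2] % div or x.shape[3] % div:
            raise ValueError(
                f"input size {x.shape[2]}x{x.shape[3]} must be divisible by {div}")
        return x

    def forward(self, image: np.ndarray) -> np.ndarray:
        """Probability map with the same shape as the input image."""
        x = self._as_batch(image)
        for layer in self.layers:
            x = layer.forward(x)
        if np.asarray(image).ndim == 2:
            return x[0, 0]
        if np.asarray(image).ndim == 3:
            return x[:, 0]
        return x

    __call__ = forward

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self):
        out = []
        for layer in self.layers:
            for name, owner in layer.params():
                out.append((name, owner))
        return out


def ars(predicted: np.ndarray, target: np.ndarray) -> float:
    """Average residual square: RMS per-pixel residual against a target mask.

    Zero iff the prediction matches a binary target exactly; bounded by 1
    when predictions lie in [0, 1] and targets are binary.  The normalizer
    is the actual pixel count, generalizing the fixed 512x512 grid.
    """
    predicted = np.asarray(predicted, dtype=float)
    target = np.asarray(target, dtype=float)
    if predicted.shape != target.shape:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {target.shape}")
    return float(np.sqrt(np.mean((predicted - target) ** 2)))


class _Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(getattr(o, n)) for n, o in params]
        self.v = [np.zeros_like(getattr(o, n)) for n, o in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (name, owner) in enumerate(self.params):
            g = getattr(owner, "d" + name)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p = getattr(owner, name)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train_adam(net: EncoderDecoderNet, images: np.ndarray, targets: np.ndarray,
               *, epochs: int = 100, lr: float = 1e-3, betas=(0.9, 0.999),
               batch_size: int = 8, seed: int = 0, loss: str = "mse") -> dict:
    """Train ``net`` with Adam; returns the per-epoch loss trace.

    ``loss`` is mean squared error by default (consistent with the ARS used
    for evaluation); ``"bce"`` selects binary cross-entropy.  Raises
    :class:`TrainingDiverged` if the loss becomes non-finite.
    """
    images = np.asarray(images, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    if len(images) == 0:
        raise ValueError("empty training set")
    if images.shape != targets.shape:
        raise ValueError("images and targets must have matching shapes")
    rng = np.random.default_rng(seed)
    opt = _Adam(net.parameters(), lr=lr, betas=betas)
    n = len(images)
    initial = ars(net.forward(images), targets)
    trace = []
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            x = images[idx][:, None]
            d = targets[idx][:, None]
            y = x
            for layer in net.layers:
                y = layer.forward(y)
            if loss == "mse":
                batch_loss = float(np.mean((y - d) ** 2))
                dy = 2.0 * (y - d) / y.size
            elif loss == "bce":
                yc = np.clip(y, 1e-7, 1 - 1e-7)
                batch_loss = float(-np.mean(d * np.log(yc) + (1 - d) * np.log(1 - yc)))
                dy = (yc - d) / (yc * (1 - yc)) / y.size
            else:
                raise ValueError(f"unknown loss {loss!r}")
            if not np.isfinite(batch_loss):
                raise TrainingDiverged(f"loss became {batch_loss} during training")
            net.backward(dy)
            opt.step()
            epoch_loss += batch_loss * len(idx) / n
        trace.append(epoch_loss)
    final = ars(net.forward(images), targets)
    return {"trace": trace, "initial_ars": initial, "final_ars": final}


def cross_validate_training_size(images: np.ndarray, targets: np.ndarray,
                                 sizes, *, folds: int = 3, seed: int = 0,
                                 net_kwargs: dict | None = None,
                                 train_kwargs: dict | None = None):
    """Train/test ARS gap versus training-set size.

    For each requested size, ``folds`` networks are trained on random
    subsets of the pool and evaluated on the complementary images; the
    returned rows report the mean train ARS, test ARS and their distance.
    When the size equals the full pool the test set falls back to the
    training set, so the distance is 0 by construction.
    """
    import pandas as pd

    images = np.asarray(images, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    pool = len(images)
    net_kwargs = dict(net_kwargs or {})
    train_kwargs = dict(train_kwargs or {})
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        if size > pool:
            raise ValueError(f"size {size} exceeds pool size {pool}")
        tr_scores, te_scores = [], []
        for fold in range(folds):
            perm = rng.permutation(pool)
            tr, te = perm[:size], perm[size:]
            if len(te) == 0:
                te = tr
            net = EncoderDecoderNet(seed=int(rng.integers(2 ** 31)), **net_kwargs)
            train_adam(net, images[tr], targets[tr],
                       seed=int(rng.integers(2 ** 31)), **train_kwargs)
            tr_scores.append(ars(net.forward(images[tr]), targets[tr]))
            te_scores.append(ars(net.forward(images[te]), targets[te]))
        rows.append({"size": int(size),
                     "train_ars": float(np.mean(tr_scores)),
                     "test_ars": float(np.mean(te_scores)),
                     "distance": float(np.mean(te_scores) - np.mean(tr_scores))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Serialization: one binary settings file holding architecture + weights

def save_net(net: EncoderDecoderNet, path) -> None:
    meta = json.dumps({"in_channels": net.in_channels, "widths": list(net.widths)})
    arrays = {}
    for i, layer in enumerate(net.layers):
        if hasattr(layer, "W"):
            arrays[f"W{i}"] = layer.W
            arrays[f"b{i}"] = layer.b
    np.savez(path, meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_net(path) -> EncoderDecoderNet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        net = EncoderDecoderNet(in_channels=meta["in_channels"],
                                widths=tuple(meta["widths"]), seed=0)
        for i, layer in enumerate(net.layers):
            if hasattr(layer, "W"):
                layer.W = data[f"W{i}"].copy()
                layer.b = data[f"b{i}"].copy()
    return net
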