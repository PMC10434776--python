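"""Pixel-importance prediction: a small fully-convolutional network.

The importance-viewpoint prediction model (IVPM) maps a grayscale
layout image to a per-pixel importance map in [0, 1].  The architecture
follows the FCN-16s pattern: five stride-2 convolution stages reduce
the input 32x, a 1x1 score head reads the deepest features, the score
is upsampled 2x and summed with a second 1x1 score head applied to the
stride-16 stage (the skip connection), and the fused score is upsampled
16x back to input resolution.  The output passes through a sigmoid and
is trained with the real-valued sigmoid cross-entropy loss
(:func:`hudopt.metrics.sigmoid_xent`).

Everything is plain NumPy with hand-derived gradients: convolutions use
im2col, upsampling is a fixed bilinear interpolation matrix whose
adjoint is exact, and optimization is Adam on mini-batches.  The
network is deliberately tiny (a few thousand parameters) so it trains
from scratch on synthetic scenes in seconds; it is not a pretrained
VGG-scale backbone and makes no claim to natural-image performance.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .errors import HudoptError
from .metrics import LOSS_EPS, cross_correlation, kl_divergence

__all__ = ["ImportancePredictor", "train_ivpm", "evaluate_ivpm", "center_prior_map"]


# --------------------------------------------------------------------- #
# conv primitives (NCHW)


def _im2col(x: np.ndarray, k: int, s: int, p: int):
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    ho = (h + 2 * p - k) // s + 1
    wo = (w + 2 * p - k) // s + 1
    st = xp.strides
    windows = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, ho, wo, k, k),
        strides=(st[0], st[1], st[2] * s, st[3] * s, st[2], st[3]),
    )
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * k * k)
    return np.ascontiguousarray(cols), ho, wo


def _conv_forward(x, W, b, s, p):
    """x (n,c,h,w), W (co,c,k,k) -> y (n,co,ho,wo) plus cache."""
    co, c, k, _ = W.shape
    cols, ho, wo = _im2col(x, k, s, p)
    y = cols @ W.reshape(co, -1).T + b
    return y.reshape(x.shape[0], ho, wo, co).transpose(0, 3, 1, 2), (x.shape, cols, ho, wo)


def _conv_backward(dy, W, s, p, cache):
    x_shape, cols, ho, wo = cache
    n, c, h, w = x_shape
    co, _, k, _ = W.shape
    dyf = dy.transpose(0, 2, 3, 1).reshape(n, ho * wo, co)
    dW = np.einsum("npo,npi->oi", dyf, cols).reshape(W.shape)
    db = dyf.sum(axis=(0, 1))
    dcols = dyf @ W.reshape(co, -1)  # (n, ho*wo, c*k*k)
    dwin = dcols.reshape(n, ho, wo, c, k, k)
    dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
    for ki in range(k):
        for kj in range(k):
            dxp[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s] += dwin[
                :, :, :, :, ki, kj
            ].transpose(0, 3, 1, 2)
    dx = dxp[:, :, p : p + h, p : p + w] if p else dxp
    return dx, dW, db


def _interp_matrix(n_out: int, n_in: int, mode: str) -> np.ndarray:
    """1-D upsampling matrix (n_out x n_in); adjoint is its transpose."""
    U = np.zeros((n_out, n_in))
    scale = n_in / n_out
    for i in range(n_out):
        x = (i + 0.5) * scale - 0.5
        if mode == "nearest":
            U[i, int(np.clip(round(x), 0, n_in - 1))] = 1.0
            continue
        x = np.clip(x, 0.0, n_in - 1.0)
        lo = int(np.floor(x))
        hi = min(lo + 1, n_in - 1)
        t = x - lo
        U[i, lo] += 1.0 - t
        U[i, hi] += t
    return U


# --------------------------------------------------------------------- #


class ImportancePredictor(BaseEstimator):
    """FCN-16s-style importance predictor with a tiny trained-from-scratch encoder.

    Parameters
    ----------
    channels :
        Output channels of the five stride-2 encoder stages (deepest
        stride is 32, so inputs must have dimensions divisible by 32).
    skip_stage :
        Encoder stage feeding the skip score head; 4 gives the
        classic stride-16 skip.
    upsample : {'bilinear', 'nearest'}
        Fixed interpolation used by the 2x and 16x upsampling steps.
    epochs, batch_size, learning_rate :
        Adam training schedule for the sigmoid cross-entropy loss.

    Attributes
    ----------
    params_ : dict of ndarray
        Convolution weights and biases.
    loss_history_ : list of float
        Mean training loss per epoch.
    """

    def __init__(
        self,
        channels: tuple[int, ...] = (8, 12, 16, 16, 16),
        skip_stage: int = 4,
        upsample: str = "bilinear",
        epochs: int = 30,
        batch_size: int = 8,
        learning_rate: float = 0.01,
        random_state: int | None = None,
    ) -> None:
        self.channels = channels
        self.skip_stage = skip_stage
        self.upsample = upsample
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state

    # ------------------------------------------------------------------ #

    def _init_params(self, rng) -> dict[str, np.ndarray]:
        if len(self.channels) != 5:
            raise HudoptError("exactly 5 encoder stages are required (stride 32)")
        if not (1 <= self.skip_stage < 5):
            raise HudoptError("skip_stage must be in 1..4")
        if self.upsample not in ("bilinear", "nearest"):
            raise HudoptError(f"unknown upsample mode {self.upsample!r}")
        params: dict[str, np.ndarray] = {}
        c_in = 1
        for i, c_out in enumerate(self.channels, start=1):
            fan = c_in * 9
            params[f"W{i}"] = rng.normal(0, np.sqrt(2.0 / fan), (c_out, c_in, 3, 3))
            params[f"b{i}"] = np.zeros(c_out)
            c_in = c_out
        params["Ws32"] = rng.normal(0, 0.1, (1, self.channels[-1], 1, 1))
        params["bs32"] = np.zeros(1)
        params["Ws16"] = rng.normal(0, 0.1, (1, self.channels[self.skip_stage - 1], 1, 1))
        params["bs16"] = np.zeros(1)
        return params

    def _forward(self, x: np.ndarray, params):
        """x (n,1,h,w) -> logits (n,h,w) plus caches for backprop."""
        acts = {"a0": x}
        caches = {}
        a = x
        for i in range(1, 6):
            z, caches[f"c{i}"] = _conv_forward(a, params[f"W{i}"], params[f"b{i}"], 2, 1)
            a = np.maximum(z, 0.0)
            acts[f"z{i}"] = z
            acts[f"a{i}"] = a
        s32, caches["cs32"] = _conv_forward(acts["a5"], params["Ws32"], params["bs32"], 1, 0)
        skip = acts[f"a{self.skip_stage}"]
        s16, caches["cs16"] = _conv_forward(skip, params["Ws16"], params["bs16"], 1, 0)
        h16, w16 = s16.shape[2], s16.shape[3]
        U2h = _interp_matrix(h16, s32.shape[2], self.upsample)
        U2w = _interp_matrix(w16, s32.shape[3], self.upsample)
        fused = np.einsum("ij,ncjk,lk->ncil", U2h, s32, U2w) + s16
        H, W = x.shape[2], x.shape[3]
        U16h = _interp_matrix(H, h16, self.upsample)
        U16w = _interp_matrix(W, w16, self.upsample)
        logits = np.einsum("ij,ncjk,lk->ncil", U16h, fused, U16w)[:, 0]
        caches["U"] = (U2h, U2w, U16h, U16w)
        return logits, acts, caches

    def _backward(self, dlogits, acts, caches, params):
        U2h, U2w, U16h, U16w = caches["U"]
        grads = {}
        dfused = np.einsum("ij,njk,lk->nil", U16h.T, dlogits, U16w.T)[:, None]
        ds16 = dfused
        ds32 = np.einsum("ij,ncjk,lk->ncil", U2h.T, dfused, U2w.T)
        dskip, grads["Ws16"], grads["bs16"] = _conv_backward(
            ds16, params["Ws16"], 1, 0, caches["cs16"]
        )
        da5, grads["Ws32"], grads["bs32"] = _conv_backward(
            ds32, params["Ws32"], 1, 0, caches["cs32"]
        )
        da = {i: None for i in range(6)}
        da[5] = da5
        da[self.skip_stage] = dskip if da[self.skip_stage] is None else da[self.skip_stage] + dskip
        for i in range(5, 0, -1):
            d = da[i]
            dz = d * (acts[f"z{i}"] > 0)
            dx, grads[f"W{i}"], grads[f"b{i}"] = _conv_backward(
                dz, params[f"W{i}"], 2, 1, caches[f"c{i}"]
            )
            if i - 1 > 0:
                da[i - 1] = dx if da[i - 1] is None else da[i - 1] + dx
        return grads

    @staticmethod
    def _check_maps(X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        if X.ndim != 3:
            raise HudoptError("images must be (n, H, W)")
        if X.shape[1] % 32 or X.shape[2] % 32:
            raise HudoptError(f"image dimensions {X.shape[1:]} must be divisible by 32")
        if y is None:
            return X
        y = np.asarray(y, dtype=float)
        if y.ndim == 2:
            y = y[None]
        if y.shape != X.shape:
            raise HudoptError("images and importance maps must share dimensions")
        if y.min() < 0 or y.max() > 1:
            raise HudoptError("importance targets must lie in [0, 1]")
        return X, y

    # ------------------------------------------------------------------ #

    def fit(self, X, y):
        """Train on images X (n, H, W) with importance targets y (n, H, W)."""
        X, y = self._check_maps(X, y)
        if len(X) < 2:
            raise HudoptError("at least 2 scenes are required")
        rng = np.random.default_rng(self.random_state)
        params = self._init_params(rng)
        m = {k: np.zeros_like(v) for k, v in params.items()}
        v = {k: np.zeros_like(va) for k, va in params.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        self.loss_history_ = []
        n = len(X)
        for _epoch in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb = X[idx][:, None]
                qb = y[idx]
                logits, acts, caches = self._forward(xb, params)
                P = np.clip(1.0 / (1.0 + np.exp(-logits)), LOSS_EPS, 1.0 - LOSS_EPS)
                losses.append(float(-np.mean(qb * np.log(P) + (1 - qb) * np.log(1 - P))))
                dlogits = (P - qb) / P[0].size / len(idx)
                grads = self._backward(dlogits, acts, caches, params)
                step += 1
                for k in params:
                    m[k] = b1 * m[k] + (1 - b1) * grads[k]
                    v[k] = b2 * v[k] + (1 - b2) * grads[k] ** 2
                    mh = m[k] / (1 - b1**step)
                    vh = v[k] / (1 - b2**step)
                    params[k] -= self.learning_rate * mh / (np.sqrt(vh) + eps)
            self.loss_history_.append(float(np.mean(losses)))
        self.params_ = params
        return self

    def predict_logits(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        X = self._check_maps(X)
        out = []
        for start in range(0, len(X), 16):
            logits, _, _ = self._forward(X[start : start + 16][:, None], self.params_)
            out.append(logits)
        return np.concatenate(out)

    def predict(self, X) -> np.ndarray:
        """Predicted importance maps in (0, 1), same shape as the input."""
        return 1.0 / (1.0 + np.exp(-self.predict_logits(X)))


# --------------------------------------------------------------------- #


def center_prior_map(height: int, width: int) -> np.ndarray:
    """Isotropic center-Gaussian baseline map (peak 1 at the canvas center)."""
    rows, cols = np.mgrid[0:height, 0:width].astype(float)
    cr, cc = (height - 1) / 2.0, (width - 1) / 2.0
    sigma = 0.25 * min(height, width)
    return np.exp(-((rows - cr) ** 2 + (cols - cc) ** 2) / (2 * sigma**2))


def train_ivpm(scenes, test_fraction: float = 0.2, seed: int = 0, **params):
    """Split scenes 80-20, fit an :class:`ImportancePredictor` on the 80%.

    Returns ``(model, train_scenes, test_scenes)``.
    """
    if len(scenes) < 2:
        raise HudoptError("at least 2 scenes are required")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(scenes))
    n_test = max(1, int(round(test_fraction * len(scenes))))
    test = [scenes[i] for i in idx[:n_test]]
    train = [scenes[i] for i in idx[n_test:]]
    model = ImportancePredictor(random_state=seed, **params)
    model.fit(
        np.stack([s.image for s in train]),
        np.stack([s.importance for s in train]),
    )
    return model, train, test


def evaluate_ivpm(model: ImportancePredictor, scenes):
    """Mean CC and KL of predictions against ground truth on held-out scenes.

    Returns ``(mean_cc, mean_kl, per_scene)`` where ``per_scene`` is a
    list of (cc, kl) pairs in scene order.
    """
    if not len(scenes):
        raise HudoptError("no scenes to evaluate")
    preds = model.predict(np.stack([s.image for s in scenes]))
    per_scene = []
    for pred, scene in zip(preds, scenes):
        per_scene.append(
            (cross_correlation(pred, scene.importance), kl_divergence(pred, scene.importance))
        )
    ccs, kls = zip(*per_scene)
    return float(np.mean(ccs)), float(np.mean(kls)), per_scene
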