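"""Feedforward cognitive-load surrogate: 26-bit code -> NASA-TLX estimate.

The predictor is a small fully-connected network, 26 inputs, three
hidden layers of 15 log-sigmoid units and one log-sigmoid output,
trained by damped least squares (Levenberg-Marquardt).  Because the
output unit saturates in (0, 1), raw NASA-TLX targets are min-max
scaled into [0.05, 0.95] before training and predictions are
inverse-scaled on the way out.

Training holds out a validation fraction for early stopping (the epoch
with the lowest validation error wins; training stops after ``patience``
consecutive validation failures, mirroring the usual toolbox rule) and
optionally an untouched test fraction.  Levenberg-Marquardt only ever
accepts parameter steps that reduce the training error, raising the
damping factor until one is found, so the accepted-step error history
is non-increasing by construction.
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import codec
from .errors import HudoptError

__all__ = ["CognitiveLoadRegressor", "train", "predict"]


def _logsig(x: np.ndarray) -> np.ndarray:
    # numerically stable log-sigmoid
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _as_matrix(X) -> np.ndarray:
    """Accept an (n, 26) 0/1 array, a bit-string, or a sequence of them."""
    if isinstance(X, str):
        X = [X]
    if len(X) and isinstance(X[0] if not hasattr(X, "iloc") else X.iloc[0], str):
        return codec.codes_to_matrix(X)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != codec.CHROMOSOME_LENGTH:
        raise HudoptError(f"expected {codec.CHROMOSOME_LENGTH} features, got {X.shape[1]}")
    if not np.isin(X, (0.0, 1.0)).all():
        raise HudoptError("chromosome features must be binary")
    return X


class CognitiveLoadRegressor(RegressorMixin, BaseEstimator):
    """Log-sigmoid MLP surrogate for NASA-TLX, trained by Levenberg-Marquardt.

    Parameters
    ----------
    hidden_layers, hidden_units :
        Network depth and width; default 3 layers of 15 units.
    optimizer : {'levenberg_marquardt', 'gradient_descent'}
        Damped least squares (default) or plain full-batch gradient
        descent with step size ``learning_rate``.
    learning_rate :
        Step size for the gradient-descent optimizer; the
        Levenberg-Marquardt path controls its own damping and ignores it.
    split :
        (train, validation, test) fractions; must sum to 1.  The test
        share is held out untouched and its indices exposed as
        ``test_idx_`` for external evaluation.
    patience :
        Consecutive validation-error increases tolerated before
        stopping.
    goal :
        Optional absolute training-MSE goal (scaled targets); training
        stops early when reached.  Disabled by default.
    target_range :
        Interval the raw targets are mapped into before training;
        must sit strictly inside (0, 1) because the output unit is a
        log-sigmoid.

    Attributes
    ----------
    weights_, biases_ : list of ndarray
        Layer parameters at the best validation epoch.
    y_min_, y_max_ : float
        Raw-target bounds used by the affine target scaler.
    history_ : dict
        Per accepted epoch: ``train_mse`` (scaled), ``val_mse`` and
        ``val_mse_raw``.
    best_epoch_ : int
        1-based epoch whose weights were retained.
    best_val_mse_raw_ : float
        Minimum validation MSE on the raw NASA-TLX scale.
    """

    def __init__(
        self,
        hidden_layers: int = 3,
        hidden_units: int = 15,
        max_epochs: int = 1000,
        learning_rate: float = 0.1,
        optimizer: str = "levenberg_marquardt",
        split: tuple[float, float, float] = (0.70, 0.15, 0.15),
        patience: int = 6,
        goal: float | None = None,
        target_range: tuple[float, float] = (0.05, 0.95),
        random_state: int | None = None,
    ) -> None:
        self.hidden_layers = hidden_layers
        self.hidden_units = hidden_units
        self.max_epochs = max_epochs
        self.learning_rate = learning_rate
        self.optimizer = optimizer
        self.split = split
        self.patience = patience
        self.goal = goal
        self.target_range = target_range
        self.random_state = random_state

    # ------------------------------------------------------------------ #

    def _forward(self, X: np.ndarray, Ws, bs) -> list[np.ndarray]:
        acts = [X]
        for W, b in zip(Ws, bs):
            acts.append(_logsig(acts[-1] @ W.T + b))
        return acts

    def _jacobian(self, acts, Ws) -> np.ndarray:
        """d output / d params, one row per sample, logsig at every layer."""
        n = acts[0].shape[0]
        L = len(Ws)
        deltas = [None] * L
        out = acts[-1][:, 0]
        deltas[L - 1] = (out * (1 - out))[:, None]  # (n, 1)
        for l in range(L - 2, -1, -1):
            a = acts[l + 1]
            deltas[l] = (deltas[l + 1] @ Ws[l + 1]) * a * (1 - a)
        cols = []
        for l in range(L):
            cols.append(np.einsum("no,ni->noi", deltas[l], acts[l]).reshape(n, -1))
            cols.append(deltas[l])
        return np.concatenate(cols, axis=1)

    def _pack(self, Ws, bs) -> np.ndarray:
        return np.concatenate([np.concatenate([W.ravel(), b]) for W, b in zip(Ws, bs)])

    def _unpack(self, w: np.ndarray, shapes) -> tuple[list, list]:
        Ws, bs, off = [], [], 0
        for out_d, in_d in shapes:
            Ws.append(w[off : off + out_d * in_d].reshape(out_d, in_d))
            off += out_d * in_d
            bs.append(w[off : off + out_d])
            off += out_d
        return Ws, bs

    # ------------------------------------------------------------------ #

    def fit(self, X, y):
        X = _as_matrix(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != len(X):
            raise HudoptError("X and y length mismatch")
        if len(X) == 0:
            raise HudoptError("empty dataset")
        if not np.isclose(sum(self.split), 1.0):
            raise HudoptError("split fractions must sum to 1")
        if self.max_epochs < 1:
            raise HudoptError("max_epochs must be >= 1")
        lo, hi = self.target_range
        if not (0.0 < lo < hi < 1.0):
            raise HudoptError("target_range must sit strictly inside (0, 1)")

        self.y_min_, self.y_max_ = float(y.min()), float(y.max())
        if self.y_max_ == self.y_min_:
            raise HudoptError("degenerate target range: all targets equal")
        t = lo + (y - self.y_min_) / (self.y_max_ - self.y_min_) * (hi - lo)

        rng = np.random.default_rng(self.random_state)
        n = len(X)
        idx = rng.permutation(n)
        n_val = int(round(self.split[1] * n))
        n_test = int(round(self.split[2] * n))
        self.val_idx_ = np.sort(idx[:n_val])
        self.test_idx_ = np.sort(idx[n_val : n_val + n_test])
        self.train_idx_ = np.sort(idx[n_val + n_test :])
        if len(self.train_idx_) == 0:
            raise HudoptError("train split is empty")
        Xtr, ttr = X[self.train_idx_], t[self.train_idx_]
        Xval, tval = X[self.val_idx_], t[self.val_idx_]

        dims = [codec.CHROMOSOME_LENGTH] + [self.hidden_units] * self.hidden_layers + [1]
        shapes = [(dims[i + 1], dims[i]) for i in range(len(dims) - 1)]
        Ws = [rng.uniform(-1, 1, s) * np.sqrt(6.0 / (s[0] + s[1])) for s in shapes]
        bs = [rng.uniform(-0.1, 0.1, s[0]) for s in shapes]

        if self.optimizer == "levenberg_marquardt":
            self._fit_lm(Xtr, ttr, Xval, tval, Ws, bs, shapes)
        elif self.optimizer == "gradient_descent":
            self._fit_gd(Xtr, ttr, Xval, tval, Ws, bs, shapes)
        else:
            raise HudoptError(f"unknown optimizer {self.optimizer!r}")
        self.n_features_in_ = codec.CHROMOSOME_LENGTH
        return self

    def _record(self, train_mse, Xval, tval, Ws, bs, hist):
        hist["train_mse"].append(train_mse)
        if len(Xval):
            r = self._forward(Xval, Ws, bs)[-1][:, 0] - tval
            vmse = float(np.mean(r**2))
        else:
            vmse = train_mse
        scale = (self.y_max_ - self.y_min_) / (self.target_range[1] - self.target_range[0])
        hist["val_mse"].append(vmse)
        hist["val_mse_raw"].append(vmse * scale**2)
        return vmse

    def _finish(self, hist, best, shapes):
        epoch, w = best
        self.weights_, self.biases_ = self._unpack(w, shapes)
        self.history_ = hist
        self.best_epoch_ = epoch
        self.best_val_mse_raw_ = hist["val_mse_raw"][epoch - 1]
        self.n_iter_ = len(hist["train_mse"])

    def _fit_lm(self, Xtr, ttr, Xval, tval, Ws, bs, shapes):
        w = self._pack(Ws, bs)
        mu, mu_max = 1e-3, 1e10
        acts = self._forward(Xtr, *self._unpack(w, shapes))
        r = acts[-1][:, 0] - ttr
        sse = float(r @ r)
        hist = {"train_mse": [], "val_mse": [], "val_mse_raw": []}
        best = (0, w.copy())
        best_val, fails = np.inf, 0
        for epoch in range(1, self.max_epochs + 1):
            Ws_c, _bs_c = self._unpack(w, shapes)
            J = self._jacobian(acts, Ws_c)
            g = J.T @ r
            JtJ = J.T @ J
            accepted = False
            while mu <= mu_max:
                try:
                    dw = np.linalg.solve(JtJ + mu * np.eye(len(w)), g)
                except np.linalg.LinAlgError:
                    mu *= 10
                    continue
                w_new = w - dw
                acts_new = self._forward(Xtr, *self._unpack(w_new, shapes))
                r_new = acts_new[-1][:, 0] - ttr
                sse_new = float(r_new @ r_new)
                if sse_new < sse:
                    w, acts, r, sse = w_new, acts_new, r_new, sse_new
                    mu = max(mu / 10.0, 1e-20)
                    accepted = True
                    break
                mu *= 10
            if not accepted:  # damping exhausted: a (local) minimum
                break
            vmse = self._record(sse / len(ttr), Xval, tval, *self._unpack(w, shapes), hist)
            if vmse < best_val:
                best_val, best, fails = vmse, (epoch, w.copy()), 0
            else:
                fails += 1
                if len(Xval) and fails >= self.patience:
                    break
            if self.goal is not None and sse / len(ttr) <= self.goal:
                break
        if best[0] == 0:  # no accepted step
            self._record(sse / len(ttr), Xval, tval, *self._unpack(w, shapes), hist)
            best = (1, w.copy())
        self._finish(hist, best, shapes)

    def _fit_gd(self, Xtr, ttr, Xval, tval, Ws, bs, shapes):
        w = self._pack(Ws, bs)
        hist = {"train_mse": [], "val_mse": [], "val_mse_raw": []}
        best = (0, w.copy())
        best_val, fails = np.inf, 0
        for epoch in range(1, self.max_epochs + 1):
            Ws_c, bs_c = self._unpack(w, shapes)
            acts = self._forward(Xtr, Ws_c, bs_c)
            r = acts[-1][:, 0] - ttr
            J = self._jacobian(acts, Ws_c)
            grad = 2.0 * (J.T @ r) / len(ttr)
            w = w - self.learning_rate * grad
            acts = self._forward(Xtr, *self._unpack(w, shapes))
            mse = float(np.mean((acts[-1][:, 0] - ttr) ** 2))
            vmse = self._record(mse, Xval, tval, *self._unpack(w, shapes), hist)
            if vmse < best_val:
                best_val, best, fails = vmse, (epoch, w.copy()), 0
            else:
                fails += 1
                if len(Xval) and fails >= self.patience:
                    break
            if self.goal is not None and mse <= self.goal:
                break
        if best[0] == 0:
            best = (1, w.copy())
        self._finish(hist, best, shapes)

    # ------------------------------------------------------------------ #

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "weights_")
        X = _as_matrix(X)
        out = self._forward(X, self.weights_, self.biases_)[-1][:, 0]
        lo, hi = self.target_range
        return self.y_min_ + (out - lo) / (hi - lo) * (self.y_max_ - self.y_min_)

    def predict_one(self, code: str) -> float:
        return float(self.predict([code])[0])

    # ------------------------------------------------------------------ #

    def to_json(self) -> str:
        """Serialize the fitted model to a bit-exact JSON checkpoint."""
        check_is_fitted(self, "weights_")
        payload = {
            "params": self.get_params(),
            "dims": [W.shape for W in self.weights_],
            "weights": [W.tolist() for W in self.weights_],
            "biases": [b.tolist() for b in self.biases_],
            "y_min": self.y_min_,
            "y_max": self.y_max_,
            "history": self.history_,
            "best_epoch": self.best_epoch_,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "CognitiveLoadRegressor":
        payload = json.loads(text)
        model = cls(**payload["params"])
        model.weights_ = [np.asarray(W, dtype=float) for W in payload["weights"]]
        model.biases_ = [np.asarray(b, dtype=float) for b in payload["biases"]]
        model.y_min_ = payload["y_min"]
        model.y_max_ = payload["y_max"]
        model.history_ = payload["history"]
        model.best_epoch_ = payload["best_epoch"]
        model.best_val_mse_raw_ = model.history_["val_mse_raw"][model.best_epoch_ - 1]
        model.n_features_in_ = codec.CHROMOSOME_LENGTH
        return model


# Thin functional wrappers over the estimator -------------------------- #


def train(dataset, **params) -> CognitiveLoadRegressor:
    """Fit a :class:`CognitiveLoadRegressor` on a load dataset."""
    model = CognitiveLoadRegressor(**params)
    return model.fit(list(dataset.codes), dataset.scores)


def predict(model: CognitiveLoadRegressor, code: str) -> float:
    """Predicted NASA-TLX for one 26-bit code."""
    return model.predict_one(code)
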