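"""Cultivar prediction from leaf traits: GRNN, LS-SVM and BP models.

Six per-leaf traits (bounding-box volume, shell volume, projection length,
projection width, projection area, tilt angle) predict the cultivar.
Cultivars are encoded as integer labels 1..C and *regressed* — the
correlation/RMSE metrics (Rc/RMSEC on the training set, Rp/RMSEP on the
test set) are computed on the numeric predictions, and a hard class label
is obtained by rounding to the nearest valid integer.

The three models are written here from first principles and wrapped as
scikit-learn-compatible estimators (``fit``/``predict``,
``get_params``/``set_params``), so they compose with sklearn model
selection.  Features are standardised with training-set statistics inside
``fit``; GRNN and RBF kernels are scale-sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "TraitMatrix",
    "MetricsReport",
    "GRNN",
    "LSSVM",
    "BPNetwork",
    "train_test_split",
    "grnn_fit_predict",
    "lssvm_fit_predict",
    "bp_fit_predict",
    "regression_metrics",
    "evaluate_model",
]

FEATURE_NAMES = [
    "leaf_aabb_volume_cm3",
    "leaf_volume_cm3",
    "projection_length_cm",
    "projection_width_cm",
    "projection_area_cm2",
    "tilt_angle_deg",
]


@dataclass
class TraitMatrix:
    """n x 6 leaf-trait design matrix with integer class labels."""

    X: np.ndarray
    y: np.ndarray
    feature_names: Sequence[str] = tuple(FEATURE_NAMES)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2D")
        if len(self.y) != len(self.X):
            raise ValueError("y length must match X rows")
        if not np.isfinite(self.X).all():
            raise ValueError("X contains missing/non-finite values")

    def __len__(self) -> int:
        return len(self.X)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label"):
        feats = [c for c in FEATURE_NAMES if c in df.columns]
        if len(feats) != len(FEATURE_NAMES):
            missing = set(FEATURE_NAMES) - set(feats)
            raise ValueError(f"trait table lacks feature columns: {sorted(missing)}")
        return cls(df[feats].to_numpy(float), df[label_col].to_numpy(int), feats)

    def select(self, idx) -> "TraitMatrix":
        return TraitMatrix(self.X[idx], self.y[idx], self.feature_names)


@dataclass(frozen=True)
class MetricsReport:
    """Fit-quality metrics: MAPE (%), RMSE, R^2 plus the calibration /
    prediction pairs Rc/RMSEC (training set) and Rp/RMSEP (test set)."""

    mape: float
    rmse: float
    r2: float
    rc: float = float("nan")
    rmsec: float = float("nan")
    rp: float = float("nan")
    rmsep: float = float("nan")


def train_test_split(
    data: TraitMatrix, train_fraction: float = 0.8, seed: int = 0
) -> Tuple[TraitMatrix, TraitMatrix]:
    """Seed-deterministic, class-stratified split into train/test.

    Per class, ``round(train_fraction * n_class)`` samples go to training
    (at least 1 on each side), so balanced classes split 80/20 within one
    sample.  The split is a disjoint, exhaustive partition.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx = []
    test_idx = []
    for lab in np.unique(data.y):
        members = np.flatnonzero(data.y == lab)
        if len(members) < 2:
            raise ValueError(
                f"class {lab!r} has {len(members)} sample(s); need >= 2 to split"
            )
        perm = rng.permutation(members)
        n_train = int(round(train_fraction * len(members)))
        n_train = min(max(n_train, 1), len(members) - 1)
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    train_idx = np.sort(np.concatenate(train_idx))
    test_idx = np.sort(np.concatenate(test_idx))
    return data.select(train_idx), data.select(test_idx)


# ---------------------------------------------------------------------------
# standardisation helper shared by the estimators

def _fit_standardiser(X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mean, sd


# ---------------------------------------------------------------------------
# GRNN

class GRNN(BaseEstimator, RegressorMixin):
    """Generalized regression neural network (Nadaraya-Watson with a
    Gaussian kernel and a single bandwidth, the *spread*).

    ``y_hat(q) = sum_i y_i w_i / sum_i w_i`` with
    ``w_i = exp(-||q - x_i||^2 / (2 spread^2))`` — a convex combination of
    the stored training targets.  ``spread=None`` selects the bandwidth by
    leave-one-out grid search on the training set (deterministic).

    Fitted attributes: ``X_``, ``y_``, ``spread_``, ``mean_``, ``sd_``.
    """

    def __init__(self, spread: Optional[float] = None, standardize: bool = True):
        self.spread = spread
        self.standardize = standardize

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if self.standardize:
            self.mean_, self.sd_ = _fit_standardiser(X)
        else:
            self.mean_, self.sd_ = np.zeros(X.shape[1]), np.ones(X.shape[1])
        self.X_ = (X - self.mean_) / self.sd_
        self.y_ = y
        self.label_range_ = (float(y.min()), float(y.max()))
        if self.spread is not None:
            if self.spread <= 0:
                raise ValueError("spread must be > 0")
            self.spread_ = float(self.spread)
        else:
            self.spread_ = self._loo_spread()
        return self

    def _loo_spread(self) -> float:
        grid = np.geomspace(0.05, 5.0, 25)
        n = len(self.X_)
        d2 = _sq_dists(self.X_, self.X_)
        np.fill_diagonal(d2, np.inf)  # leave-one-out: exclude self
        best = (np.inf, grid[0])
        for s in grid:
            logw = -d2 / (2.0 * s * s)
            logw -= logw.max(axis=1, keepdims=True)
            w = np.exp(logw)
            pred = (w @ self.y_) / w.sum(axis=1)
            mse = float(np.mean((pred - self.y_) ** 2))
            if mse < best[0] - 1e-15:
                best = (mse, s)
        return float(best[1])

    def predict(self, X):
        X = (np.asarray(X, dtype=np.float64) - self.mean_) / self.sd_
        d2 = _sq_dists(X, self.X_)
        s2 = 2.0 * self.spread_**2
        logw = -d2 / s2
        shift = logw.max(axis=1, keepdims=True)
        w = np.exp(logw - shift)
        den = w.sum(axis=1)
        out = np.empty(len(X))
        ok = den > 0
        out[ok] = (w[ok] @ self.y_) / den[ok]
        if not ok.all():
            # all kernel weights underflowed: nearest training sample
            nearest = np.argmin(d2[~ok], axis=1)
            out[~ok] = self.y_[nearest]
        return out

    def predict_label(self, X):
        """Integer class labels: rounded prediction, clipped to the
        training label range."""
        lo, hi = self.label_range_
        return np.clip(np.rint(self.predict(X)), lo, hi).astype(int)


def _sq_dists(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    d = A[:, None, :] - B[None, :, :]
    return np.einsum("ijk,ijk->ij", d, d)


# ---------------------------------------------------------------------------
# LS-SVM

class LSSVM(BaseEstimator, RegressorMixin):
    """Least-squares SVM with an RBF kernel, solved as one linear system.

    The dual system is ``[[0, 1^T], [1, K + I/gamma]] [b; alpha] = [0; y]``
    with ``K_ij = exp(-||x_i - x_j||^2 / (2 kernel_width^2))``; prediction
    is ``sum_i alpha_i k(q, x_i) + b``.  Multiclass labels are handled
    one-vs-rest with argmax over the C binary decision values, while
    ``predict`` returns the numeric regression output on the raw labels
    (used for the Rc/Rp metrics).

    Fitted attributes: ``alpha_``, ``bias_``, ``residual_`` (solver
    residual norm), plus the one-vs-rest duplicates ``ovr_``.
    """

    def __init__(
        self,
        gamma: float = 10.0,
        kernel_width: float = 1.0,
        standardize: bool = True,
    ):
        self.gamma = gamma
        self.kernel_width = kernel_width
        self.standardize = standardize

    def _kernel(self, A, B):
        return np.exp(-_sq_dists(A, B) / (2.0 * self.kernel_width**2))

    def _solve(self, K, y):
        n = len(y)
        A = np.zeros((n + 1, n + 1))
        A[0, 1:] = 1.0
        A[1:, 0] = 1.0
        A[1:, 1:] = K + np.eye(n) / self.gamma
        rhs = np.r_[0.0, y]
        try:
            sol = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            warnings.warn(
                "LS-SVM system singular; bumping regularisation", stacklevel=2
            )
            A[1:, 1:] += 1e-8 * np.eye(n)
            sol = np.linalg.solve(A, rhs)
        resid = float(np.linalg.norm(A @ sol - rhs))
        return sol[0], sol[1:], resid

    def fit(self, X, y):
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if self.standardize:
            self.mean_, self.sd_ = _fit_standardiser(X)
        else:
            self.mean_, self.sd_ = np.zeros(X.shape[1]), np.ones(X.shape[1])
        self.X_ = (X - self.mean_) / self.sd_
        self.y_ = y
        K = self._kernel(self.X_, self.X_)
        self.bias_, self.alpha_, self.residual_ = self._solve(K, y)
        self.classes_ = np.unique(y)
        self.ovr_ = []
        if len(self.classes_) > 2:
            for c in self.classes_:
                t = np.where(y == c, 1.0, -1.0)
                b, a, _ = self._solve(K, t)
                self.ovr_.append((c, b, a))
        return self

    def predict(self, X):
        """Numeric regression output on the raw integer labels."""
        Xs = (np.asarray(X, dtype=np.float64) - self.mean_) / self.sd_
        K = self._kernel(Xs, self.X_)
        return K @ self.alpha_ + self.bias_

    def predict_label(self, X):
        """Hard class labels (one-vs-rest argmax for >2 classes)."""
        Xs = (np.asarray(X, dtype=np.float64) - self.mean_) / self.sd_
        K = self._kernel(Xs, self.X_)
        if len(self.classes_) <= 2:
            raw = K @ self.alpha_ + self.bias_
            lo, hi = self.classes_[0], self.classes_[-1]
            return np.where(raw >= (lo + hi) / 2.0, hi, lo).astype(int)
        scores = np.stack([K @ a + b for _, b, a in self.ovr_], axis=1)
        return self.classes_[np.argmax(scores, axis=1)].astype(int)


# ---------------------------------------------------------------------------
# BP network

class BPNetwork(BaseEstimator, RegressorMixin):
    """Single-hidden-layer feedforward network trained by backpropagation.

    Sigmoid hidden activation, linear scalar output, full-batch gradient
    descent on mean squared error.  Initialisation is seed-deterministic;
    ``epochs=0`` returns the untrained network's outputs.

    Fitted attributes: ``W1_``, ``b1_``, ``W2_``, ``b2_``, ``loss_curve_``.
    """

    def __init__(
        self,
        hidden: int = 8,
        lr: float = 0.05,
        epochs: int = 2000,
        seed: int = 0,
        standardize: bool = True,
    ):
        self.hidden = hidden
        self.lr = lr
        self.epochs = epochs
        self.seed = seed
        self.standardize = standardize

    @staticmethod
    def _sigmoid(z):
        return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))

    def _forward(self, X):
        H = self._sigmoid(X @ self.W1_ + self.b1_)
        return H, H @ self.W2_ + self.b2_

    def fit(self, X, y):
        if self.hidden < 1:
            raise ValueError("hidden must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).reshape(-1)
        if self.standardize:
            self.mean_, self.sd_ = _fit_standardiser(X)
        else:
            self.mean_, self.sd_ = np.zeros(X.shape[1]), np.ones(X.shape[1])
        Xs = (X - self.mean_) / self.sd_
        n, p = Xs.shape
        rng = np.random.default_rng(self.seed)
        self.W1_ = rng.normal(0.0, 1.0 / np.sqrt(p), size=(p, self.hidden))
        self.b1_ = np.zeros(self.hidden)
        self.W2_ = rng.normal(0.0, 1.0 / np.sqrt(self.hidden), size=self.hidden)
        self.b2_ = 0.0
        self.loss_curve_ = []
        for _ in range(self.epochs):
            H, out = self._forward(Xs)
            err = out - y
            loss = float(np.mean(err**2))
            self.loss_curve_.append(loss)
            if loss > 1e6 or not np.isfinite(loss):
                raise RuntimeError(
                    f"BP training diverged (loss={loss:.3g}); lower the learning rate"
                )
            gout = 2.0 * err / n                       # dL/dout
            gW2 = H.T @ gout
            gb2 = gout.sum()
            gH = np.outer(gout, self.W2_)
            gZ = gH * H * (1.0 - H)                    # sigmoid'
            gW1 = Xs.T @ gZ
            gb1 = gZ.sum(axis=0)
            self.W2_ -= self.lr * gW2
            self.b2_ -= self.lr * gb2
            self.W1_ -= self.lr * gW1
            self.b1_ -= self.lr * gb1
        self.label_range_ = (float(y.min()), float(y.max()))
        return self

    def gradients(self, X, y):
        """Analytic MSE gradients at the current weights (for checking
        against finite differences)."""
        Xs = (np.asarray(X, float) - self.mean_) / self.sd_
        y = np.asarray(y, float).reshape(-1)
        n = len(y)
        H, out = self._forward(Xs)
        gout = 2.0 * (out - y) / n
        gW2 = H.T @ gout
        gb2 = gout.sum()
        gZ = np.outer(gout, self.W2_) * H * (1.0 - H)
        gW1 = Xs.T @ gZ
        gb1 = gZ.sum(axis=0)
        return {"W1": gW1, "b1": gb1, "W2": gW2, "b2": np.array(gb2)}

    def loss(self, X, y):
        Xs = (np.asarray(X, float) - self.mean_) / self.sd_
        _, out = self._forward(Xs)
        return float(np.mean((out - np.asarray(y, float).reshape(-1)) ** 2))

    def predict(self, X):
        Xs = (np.asarray(X, dtype=np.float64) - self.mean_) / self.sd_
        return self._forward(Xs)[1]

    def predict_label(self, X):
        lo, hi = self.label_range_
        return np.clip(np.rint(self.predict(X)), lo, hi).astype(int)


# ---------------------------------------------------------------------------
# functional wrappers

def grnn_fit_predict(train: TraitMatrix, queries, spread=None):
    model = GRNN(spread=spread).fit(train.X, train.y)
    return model.predict(np.asarray(queries, float))


def lssvm_fit_predict(train: TraitMatrix, queries, gamma=10.0, kernel_width=1.0):
    model = LSSVM(gamma=gamma, kernel_width=kernel_width).fit(train.X, train.y)
    return model.predict(np.asarray(queries, float))


def bp_fit_predict(
    train: TraitMatrix, queries, hidden=8, lr=0.05, epochs=2000, seed=0
):
    model = BPNetwork(hidden=hidden, lr=lr, epochs=epochs, seed=seed).fit(
        train.X, train.y
    )
    return model.predict(np.asarray(queries, float))


# ---------------------------------------------------------------------------
# metrics

def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    den = np.sqrt((a @ a) * (b @ b))
    if den == 0:
        warnings.warn("zero variance: correlation undefined", stacklevel=3)
        return float("nan")
    return float(np.clip((a @ b) / den, -1.0, 1.0))


def regression_metrics(
    y_true,
    y_pred,
    y_train_true=None,
    y_train_pred=None,
) -> MetricsReport:
    """MAPE (%), RMSE and R^2 of predictions, plus Rc/RMSEC (training set)
    and Rp/RMSEP (test set) when the training pair is supplied.

    ``MAPE = 100/n sum |y - yhat| / |y|`` (requires non-zero y),
    ``RMSE = sqrt(mean (y - yhat)^2)``,
    ``R^2 = 1 - SS_res / SS_tot``; Rc/Rp are Pearson correlations and
    RMSEC/RMSEP the RMSEs on the respective sets.
    """
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must be equal, non-zero length")
    if np.any(y_true == 0):
        raise ValueError("MAPE undefined: y_true contains zeros")
    err = y_true - y_pred
    mape = float(100.0 * np.mean(np.abs(err) / np.abs(y_true)))
    rmse = float(np.sqrt(np.mean(err**2)))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        warnings.warn("zero-variance y_true: R^2 undefined", stacklevel=2)
        r2 = float("nan")
    else:
        r2 = 1.0 - float(np.sum(err**2)) / ss_tot
    rp = _pearson(y_true, y_pred)
    rmsep = rmse
    if y_train_true is not None and y_train_pred is not None:
        yt = np.asarray(y_train_true, dtype=np.float64)
        yp = np.asarray(y_train_pred, dtype=np.float64)
        rc = _pearson(yt, yp)
        rmsec = float(np.sqrt(np.mean((yt - yp) ** 2)))
    else:
        rc, rmsec = float("nan"), float("nan")
    return MetricsReport(
        mape=mape, rmse=rmse, r2=r2, rc=rc, rmsec=rmsec, rp=rp, rmsep=rmsep
    )


def evaluate_model(
    model, data: TraitMatrix, train_fraction: float = 0.8, seed: int = 0
):
    """Fit ``model`` on a stratified split and report the full protocol:
    the metrics report plus rounded-label test accuracy."""
    train, test = train_test_split(data, train_fraction, seed)
    model.fit(train.X, train.y)
    pred_test = model.predict(test.X)
    pred_train = model.predict(train.X)
    report = regression_metrics(
        test.y.astype(float), pred_test, train.y.astype(float), pred_train
    )
    labels = model.predict_label(test.X)
    accuracy = float(np.mean(labels == test.y.astype(int)))
    return report, accuracy
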