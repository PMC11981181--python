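"""Linear soft-margin SVM core with fast leave-one-out cross-validation.

Solves the L2-regularized hinge-loss SVM in the dual by coordinate
descent (the liblinear formulation: the bias enters as an augmented
constant feature and is regularized). Everything is compiled with numba
because wrapper feature selection evaluates LOOCV for thousands of
(feature subset, cost) pairs, and nested cross-validation multiplies that
by the number of outer folds; per-fit overhead dominates at these sizes.

Per-fold standardization is built into the LOOCV routines: each held-out
sample is z-scored with the mean/SD of the remaining n-1 rows, so no
information leaks from the test sample into the scaler.

Deterministic by construction: fixed coordinate order, no shuffling.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: Decision value assigned when a training fold is single-class: the fold
#: degenerately predicts the training class with maximal confidence.
_DEGENERATE_DECISION = 1e6


@njit(cache=False)
def _dual_cd(Xa: np.ndarray, y: np.ndarray, C: float, max_iter: int, tol: float) -> np.ndarray:
    """Dual coordinate descent for min_w 0.5||w||^2 + C sum hinge(y_i w.x_i).

    ``Xa`` must already include the bias column. Returns ``w`` (d+1,).
    """
    n, d = Xa.shape
    alpha = np.zeros(n)
    w = np.zeros(d)
    qii = np.empty(n)
    for i in range(n):
        s = 0.0
        for j in range(d):
            s += Xa[i, j] * Xa[i, j]
        qii[i] = s
    for _ in range(max_iter):
        max_viol = 0.0
        for i in range(n):
            if qii[i] <= 0.0:
                continue
            g = 0.0
            for j in range(d):
                g += w[j] * Xa[i, j]
            g = y[i] * g - 1.0
            if alpha[i] <= 0.0:
                pg = g if g < 0.0 else 0.0
            elif alpha[i] >= C:
                pg = g if g > 0.0 else 0.0
            else:
                pg = g
            if pg != 0.0:
                av = -pg if pg < 0.0 else pg
                if av > max_viol:
                    max_viol = av
                a_old = alpha[i]
                a_new = a_old - g / qii[i]
                if a_new < 0.0:
                    a_new = 0.0
                elif a_new > C:
                    a_new = C
                alpha[i] = a_new
                da = (a_new - a_old) * y[i]
                if da != 0.0:
                    for j in range(d):
                        w[j] += da * Xa[i, j]
        if max_viol < tol:
            break
    return w


@njit(cache=False)
def _loocv_decisions(
    X: np.ndarray, y: np.ndarray, C: float, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out decision values with per-fold z-scoring.

    Returns ``(dec, degenerate)`` where ``dec[i]`` is the decision value
    of the model trained without sample i, evaluated on sample i, and
    ``degenerate[i]`` flags single-class training folds.
    """
    n, d = X.shape
    dec = np.empty(n)
    degen = np.zeros(n, dtype=np.bool_)
    colsum = np.zeros(d)
    possum = 0.0
    for i in range(n):
        for j in range(d):
            colsum[j] += X[i, j]
        if y[i] > 0:
            possum += 1.0
    Xtr = np.empty((n - 1, d + 1))
    ytr = np.empty(n - 1)
    mean = np.empty(d)
    sd = np.empty(d)
    for i in range(n):
        npos = possum - (1.0 if y[i] > 0 else 0.0)
        if npos == 0.0 or npos == n - 1:
            cls = 1.0 if npos == n - 1 else -1.0
            dec[i] = cls * _DEGENERATE_DECISION
            degen[i] = True
            continue
        for j in range(d):
            mean[j] = (colsum[j] - X[i, j]) / (n - 1)
        for j in range(d):
            acc = 0.0
            for k in range(n):
                if k == i:
                    continue
                dv = X[k, j] - mean[j]
                acc += dv * dv
            v = acc / (n - 1)
            sd[j] = np.sqrt(v) if v > 1e-24 else 1.0
        r = 0
        for k in range(n):
            if k == i:
                continue
            for j in range(d):
                Xtr[r, j] = (X[k, j] - mean[j]) / sd[j]
            Xtr[r, d] = 1.0
            ytr[r] = y[k]
            r += 1
        w = _dual_cd(Xtr, ytr, C, max_iter, tol)
        s = w[d]
        for j in range(d):
            s += w[j] * (X[i, j] - mean[j]) / sd[j]
        dec[i] = s
    return dec, degen


@njit(cache=False)
def _loocv_accuracy(X: np.ndarray, y: np.ndarray, C: float, max_iter: int, tol: float) -> tuple[int, int, int, int]:
    """Confusion counts (tp, fn, tn, fp) from LOOCV; positive class y=+1."""
    dec, _ = _loocv_decisions(X, y, C, max_iter, tol)
    tp = fn = tn = fp = 0
    for i in range(len(y)):
        pred_pos = dec[i] > 0.0
        if y[i] > 0:
            if pred_pos:
                tp += 1
            else:
                fn += 1
        else:
            if pred_pos:
                fp += 1
            else:
                tn += 1
    return tp, fn, tn, fp


def loocv_decisions(
    X: np.ndarray, y: np.ndarray, C: float, max_iter: int = 1000, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Python-facing wrapper; ``y`` in {-1, +1}."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    return _loocv_decisions(X, y, float(C), max_iter, tol)


def loocv_confusion_counts(
    X: np.ndarray, y: np.ndarray, C: float, max_iter: int = 1000, tol: float = 1e-8
) -> tuple[int, int, int, int]:
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    return _loocv_accuracy(X, y, float(C), max_iter, tol)


class LinearSVM:
    """A fitted linear SVM with z-score standardization baked in.

    ``decision_function(X)`` = ``w . z(X) + b`` where ``z`` standardizes
    with the training mean/SD. Weights are in standardized-feature space.
    """

    def __init__(self, C: float = 1.0, max_iter: int = 1000, tol: float = 1e-8,
                 standardize: bool = True):
        self.C = float(C)
        self.max_iter = max_iter
        self.tol = tol
        self.standardize = standardize

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LinearSVM":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if set(np.unique(y)) - {-1.0, 1.0}:
            raise ValueError("labels must be in {-1, +1}")
        if len(np.unique(y)) < 2:
            raise ValueError("training data contains a single class")
        if self.standardize:
            self.mean_ = X.mean(axis=0)
            sd = X.std(axis=0)
            self.scale_ = np.where(sd > 1e-12, sd, 1.0)
        else:
            self.mean_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        Z = (X - self.mean_) / self.scale_
        Za = np.ascontiguousarray(np.hstack([Z, np.ones((len(Z), 1))]))
        w = _dual_cd(Za, np.ascontiguousarray(y), self.C, self.max_iter, self.tol)
        self.coef_ = w[:-1]
        self.intercept_ = float(w[-1])
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=np.float64) - self.mean_) / self.scale_
        return Z @ self.coef_ + self.intercept_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X) > 0, 1, -1)


def warmup() -> None:
    """Trigger numba compilation on a toy problem (one-off per process)."""
    X = np.array([[0.0, 1.0], [1.0, 0.0], [2.0, 2.0], [3.0, 1.0]])
    y = np.array([-1.0, -1.0, 1.0, 1.0])
    loocv_decisions(X, y, 1.0)
    loocv_confusion_counts(X, y, 1.0)
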