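"""Linear soft-margin SVM (C-SVC) tuned for the decoding workload.

Transfer decoding fits one binary SVM per (timepoint, bin assignment,
neighborhood pair, ROI, condition, subject) — millions of problems with a
dozen training samples and eight features each.  General-purpose wrappers
spend orders of magnitude more time in validation than in optimization at
this size, so the dual problem is solved here directly with libsvm's
algorithm: SMO with maximal-violating-pair working-set selection and the
same box-clipping and rho (intercept) rules.  The test suite checks the
solution against scikit-learn's libsvm-backed ``SVC`` (identical decision
signs, matching weight vectors) on randomized problems.

Labels are +1 / -1; ties at the decision boundary (decision value exactly
0) are broken deterministically toward the +1 class.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["fit_linear_svm", "decision_values", "accuracy_over_time"]


@njit(cache=False)
def _smo(K, y, C, tol, max_iter):
    """SMO on the C-SVC dual  min 0.5 a'Qa - e'a,  0<=a<=C,  y'a=0.

    Q_ij = y_i y_j K_ij.  Returns (alpha, rho); the decision function is
    f(x) = sum_j alpha_j y_j k(x_j, x) - rho.
    """
    n = y.shape[0]
    alpha = np.zeros(n)
    G = -np.ones(n)
    for _ in range(max_iter):
        gmax = -1e300
        gmin = 1e300
        i = -1
        j = -1
        for t in range(n):
            v = -y[t] * G[t]
            if ((y[t] > 0 and alpha[t] < C) or (y[t] < 0 and alpha[t] > 0)) and v > gmax:
                gmax = v
                i = t
            if ((y[t] < 0 and alpha[t] < C) or (y[t] > 0 and alpha[t] > 0)) and v < gmin:
                gmin = v
                j = t
        if i < 0 or j < 0 or gmax - gmin < tol:
            break
        ai_old = alpha[i]
        aj_old = alpha[j]
        quad = K[i, i] + K[j, j] - 2.0 * K[i, j]
        if quad <= 0.0:
            quad = 1e-12
        if y[i] != y[j]:
            delta = (-G[i] - G[j]) / quad
            diff = alpha[i] - alpha[j]
            alpha[i] += delta
            alpha[j] += delta
            if diff > 0.0:
                if alpha[j] < 0.0:
                    alpha[j] = 0.0
                    alpha[i] = diff
                if alpha[i] > C:
                    alpha[i] = C
                    alpha[j] = C - diff
            else:
                if alpha[i] < 0.0:
                    alpha[i] = 0.0
                    alpha[j] = -diff
                if alpha[j] > C:
                    alpha[j] = C
                    alpha[i] = C + diff
        else:
            delta = (G[i] - G[j]) / quad
            s = alpha[i] + alpha[j]
            alpha[i] -= delta
            alpha[j] += delta
            if s > C:
                if alpha[i] > C:
                    alpha[i] = C
                    alpha[j] = s - C
                if alpha[j] > C:
                    alpha[j] = C
                    alpha[i] = s - C
            else:
                if alpha[j] < 0.0:
                    alpha[j] = 0.0
                    alpha[i] = s
                if alpha[i] < 0.0:
                    alpha[i] = 0.0
                    alpha[j] = s
        dai = alpha[i] - ai_old
        daj = alpha[j] - aj_old
        for t in range(n):
            G[t] += y[t] * y[i] * K[i, t] * dai + y[t] * y[j] * K[j, t] * daj
    # intercept, libsvm's calculate_rho
    ub = 1e300
    lb = -1e300
    nfree = 0
    sfree = 0.0
    for t in range(n):
        yg = y[t] * G[t]
        if alpha[t] >= C:
            if y[t] < 0:
                ub = min(ub, yg)
            else:
                lb = max(lb, yg)
        elif alpha[t] <= 0.0:
            if y[t] > 0:
                ub = min(ub, yg)
            else:
                lb = max(lb, yg)
        else:
            nfree += 1
            sfree += yg
    rho = sfree / nfree if nfree > 0 else 0.5 * (ub + lb)
    return alpha, rho


@njit(cache=False)
def _accuracy_over_time(Xtr, ytr, Xte, yte, C, tol, max_iter):
    """Fraction of test samples classified correctly, per timepoint.

    Xtr: (n_train, T, d); Xte: (n_test, T, d); labels +-1.
    """
    T = Xtr.shape[1]
    m = Xte.shape[0]
    acc = np.empty(T)
    for t in range(T):
        Xt = np.ascontiguousarray(Xtr[:, t, :])
        K = Xt @ Xt.T
        alpha, rho = _smo(K, ytr, C, tol, max_iter)
        w = (alpha * ytr) @ Xt
        hits = 0
        for i in range(m):
            d = np.dot(Xte[i, t, :], w) - rho
            pred = 1.0 if d >= 0.0 else -1.0
            if pred == yte[i]:
                hits += 1
        acc[t] = hits / m
    return acc


def fit_linear_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0,
                   tol: float = 1e-6, max_iter: int = 100_000):
    """Fit a linear C-SVC; returns (w, b) with decision f(x) = x.w + b."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n_samples, n_features) matching y")
    if not (np.any(y > 0) and np.any(y < 0)):
        raise ValueError("training set must contain both classes")
    K = X @ X.T
    alpha, rho = _smo(K, y, C, tol, max_iter)
    w = (alpha * y) @ X
    return w, -rho


def decision_values(X: np.ndarray, w: np.ndarray, b: float) -> np.ndarray:
    return X @ w + b


def accuracy_over_time(Xtr, ytr, Xte, yte, C: float = 1.0,
                       tol: float = 1e-6, max_iter: int = 100_000) -> np.ndarray:
    """Vectorized-over-timepoints train/test accuracy (see `_accuracy_over_time`)."""
    Xtr = np.asarray(Xtr, dtype=np.float64)
    Xte = np.asarray(Xte, dtype=np.float64)
    ytr = np.asarray(ytr, dtype=np.float64)
    yte = np.asarray(yte, dtype=np.float64)
    if not (np.any(ytr > 0) and np.any(ytr < 0)):
        raise ValueError("training set must contain both classes")
    if Xtr.shape[1] != Xte.shape[1] or Xtr.shape[2] != Xte.shape[2]:
        raise ValueError("train/test feature or time dimensions differ")
    # (n, d, T) -> (n, T, d) so per-timepoint slices are contiguous
    Xtr_t = np.ascontiguousarray(np.swapaxes(Xtr, 1, 2))
    Xte_t = np.ascontiguousarray(np.swapaxes(Xte, 1, 2))
    return _accuracy_over_time(Xtr_t, ytr, Xte_t, yte, C, tol, max_iter)
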