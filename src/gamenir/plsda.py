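"""Multi-class PLS-DA: NIPALS PLS2 regression on a dummy-coded class matrix.

Class membership is one-hot (dummy) coded into Y; a PLS2 regression of the
centred spectra onto the centred indicators yields per-class response
predictions, and a sample is assigned to the class with the largest
predicted response (argmax rule; an optional 0.5-threshold rule exists for
two-class nodes).  Model complexity is the number of latent variables (LVs).

The NIPALS core is written out explicitly rather than delegated, so that the
weight/loading/score matrices the VIP statistic needs are first-class fitted
attributes; equivalence with a reference PLS implementation is asserted in
the test suite.

Accuracy follows the TN-inclusive convention: for each class, one-vs-rest
TP, TN, FP, FN are tallied and accuracy = 100*(TP+TN)/(TP+TN+FP+FN); the
overall accuracy is 100 * (correctly assigned) / (total), i.e. 100*nC/nT.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

NIPALS_MAX_ITER = 500
NIPALS_TOL = 1e-12


def dummy_code(labels, classes) -> np.ndarray:
    """One-hot indicator matrix: entry (i, c) is 1 iff sample i is in class c."""
    classes = list(classes)
    labels = np.asarray(labels)
    unknown = set(labels) - set(classes)
    if unknown:
        raise ValueError(f"labels not in class list: {sorted(unknown)}")
    Y = np.zeros((len(labels), len(classes)))
    for c, cls in enumerate(classes):
        Y[labels == cls, c] = 1.0
    return Y


def nipals_pls2(X: np.ndarray, Y: np.ndarray, n_lv: int):
    """NIPALS PLS2 on column-centred X and Y.

    Returns (x_mean, y_mean, W, P, Q, T) with unit-norm weight columns W,
    x-loadings P, y-loadings Q and x-scores T; deflation of both blocks per
    component.  The regression coefficients are B = W (P'W)^-1 Q'.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if not 1 <= n_lv <= min(n - 1, p):
        raise ValueError(f"n_lv must be in [1, {min(n - 1, p)}], got {n_lv}")
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    E = X - x_mean
    F = Y - y_mean
    if np.allclose(E, 0):
        raise ValueError("X has zero variance")
    W = np.empty((p, n_lv))
    P = np.empty((p, n_lv))
    Q = np.empty((Y.shape[1], n_lv))
    T = np.empty((n, n_lv))
    for a in range(n_lv):
        u = F[:, np.argmax(F.var(axis=0))].copy()
        if np.allclose(u, 0):      # Y fully deflated: continue on X structure
            u = E[:, np.argmax(E.var(axis=0))].copy()
        t_old = None
        for _ in range(NIPALS_MAX_ITER):
            w = E.T @ u / (u @ u)
            nw = np.linalg.norm(w)
            if nw == 0.0:
                # Y direction exactly orthogonal to X in sample space (e.g.
                # duplicated spectra across classes): fall back to the
                # dominant X column so the component captures X structure
                # and the Y loading comes out (near) zero
                u = E[:, np.argmax(E.var(axis=0))].copy()
                w = E.T @ u / (u @ u)
                nw = np.linalg.norm(w)
                if nw == 0.0:
                    raise ValueError("X residual has zero variance")
            w /= nw
            t = E @ w
            q = F.T @ t / (t @ t)
            qn = q @ q
            if qn == 0:
                break
            u = F @ q / qn
            if t_old is not None and np.linalg.norm(t - t_old) <= NIPALS_TOL * np.linalg.norm(t):
                break
            t_old = t
        else:
            raise RuntimeError(
                f"NIPALS failed to converge for LV {a + 1} "
                f"after {NIPALS_MAX_ITER} iterations"
            )
        p_a = E.T @ t / (t @ t)
        E = E - np.outer(t, p_a)
        F = F - np.outer(t, q)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, p_a, q, t
    return x_mean, y_mean, W, P, Q, T


class PLSDAClassifier(ClassifierMixin, BaseEstimator):
    """PLS-DA classifier (NIPALS PLS2 + argmax class assignment).

    Parameters
    ----------
    n_components : int
        Number of latent variables.
    decision_rule : {"argmax", "threshold"}
        "argmax" assigns the class with the largest predicted response
        (ties -> lowest class index, logged); "threshold" (two-class only)
        assigns the positive class when its response exceeds 0.5.

    Attributes (after fit)
    ----------------------
    classes_ : ordered class labels (sorted unique).
    x_mean_, y_mean_ : centering vectors.
    x_weights_ (W), x_loadings_ (P), y_loadings_ (Q), x_scores_ (T).
    coef_ : (n_channels, n_classes) regression matrix B, so that
        predicted responses = (X - x_mean_) @ coef_ + y_mean_.
    """

    def __init__(self, n_components: int = 2, decision_rule: str = "argmax"):
        self.n_components = n_components
        self.decision_rule = decision_rule

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        Y = dummy_code(y, self.classes_)
        (self.x_mean_, self.y_mean_, self.x_weights_, self.x_loadings_,
         self.y_loadings_, self.x_scores_) = nipals_pls2(X, Y, self.n_components)
        R = self.x_weights_ @ np.linalg.inv(self.x_loadings_.T @ self.x_weights_)
        self.x_rotations_ = R
        self.coef_ = R @ self.y_loadings_.T
        return self

    def decision_function(self, X) -> np.ndarray:
        """Predicted per-class responses (rows of the dummy-coded fit)."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.coef_.shape[0]:
            raise ValueError(
                f"channel mismatch: model has {self.coef_.shape[0]}, data has {X.shape[1]}"
            )
        return (X - self.x_mean_) @ self.coef_ + self.y_mean_

    def predict(self, X) -> np.ndarray:
        Yhat = self.decision_function(X)
        if self.decision_rule == "threshold":
            if len(self.classes_) != 2:
                raise ValueError("threshold rule is defined for two classes only")
            return np.where(Yhat[:, 1] > 0.5, self.classes_[1], self.classes_[0])
        # argmax; np.argmax takes the first maximum = lowest class index
        ties = (Yhat == Yhat.max(axis=1, keepdims=True)).sum(axis=1) > 1
        if ties.any():
            warnings.warn(f"{int(ties.sum())} tied response row(s); "
                          "assigned lowest class index", UserWarning)
        return self.classes_[np.argmax(Yhat, axis=1)]

    def vip(self) -> np.ndarray:
        """Variable importance in projection, per channel.

        VIP_j = sqrt( p * sum_a SSY_a w_ja^2 / sum_a SSY_a ) with unit-norm
        weights, where SSY_a = ||q_a||^2 t_a't_a is the Y-variance captured
        by LV a (calibration variance).  Mean squared VIP is 1; channels
        with VIP > 1 are deemed influential.
        """
        T, Q, W = self.x_scores_, self.y_loadings_, self.x_weights_
        ssy = np.sum(T**2, axis=0) * np.sum(Q**2, axis=0)
        p = W.shape[0]
        return np.sqrt(p * (W**2 @ ssy) / ssy.sum())


@dataclasses.dataclass
class ConfusionMatrix:
    """True-by-predicted counts plus one-vs-rest TP/TN/FP/FN bookkeeping."""

    counts: np.ndarray
    classes: list

    @classmethod
    def from_labels(cls, y_true, y_pred, classes=None) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if classes is None:
            classes = np.unique(np.concatenate([y_true, y_pred]))
        classes = list(classes)
        idx = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(y_true, y_pred):
            counts[idx[t], idx[p]] += 1
        return cls(counts, classes)

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_correct(self) -> int:
        return int(np.trace(self.counts))

    def one_vs_rest(self, cls) -> dict:
        i = self.classes.index(cls)
        tp = int(self.counts[i, i])
        fn = int(self.counts[i].sum() - tp)
        fp = int(self.counts[:, i].sum() - tp)
        tn = self.n_total - tp - fn - fp
        return {"TP": tp, "TN": tn, "FP": fp, "FN": fn}

    def accuracy(self, cls=None) -> float:
        """TN-inclusive accuracy in percent: 100*(TP+TN)/(TP+TN+FP+FN).

        With ``cls=None`` the overall accuracy 100*nC/nT.
        """
        if self.n_total == 0:
            raise ValueError("empty confusion matrix")
        if cls is None:
            return 100.0 * self.n_correct / self.n_total
        c = self.one_vs_rest(cls)
        return 100.0 * (c["TP"] + c["TN"]) / self.n_total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


def accuracy_percent(n_correct: int, n_total: int) -> float:
    """Overall accuracy from a correct/total count pair, in percent."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 100.0 * n_correct / n_total


def _fold_indices(n: int, scheme: str):
    """Held-out index arrays for 'loo' or 'venetian:k' cross-validation."""
    if scheme == "loo":
        for i in range(n):
            yield np.array([i])
    elif scheme.startswith("venetian"):
        k = int(scheme.split(":")[1]) if ":" in scheme else 10
        for b in range(k):
            fold = np.arange(b, n, k)
            if fold.size:
                yield fold
    else:
        raise ValueError(f"unknown CV scheme {scheme!r}")


def cross_validate(X, y, n_lv: int, scheme: str = "loo", groups=None,
                   decision_rule: str = "argmax"):
    """Cross-validated class predictions.

    ``scheme`` is ``"loo"`` (leave one sample out; the study's default) or
    ``"venetian:k"`` (venetian blinds with k interleaved folds).  When
    ``groups`` is given, leave-one-group-out replaces LOO — used to hold out
    whole animals, whose muscles are correlated.  Pre-treatments are
    per-spectrum row operations applied upstream, so they need no refit
    inside the loop.  Returns (ConfusionMatrix, per-sample predictions).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    classes = np.unique(y)
    if n < len(classes) + 2:
        raise ValueError("too few samples for cross-validation")
    if groups is not None:
        groups = np.asarray(groups)
        folds = [np.flatnonzero(groups == g) for g in np.unique(groups)]
    else:
        folds = list(_fold_indices(n, scheme))
    pred = np.empty(n, dtype=y.dtype)
    for fold in folds:
        train = np.setdiff1d(np.arange(n), fold)
        if len(np.unique(y[train])) < len(classes):
            warnings.warn("a class is absent from one training fold", UserWarning)
        model = PLSDAClassifier(n_components=min(n_lv, len(train) - 1),
                                decision_rule=decision_rule)
        model.fit(X[train], y[train])
        p = model.predict(X[fold])
        if not np.array_equal(model.classes_, classes):
            # a fold may drop a class; predictions are still valid labels
            pass
        pred[fold] = p
    return ConfusionMatrix.from_labels(y, pred, classes), pred


def loocv(X, y, n_lv: int, groups=None):
    """Leave-one-out cross-validation (the study's reported scheme)."""
    return cross_validate(X, y, n_lv, scheme="loo", groups=groups)
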