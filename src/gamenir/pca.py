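"""PCA exploration of mean-centred spectra with influence-based outlier flagging.

The decomposition is the plain SVD of the mean-centred spectra matrix,
implemented directly (no scikit-learn) so its conventions are explicit:
scores are U*S, loadings are the right singular vectors, and for
reproducibility each component's sign is fixed so that the largest-magnitude
loading element is positive.  Seven components is the study's default cap.

Outlier screening follows the influence-plot idea: Hotelling's T-squared
(leverage within the model plane) and the Q residual (distance from the
plane).  The study inspected these visually; here the rule is quantitative —
samples beyond an empirical quantile of either statistic are flagged — so it
can be tested and its parameters exposed.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

MAX_COMPONENTS_DEFAULT = 7


class SpectralPCA(TransformerMixin, BaseEstimator):
    """PCA on mean-centred spectra via SVD.

    Parameters
    ----------
    n_components : int, default 7
        Requested components; silently clipped (with a warning) to
        ``min(n_samples - 1, n_channels)``.

    Attributes (after fit)
    ----------------------
    mean_ : (n_channels,) per-channel mean spectrum.
    loadings_ : (n_channels, n_components), orthonormal columns.
    scores_ : (n_samples, n_components), U*S of the training data.
    explained_variance_ratio_ : (n_components,) non-increasing, sums <= 1.
    """

    def __init__(self, n_components: int = MAX_COMPONENTS_DEFAULT):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if n < 2:
            raise ValueError("PCA needs at least 2 samples")
        limit = min(n - 1, p)
        k = self.n_components
        if k > limit:
            warnings.warn(f"n_components={k} clipped to {limit}", UserWarning)
            k = limit
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        # sign convention: largest-|loading| element of each PC is positive
        for a in range(Vt.shape[0]):
            j = np.argmax(np.abs(Vt[a]))
            if Vt[a, j] < 0:
                Vt[a] *= -1.0
                U[:, a] *= -1.0
        total = np.sum(S**2)
        self.n_components_ = k
        self.loadings_ = Vt[:k].T
        self.scores_ = U[:, :k] * S[:k]
        self.singular_values_ = S[:k]
        self.explained_variance_ratio_ = (S[:k] ** 2) / total if total > 0 else np.zeros(k)
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.loadings_

    def inverse_transform(self, T) -> np.ndarray:
        return np.asarray(T) @ self.loadings_.T + self.mean_

    # -- exploration aids ---------------------------------------------------

    def correlation_loadings(self, X) -> np.ndarray:
        """Pearson correlation of each centred channel with each PC score.

        Entry (j, a) tells how much of channel j a component models; values
        near +/-1 mark the wavelengths a PC is built on.  Zero-variance
        channels get 0 with a warning.
        """
        X = np.asarray(X, dtype=float)
        Xc = X - X.mean(axis=0)
        T = self.transform(X)
        Tc = T - T.mean(axis=0)
        ch_sd = Xc.std(axis=0)
        t_sd = Tc.std(axis=0)
        zero = ch_sd == 0
        if zero.any():
            warnings.warn(f"{int(zero.sum())} zero-variance channel(s); "
                          "correlation loadings set to 0", UserWarning)
        denom = np.outer(np.where(zero, 1.0, ch_sd), np.where(t_sd == 0, 1.0, t_sd))
        corr = (Xc.T @ Tc) / (len(X) * denom)
        corr[zero, :] = 0.0
        corr[:, t_sd == 0] = 0.0
        return np.clip(corr, -1.0, 1.0)

    def influence_stats(self, X):
        """Per-sample Hotelling T-squared and Q residual.

        T^2 = sum_a t_a^2 / var(t_a) with the training score variances;
        Q = squared norm of the off-plane reconstruction residual.
        """
        X = np.asarray(X, dtype=float)
        T = self.transform(X)
        var = self.scores_.var(axis=0, ddof=1)
        var = np.where(var > 0, var, np.inf)   # degenerate PCs contribute 0
        t2 = np.sum(T**2 / var, axis=1)
        resid = (X - self.mean_) - T @ self.loadings_.T
        q = np.sum(resid**2, axis=1)
        return t2, q


def flag_outliers(t2: np.ndarray, q: np.ndarray,
                  t2_quantile: float = 0.975, q_quantile: float = 0.975) -> np.ndarray:
    """Indices of samples beyond either empirical-quantile threshold.

    Quantiles of 1.0 disable a criterion.  Re-fitting after removal is the
    caller's job (the study recalculated PCA once after removing outliers).
    """
    t2 = np.asarray(t2, dtype=float)
    q = np.asarray(q, dtype=float)
    if t2.size < 10:
        warnings.warn("fewer than 10 samples: quantile thresholds are unstable",
                      UserWarning)
    t2_cut = np.quantile(t2, t2_quantile) if t2_quantile < 1.0 else np.inf
    q_cut = np.quantile(q, q_quantile) if q_quantile < 1.0 else np.inf
    return np.flatnonzero((t2 > t2_cut) | (q > q_cut))


def outlier_pass(X: np.ndarray, n_components: int = MAX_COMPONENTS_DEFAULT,
                 t2_quantile: float = 0.975, q_quantile: float = 0.975):
    """One screen-and-refit round: fit PCA, flag, refit on the survivors.

    Returns (kept_indices, flagged_indices, refitted_model).
    """
    model = SpectralPCA(n_components=n_components).fit(X)
    t2, q = model.influence_stats(X)
    flagged = flag_outliers(t2, q, t2_quantile, q_quantile)
    kept = np.setdiff1d(np.arange(len(X)), flagged)
    refit = SpectralPCA(n_components=n_components).fit(X[kept])
    return kept, flagged, refit
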