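"""Spectral pre-treatments as scikit-learn style transformers.

Four row-wise (per-spectrum) operations: moving-average smoothing, standard
normal variate (SNV), polynomial detrend, and Savitzky-Golay smoothing /
derivatives.  All are stateless with respect to the training data (``fit``
only validates), which is what makes leave-one-out cross-validation with
pre-treatments leakage-free: each spectrum is transformed using only its own
values.

A :class:`PreprocessPipeline` is an ordered list of steps with a
deterministic short label in the field's notation, e.g. ``SNV+DT+SGd2(7)``
for SNV, detrend, then a second-derivative 7-point Savitzky-Golay filter.
"""

from __future__ import annotations

import math

import numpy as np
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

from .dataset import SpectraSet


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    return X


class MovingAverage(TransformerMixin, BaseEstimator):
    """Centered moving-average smoothing with truncated windows at the edges.

    Interior channel i becomes the mean over [i-h, i+h], h = (window-1)/2;
    the first/last h channels average whatever part of the window exists.
    """

    def __init__(self, window: int = 5):
        self.window = window

    def fit(self, X, y=None):
        if self.window % 2 == 0 or self.window < 3:
            raise ValueError("moving-average window must be odd and >= 3")
        if _as_matrix(X).shape[1] < self.window:
            raise ValueError("window exceeds channel count")
        return self

    def transform(self, X):
        X = _as_matrix(X)
        self.fit(X)
        n = X.shape[1]
        h = (self.window - 1) // 2
        # cumulative-sum windowed means with edge truncation
        cs = np.concatenate([np.zeros((X.shape[0], 1)), np.cumsum(X, axis=1)], axis=1)
        lo = np.maximum(np.arange(n) - h, 0)
        hi = np.minimum(np.arange(n) + h, n - 1)
        return (cs[:, hi + 1] - cs[:, lo]) / (hi - lo + 1)


class SNV(TransformerMixin, BaseEstimator):
    """Standard normal variate: center and scale each spectrum.

    Removes additive offsets and multiplicative scatter; every output row has
    mean 0 and sample standard deviation 1 (ddof=1, the chemometrics
    convention).
    """

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = _as_matrix(X)
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=1, keepdims=True)
        bad = np.flatnonzero(sd.ravel() == 0)
        if bad.size:
            raise ValueError(f"SNV undefined for constant spectrum at row(s) {bad.tolist()}")
        return (X - mu) / sd


class Detrend(TransformerMixin, BaseEstimator):
    """Subtract a least-squares polynomial baseline from each spectrum.

    Order 2 (the usual choice after SNV) removes offset, slope and curvature.
    The fit uses the wavelength axis when given, else channel index; the
    residual is identical either way for an affine re-parameterisation, and
    the axis is rescaled to [-1, 1] internally for conditioning.
    """

    def __init__(self, order: int = 2, wavelengths=None):
        self.order = order
        self.wavelengths = wavelengths

    def _basis(self, n_channels: int) -> np.ndarray:
        x = (np.arange(n_channels, dtype=float) if self.wavelengths is None
             else np.asarray(self.wavelengths, dtype=float))
        if x.size != n_channels:
            raise ValueError("wavelength axis length does not match channel count")
        x = 2.0 * (x - x.min()) / (x.max() - x.min()) - 1.0
        return np.vander(x, self.order + 1, increasing=True)

    def fit(self, X, y=None):
        if self.order >= _as_matrix(X).shape[1]:
            raise ValueError("detrend order must be < number of channels")
        return self

    def transform(self, X):
        X = _as_matrix(X)
        self.fit(X)
        V = self._basis(X.shape[1])
        coef, *_ = np.linalg.lstsq(V, X.T, rcond=None)
        return X - (V @ coef).T


def savgol_coefficients(window: int, poly_order: int, deriv_order: int = 0,
                        spacing: float = 1.0, offset: float = 0.0) -> np.ndarray:
    """Savitzky-Golay convolution weights from the local least-squares fit.

    A polynomial of degree ``poly_order`` is fitted to ``window`` equally
    spaced points and its ``deriv_order``-th derivative evaluated at
    ``offset`` channels from the window center (0 = classic centered filter).
    Weights are scaled by ``spacing**deriv_order`` so the output is a
    derivative per nm (or whatever unit the spacing carries).
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if not 0 <= poly_order < window:
        raise ValueError("need 0 <= poly_order < window")
    if not 0 <= deriv_order <= poly_order:
        raise ValueError("need 0 <= deriv_order <= poly_order")
    h = (window - 1) // 2
    t = np.arange(-h, h + 1, dtype=float)
    A = np.vander(t, poly_order + 1, increasing=True)     # A[m, k] = t_m^k
    # row of the pseudo-inverse: derivative of the fitted polynomial at `offset`
    e = np.zeros(poly_order + 1)
    for k in range(deriv_order, poly_order + 1):
        e[k] = math.factorial(k) / math.factorial(k - deriv_order) * offset ** (k - deriv_order)
    weights = np.linalg.solve(A.T @ A, A.T).T @ e          # = pinv(A).T @ e
    return weights / spacing ** deriv_order


class SavitzkyGolay(TransformerMixin, BaseEstimator):
    """Savitzky-Golay smoothing / derivative filter, SGd_k(w) in the field's
    notation (k-th derivative, polynomial order ``poly_order``, w points).

    Interior channels are the centered convolution; the first and last half
    windows are evaluated from the polynomial fitted to the first/last full
    window, so output length equals input length and the filter is exact on
    polynomials of degree <= poly_order everywhere, edges included.

    Requires a uniform axis (within 1% of the mean spacing); the derivative
    is returned per nm when ``wavelengths`` is given, per channel otherwise.
    """

    def __init__(self, window: int = 7, poly_order: int = 2, deriv_order: int = 1,
                 wavelengths=None):
        self.window = window
        self.poly_order = poly_order
        self.deriv_order = deriv_order
        self.wavelengths = wavelengths

    def _spacing(self, n_channels: int) -> float:
        if self.wavelengths is None:
            return 1.0
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.size != n_channels:
            raise ValueError("wavelength axis length does not match channel count")
        d = np.diff(wl)
        if np.max(np.abs(d - d.mean())) > 0.01 * d.mean():
            raise ValueError("Savitzky-Golay requires a uniform axis (within 1%); resample first")
        return float(d.mean())

    def fit(self, X, y=None):
        if _as_matrix(X).shape[1] < self.window:
            raise ValueError("window exceeds channel count")
        savgol_coefficients(self.window, self.poly_order, self.deriv_order)
        return self

    def transform(self, X):
        X = _as_matrix(X)
        self.fit(X)
        n = X.shape[1]
        h = (self.window - 1) // 2
        spacing = self._spacing(n)
        center = savgol_coefficients(self.window, self.poly_order,
                                     self.deriv_order, spacing)
        out = np.empty_like(X)
        # interior: correlation with the centered weights
        for i in range(h, n - h):
            out[:, i] = X[:, i - h:i + h + 1] @ center
        # edges: evaluate the first/last full-window polynomial off-center
        for j in range(h):
            w_lo = savgol_coefficients(self.window, self.poly_order,
                                       self.deriv_order, spacing, offset=j - h)
            out[:, j] = X[:, :self.window] @ w_lo
            w_hi = savgol_coefficients(self.window, self.poly_order,
                                       self.deriv_order, spacing, offset=h - j)
            out[:, n - 1 - j] = X[:, n - self.window:] @ w_hi
        return out


# ---------------------------------------------------------------------------
# Pipelines
# ---------------------------------------------------------------------------

def step_label(step) -> str:
    """Short field-notation label for one step."""
    if isinstance(step, MovingAverage):
        return f"MA({step.window})"
    if isinstance(step, SNV):
        return "SNV"
    if isinstance(step, Detrend):
        return "DT" if step.order == 2 else f"DT{step.order}"
    if isinstance(step, SavitzkyGolay):
        return f"SGd{step.deriv_order}({step.window})"
    raise TypeError(f"unknown preprocessing step {type(step).__name__}")


class PreprocessPipeline:
    """Ordered pre-treatment steps applied left to right.

    The composite label reads in application order, e.g. ``SNV+DT+SGd2(7)``
    means SNV, then detrend, then the 7-point second-derivative filter.
    """

    def __init__(self, steps=()):
        self.steps = list(steps)

    @property
    def label(self) -> str:
        return "+".join(step_label(s) for s in self.steps) if self.steps else "raw"

    def transform(self, X, wavelengths=None) -> np.ndarray:
        X = _as_matrix(X)
        for i, step in enumerate(self.steps):
            step = self._with_axis(step, wavelengths)
            try:
                X = step.transform(X)
            except ValueError as err:
                raise ValueError(f"step {i} ({step_label(step)}): {err}") from err
        return X

    @staticmethod
    def _with_axis(step, wavelengths):
        if wavelengths is not None and isinstance(step, (Detrend, SavitzkyGolay)):
            params = step.get_params()
            params["wavelengths"] = wavelengths
            return type(step)(**params)
        return step

    def apply(self, dataset: SpectraSet) -> SpectraSet:
        """Apply to a SpectraSet; metadata untouched, label recorded."""
        X = self.transform(dataset.X, wavelengths=dataset.wavelengths)
        return dataset.with_X(X, step=self.label)

    # -- serialisation ------------------------------------------------------

    _KINDS = {"moving_average": MovingAverage, "snv": SNV,
              "detrend": Detrend, "savgol": SavitzkyGolay}

    def to_config(self) -> list:
        out = []
        for step in self.steps:
            kind = {MovingAverage: "moving_average", SNV: "snv",
                    Detrend: "detrend", SavitzkyGolay: "savgol"}[type(step)]
            params = {k: v for k, v in step.get_params().items()
                      if k != "wavelengths" and v is not None}
            out.append({"kind": kind, **params})
        return out

    @classmethod
    def from_config(cls, config: list) -> "PreprocessPipeline":
        steps = []
        for entry in config:
            entry = dict(entry)
            kind = entry.pop("kind")
            if kind not in cls._KINDS:
                raise ValueError(f"unknown preprocessing kind {kind!r}")
            steps.append(cls._KINDS[kind](**entry))
        return cls(steps)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_config(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PreprocessPipeline":
        with open(path) as fh:
            return cls.from_config(yaml.safe_load(fh) or [])

    def __repr__(self):
        return f"PreprocessPipeline({self.label!r})"


# Common named pipelines from the study's model tables.
def snv_detrend() -> PreprocessPipeline:
    return PreprocessPipeline([SNV(), Detrend(order=2)])


def sg_derivative(deriv: int, window: int, poly_order: int = 2) -> PreprocessPipeline:
    return PreprocessPipeline([SavitzkyGolay(window, poly_order, deriv)])


def snv_detrend_sg(deriv: int, window: int, poly_order: int = 2) -> PreprocessPipeline:
    return PreprocessPipeline([SNV(), Detrend(order=2),
                               SavitzkyGolay(window, poly_order, deriv)])
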