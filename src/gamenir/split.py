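"""Kennard-Stone calibration/validation sample selection.

The Kennard-Stone (KS) algorithm picks a representative calibration subset
deterministically: the first two samples are the globally most distant pair
in Euclidean x-space, and every subsequent pick maximises the minimum
distance to the already-selected set (maximin).  The remaining samples form
the validation set.  The study's convention is a 70/30 split computed on the
pre-processed spectra.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

from .dataset import SpectraSet


@dataclasses.dataclass
class SplitResult:
    """Calibration/validation partition with KS selection order."""

    cal_indices: np.ndarray      # ordered: selection rank -> row index
    val_indices: np.ndarray

    def __post_init__(self):
        self.cal_indices = np.asarray(self.cal_indices, dtype=int)
        self.val_indices = np.asarray(self.val_indices, dtype=int)

    @property
    def selection_order(self) -> dict:
        """Row index -> rank at which it entered the calibration set."""
        return {int(i): rank for rank, i in enumerate(self.cal_indices)}

    def to_manifest(self) -> dict:
        return {"cal_indices": self.cal_indices.tolist(),
                "val_indices": self.val_indices.tolist()}


def distance_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances d(i,j) = ||x_i - x_j||."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    D = cdist(X, X, metric="euclidean")
    np.fill_diagonal(D, 0.0)
    return D


def kennard_stone(X: np.ndarray, k: int) -> SplitResult:
    """Select ``k`` calibration samples by the KS maximin rule.

    Ties are broken by the smallest row index, so runs are reproducible and
    invariant to re-running on identical input.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= {n}, got k={k}")
    D = distance_matrix(X)
    # seed pair: global maximum distance; flat argmax -> lexicographically
    # smallest (i, j), i.e. smallest-row-index tie-break
    i, j = np.unravel_index(np.argmax(D), D.shape)
    selected = [int(min(i, j)), int(max(i, j))]
    mask = np.ones(n, dtype=bool)
    mask[selected] = False
    mind = np.minimum(D[selected[0]], D[selected[1]])
    while len(selected) < k:
        cand = np.where(mask, mind, -np.inf)
        nxt = int(np.argmax(cand))          # first occurrence = smallest index
        selected.append(nxt)
        mask[nxt] = False
        mind = np.minimum(mind, D[nxt])
    val = np.flatnonzero(mask)
    return SplitResult(np.array(selected), val)


def cal_fraction_size(n: int, fraction: float) -> int:
    """Round-half-up calibration size, e.g. n=307, 0.7 -> 215."""
    return int(math.floor(fraction * n + 0.5))


def cal_val_split(dataset: SpectraSet, cal_fraction: float = 0.70) -> SplitResult:
    """KS split of a SpectraSet into calibration and validation subsets."""
    if not 0.0 < cal_fraction < 1.0:
        raise ValueError("cal_fraction must be in (0, 1)")
    n = dataset.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples to split")
    k = max(2, min(n - 1, cal_fraction_size(n, cal_fraction)))
    return kennard_stone(dataset.X, k)


class KennardStoneSplitter(BaseEstimator):
    """Estimator-style wrapper usable where a splitter object is expected.

    ``split(X)`` yields a single (cal, val) index pair, mirroring the
    scikit-learn cross-validator iteration protocol.
    """

    def __init__(self, cal_fraction: float = 0.70, stratify_by=None):
        self.cal_fraction = cal_fraction
        self.stratify_by = stratify_by

    def get_n_splits(self, X=None, y=None, groups=None) -> int:
        return 1

    def split(self, X, y=None, groups=None):
        X = np.asarray(X, dtype=float)
        if self.stratify_by is None:
            k = max(2, min(len(X) - 1, cal_fraction_size(len(X), self.cal_fraction)))
            res = kennard_stone(X, k)
            yield res.cal_indices.copy(), res.val_indices.copy()
            return
        # stratified variant (experimentation only): KS within each class
        labels = np.asarray(self.stratify_by)
        cal, val = [], []
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            k = max(2, min(len(idx) - 1, cal_fraction_size(len(idx), self.cal_fraction)))
            res = kennard_stone(X[idx], k)
            cal.extend(idx[res.cal_indices])
            val.extend(idx[res.val_indices])
        yield np.array(sorted(cal)), np.array(sorted(val))
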