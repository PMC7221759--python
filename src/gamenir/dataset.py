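"""Spectral dataset container and I/O.

The universal currency of the pipeline is :class:`SpectraSet`: an
``(n_samples, n_channels)`` absorbance matrix, a strictly increasing
wavelength axis in nm, and a per-sample metadata table (animal id, species,
treatment, muscle, replicate).

Spectra are stored wide in CSV: one header row of wavelengths, one row per
scan.  Metadata travel either as leading labelled columns of the same file
or in a sidecar CSV keyed by ``sample_id``; both layouts are auto-detected
from the header.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

#: Metadata columns recognised in spectra files, in canonical order.
META_COLUMNS = ["sample_id", "animal_id", "species", "treatment", "muscle", "replicate"]

#: Derived metadata columns the pipeline itself may add and re-read.
DERIVED_META_COLUMNS = ["n_scans", "muscle_group"]

#: Anatomical muscle grouping used by the two-group muscle models:
#: forequarters (FQ) vs hindquarters (HQ) for ungulates; the two ostrich
#: muscles are kept as their own groups so the grouping is total.
MUSCLE_GROUPS = {
    "IS": "FQ",
    "SS": "FQ",
    "BF": "HQ",
    "fillet": "HQ",
    "LTL": "HQ",
    "SM": "HQ",
    "ST": "HQ",
    "BD": "BD",
    "FF": "FF",
}

UNGULATE_MUSCLES = ["LTL", "BF", "SM", "ST", "IS", "SS", "fillet"]
OSTRICH_MUSCLES = ["BD", "FF"]


class FormatError(ValueError):
    """Raised when a spectra file does not match the expected layout."""


def check_axis(wavelengths: np.ndarray) -> np.ndarray:
    """Validate a wavelength axis: 1-D, length >= 2, finite, strictly increasing."""
    wl = np.asarray(wavelengths, dtype=float)
    if wl.ndim != 1 or wl.size < 2:
        raise ValueError("wavelength axis must be a 1-D vector of length >= 2")
    if not np.all(np.isfinite(wl)):
        raise ValueError("wavelength axis contains non-finite values")
    if not np.all(np.diff(wl) > 0):
        raise ValueError("wavelength axis must be strictly increasing")
    return wl


@dataclasses.dataclass
class SpectraSet:
    """Spectral matrix + wavelength axis + per-sample metadata.

    Parameters
    ----------
    X : ndarray of shape (n_samples, n_channels)
        Absorbance spectra (the canonical internal unit).
    wavelengths : ndarray of shape (n_channels,)
        Strictly increasing axis in nm.
    meta : DataFrame with n_samples rows
        Sample metadata; expected columns are a subset of ``META_COLUMNS``.
    provenance : list of str
        Labels of the processing steps applied so far.
    """

    X: np.ndarray
    wavelengths: np.ndarray
    meta: pd.DataFrame
    provenance: list = dataclasses.field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.wavelengths = check_axis(self.wavelengths)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x channels)")
        if self.X.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"X has {self.X.shape[1]} channels but axis has {self.wavelengths.size}"
            )
        if len(self.meta) != self.X.shape[0]:
            raise ValueError("meta row count does not match X")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite values")
        self.meta = self.meta.reset_index(drop=True)
        key_cols = [c for c in ("animal_id", "muscle", "treatment", "replicate") if c in self.meta]
        if key_cols == ["animal_id", "muscle", "treatment", "replicate"]:
            if self.meta.duplicated(subset=key_cols).any():
                raise ValueError("duplicated (animal_id, muscle, treatment, replicate) keys")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_channels(self) -> int:
        return self.X.shape[1]

    def copy(self) -> "SpectraSet":
        return SpectraSet(
            self.X.copy(), self.wavelengths.copy(), self.meta.copy(), list(self.provenance)
        )

    def with_X(self, X: np.ndarray, step: str | None = None) -> "SpectraSet":
        """Return a copy with a new spectra matrix (same axis and metadata)."""
        prov = self.provenance + ([step] if step else [])
        return SpectraSet(X, self.wavelengths.copy(), self.meta.copy(), prov)

    def select(self, mask_or_indices) -> "SpectraSet":
        """Row subset, keeping metadata aligned."""
        idx = np.asarray(mask_or_indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SpectraSet(
            self.X[idx], self.wavelengths.copy(),
            self.meta.iloc[idx].reset_index(drop=True), list(self.provenance),
        )

    def add_muscle_group(self) -> "SpectraSet":
        """Attach the FQ/HQ (or BD/FF) ``muscle_group`` metadata column."""
        out = self.copy()
        out.meta["muscle_group"] = out.meta["muscle"].map(MUSCLE_GROUPS)
        if out.meta["muscle_group"].isna().any():
            bad = out.meta.loc[out.meta["muscle_group"].isna(), "muscle"].unique()
            raise ValueError(f"unknown muscle codes: {sorted(bad)}")
        return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except (TypeError, ValueError):
        return False


def write_spectra(dataset: SpectraSet, path, float_format: str = "%.17g") -> None:
    """Write a SpectraSet as a wide CSV with leading metadata columns."""
    spectra = pd.DataFrame(
        dataset.X, columns=[f"{wl:.10g}" for wl in dataset.wavelengths],
        index=dataset.meta.index)
    wide = pd.concat([dataset.meta, spectra], axis=1)
    wide.to_csv(path, index=False, float_format=float_format)


def read_spectra(path, sidecar=None, units: str = "absorbance") -> SpectraSet:
    """Read a wide spectra CSV into a canonical :class:`SpectraSet`.

    The header row carries wavelengths (nm); non-numeric leading columns are
    metadata.  A ``sidecar`` metadata CSV keyed by ``sample_id`` may supply
    the metadata instead.  Columns are permuted so the axis is ascending.
    With ``units="reflectance"`` spectra are converted to absorbance on load.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    meta_cols = [c for c in df.columns if not _is_number(c)]
    wl_cols = [c for c in df.columns if _is_number(c)]
    if not wl_cols:
        raise FormatError(f"{path}: no numeric wavelength columns in header")
    unknown = [c for c in meta_cols if c not in META_COLUMNS + DERIVED_META_COLUMNS]
    if unknown:
        raise FormatError(f"{path}: non-numeric header fields {unknown} are not metadata columns")
    wl = np.array([float(c) for c in wl_cols])
    X = df[wl_cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise FormatError(f"{path}: ragged or non-numeric spectral rows")
    order = np.argsort(wl)
    wl, X = wl[order], X[:, order]

    meta = df[meta_cols].copy()
    if sidecar is not None:
        side = pd.read_csv(sidecar)
        if "sample_id" not in side.columns:
            raise FormatError("sidecar metadata must contain a sample_id column")
        if "sample_id" not in meta.columns:
            raise FormatError("spectra file needs a sample_id column to join a sidecar")
        meta = meta[["sample_id"]].merge(side, on="sample_id", how="left", validate="one_to_one")
    if meta.empty or meta.shape[1] == 0:
        meta = pd.DataFrame({"sample_id": [f"s{i}" for i in range(X.shape[0])]})

    dataset = SpectraSet(X, wl, meta)
    if units == "reflectance":
        dataset = to_absorbance(dataset)
    elif units != "absorbance":
        raise ValueError("units must be 'reflectance' or 'absorbance'")
    return dataset


def to_absorbance(dataset: SpectraSet) -> SpectraSet:
    """Convert reflectance to absorbance, A = log10(1/R), elementwise."""
    R = dataset.X
    if np.any(R <= 0):
        i, j = np.argwhere(R <= 0)[0]
        sid = dataset.meta.iloc[i].get("sample_id", i)
        raise ValueError(
            f"reflectance must be positive; sample {sid!r} at "
            f"{dataset.wavelengths[j]:.6g} nm has R={R[i, j]:.6g}"
        )
    return dataset.with_X(np.log10(1.0 / R), step="to_absorbance")


def average_replicates(dataset: SpectraSet) -> SpectraSet:
    """Average replicate scans to one spectrum per steak.

    Replicate groups are keyed by (animal_id, muscle, treatment); the
    replicate field is dropped and the group size recorded as ``n_scans``.
    """
    if dataset.n_samples == 0:
        raise ValueError("cannot average an empty SpectraSet")
    keys = ["animal_id", "muscle", "treatment"]
    missing = [k for k in keys if k not in dataset.meta.columns]
    if missing:
        raise ValueError(f"metadata lacks replicate-group keys: {missing}")
    grouped = dataset.meta.groupby(keys, sort=True, dropna=False)
    rows, recs = [], []
    for key, idx in grouped.indices.items():
        rows.append(dataset.X[idx].mean(axis=0))
        rec = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        rec["sample_id"] = "_".join(str(v) for v in rec.values())
        rec["n_scans"] = len(idx)
        # carry over species from the first member scan
        first = dataset.meta.iloc[idx[0]]
        if "species" in dataset.meta.columns:
            rec["species"] = first["species"]
        recs.append(rec)
    meta = pd.DataFrame(recs)
    cols = [c for c in META_COLUMNS if c in meta.columns] + ["n_scans"]
    return SpectraSet(
        np.vstack(rows), dataset.wavelengths.copy(), meta[cols],
        dataset.provenance + ["average_replicates"],
    )


def trim_wavelengths(dataset: SpectraSet, lo: float, hi: float) -> SpectraSet:
    """Keep channels with lo <= lambda <= hi (closed interval)."""
    if not lo < hi:
        raise ValueError("trim requires lo < hi")
    keep = (dataset.wavelengths >= lo) & (dataset.wavelengths <= hi)
    if not keep.any():
        raise ValueError(f"no channels in [{lo}, {hi}] nm")
    return SpectraSet(
        dataset.X[:, keep], dataset.wavelengths[keep], dataset.meta.copy(),
        dataset.provenance + [f"trim[{lo:g},{hi:g}]"],
    )
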