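"""Model evaluation reports and the end-to-end experiment runner.

`evaluate_model` produces one row in the layout of the study's model
overview tables: pre-treatment, LV count, calibration nT/nC/accuracy, CV
accuracy, and validation nT/nP/accuracy.  ``run_experiment`` chains the full
procedure — replicate averaging, wavelength trimming, optional smoothing,
a PCA outlier pass, Kennard-Stone splitting, PLS-DA fits with
cross-validation, and the hierarchical cascade — and writes CSV reports
with a provenance header.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dataset import SpectraSet, average_replicates, read_spectra, trim_wavelengths
from .hierarchy import HierarchicalClassifier, HierarchyReport
from .pca import flag_outliers, SpectralPCA
from .plsda import ConfusionMatrix, PLSDAClassifier, cross_validate
from .preprocess import MovingAverage, PreprocessPipeline
from .split import cal_val_split

TRIM_LO, TRIM_HI = 920.0, 1651.0   # instrument ends are noisy; standard window


def format_accuracy(value: float) -> str:
    """Percentage string at one decimal, round half-up; whole values bare.

    Input is a proportion in [0, 1]; 219/235 -> "93.2", 1.0 -> "100".
    """
    if not 0.0 <= value <= 1.0:
        raise ValueError("accuracy proportion must be in [0, 1]")
    pct = (Decimal(value) * 100).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    if pct == pct.to_integral_value():
        return str(int(pct))
    return str(pct)


@dataclasses.dataclass
class ModelReport:
    """One table row for a single PLS-DA model."""

    name: str
    pre_treatment: str
    n_lv: int
    cal_nT: int
    cal_nC: int
    cv_nC: int
    val_nT: int
    val_nP: int
    cal_confusion: ConfusionMatrix
    cv_confusion: ConfusionMatrix
    val_confusion: ConfusionMatrix

    @property
    def cal_accuracy_pct(self) -> float:
        return 100.0 * self.cal_nC / self.cal_nT

    @property
    def cv_accuracy_pct(self) -> float:
        return 100.0 * self.cv_nC / self.cal_nT

    @property
    def val_accuracy_pct(self) -> float:
        return 100.0 * self.val_nP / self.val_nT

    def to_row(self) -> dict:
        return dict(
            model=self.name, pre_processing=self.pre_treatment, LVs=self.n_lv,
            nT=self.cal_nT, nC=self.cal_nC,
            cal_acc=format_accuracy(self.cal_nC / self.cal_nT),
            cv_nC=self.cv_nC, cv_acc=format_accuracy(self.cv_nC / self.cal_nT),
            val_nT=self.val_nT, nP=self.val_nP,
            val_acc=format_accuracy(self.val_nP / self.val_nT),
        )


def evaluate_model(dataset: SpectraSet, label_field: str,
                   pipeline: PreprocessPipeline, n_lv: int,
                   cal_fraction: float = 0.70, cv_scheme: str = "loo",
                   name: str | None = None) -> ModelReport:
    """Pre-process, KS-split, fit, cross-validate and validate one model."""
    processed = pipeline.apply(dataset)
    split = cal_val_split(processed, cal_fraction)
    cal = processed.select(split.cal_indices)
    val = processed.select(split.val_indices)
    y_cal = cal.meta[label_field].to_numpy()
    y_val = val.meta[label_field].to_numpy()
    n_lv_eff = min(n_lv, cal.n_samples - 1, cal.n_channels)
    model = PLSDAClassifier(n_components=n_lv_eff).fit(cal.X, y_cal)
    cal_cm = ConfusionMatrix.from_labels(y_cal, model.predict(cal.X), model.classes_)
    cv_cm, _ = cross_validate(cal.X, y_cal, n_lv_eff, scheme=cv_scheme)
    val_cm = ConfusionMatrix.from_labels(y_val, model.predict(val.X), model.classes_)
    return ModelReport(
        name=name or label_field, pre_treatment=pipeline.label, n_lv=n_lv_eff,
        cal_nT=cal_cm.n_total, cal_nC=cal_cm.n_correct, cv_nC=cv_cm.n_correct,
        val_nT=val_cm.n_total, val_nP=val_cm.n_correct,
        cal_confusion=cal_cm, cv_confusion=cv_cm, val_confusion=val_cm,
    )


# ---------------------------------------------------------------------------
# Experiment orchestration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Configuration for a full experiment run.

    Either ``input_path`` (wide spectra CSV, optional ``sidecar``) or
    ``synthetic: true`` with a seed.  ``models`` lists per-model specs:
    name, label_field, optional subset (metadata equality filter), pipeline
    (preprocess config list) and n_lv.
    """

    seed: int = 0
    synthetic: bool = True
    synthetic_animals: dict | None = None      # e.g. {"zebra": 4, ...}
    synthetic_replicates: int = 3
    input_path: str | None = None
    sidecar: str | None = None
    units: str = "absorbance"
    trim: tuple = (TRIM_LO, TRIM_HI)
    smooth_window: int | None = 5
    outlier_quantile: float | None = 0.975
    cal_fraction: float = 0.70
    cv_scheme: str = "loo"
    models: list = dataclasses.field(default_factory=list)
    run_hierarchy: bool = True
    output_dir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "trim" in d:
            d["trim"] = tuple(d["trim"])
        return cls(**d)

    def digest(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("output_dir", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def default_model_specs() -> list:
    """The replication set: species, per-species treatment and muscle-group
    models with the pre-treatments and LV counts of the study's final tables."""
    return [
        dict(name="species", label_field="species", subset=None,
             pipeline=[{"kind": "savgol", "window": 7, "poly_order": 2, "deriv_order": 1}],
             n_lv=7),
        dict(name="zebra_treatment", label_field="treatment", subset={"species": "zebra"},
             pipeline=[{"kind": "savgol", "window": 5, "poly_order": 2, "deriv_order": 1}],
             n_lv=5),
        dict(name="springbok_treatment", label_field="treatment",
             subset={"species": "springbok"},
             pipeline=[{"kind": "snv"}, {"kind": "detrend", "order": 2}], n_lv=2),
        dict(name="ostrich_treatment", label_field="treatment", subset={"species": "ostrich"},
             pipeline=[{"kind": "savgol", "window": 5, "poly_order": 2, "deriv_order": 1}],
             n_lv=3),
        dict(name="zebra_muscle_group", label_field="muscle_group",
             subset={"species": "zebra"},
             pipeline=[{"kind": "snv"}, {"kind": "detrend", "order": 2},
                       {"kind": "savgol", "window": 9, "poly_order": 2, "deriv_order": 2}],
             n_lv=6),
        dict(name="springbok_muscle_group", label_field="muscle_group",
             subset={"species": "springbok"},
             pipeline=[{"kind": "snv"}, {"kind": "detrend", "order": 2},
                       {"kind": "savgol", "window": 7, "poly_order": 2, "deriv_order": 2}],
             n_lv=5),
        dict(name="ostrich_muscle", label_field="muscle", subset={"species": "ostrich"},
             pipeline=[{"kind": "snv"}, {"kind": "detrend", "order": 2}], n_lv=5),
    ]


def prepare_dataset(config: RunConfig) -> SpectraSet:
    """Load or simulate, average replicates, trim, and optionally smooth."""
    if config.synthetic:
        from .simulate import default_config, generate_dataset
        dataset = generate_dataset(default_config(
            seed=config.seed,
            animals_per_species=config.synthetic_animals,
            replicates=config.synthetic_replicates,
        ))
    else:
        if not config.input_path:
            raise ValueError("input_path required when synthetic is false")
        dataset = read_spectra(config.input_path, sidecar=config.sidecar,
                               units=config.units)
    if "replicate" in dataset.meta.columns:
        dataset = average_replicates(dataset)
    dataset = trim_wavelengths(dataset, *config.trim)
    if config.smooth_window:
        smoothed = MovingAverage(config.smooth_window).transform(dataset.X)
        dataset = dataset.with_X(smoothed, step=f"MA({config.smooth_window})")
    return dataset.add_muscle_group()


def remove_outliers(dataset: SpectraSet, quantile: float):
    """One PCA influence-plot pass; returns (kept dataset, flagged indices)."""
    model = SpectralPCA().fit(dataset.X)
    t2, q = model.influence_stats(dataset.X)
    flagged = flag_outliers(t2, q, quantile, quantile)
    kept = np.setdiff1d(np.arange(dataset.n_samples), flagged)
    return dataset.select(kept), flagged


def _provenance_header(config: RunConfig) -> str:
    return (f"# gamenir {__version__} | config {config.digest()} | "
            f"seed {config.seed}\n")


def run_experiment(config: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns a dict with the prepared dataset, per-model reports, the
    hierarchy report, and output paths.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset = prepare_dataset(config)
    flagged = np.array([], dtype=int)
    if config.outlier_quantile is not None:
        dataset, flagged = remove_outliers(dataset, config.outlier_quantile)

    specs = config.models or default_model_specs()
    reports = []
    for spec in specs:
        subset = dataset
        for field, value in (spec.get("subset") or {}).items():
            subset = subset.select(subset.meta[field].to_numpy() == value)
        pipeline = PreprocessPipeline.from_config(spec["pipeline"])
        reports.append(evaluate_model(
            subset, spec["label_field"], pipeline, spec["n_lv"],
            cal_fraction=config.cal_fraction, cv_scheme=config.cv_scheme,
            name=spec["name"],
        ))
    models_csv = outdir / "models.csv"
    frame = pd.DataFrame([r.to_row() for r in reports])
    with open(models_csv, "w") as fh:
        fh.write(_provenance_header(config))
        frame.to_csv(fh, index=False)

    hierarchy_report = None
    if config.run_hierarchy:
        clf = HierarchicalClassifier()
        root_processed = clf.root.pipeline.apply(dataset)
        split = cal_val_split(root_processed, config.cal_fraction)
        clf.fit(dataset.select(split.cal_indices))
        hierarchy_report = clf.evaluate(dataset.select(split.val_indices))
        hier_csv = outdir / "hierarchy.csv"
        with open(hier_csv, "w") as fh:
            fh.write(_provenance_header(config))
            hierarchy_report.table.to_csv(fh, index=False)

    return dict(dataset=dataset, flagged=flagged, model_reports=reports,
                hierarchy_report=hierarchy_report, output_dir=outdir)
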