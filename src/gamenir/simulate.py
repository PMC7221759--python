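"""Synthetic NIR spectra with game-meat class structure.

Real spectra of this kind show broad overtone absorption bands near 970 nm
(O-H, water), 1193 nm (C-H, fat) and 1428 nm (N-H/O-H, protein + moisture),
riding on an instrument baseline.  The generator models each class
(species x treatment x muscle) as a sum of Gaussian bands whose amplitudes
carry the class contrasts, under four nuisance effects per scan:

    a(lambda) = gain * sum_b A_b exp(-(lambda-c_b)^2 / (2 s_b^2))
                + offset + slope * (lambda - lambda_mid) + noise

with ``gain ~ 1 + N(0, gain_sd^2)`` (truncated at 0.1 so spectra stay
positive-gain), ``offset ~ N(0, baseline_offset_sd^2)``,
``slope ~ N(0, baseline_slope_sd^2)`` and i.i.d. channel noise
``N(0, noise_sd^2)``.  Gaussian bands plus offset/slope/gain nuisances make
the standard pre-treatments provably appropriate: SNV removes gain and
offset, detrend removes baseline polynomials, derivatives remove both.

Class contrasts encoded by the default profiles:

* treatment — fresh exceeds frozen-thawed at the 970 nm water band and the
  1428 nm protein/moisture band; frozen-thawed exceeds fresh at the 1193 nm
  fat band (moisture loss concentrates fat);
* species — amplitudes of the 1031 nm (protein) and 1143 nm (C-H aromatic)
  bands differ between zebra, springbok and ostrich;
* muscle group — hindquarter (and FF) muscles carry a larger 1193 nm fat
  band than forequarter (and BD) muscles.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataset import (
    MUSCLE_GROUPS,
    OSTRICH_MUSCLES,
    UNGULATE_MUSCLES,
    SpectraSet,
    check_axis,
)

SPECIES = ["zebra", "springbok", "ostrich"]
TREATMENTS = ["fresh", "frozen_thawed"]

#: Instrument axis: 125 channels spanning 908-1676 nm (~6.19 nm spacing).
AXIS_LO, AXIS_HI, AXIS_CHANNELS = 908.0, 1676.0, 125

#: Minimum multiplicative gain (truncation of 1 + N(0, gain_sd^2)).
GAIN_FLOOR = 0.1


def default_axis() -> np.ndarray:
    return np.linspace(AXIS_LO, AXIS_HI, AXIS_CHANNELS)


class ConfigurationError(ValueError):
    """Raised when a synthetic configuration is inconsistent."""


@dataclasses.dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band: center (nm), sigma (nm), amplitude (AU)."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self):
        if not self.width > 0:
            raise ConfigurationError("band width must be > 0")
        if not (AXIS_LO <= self.center <= AXIS_HI):
            raise ConfigurationError(
                f"band center {self.center} nm outside instrument axis "
                f"[{AXIS_LO:g}, {AXIS_HI:g}] nm"
            )


@dataclasses.dataclass(frozen=True)
class ClassProfile:
    """Generative profile for one (species, treatment, muscle) class."""

    species: str
    treatment: str
    muscle: str
    bands: tuple
    baseline_offset_sd: float = 0.0
    baseline_slope_sd: float = 0.0
    gain_sd: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.species not in SPECIES:
            raise ConfigurationError(f"unknown species {self.species!r}")
        if self.treatment not in TREATMENTS:
            raise ConfigurationError(f"unknown treatment {self.treatment!r}")
        allowed = OSTRICH_MUSCLES if self.species == "ostrich" else UNGULATE_MUSCLES
        if self.muscle not in allowed:
            raise ConfigurationError(
                f"muscle {self.muscle!r} not valid for {self.species} "
                f"(allowed: {allowed})"
            )
        for sd in (self.baseline_offset_sd, self.baseline_slope_sd,
                   self.gain_sd, self.noise_sd):
            if sd < 0:
                raise ConfigurationError("sd fields must be >= 0")
        object.__setattr__(self, "bands", tuple(self.bands))

    @property
    def key(self):
        return (self.species, self.treatment, self.muscle)


@dataclasses.dataclass(frozen=True, eq=False)
class SyntheticConfig:
    """Full recipe for one synthetic dataset."""

    axis: np.ndarray
    profiles: tuple
    animals_per_species: dict
    replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "axis", check_axis(self.axis))
        object.__setattr__(self, "profiles", tuple(self.profiles))
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        keys = [p.key for p in self.profiles]
        if len(set(keys)) != len(keys):
            raise ConfigurationError("duplicate (species, treatment, muscle) profiles")
        for sp in self.animals_per_species:
            if sp not in SPECIES:
                raise ConfigurationError(f"unknown species {sp!r}")
            if not any(p.species == sp for p in self.profiles):
                raise ConfigurationError(f"no profiles cover species {sp!r}")

    def profile_map(self) -> dict:
        return {p.key: p for p in self.profiles}


# ---------------------------------------------------------------------------
# Default study-design profiles
# ---------------------------------------------------------------------------

#: Shared bands: (center nm, sigma nm, base amplitude AU).
_BASE_BANDS = {"water": (970.0, 35.0, 0.50),
               "fat": (1193.0, 30.0, 0.30),
               "protein_moisture": (1428.0, 45.0, 0.45)}

#: Species signature amplitudes at the 1031 / 1143 nm bands.
_SPECIES_BANDS = {"zebra": (0.20, 0.10),
                  "springbok": (0.12, 0.18),
                  "ostrich": (0.05, 0.26)}

#: Treatment contrasts (AU added to the base amplitude).
_TREATMENT_DELTA = {
    "fresh": {"water": +0.05, "fat": 0.0, "protein_moisture": +0.04},
    "frozen_thawed": {"water": 0.0, "fat": +0.04, "protein_moisture": 0.0},
}

#: Muscle-group contrast at the fat band (HQ and FF are fattier).
_GROUP_FAT_DELTA = {"FQ": 0.0, "HQ": +0.05, "BD": 0.0, "FF": +0.05}

#: Default nuisance levels (AU, AU/nm, unitless, AU).
DEFAULT_NOISE = dict(baseline_offset_sd=0.02, baseline_slope_sd=2e-5,
                     gain_sd=0.03, noise_sd=0.002)

#: The study design: animals per species, each contributing all its muscles
#: under both treatments, scanned in triplicate.
DEFAULT_ANIMALS = {"zebra": 22, "springbok": 19, "ostrich": 10}


def high_snr_noise() -> dict:
    """The high signal-to-noise condition: default nuisances scaled by 1/10.

    Used for end-to-end separability checks where the class structure, not
    the noise floor, is under test.
    """
    return {k: v / 10.0 for k, v in DEFAULT_NOISE.items()}


def make_profile(species: str, treatment: str, muscle: str,
                 noise: dict | None = None) -> ClassProfile:
    """Build the default generative profile for one class."""
    noise = DEFAULT_NOISE if noise is None else noise
    group = MUSCLE_GROUPS[muscle]
    bands = []
    for name, (c, s, a) in _BASE_BANDS.items():
        amp = a + _TREATMENT_DELTA[treatment][name]
        if name == "fat":
            amp += _GROUP_FAT_DELTA[group]
        bands.append(BandSpec(c, s, amp))
    a1031, a1143 = _SPECIES_BANDS[species]
    bands.append(BandSpec(1031.0, 25.0, a1031))
    bands.append(BandSpec(1143.0, 25.0, a1143))
    return ClassProfile(species, treatment, muscle, tuple(bands), **noise)


def default_config(seed: int = 0,
                   animals_per_species: dict | None = None,
                   treatments=tuple(TREATMENTS),
                   replicates: int = 3,
                   noise: dict | None = None) -> SyntheticConfig:
    """The bundled study-design configuration (override pieces as needed)."""
    animals = dict(DEFAULT_ANIMALS if animals_per_species is None else animals_per_species)
    profiles = []
    for sp in animals:
        muscles = OSTRICH_MUSCLES if sp == "ostrich" else UNGULATE_MUSCLES
        for tr in treatments:
            for mu in muscles:
                profiles.append(make_profile(sp, tr, mu, noise=noise))
    return SyntheticConfig(default_axis(), tuple(profiles), animals,
                           replicates=replicates, seed=seed)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def make_design(config: SyntheticConfig) -> pd.DataFrame:
    """Expand a configuration into the sample design table.

    One row per (animal, muscle, treatment, replicate); animal ids unique
    within species; ungulates contribute seven muscles each, ostriches two.
    """
    pmap = config.profile_map()
    rows = []
    for sp, n_animals in config.animals_per_species.items():
        muscles = OSTRICH_MUSCLES if sp == "ostrich" else UNGULATE_MUSCLES
        treatments = sorted({p.treatment for p in config.profiles if p.species == sp},
                            key=TREATMENTS.index)
        for mu in muscles:
            for tr in treatments:
                if (sp, tr, mu) not in pmap:
                    raise ConfigurationError(
                        f"no profile for ({sp}, {tr}, {mu}); profiles must "
                        "cover every requested combination"
                    )
        for a in range(1, n_animals + 1):
            animal_id = f"{sp}_{a:03d}"
            for mu in muscles:
                for tr in treatments:
                    for r in range(1, config.replicates + 1):
                        rows.append(dict(
                            sample_id=f"{animal_id}_{mu}_{tr}_r{r}",
                            animal_id=animal_id, species=sp, treatment=tr,
                            muscle=mu, replicate=r,
                        ))
    return pd.DataFrame(rows)


def band_sum(bands, axis: np.ndarray) -> np.ndarray:
    """Closed-form noise-free spectrum: the sum of Gaussian bands."""
    axis = np.asarray(axis, dtype=float)
    out = np.zeros_like(axis)
    for b in bands:
        out += b.amplitude * np.exp(-0.5 * ((axis - b.center) / b.width) ** 2)
    return out


def generate_spectrum(profile: ClassProfile, axis: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Draw one scan from a class profile (see module docstring for the model)."""
    axis = check_axis(axis)
    clean = band_sum(profile.bands, axis)
    gain = max(GAIN_FLOOR, 1.0 + rng.normal(0.0, profile.gain_sd))
    offset = rng.normal(0.0, profile.baseline_offset_sd)
    slope = rng.normal(0.0, profile.baseline_slope_sd)
    noise = rng.normal(0.0, profile.noise_sd, size=axis.size)
    mid = 0.5 * (axis[0] + axis[-1])
    return gain * clean + offset + slope * (axis - mid) + noise


def generate_dataset(config: SyntheticConfig) -> SpectraSet:
    """Generate the full labelled dataset, reproducibly from ``config.seed``."""
    design = make_design(config)
    pmap = config.profile_map()
    rng = np.random.default_rng(config.seed)
    X = np.empty((len(design), config.axis.size))
    for i, rec in enumerate(design.itertuples(index=False)):
        profile = pmap[(rec.species, rec.treatment, rec.muscle)]
        X[i] = generate_spectrum(profile, config.axis, rng)
    return SpectraSet(X, config.axis.copy(), design,
                      provenance=[f"synthetic(seed={config.seed})"])


def discriminating_bands(config: SyntheticConfig, label_field: str,
                         subset: dict | None = None,
                         min_contrast: float = 0.02) -> list:
    """Bands whose amplitude differs across classes of ``label_field``.

    ``subset`` restricts the profiles considered (e.g. one species' subtree);
    returns ``(center, width)`` pairs with amplitude spread > ``min_contrast``
    between class means — the ground truth a VIP selection should recover.
    """
    profiles = list(config.profiles)
    if subset:
        for field, value in subset.items():
            profiles = [p for p in profiles if getattr(p, field) == value]
    if label_field == "muscle_group":
        label_of = lambda p: MUSCLE_GROUPS[p.muscle]
    else:
        label_of = lambda p: getattr(p, label_field)
    amp = {}
    for p in profiles:
        for b in p.bands:
            amp.setdefault((b.center, b.width), {}).setdefault(label_of(p), []).append(b.amplitude)
    out = []
    for (c, w), by_class in amp.items():
        means = [float(np.mean(v)) for v in by_class.values()]
        if len(means) > 1 and max(means) - min(means) > min_contrast:
            out.append((c, w))
    return sorted(out)


# ---------------------------------------------------------------------------
# Config serialisation
# ---------------------------------------------------------------------------

def config_to_dict(config: SyntheticConfig) -> dict:
    return {
        "axis": {"lo": float(config.axis[0]), "hi": float(config.axis[-1]),
                 "channels": int(config.axis.size)},
        "animals_per_species": {k: int(v) for k, v in config.animals_per_species.items()},
        "replicates": int(config.replicates),
        "seed": int(config.seed),
        "profiles": [
            {
                "species": p.species, "treatment": p.treatment, "muscle": p.muscle,
                "bands": [[b.center, b.width, b.amplitude] for b in p.bands],
                "baseline_offset_sd": p.baseline_offset_sd,
                "baseline_slope_sd": p.baseline_slope_sd,
                "gain_sd": p.gain_sd, "noise_sd": p.noise_sd,
            }
            for p in config.profiles
        ],
    }


def config_from_dict(d: dict) -> SyntheticConfig:
    ax = d["axis"]
    axis = np.linspace(float(ax["lo"]), float(ax["hi"]), int(ax["channels"]))
    profiles = tuple(
        ClassProfile(
            p["species"], p["treatment"], p["muscle"],
            tuple(BandSpec(*b) for b in p["bands"]),
            baseline_offset_sd=float(p.get("baseline_offset_sd", 0.0)),
            baseline_slope_sd=float(p.get("baseline_slope_sd", 0.0)),
            gain_sd=float(p.get("gain_sd", 0.0)),
            noise_sd=float(p.get("noise_sd", 0.0)),
        )
        for p in d["profiles"]
    )
    return SyntheticConfig(axis, profiles, dict(d["animals_per_species"]),
                           replicates=int(d.get("replicates", 3)),
                           seed=int(d.get("seed", 0)))


def save_config(config: SyntheticConfig, path) -> None:
    path = Path(path)
    d = config_to_dict(config)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2))


def load_config(path) -> SyntheticConfig:
    path = Path(path)
    text = path.read_text()
    d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return config_from_dict(d)
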