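import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from gamenir import SpectraSet, average_replicates, default_config, generate_dataset, trim_wavelengths
from gamenir.simulate import high_snr_noise

settings.register_profile(
    "deterministic", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def toy_set() -> SpectraSet:
    """3 samples x 5 channels with full metadata."""
    X = np.array([[0.1, 0.2, 0.3, 0.4, 0.5],
                  [1.0, 1.1, 1.2, 1.3, 1.4],
                  [2.0, 2.2, 2.4, 2.6, 2.8]])
    wl = np.array([900.0, 1000.0, 1100.0, 1200.0, 1300.0])
    meta = pd.DataFrame({
        "sample_id": ["s0", "s1", "s2"],
        "animal_id": ["a0", "a0", "a1"],
        "species": ["zebra", "zebra", "ostrich"],
        "treatment": ["fresh", "frozen_thawed", "fresh"],
        "muscle": ["LTL", "LTL", "BD"],
        "replicate": [1, 1, 1],
    })
    return SpectraSet(X, wl, meta)


def _prepared(config):
    ds = generate_dataset(config)
    ds = average_replicates(ds)
    return trim_wavelengths(ds, 920, 1651).add_muscle_group()


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down study design: 4/4/3 animals, both treatments, triplicate."""
    return default_config(seed=11, animals_per_species={"zebra": 4, "springbok": 4, "ostrich": 3})


@pytest.fixture(scope="session")
def small_dataset(small_config) -> SpectraSet:
    """Averaged + trimmed spectra from the scaled-down design (treat read-only)."""
    return _prepared(small_config)


@pytest.fixture(scope="session")
def small_hi_snr_config():
    return default_config(
        seed=13, animals_per_species={"zebra": 4, "springbok": 4, "ostrich": 3},
        noise=high_snr_noise(),
    )


@pytest.fixture(scope="session")
def small_hi_snr_dataset(small_hi_snr_config) -> SpectraSet:
    return _prepared(small_hi_snr_config)


@pytest.fixture(scope="session")
def noisefree_config():
    """Zero-noise scaled-down design: classes are exactly their band sums."""
    zero = dict(baseline_offset_sd=0.0, baseline_slope_sd=0.0, gain_sd=0.0, noise_sd=0.0)
    return default_config(
        seed=5, animals_per_species={"zebra": 3, "springbok": 3, "ostrich": 3},
        replicates=1, noise=zero,
    )


@pytest.fixture(scope="session")
def noisefree_dataset(noisefree_config) -> SpectraSet:
    return _prepared(noisefree_config)
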