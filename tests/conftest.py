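import numpy as np
import pytest

import rsmvpa as rm


@pytest.fixture(scope="session")
def small_config():
    """Tiny cohort with a strong injected effect: 5+5 subjects, 6 regions."""
    return rm.SimulationConfig(
        grid_shape=(16, 16, 16),
        n_per_group=(5, 5),
        n_regions=6,
        region_shape=(2, 2, 2),
        effect_strength=0.8,
        n_timepoints=60,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    manifest, series, motion = rm.simulate_cohort(small_config)
    return manifest, series, motion


@pytest.fixture(scope="session")
def small_masks(small_config):
    return rm.region_masks(small_config)


@pytest.fixture(scope="session")
def small_fcs_table(small_config, small_cohort, small_masks):
    manifest, series, _ = small_cohort
    mask, _ = small_masks
    spec = rm.FeatureSpec(kind="FCS", smooth_fwhm_mm=0.0)
    return rm.build_feature_table(series, manifest, spec, mask=mask)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
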