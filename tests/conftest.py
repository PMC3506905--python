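"""Shared fixtures: small seeded phantoms reused across the suite.

The desk-scale test specimen is 64^3 (0.35 mm voxels, 7-voxel cortical
ribbon); geometry/depth oracles use even smaller hand-built fixtures inside
the individual test modules.
"""

import numpy as np
import pytest

from cortiq import AnalysisConfig, CorticalQMRIModel, PhantomSpec
from cortiq.phantom import generate_phantom


def small_spec(**overrides) -> PhantomSpec:
    base = dict(
        grid_shape=(64, 64, 64),
        cortical_thickness_vox=7,
        wm_radius_frac=0.30,
        fold_amplitude_vox=2.0,
        seed=11,
    )
    base.update(overrides)
    return PhantomSpec(**base)


@pytest.fixture(scope="session")
def spec64() -> PhantomSpec:
    return small_spec()


@pytest.fixture(scope="session")
def dataset64(spec64):
    """Default stochastic 64^3 specimen with auto-placed lesions."""
    return generate_phantom(spec64)


@pytest.fixture(scope="session")
def results64(dataset64):
    """Full analysis of the stochastic specimen."""
    return CorticalQMRIModel(dataset64, AnalysisConfig()).fit()


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Noiseless specimen: zero tissue SDs, flat laminar field, no noise."""
    return generate_phantom(small_spec(seed=5).noiseless())


@pytest.fixture(scope="session")
def noiseless_results(noiseless_dataset):
    return CorticalQMRIModel(noiseless_dataset, AnalysisConfig()).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
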