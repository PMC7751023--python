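import numpy as np
import pytest

from scnpls.gm_maps import GMDataset, SeedSpec, build_gm_dataset
from scnpls.simulate import CohortConfig, generate_cohort


def make_gm(volumes, spacing=1.0, threshold=0.45, timepoint="subacute"):
    """GMDataset from a (n, x, y, z) array on an origin-cornered grid."""
    volumes = np.asarray(volumes, dtype=float)
    affine = np.diag([spacing, spacing, spacing, 1.0])
    return build_gm_dataset(volumes, affine, mask_threshold=threshold,
                            timepoint=timepoint)


@pytest.fixture(scope="session")
def small_cohort():
    """One default-condition cohort (n=73, 6 networks, both timepoints)."""
    return generate_cohort(CohortConfig(), rng_seed=42)


@pytest.fixture(scope="session")
def baseline_cohort():
    """Cross-sectional-only cohort, cheaper for single-timepoint tests."""
    return generate_cohort(CohortConfig(make_chronic=False), rng_seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def centred_seed():
    return SeedSpec(name="centre", network="DAN", centre_mm=(8.0, 8.0, 8.0),
                    radius_mm=4.0)
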