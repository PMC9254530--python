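import numpy as np
import pytest

from pethet import (
    CohortSpec,
    PhantomSpec,
    SUVVolume,
    TumourMask,
    generate_cohort,
    generate_phantom,
)


def make_volume(values, spacing=(2.0, 2.0, 2.0)):
    return SUVVolume(np.asarray(values, dtype=float), spacing)


def make_mask(values, spacing=(2.0, 2.0, 2.0), label="total_lesion"):
    return TumourMask(np.asarray(values), spacing, label=label)


@pytest.fixture(scope="session")
def radial_phantom():
    """Noise-free linear-gradient phantom at 2 mm voxels."""
    spec = PhantomSpec(profile_kind="radial_linear")
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def two_level_phantom():
    """Half the volume at SUV S, half at S/2."""
    spec = PhantomSpec(profile_kind="two_level", suv_max_true=4.0)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def homogeneous_phantom():
    spec = PhantomSpec(profile_kind="homogeneous", suv_max_true=4.0)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def default_cohort():
    """One default simulated cohort (n = 38)."""
    return generate_cohort(CohortSpec(seed=7))
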