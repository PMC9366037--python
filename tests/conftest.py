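import numpy as np
import pytest

from petstrat import CohortSpec, LesionSpec, PhantomSpec, gen_cohort, gen_phantom


@pytest.fixture
def sphere_phantom():
    """One noiseless uniform sphere, radius 10 mm, peak SUV 10, 2 mm voxels."""
    spec = PhantomSpec(
        grid_shape=(40, 40, 40),
        spacing_mm=(2.0, 2.0, 2.0),
        background_suv=1.0,
        background_noise_sd=0.0,
        lesions=[LesionSpec((40.0, 40.0, 40.0), (10.0, 10.0, 10.0), 10.0)],
        seed=0,
    )
    return gen_phantom(spec)


@pytest.fixture
def multi_lesion_phantom():
    """Three noiseless lesions of different sizes and uptakes."""
    spec = PhantomSpec(
        grid_shape=(60, 60, 60),
        spacing_mm=(3.0, 3.0, 2.0),
        background_suv=0.8,
        background_noise_sd=0.0,
        lesions=[
            LesionSpec((45.0, 45.0, 30.0), (12.0, 9.0, 9.0), 9.0),
            LesionSpec((120.0, 120.0, 80.0), (8.0, 8.0, 8.0), 6.0),
            LesionSpec((45.0, 135.0, 100.0), (6.0, 6.0, 10.0), 12.0),
        ],
        seed=0,
    )
    return gen_phantom(spec)


@pytest.fixture(scope="session")
def default_cohort():
    """One simulated cohort at the study's size and prevalences."""
    return gen_cohort(CohortSpec(n=126, seed=7))
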