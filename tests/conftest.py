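import numpy as np
import pytest

from marrowtex.feature_aggregate import extract_cohort
from marrowtex.roi_io import ROISample
from marrowtex.synthetic_cohort import SyntheticCohortSpec, generate_cohort


def make_sample(image, mask=None, group="BME", sequence="PDFSE", subject_id="s1"):
    image = np.asarray(image, dtype=float)
    if mask is None:
        mask = np.ones_like(image, dtype=bool)
    return ROISample(
        subject_id=subject_id, group=group, sequence=sequence, image=image, mask=mask
    )


@pytest.fixture
def constant_sample():
    return make_sample(np.full((16, 16), 5.0))


@pytest.fixture
def random_sample():
    rng = np.random.default_rng(42)
    return make_sample(rng.normal(100.0, 15.0, size=(32, 32)))


def random_masked_levels(rng, size=8, ng=4):
    """A random quantized-level grid with a random nondegenerate mask."""
    levels = rng.integers(1, ng + 1, size=(size, size))
    while True:
        mask = rng.random((size, size)) < 0.75
        if mask.sum() >= 16:
            break
    levels = np.where(mask, levels, 0)
    return levels, mask


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticCohortSpec(n_per_group=(14, 12, 13), seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return extract_cohort(small_cohort)


@pytest.fixture(scope="session")
def default_table():
    """Feature table of one full default cohort (121 subjects, 242 ROIs)."""
    return extract_cohort(generate_cohort(SyntheticCohortSpec(seed=1)))
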