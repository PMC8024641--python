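import numpy as np
import pytest

from ctpm.phantom import PhantomSpec, generate_subject
from ctpm.prep import apply_mask, crop_and_resize, separate_lungs
from ctpm.volume import ImageVolume, CONTINUOUS, LABEL


SMALL_GRID = (48, 32, 32)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Desk-scale phantom spec shared across tests."""
    return PhantomSpec(
        n_subjects=4, seed=7, grid_shape=SMALL_GRID, ct_spacing_mm=(1.0, 1.0, 1.0)
    )


@pytest.fixture(scope="session")
def subject(small_spec):
    return generate_subject(small_spec, 0)


@pytest.fixture(scope="session")
def raw_lung_samples(subject):
    """Left and right prepared (but unprocessed) lung samples at 32x16x16."""
    samples = []
    for side, vols in separate_lungs(subject.ct, subject.perfusion, subject.mask).items():
        ct_m = apply_mask(vols["ct"], vols["mask"])
        pf_m = apply_mask(vols["perfusion"], vols["mask"])
        samples.append(
            crop_and_resize(ct_m, pf_m, vols["mask"], side, subject.subject_id, (32, 16, 16))
        )
    return samples


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_volume(values, spacing=(1.0, 1.0, 1.0), kind=CONTINUOUS) -> ImageVolume:
    return ImageVolume(np.asarray(values), spacing, interpolation_class=kind)


@pytest.fixture()
def ramp_volume():
    """Deterministic smooth ramp volume for interpolation tests."""
    z, y, x = np.meshgrid(
        np.linspace(0, 1, 16), np.linspace(0, 1, 12), np.linspace(0, 1, 12), indexing="ij"
    )
    return make_volume(0.2 + 0.3 * z + 0.25 * y + 0.2 * x)
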