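import numpy as np
import pytest

from wmhseg import PhantomSpec, generate_phantom
from wmhseg.phantom import Infarct, Lesion


def small_spec(**kw) -> PhantomSpec:
    """Phantom spec on a coarser grid (same ~115 mm field of view) so
    whole-pipeline tests stay fast; geometry in mm is unchanged except the
    brain/cerebellum z extent, shrunk to fit 16 slices."""
    defaults = dict(
        shape=(64, 64, 16), spacing=(1.8, 1.8, 6.0),
        brain_radii=(46.0, 52.0, 40.0),
        cerebellum_center=(0.0, 36.0, -34.0),
        cerebellum_radii=(24.0, 18.0, 12.0),
        # lesions enlarged vs the full-resolution defaults and blur kept at
        # the same physical width (0.72 mm = 0.4 voxels here): at 1.8 mm
        # pitch the partial-volume shell would dominate 7 mm lesions
        wmh_lesions=[Lesion(center=(-26.0, -14.0, 6.0), radii=(9.0, 9.0, 9.0)),
                     Lesion(center=(24.0, 18.0, 0.0), radii=(8.0, 10.0, 9.0))],
        junction_blur_vox=0.4,
    )
    defaults.update(kw)
    return PhantomSpec(**defaults)


def small_infarct_spec(**kw) -> PhantomSpec:
    spec = small_spec(**kw)
    spec.infarcts = [Infarct(center=(18.0, -26.0, 0.0), radii=(13.5, 13.5, 8.0),
                             edema_width=0.9)]
    return spec


@pytest.fixture(scope="session")
def wmh_phantom():
    return generate_phantom(small_spec(seed=11))


@pytest.fixture(scope="session")
def infarct_phantom():
    return generate_phantom(small_infarct_spec(seed=12))


@pytest.fixture
def rng():
    return np.random.default_rng(20240815)
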