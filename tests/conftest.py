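import numpy as np
import pytest

from scalpdose.grids import StructureMask
from scalpdose.synthetic import PhantomSpec, generate_cohort


def make_sphere_mask(radius_mm=50.0, voxel_mm=1.0, margin_mm=4.0, name="body"):
    """Solid sphere mask with voxel centers on a regular grid."""
    n = int(np.ceil(2 * (radius_mm + margin_mm) / voxel_mm)) + 1
    ax = (np.arange(n) - (n - 1) / 2) * voxel_mm
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(xx**2 + yy**2 + zz**2)
    return StructureMask(r <= radius_mm, (voxel_mm,) * 3, name=name)


@pytest.fixture(scope="session")
def sphere_body():
    return make_sphere_mask()


@pytest.fixture(scope="session")
def small_cohort():
    """One 7-patient synthetic cohort at reduced resolution, shared by
    the ordering, statistics and acceptance checks."""
    spec = PhantomSpec(head_radius_mm=70.0, voxel_mm=2.0)
    return generate_cohort(n_patients=7, seed=20260920, base_spec=spec,
                           n_fixation_periods=8)
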