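import numpy as np
import pytest

from cystseg import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_exam():
    """A small clustered-cyst exam shared by read-only tests."""
    spec = PhantomSpec(
        shape=(48, 48, 12),
        spacing=(1.5, 1.5, 4.5),
        n_cysts=8,
        cluster_fraction=0.6,
        seed=42,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def roundtrip_exam():
    """A mid-size exam with near-isotropic working grid for decode tests."""
    spec = PhantomSpec(
        shape=(64, 64, 24),
        spacing=(1.5, 1.5, 3.0),
        n_cysts=15,
        cluster_fraction=0.5,
        radius_median_mm=6.5,
        radius_sigma=0.15,
        seed=3,
    )
    return generate_phantom(spec)


def digitized_sphere(shape, center, r, spacing=(1, 1, 1)):
    """Voxel-center digitization of a sphere in physical coordinates."""
    grids = np.meshgrid(*(np.arange(s) * d for s, d in zip(shape, spacing)), indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= r**2
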