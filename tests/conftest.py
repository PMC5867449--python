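import numpy as np
import pytest

from bullseye_wmh import (LabeledVolume, PhantomSpec, generate_phantom,
                          parcellate)


@pytest.fixture(scope="session")
def spherical_phantom():
    """Spherical shell phantom, inner radius 8, outer 16, with oracle d."""
    spec = PhantomSpec(shape=(48, 48, 48), ventricle_radii=(8.0, 8.0, 8.0),
                       wm_outer_radii=(16.0, 16.0, 16.0), include_bgit=False)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def spherical_parcellation(spherical_phantom):
    ph = spherical_phantom
    return parcellate(ph.wm, ph.ventricles, ph.cortex_lobes)


@pytest.fixture(scope="session")
def full_phantom():
    """Default ellipsoidal phantom with all 9 zones, modest grid."""
    spec = PhantomSpec(shape=(64, 64, 64),
                       ventricle_radii=(7.0, 9.5, 7.0),
                       wm_outer_radii=(20.0, 25.0, 21.0),
                       cortex_thickness=2.0, bgit_blob_radius=3.0)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def full_parcellation(full_phantom):
    ph = full_phantom
    return parcellate(ph.wm, ph.ventricles, ph.cortex_lobes,
                      ph.basal_ganglia, ph.thalami, ph.infratentorial)


def make_slab(thickness=10, width=16):
    """Slab domain of given thickness between two parallel boundary planes."""
    shape = (thickness + 8, width, width)
    wm = np.zeros(shape, dtype=np.int16)
    inn = np.zeros(shape, dtype=np.int16)
    out = np.zeros(shape, dtype=np.int16)
    wm[4:4 + thickness] = 1
    inn[2:4] = 1
    out[4 + thickness:6 + thickness] = 1
    return (LabeledVolume(wm), LabeledVolume(inn), LabeledVolume(out))
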