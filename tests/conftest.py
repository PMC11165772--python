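import numpy as np
import pytest

from sinusect.synthetic import (
    SyntheticSpec,
    generate_cavity,
    voxelize_ellipsoid,
)


@pytest.fixture(scope="session")
def clean_spec():
    """Zero noise, zero misorientation, fixed length."""
    return SyntheticSpec(
        n_subjects_per_sex=1,
        length_sd_mm=0.0,
        misorientation_sd_deg=(0.0, 0.0, 0.0),
        surface_noise_sd_mm=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def clean_sinus(clean_spec):
    return generate_cavity(clean_spec, 0, "female", "left")


@pytest.fixture(scope="session")
def clean_mesh(clean_sinus):
    from sinusect.reconstruct import extract_isosurface

    return extract_isosurface(clean_sinus.volume)


@pytest.fixture(scope="session")
def ellipsoid_volume():
    """Voxelized ellipsoid with ML/AP/SI semi-axes (6, 20, 9) mm."""
    return voxelize_ellipsoid((6.0, 20.0, 9.0))


def ring_contour(xz_points, fraction=50, y=0.0):
    """Build a SectionContour from 2D (ML, SI) points."""
    from sinusect.morphometry import SectionContour

    xz = np.asarray(xz_points, float)
    pts = np.zeros((len(xz), 3))
    pts[:, 0] = xz[:, 0]
    pts[:, 1] = y
    pts[:, 2] = xz[:, 1]
    return SectionContour(fraction, y, pts)
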