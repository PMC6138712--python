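"""Shared fixtures: small meshes, canonical material parameters and one
cached synthetic subject, kept deliberately coarse so the suite stays fast.
"""

import numpy as np
import pytest

from tendontwist.constitutive import MaterialParams
from tendontwist.geometry import (
    CrossSectionProfile,
    TendonMesh,
    build_mesh,
    label_compartments,
    label_subtendons,
)
from tendontwist.synthetic import (
    ANATOMICAL_AREA_FRACTIONS,
    PopulationModel,
    draw_subject,
)


@pytest.fixture(scope="session")
def params():
    """Mid-range published coefficients (subject-1-like, 0 degrees)."""
    return MaterialParams(c1=38.07, c3=11.57, c4=30.65, c5=1200.0,
                          lambda_star=1.03)


@pytest.fixture(scope="session")
def circular_profile():
    return CrossSectionProfile.circular(5.0, 60.0)


@pytest.fixture(scope="session")
def elliptical_profile():
    st = np.array([
        [0.0, 8.2, 4.1, 0.0, 0.0],
        [20.0, 7.6, 3.8, -0.8, 0.3],
        [40.0, 7.2, 3.6, -1.2, 0.4],
        [60.0, 7.8, 3.9, 0.0, 0.0],
    ])
    return CrossSectionProfile(st)


@pytest.fixture(scope="session")
def circular_mesh(circular_profile):
    return build_mesh(circular_profile, n_axial=6, n_circ=16, n_radial=2)


@pytest.fixture(scope="session")
def small_mesh(elliptical_profile):
    """Coarse working mesh used by most solver-level tests."""
    return build_mesh(elliptical_profile, n_axial=4, n_circ=8, n_radial=1)


@pytest.fixture(scope="session")
def labeled_mesh(elliptical_profile):
    mesh = build_mesh(elliptical_profile, n_axial=8, n_circ=12, n_radial=1)
    return label_subtendons(label_compartments(mesh), "three_way",
                            fractions=ANATOMICAL_AREA_FRACTIONS)


@pytest.fixture(scope="session")
def unit_cube_mesh():
    """Single unit-cube element with minimal section metadata."""
    nc = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                   [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], dtype=float)
    return TendonMesh(
        node_coords=nc, hexes=np.array([[0, 1, 2, 3, 4, 5, 6, 7]]),
        n_axial=1, nodes_per_section=4, elems_per_section=1,
        elem_inplane=np.array([0]), elem_axial=np.array([0]),
        boundary_ring=np.array([0, 1, 2, 3]),
    )


@pytest.fixture(scope="session")
def subject42():
    """One cached synthetic subject (profile, truth, twist)."""
    profile, true_params, twist = draw_subject(PopulationModel(), seed=42)
    return profile, true_params, twist
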