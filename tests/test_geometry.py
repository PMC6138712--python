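"""Mesh construction, labelling and free-form CSA morphing."""

import numpy as np
import pytest

from tendontwist.geometry import (
    CrossSectionProfile,
    MeshQualityError,
    build_mesh,
    ffd_scale_csa,
    label_compartments,
    label_subtendons,
    mesh_volume,
    section_area,
    LATERAL,
    MEDIAL,
)


class TestBuildMesh:
    def test_discrete_sections_match_profile_area(self, circular_mesh,
                                                  circular_profile):
        target = np.pi * 5.0**2
        for s in (0, 3, 6):
            assert section_area(circular_mesh, s) == pytest.approx(
                target, rel=0.02)

    def test_axial_extent_spans_the_stations(self, circular_mesh):
        z = circular_mesh.node_coords[:, 2]
        assert z.min() == 0.0 and z.max() == 60.0

    def test_all_jacobians_positive(self, circular_mesh, small_mesh):
        assert circular_mesh.check_jacobians() > 0
        assert small_mesh.check_jacobians() > 0

    def test_minimal_resolution_smoke(self, circular_profile):
        mesh = build_mesh(circular_profile, n_axial=1, n_circ=4, n_radial=1)
        assert mesh.check_jacobians() > 0
        assert mesh.n_elems == mesh.elems_per_section

    def test_prism_volume_matches_csa_times_length(self):
        prof = CrossSectionProfile(np.array([
            [0.0, 6.0, 3.0, 1.0, -0.5],
            [30.0, 6.0, 3.0, 1.0, -0.5],
            [60.0, 6.0, 3.0, 1.0, -0.5],
        ]))
        mesh = build_mesh(prof, 4, 16, 2)
        assert mesh_volume(mesh) == pytest.approx(np.pi * 18.0 * 60.0,
                                                  rel=0.02)

    def test_volume_converges_to_lofted_solid(self, elliptical_profile):
        # axial interpolation error must shrink at least linearly
        z = np.linspace(0.0, 60.0, 2001)
        exact = np.trapezoid(elliptical_profile.area(z), z)
        errs = []
        for na, nc in ((4, 16), (8, 32)):
            v = mesh_volume(build_mesh(elliptical_profile, na, nc, 2))
            errs.append(abs(v - exact) / exact)
        assert errs[1] < errs[0]
        assert errs[0] / errs[1] > 2.0  # observed order >= 1

    def test_rejects_degenerate_profile(self):
        with pytest.raises(ValueError):
            CrossSectionProfile(np.array([[0, 5, -1, 0, 0], [60, 5, 1, 0, 0]]))
        with pytest.raises(ValueError):
            CrossSectionProfile(np.array([[0, 5, 2, 0, 0], [0, 5, 2, 0, 0]]))


class TestCompartments:
    def test_symmetric_mesh_splits_in_half(self, circular_mesh):
        m = label_compartments(circular_mesh)
        assert (m.compartment_label == MEDIAL).sum() == m.n_elems // 2

    def test_mirroring_swaps_labels(self, circular_mesh):
        m = label_compartments(circular_mesh)
        mirrored = circular_mesh.copy()
        mirrored.node_coords[:, 0] *= -1.0
        # winding flips under reflection; relabel via the mirrored medial axis
        m2 = label_compartments(mirrored)
        assert np.array_equal(m2.compartment_label, -m.compartment_label)

    def test_translation_leaves_labels_alone(self, circular_mesh):
        m = label_compartments(circular_mesh)
        shifted = circular_mesh.copy()
        shifted.node_coords = shifted.node_coords + np.array([3.0, -2.0, 10.0])
        m2 = label_compartments(shifted)
        assert np.array_equal(m.compartment_label, m2.compartment_label)


class TestSubtendons:
    def test_default_three_way_fractions(self, circular_mesh):
        m = label_subtendons(label_compartments(circular_mesh), "three_way")
        area = m.inplane_area[m.elem_inplane]
        total = area.sum()
        fr = [area[m.subtendon_label == c].sum() / total for c in (0, 1, 2)]
        assert fr[0] == pytest.approx(2 / 3, abs=0.03)
        assert fr[1] == pytest.approx(2 / 9, abs=0.03)
        assert fr[2] == pytest.approx(1 / 9, abs=0.03)

    def test_two_way_fractions(self, circular_mesh):
        m = label_subtendons(label_compartments(circular_mesh), "two_way")
        area = m.inplane_area[m.elem_inplane]
        total = area.sum()
        sol = area[m.subtendon_label == 0].sum() / total
        assert sol == pytest.approx(2 / 3, abs=0.05)

    def test_custom_fractions(self, circular_mesh):
        m = label_subtendons(label_compartments(circular_mesh), "three_way",
                             fractions=(0.52, 0.35, 0.13))
        area = m.inplane_area[m.elem_inplane]
        total = area.sum()
        assert area[m.subtendon_label == 0].sum() / total == pytest.approx(
            0.52, abs=0.05)

    def test_partition_is_axially_constant(self, labeled_mesh):
        lab = labeled_mesh.subtendon_label.reshape(labeled_mesh.n_axial, -1)
        assert (lab == lab[0]).all()

    def test_coarse_mesh_raises(self, circular_profile):
        mesh = build_mesh(circular_profile, 2, 8, 1)
        with pytest.raises(MeshQualityError):
            label_subtendons(label_compartments(mesh), "three_way")

    def test_unknown_scheme_raises(self, circular_mesh):
        with pytest.raises(ValueError):
            label_subtendons(circular_mesh, "five_way")


class TestFFDScaling:
    def test_identity_scale_is_exact(self, circular_mesh):
        m = ffd_scale_csa(circular_mesh, 1.0)
        assert np.array_equal(m.node_coords, circular_mesh.node_coords)

    def test_mid_section_area_scales(self, circular_mesh):
        m = ffd_scale_csa(circular_mesh, 1.1)
        mid = circular_mesh.n_axial // 2
        ratio = section_area(m, mid) / section_area(circular_mesh, mid)
        assert ratio == pytest.approx(1.1, rel=0.02)

    def test_end_sections_unchanged(self, circular_mesh):
        m = ffd_scale_csa(circular_mesh, 1.2)
        for s in (0, circular_mesh.n_axial):
            ids = circular_mesh.section_nodes(s)
            assert np.allclose(m.node_coords[ids],
                               circular_mesh.node_coords[ids])

    def test_reciprocal_roundtrip(self, circular_mesh):
        m = ffd_scale_csa(ffd_scale_csa(circular_mesh, 1.15), 1 / 1.15)
        mid = circular_mesh.n_axial // 2
        assert section_area(m, mid) == pytest.approx(
            section_area(circular_mesh, mid), rel=0.02)

    def test_extreme_shrink_raises(self, circular_mesh):
        with pytest.raises(MeshQualityError):
            ffd_scale_csa(circular_mesh, 0.2)
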