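"""Rupture criterion mechanics, differential load split, compartment
stress summaries and stress-field correlation."""

import numpy as np
import pytest

from tendontwist.experiments import (
    LoadSplit,
    axial_gauss_columns,
    compartment_stress_summary,
    longest_threshold_run,
    nodal_stress_r2,
    run_rupture,
    subtendon_force_bc,
    _max_column_run,
)
from tendontwist.fiber import fiber_field_from_twist
from tendontwist.geometry import (
    build_mesh,
    ffd_scale_csa,
    label_compartments,
    label_subtendons,
)
from tendontwist.solver import SolveResult
from tendontwist.synthetic import ANATOMICAL_AREA_FRACTIONS


class TestLoadSplit:
    def test_default_is_six_two_one(self):
        s = LoadSplit()
        assert s.soleus_fraction == pytest.approx(2 / 3)
        assert s.mg_fraction == pytest.approx(2 / 9)
        assert s.lg_fraction == pytest.approx(1 / 9)

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError):
            LoadSplit(0.5, 0.2, 0.2)

    def test_900N_splits_600_200_100(self, labeled_mesh):
        n_nodes = labeled_mesh.n_nodes
        bc = subtendon_force_bc(labeled_mesh, 900.0, LoadSplit())
        total = bc.force_vector(n_nodes)
        assert total.sum() == pytest.approx(900.0, rel=1e-12)
        # per-sub-tendon allocation, isolated by degenerate load splits:
        # with all load on one sub-tendon its nodes receive the full 900 N,
        # and the 6:2:1 split is exactly the weighted sum 600/200/100
        singles = [subtendon_force_bc(labeled_mesh, 900.0, LoadSplit(*fr))
                   .force_vector(n_nodes)
                   for fr in ((1, 0, 0), (0, 1, 0), (0, 0, 1))]
        for single in singles:
            assert single.sum() == pytest.approx(900.0, rel=1e-12)
        combined = (2 / 3) * singles[0] + (2 / 9) * singles[1] \
            + (1 / 9) * singles[2]
        assert np.allclose(total, combined, atol=1e-10)
        assert (2 / 3) * singles[0].sum() == pytest.approx(600.0)
        assert (2 / 9) * singles[1].sum() == pytest.approx(200.0)
        assert (1 / 9) * singles[2].sum() == pytest.approx(100.0)


class TestRunLengthCriterion:
    def test_boundary_fourteen_vs_fifteen(self):
        v = np.zeros(32)
        v[5:19] = 150.0  # 14 consecutive points over 100 MPa
        assert longest_threshold_run(v, 100.0) == 14
        v[19] = 150.0    # the 15th tips it over
        assert longest_threshold_run(v, 100.0) == 15

    def test_interrupted_runs_do_not_count(self):
        v = np.full(40, 150.0)
        v[::10] = 0.0
        assert longest_threshold_run(v, 100.0) == 9

    def test_columns_cover_every_gauss_point(self, labeled_mesh):
        cols = axial_gauss_columns(labeled_mesh)
        assert cols.shape == (labeled_mesh.elems_per_section * 4,
                              2 * labeled_mesh.n_axial, 2)
        seen = set(map(tuple, cols.reshape(-1, 2)))
        assert len(seen) == labeled_mesh.n_elems * 8

    def test_constructed_field_rupture_boundary(self, labeled_mesh):
        cols = axial_gauss_columns(labeled_mesh)
        vm = np.zeros((labeled_mesh.n_elems, 8))
        col = cols[7]
        for (e, g) in col[:14]:
            vm[e, g] = 150.0
        assert _max_column_run(labeled_mesh, vm, 100.0, cols) == 14
        e, g = col[14]
        vm[e, g] = 150.0
        assert _max_column_run(labeled_mesh, vm, 100.0, cols) == 15


def _fake_result(mesh, vm):
    return SolveResult(
        nodal_displacements=np.zeros((mesh.n_nodes, 3)),
        gauss_cauchy_stress=np.zeros((mesh.n_elems, 8, 3, 3)),
        gauss_von_mises=vm, converged=True, newton_iterations=0,
        load_steps=0)


class TestCompartmentSummary:
    def test_uniform_field_no_difference(self, labeled_mesh):
        vm = np.full((labeled_mesh.n_elems, 8), 50.0)
        med, lat, pct = compartment_stress_summary(
            labeled_mesh, _fake_result(labeled_mesh, vm))
        assert med == lat == pytest.approx(50.0)
        assert pct == pytest.approx(0.0)

    def test_medial_only_field_flagged_infinite(self, labeled_mesh):
        vm = np.zeros((labeled_mesh.n_elems, 8))
        vm[labeled_mesh.compartment_label == 1] = 80.0
        med, lat, pct = compartment_stress_summary(
            labeled_mesh, _fake_result(labeled_mesh, vm))
        assert lat == 0.0 and np.isinf(pct)

    def test_mirrored_field_swaps_means(self, labeled_mesh):
        rng = np.random.default_rng(0)
        vm = rng.random((labeled_mesh.n_elems, 8)) * 100.0
        med, lat, _ = compartment_stress_summary(
            labeled_mesh, _fake_result(labeled_mesh, vm))
        flipped = labeled_mesh.copy()
        flipped.compartment_label = -labeled_mesh.compartment_label
        med2, lat2, _ = compartment_stress_summary(
            flipped, _fake_result(labeled_mesh, vm))
        assert med2 == pytest.approx(lat) and lat2 == pytest.approx(med)


class TestNodalR2:
    def test_identical_fields(self):
        a = np.random.default_rng(2).random(100)
        assert nodal_stress_r2(a, a) == pytest.approx(1.0)

    def test_affine_invariance(self):
        a = np.random.default_rng(3).random(100)
        assert nodal_stress_r2(a, 2.0 * a + 3.0) == pytest.approx(1.0)

    def test_orthogonalized_noise_uncorrelated(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal(1000)
        b = rng.standard_normal(1000)
        b = b - (b - b.mean()) @ (a - a.mean()) / np.sum(
            (a - a.mean())**2) * (a - a.mean())
        assert nodal_stress_r2(a, b) < 1e-20

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            nodal_stress_r2(np.ones(10), np.arange(10.0))


@pytest.fixture(scope="module")
def rupture_subject(subject42):
    profile, params, _ = subject42
    mesh = build_mesh(profile, 8, 12, 1)
    mesh = label_subtendons(label_compartments(mesh), "three_way",
                            fractions=ANATOMICAL_AREA_FRACTIONS)
    return mesh, params


class TestRupture:
    def test_unreachable_threshold_reports_no_rupture(self, rupture_subject):
        mesh, params = rupture_subject
        ff = fiber_field_from_twist(mesh, 0.0)
        res = run_rupture(mesh, ff, params, increment=200.0,
                          threshold=np.inf, max_load=400.0)
        assert res.status == "no_rupture_max_load"
        assert res.rupture_load is None
        assert res.last_converged_load == 400.0

    def test_rupture_load_is_increment_multiple(self, rupture_subject):
        mesh, params = rupture_subject
        ff = fiber_field_from_twist(mesh, 0.0)
        res = run_rupture(mesh, ff, params, increment=500.0)
        assert res.status == "ruptured"
        assert res.rupture_load % 500.0 == 0.0
        # criterion satisfied at the rupture load and not one step before
        runs = dict(res.load_history)
        assert runs[res.rupture_load] >= 15
        if res.rupture_load > 500.0:
            assert runs[res.rupture_load - 500.0] < 15

    def test_coarser_staircase_never_ruptures_earlier(self, rupture_subject):
        mesh, params = rupture_subject
        ff = fiber_field_from_twist(mesh, 0.0)
        fine = run_rupture(mesh, ff, params, increment=500.0)
        coarse = run_rupture(mesh, ff, params, increment=1000.0)
        assert coarse.rupture_load >= fine.rupture_load

    def test_rupture_monotone_in_csa_and_stiffness(self, rupture_subject):
        mesh, params = rupture_subject
        base = run_rupture(mesh, fiber_field_from_twist(mesh, 0.0), params,
                           increment=500.0)
        small = ffd_scale_csa(mesh, 0.85)
        res_small = run_rupture(small, fiber_field_from_twist(small, 0.0),
                                params, increment=500.0)
        assert res_small.rupture_load <= base.rupture_load
        soft = params.replace(c5=params.c5 * 0.6)
        res_soft = run_rupture(mesh, fiber_field_from_twist(mesh, 0.0),
                               soft, increment=500.0)
        assert res_soft.rupture_load <= base.rupture_load

    def test_too_coarse_axial_mesh_rejected(self, subject42):
        profile, params, _ = subject42
        mesh = build_mesh(profile, 4, 12, 1)
        mesh = label_subtendons(label_compartments(mesh), "three_way",
                                fractions=ANATOMICAL_AREA_FRACTIONS)
        with pytest.raises(ValueError):
            run_rupture(mesh, fiber_field_from_twist(mesh, 0.0), params)
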