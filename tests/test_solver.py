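"""FE solver verification: single-element oracles, equilibrium, marker
tracking, transverse rotation and sub-tendon interface constraints."""

import dataclasses

import numpy as np
import pytest

from tendontwist.constitutive import (
    DeformationState,
    MaterialParams,
    cauchy_stress,
    uniaxial_closed_form,
)
from tendontwist.fiber import FiberField, fiber_field_from_twist
from tendontwist.geometry import build_mesh, label_compartments, label_subtendons
from tendontwist.solver import (
    BoundaryConditions,
    SolveResult,
    SolverConfig,
    apply_interface,
    SlidingInterface,
    default_markers,
    expand_node_set,
    solve_static,
    split_subtendon_mesh,
    track_markers,
    transverse_rotation,
)


def axial_field(n_elems):
    return FiberField(gauss_fiber_dirs=np.tile([0.0, 0.0, 1.0],
                                               (n_elems, 8, 1)))


def cube_bc(mesh):
    """Uniaxial boundary conditions on the unit cube: bottom held in z,
    rigid modes pinned, lateral contraction free."""
    bc = BoundaryConditions()
    bc.fix_nodes([0, 1, 2, 3], [2])
    bc.fix_nodes([0], [0, 1])
    bc.fix_nodes([1], [1])
    return bc


class TestSingleElement:
    def test_zero_load_zero_state(self, unit_cube_mesh, params):
        bc = cube_bc(unit_cube_mesh)
        res = solve_static(unit_cube_mesh, axial_field(1), params, bc)
        assert res.converged
        assert np.abs(res.nodal_displacements).max() < 1e-12
        assert np.abs(res.gauss_cauchy_stress).max() < 1e-10

    def test_uniaxial_force_matches_closed_form(self, unit_cube_mesh, params):
        lam = 1.05
        # nominal force for the incompressible closed form: sigma * A0 / lam
        F = uniaxial_closed_form(params, lam) / lam
        bc = cube_bc(unit_cube_mesh)
        bc.add_forces([4, 5, 6, 7], [0.0, 0.0, F / 4.0])
        res = solve_static(unit_cube_mesh, axial_field(1), params, bc)
        sig = res.gauss_cauchy_stress.mean(axis=(0, 1))
        assert sig[2, 2] == pytest.approx(uniaxial_closed_form(params, lam),
                                          rel=0.01)
        assert 1.0 + res.nodal_displacements[4, 2] == pytest.approx(lam,
                                                                    rel=0.01)

    def test_patch_homogeneous_deformation(self, unit_cube_mesh, params):
        # prescribe an affine axial stretch with free faces pinned laterally
        # at the analytic incompressible contraction: stresses must equal
        # the point-wise constitutive law evaluated at that deformation
        lam = 1.04
        q = 1.0 / np.sqrt(lam)
        bc = BoundaryConditions()
        for n, (x, y, z) in enumerate(unit_cube_mesh.node_coords):
            bc.prescribe([n], 0, (q - 1.0) * x)
            bc.prescribe([n], 1, (q - 1.0) * y)
            bc.prescribe([n], 2, (lam - 1.0) * z)
        res = solve_static(unit_cube_mesh, axial_field(1), params, bc)
        F = np.diag([q, q, lam])
        expected = cauchy_stress(params, DeformationState(F=F))
        assert np.allclose(res.gauss_cauchy_stress, expected, rtol=1e-8)

    def test_reactions_balance_applied_load(self, unit_cube_mesh, params):
        bc = cube_bc(unit_cube_mesh)
        bc.add_forces([4, 5, 6, 7], [0.0, 0.0, 10.0])
        res = solve_static(unit_cube_mesh, axial_field(1), params, bc)
        Rz = res.reactions[[0, 1, 2, 3], 2].sum()
        assert Rz == pytest.approx(-40.0, rel=1e-6)  # balances applied load
        assert abs(res.reactions[:, :2].sum(axis=0)).max() < 1e-6 * 40.0

    def test_conflicting_bc_rejected(self, unit_cube_mesh, params):
        bc = cube_bc(unit_cube_mesh)
        bc.add_forces([0], [0.0, 0.0, 5.0])
        with pytest.raises(ValueError):
            solve_static(unit_cube_mesh, axial_field(1), params, bc)


@pytest.fixture(scope="module")
def loaded(small_mesh, params):
    ff = fiber_field_from_twist(small_mesh, 30.0)
    bc = BoundaryConditions()
    bc.fix_nodes(small_mesh.distal_node_set)
    prox = small_mesh.proximal_node_set
    bc.add_forces(prox, [0.0, 0.0, 1000.0 / prox.size])
    return solve_static(small_mesh, ff, params, bc)


class TestTendonSolve:
    def test_converged_flag_and_residual(self, loaded):
        assert loaded.converged
        assert loaded.residual_norm < 1e-4

    def test_stress_tensors_symmetric(self, loaded):
        s = loaded.gauss_cauchy_stress
        assert np.abs(s - np.swapaxes(s, -1, -2)).max() < 1e-8

    def test_markers_follow_displacement_field(self, small_mesh, loaded):
        mk = default_markers(small_mesh)
        moved = track_markers(small_mesh, loaded, mk)
        dz = (moved - mk)[:, 2]
        assert dz[0] == pytest.approx(0.0, abs=1e-12)  # clamped end
        assert np.all(np.diff(dz) > 0)  # monotone toward the pulled end

    def test_mesh_refinement_converges(self, elliptical_profile, params):
        tips = []
        for na, nc, nr in ((6, 16, 1), (12, 16, 1), (12, 16, 2)):
            mesh = build_mesh(elliptical_profile, na, nc, nr)
            ff = fiber_field_from_twist(mesh, 0.0)
            bc = BoundaryConditions()
            bc.fix_nodes(mesh.distal_node_set)
            prox = mesh.proximal_node_set
            bc.add_forces(prox, [0.0, 0.0, 500.0 / prox.size])
            res = solve_static(mesh, ff, params, bc)
            tips.append(res.nodal_displacements[prox, 2].mean())
        d1 = abs(tips[1] - tips[0]) / abs(tips[1])
        d2 = abs(tips[2] - tips[1]) / abs(tips[2])
        assert d1 < 0.02 and d2 < 0.02  # Cauchy within 2%
        assert d2 < d1                  # refinements keep tightening


class TestMarkers:
    def test_zero_displacement_markers_fixed(self, small_mesh):
        res = SolveResult(
            nodal_displacements=np.zeros((small_mesh.n_nodes, 3)),
            gauss_cauchy_stress=np.zeros((small_mesh.n_elems, 8, 3, 3)),
            gauss_von_mises=np.zeros((small_mesh.n_elems, 8)),
            converged=True, newton_iterations=0, load_steps=0)
        mk = default_markers(small_mesh)
        assert np.allclose(track_markers(small_mesh, res, mk), mk)

    def test_rigid_translation_moves_all_markers(self, small_mesh):
        t = np.array([1.0, -2.0, 3.0])
        res = SolveResult(
            nodal_displacements=np.tile(t, (small_mesh.n_nodes, 1)),
            gauss_cauchy_stress=np.zeros((small_mesh.n_elems, 8, 3, 3)),
            gauss_von_mises=np.zeros((small_mesh.n_elems, 8)),
            converged=True, newton_iterations=0, load_steps=0)
        mk = default_markers(small_mesh)
        assert np.allclose(track_markers(small_mesh, res, mk), mk + t)

    def test_homogeneous_stretch_scales_spacing(self, small_mesh):
        lam = 1.06
        u = np.zeros((small_mesh.n_nodes, 3))
        u[:, 2] = (lam - 1.0) * small_mesh.node_coords[:, 2]
        res = SolveResult(
            nodal_displacements=u,
            gauss_cauchy_stress=np.zeros((small_mesh.n_elems, 8, 3, 3)),
            gauss_von_mises=np.zeros((small_mesh.n_elems, 8)),
            converged=True, newton_iterations=0, load_steps=0)
        mk = default_markers(small_mesh)
        moved = track_markers(small_mesh, res, mk)
        assert np.allclose(np.diff(moved[:, 2]), lam * np.diff(mk[:, 2]),
                           rtol=1e-10)

    def test_marker_outside_mesh_rejected(self, small_mesh):
        res = SolveResult(
            nodal_displacements=np.zeros((small_mesh.n_nodes, 3)),
            gauss_cauchy_stress=np.zeros((small_mesh.n_elems, 8, 3, 3)),
            gauss_von_mises=np.zeros((small_mesh.n_elems, 8)),
            converged=True, newton_iterations=0, load_steps=0)
        with pytest.raises(ValueError):
            track_markers(small_mesh, res, np.array([[100.0, 0.0, 30.0]]))


class TestTransverseRotation:
    def _result(self, mesh, u):
        return SolveResult(
            nodal_displacements=u,
            gauss_cauchy_stress=np.zeros((mesh.n_elems, 8, 3, 3)),
            gauss_von_mises=np.zeros((mesh.n_elems, 8)),
            converged=True, newton_iterations=0, load_steps=0)

    def test_zero_displacement_zero_rotation(self, small_mesh):
        u = np.zeros((small_mesh.n_nodes, 3))
        assert transverse_rotation(small_mesh, self._result(small_mesh, u)) \
            == pytest.approx(0.0, abs=1e-10)

    def test_imposed_rigid_rotation_recovered(self, small_mesh):
        th = np.deg2rad(10.0)
        u = np.zeros((small_mesh.n_nodes, 3))
        prox = small_mesh.section_nodes(small_mesh.n_axial)
        c = small_mesh.section_centroid(small_mesh.n_axial)
        rel = small_mesh.node_coords[prox, :2] - c[:2]
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        u[prox, :2] = rel @ R.T - rel
        rot = transverse_rotation(small_mesh, self._result(small_mesh, u))
        assert rot == pytest.approx(10.0, abs=0.2)

    def test_pure_stretch_no_rotation(self, small_mesh):
        u = np.zeros((small_mesh.n_nodes, 3))
        u[:, 2] = 0.05 * small_mesh.node_coords[:, 2]
        assert transverse_rotation(small_mesh, self._result(small_mesh, u)) \
            == pytest.approx(0.0, abs=1e-10)


@pytest.fixture(scope="module")
def split_setup(elliptical_profile, params):
    mesh = build_mesh(elliptical_profile, 4, 12, 2)
    mesh = label_subtendons(label_compartments(mesh), "two_way")
    smesh, iface = split_subtendon_mesh(mesh)
    ff = fiber_field_from_twist(mesh, 0.0)

    def bc_for(m):
        bc = BoundaryConditions()
        bc.fix_nodes(expand_node_set(m, m.distal_node_set))
        prox = expand_node_set(m, m.proximal_node_set)
        bc.fix_nodes(prox, [0, 1])
        bc.prescribe(prox, 2, 2.4)
        return bc

    return mesh, smesh, iface, ff, bc_for


class TestInterfaces:
    def test_bonded_matches_monolithic(self, split_setup, params):
        mesh, smesh, iface, ff, bc_for = split_setup
        res_m = solve_static(mesh, ff, params, bc_for(mesh))
        res_b = solve_static(smesh, ff, params, bc_for(smesh),
                             interface=iface)
        du = res_b.nodal_displacements[: mesh.n_nodes] \
            - res_m.nodal_displacements
        assert np.abs(du).max() < 1e-8

    def test_frictionless_sliding_jump_structure(self, split_setup, params):
        mesh, smesh, iface, ff, bc_for = split_setup
        sliding = dataclasses.replace(iface, mode="frictionless_sliding")
        res = solve_static(smesh, ff, params, bc_for(smesh),
                           interface=sliding)
        pairs = np.asarray(iface.pairs)
        jump = res.nodal_displacements[pairs[:, 0]] \
            - res.nodal_displacements[pairs[:, 1]]
        tangential = []
        for (s, m), normals, j in zip(pairs, iface.normals, jump):
            for n in np.atleast_2d(normals):
                if len(np.atleast_2d(normals)) <= 2:
                    assert abs(j @ n) < 1e-9  # no interpenetration
            if len(np.atleast_2d(normals)) == 1:
                n = np.atleast_2d(normals)[0]
                tangential.append(np.linalg.norm(j - (j @ n) * n))
        assert max(tangential) > 1e-4  # tangential motion is free

    def test_zero_load_zero_jump(self, split_setup, params):
        mesh, smesh, iface, ff, bc_for = split_setup
        sliding = dataclasses.replace(iface, mode="frictionless_sliding")
        bc = BoundaryConditions()
        bc.fix_nodes(expand_node_set(smesh, smesh.distal_node_set))
        res = solve_static(smesh, ff, params, bc, interface=sliding)
        pairs = np.asarray(iface.pairs)
        jump = res.nodal_displacements[pairs[:, 0]] \
            - res.nodal_displacements[pairs[:, 1]]
        assert np.abs(jump).max() < 1e-10

    def test_apply_interface_constraint_structure(self):
        iface = SlidingInterface(
            pairs=np.array([[5, 1]]), normals=[np.array([[1.0, 0.0, 0.0]])],
            mode="frictionless_sliding")
        recs = apply_interface(iface)
        s, m, tied, free = recs[0]
        assert (s, m) == (5, 1)
        assert tied.shape == (1, 3) and free.shape == (2, 3)
        # tied direction orthogonal to the free tangent space
        assert np.abs(free @ tied[0]).max() < 1e-12
        bonded = apply_interface(iface, mode="bonded")
        assert bonded[0][2].shape == (3, 3)
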