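"""Static nonlinear finite-element solver for the transversely isotropic
hyperelastic tendon.

Total-Lagrangian formulation on trilinear hexahedra with 2x2x2 Gauss
quadrature. Near-incompressibility is handled by a volumetric penalty with
a mean-dilatation treatment (the volumetric stress is driven by the
element-averaged volume ratio), which avoids locking without higher-order
bases. Equilibrium is found by Newton-Raphson with incremental load
stepping and automatic step bisection; the consistent tangent is obtained
by column-wise central differencing of the element internal force, which
captures the mean-dilatation coupling exactly.

Sub-tendon interfaces are node-to-node ties on conforming surfaces
(small-sliding): bonded mode ties all three displacement components,
frictionless sliding ties only the normal component(s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import constitutive as con
from .element import gauss_points, jacobians, shape_functions, gauss_coords
from .geometry import TendonMesh
from .fiber import FiberField

__all__ = [
    "BoundaryConditions",
    "SolveResult",
    "SlidingInterface",
    "SolverConfig",
    "ConvergenceError",
    "solve_static",
    "apply_interface",
    "split_subtendon_mesh",
    "expand_node_set",
    "track_markers",
    "default_markers",
    "transverse_rotation",
    "locate_points",
]


class ConvergenceError(RuntimeError):
    """Newton iteration failed; carries the last converged load fraction."""

    def __init__(self, msg, last_converged_fraction=0.0, diagnostics=None):
        super().__init__(msg)
        self.last_converged_fraction = last_converged_fraction
        self.diagnostics = diagnostics or {}


@dataclass
class BoundaryConditions:
    """Fixed components, applied nodal forces and prescribed displacements.

    ``fixed`` is a list of (node, component) pairs held at zero;
    ``nodal_forces`` maps node -> 3-vector (N); ``prescribed`` maps
    (node, component) -> displacement (mm), ramped with the load factor.
    """

    fixed: list = field(default_factory=list)
    nodal_forces: dict = field(default_factory=dict)
    prescribed: dict = field(default_factory=dict)

    def fix_nodes(self, nodes, components=(0, 1, 2)):
        for n in np.atleast_1d(nodes):
            for c in components:
                self.fixed.append((int(n), int(c)))
        return self

    def add_forces(self, nodes, force_per_node):
        fpn = np.atleast_2d(force_per_node)
        nodes = np.atleast_1d(nodes)
        if fpn.shape[0] == 1:
            fpn = np.repeat(fpn, len(nodes), axis=0)
        for n, f in zip(nodes, fpn):
            prev = self.nodal_forces.get(int(n), np.zeros(3))
            self.nodal_forces[int(n)] = prev + np.asarray(f, dtype=float)
        return self

    def prescribe(self, nodes, component, value):
        for n in np.atleast_1d(nodes):
            self.prescribed[(int(n), int(component))] = float(value)
        return self

    def force_vector(self, n_nodes: int) -> np.ndarray:
        f = np.zeros((n_nodes, 3))
        for n, v in self.nodal_forces.items():
            f[n] += v
        return f.ravel()

    def validate(self, n_nodes: int):
        fixed_set = set(self.fixed) | set(self.prescribed)
        for n in self.nodal_forces:
            for c in range(3):
                if (n, c) in fixed_set and abs(self.nodal_forces[n][c]) > 0:
                    raise ValueError(f"node {n} comp {c} both fixed and loaded")
        total = self.force_vector(n_nodes)
        if not np.all(np.isfinite(total)):
            raise ValueError("non-finite applied force")


@dataclass
class SlidingInterface:
    """Node-to-node pairing between coincident sub-tendon surfaces.

    ``pairs`` is (npairs, 2): [slave node, master node]; ``normals`` is a
    list (per pair) of one or more unit reference facet normals; pairs whose
    adjacent facet normals disagree (seam junctions) carry several normals
    and lose the corresponding sliding freedoms.
    """

    pairs: np.ndarray
    normals: list
    mode: str = "bonded"  # "bonded" | "frictionless_sliding"

    def __post_init__(self):
        if self.mode not in ("bonded", "frictionless_sliding"):
            raise ValueError(f"unknown interface mode {self.mode!r}")


@dataclass
class SolverConfig:
    tol_rel: float = 1e-8
    tol_abs: float = 1e-8  # N
    max_iter: int = 50
    n_load_steps: int = 4
    min_step_fraction: float = 1.0 / 256.0
    fd_rel_step: float = 1e-6


@dataclass
class SolveResult:
    nodal_displacements: np.ndarray       # (Nn, 3) mm
    gauss_cauchy_stress: np.ndarray       # (Ne, ng, 3, 3) MPa
    gauss_von_mises: np.ndarray           # (Ne, ng) MPa
    converged: bool
    newton_iterations: int
    load_steps: int
    reactions: np.ndarray | None = None   # (Nn, 3) N at constrained dofs
    residual_norm: float = np.nan


class _InversionError(RuntimeError):
    pass


class _Assembly:
    """Precomputed element data and vectorized force/tangent evaluation."""

    def __init__(self, mesh: TendonMesh, fiber_field: FiberField,
                 params: con.MaterialParams):
        self.mesh = mesh
        self.params = params
        xi, w = gauss_points(mesh.gauss_order)
        detJ0, gradN = jacobians(mesh.node_coords, mesh.hexes, xi)
        if detJ0.min() <= 0:
            raise ValueError("mesh has inverted elements")
        self.gradN = gradN                        # (Ne, ng, 8, 3)
        self.wdet = detJ0 * w                     # (Ne, ng)
        self.v0 = self.wdet.sum(axis=1)           # (Ne,)
        self.fib = fiber_field.gauss_fiber_dirs   # (Ne, ng, 3)
        self.dofmap = (3 * mesh.hexes[:, :, None]
                       + np.arange(3)[None, None, :]).reshape(mesh.n_elems, 24)
        self.ndof = 3 * mesh.n_nodes
        self.char_len = float(np.mean(self.v0) ** (1.0 / 3.0))

    def deformation(self, u_e: np.ndarray):
        """F (Ne, ng, 3, 3) and element-mean volume ratio Jbar (Ne,)."""
        F = np.einsum("eai,egaj->egij", u_e, self.gradN)
        F += np.eye(3)
        J = con._det3(F)
        if J.min() <= 0.0:
            raise _InversionError("element inversion during iteration")
        jbar = (self.wdet * J).sum(axis=1) / self.v0
        return F, jbar

    def elem_forces(self, u_e: np.ndarray) -> np.ndarray:
        """Internal nodal forces per element (Ne, 8, 3)."""
        F, jbar = self.deformation(u_e)
        P = con.pk1_stress(F, self.fib, self.params, jbar=jbar[:, None])
        return np.einsum("eg,egij,egaj->eai", self.wdet, P, self.gradN)

    def internal_force(self, u: np.ndarray) -> np.ndarray:
        f_e = self.elem_forces(u.reshape(-1, 3)[self.mesh.hexes])
        f = np.zeros(self.ndof)
        np.add.at(f, self.dofmap.ravel(), f_e.reshape(-1, 24).ravel())
        return f

    def _batch_forces(self, U: np.ndarray) -> np.ndarray:
        """Element forces for a batch of nodal displacement states
        (nb, Ne, 8, 3) -> (nb, Ne, 8, 3)."""
        F = np.einsum("peai,egaj->pegij", U, self.gradN)
        F += np.eye(3)
        J = con._det3(F)
        if J.min() <= 0.0:
            raise _InversionError("element inversion during iteration")
        jbar = (self.wdet * J).sum(axis=2) / self.v0
        P = con.pk1_stress(F, self.fib, self.params, jbar=jbar[:, :, None])
        return np.einsum("eg,pegij,egaj->peai", self.wdet, P, self.gradN)

    def tangent(self, u: np.ndarray) -> sp.csr_matrix:
        """Consistent tangent by central differences on element dofs.

        All 48 perturbed states (24 dofs, +/-) are evaluated in one batched
        constitutive call; the mean-dilatation coupling within each element
        is therefore differenced exactly.
        """
        u_e = u.reshape(-1, 3)[self.mesh.hexes]
        h = SolverConfig.fd_rel_step * self.char_len
        U = np.tile(u_e, (48, 1, 1, 1))
        for a in range(8):
            for i in range(3):
                k = 3 * a + i
                U[2 * k, :, a, i] += h
                U[2 * k + 1, :, a, i] -= h
        try:
            fb = self._batch_forces(U)
        except _InversionError:
            # shrink the step away from the inversion boundary
            U = u_e + 0.25 * (U - u_e)
            fb = self._batch_forces(U)
            h *= 0.25
        Ke = np.empty((self.mesh.n_elems, 24, 24))
        for k in range(24):
            Ke[:, :, k] = (fb[2 * k] - fb[2 * k + 1]).reshape(-1, 24) / (2 * h)
        rows = np.broadcast_to(self.dofmap[:, :, None], Ke.shape)
        cols = np.broadcast_to(self.dofmap[:, None, :], Ke.shape)
        K = sp.coo_matrix((Ke.ravel(), (rows.ravel(), cols.ravel())),
                          shape=(self.ndof, self.ndof))
        return K.tocsr()

    def stresses(self, u: np.ndarray):
        u_e = u.reshape(-1, 3)[self.mesh.hexes]
        F, jbar = self.deformation(u_e)
        P = con.pk1_stress(F, self.fib, self.params, jbar=jbar[:, None])
        J = con._det3(F)
        sig = np.einsum("egij,egkj->egik", P, F) / J[..., None, None]
        sig = 0.5 * (sig + np.swapaxes(sig, -1, -2))
        vm = con.von_mises(sig)
        return sig, vm


def apply_interface(interface: SlidingInterface, mode: str | None = None) -> list:
    """Expand an interface into per-pair constraint records.

    Each record is (slave_node, master_node, tied_normals, free_tangents):
    bonded ties all three components (three orthonormal 'normals');
    frictionless sliding ties the facet normal component(s) and leaves the
    tangential space free.
    """
    mode = mode or interface.mode
    out = []
    for (s, m), nlist in zip(np.asarray(interface.pairs), interface.normals):
        nlist = np.atleast_2d(np.asarray(nlist, dtype=float))
        if mode == "bonded":
            out.append((int(s), int(m), np.eye(3), np.zeros((0, 3))))
            continue
        # orthonormalize the tied directions
        basis = []
        for n in nlist:
            v = n.copy()
            for b in basis:
                v -= (v @ b) * b
            if np.linalg.norm(v) > 1e-6:
                basis.append(v / np.linalg.norm(v))
        tied = np.array(basis)
        # free tangential space = orthogonal complement
        full = np.vstack([tied, np.eye(3)])
        free = []
        for v in full[len(basis):]:
            w = v.copy()
            for b in list(tied) + free:
                w -= (w @ b) * b
            if np.linalg.norm(w) > 1e-8:
                free.append(w / np.linalg.norm(w))
        out.append((int(s), int(m), tied, np.array(free)))
    return out


def _build_transform(n_nodes: int, bc: BoundaryConditions,
                     interface: SlidingInterface | None):
    """Constraint handling via u = T q + g.

    Returns (T sparse (ndof, nq), g_unit (ndof,), constrained_mask), where
    the prescribed part g scales with the load factor.
    """
    ndof = 3 * n_nodes
    g = np.zeros(ndof)
    constrained = np.zeros(ndof, dtype=bool)
    for (n, c) in bc.fixed:
        constrained[3 * n + c] = True
    for (n, c), v in bc.prescribed.items():
        constrained[3 * n + c] = True
        g[3 * n + c] = v

    records = apply_interface(interface) if interface is not None else []
    slave_nodes = {}
    for rec in records:
        s, m, tied, free = rec
        sd = [3 * s + i for i in range(3)]
        if constrained[sd].any():
            # constrained pair: keep Dirichlet, drop the tie
            continue
        slave_nodes[s] = rec

    is_slave = np.zeros(ndof, dtype=bool)
    for s in slave_nodes:
        is_slave[3 * s: 3 * s + 3] = True

    plain = ~constrained & ~is_slave
    plain_ids = np.where(plain)[0]
    col_of = -np.ones(ndof, dtype=int)
    col_of[plain_ids] = np.arange(plain_ids.size)
    nq = plain_ids.size

    rows, cols, vals = list(plain_ids), list(range(plain_ids.size)), [1.0] * plain_ids.size
    for s, (s_, m, tied, free) in slave_nodes.items():
        # tied part: u_s . n = u_m . n  ->  contribution n_i n_j on master dofs
        for n in tied:
            for i in range(3):
                for j in range(3):
                    md = 3 * m + j
                    w = n[i] * n[j]
                    if abs(w) < 1e-14:
                        continue
                    if constrained[md]:
                        g[3 * s + i] += w * g[md]
                    else:
                        rows.append(3 * s + i)
                        cols.append(col_of[md])
                        vals.append(w)
        # free tangential amplitudes get fresh columns
        for t in free:
            for i in range(3):
                if abs(t[i]) < 1e-14:
                    continue
                rows.append(3 * s + i)
                cols.append(nq)
                vals.append(t[i])
            nq += 1
    T = sp.csr_matrix((vals, (rows, cols)), shape=(ndof, nq))
    return T, g, constrained


def solve_static(mesh: TendonMesh, fiber_field: FiberField,
                 params: con.MaterialParams, bc: BoundaryConditions,
                 interface: SlidingInterface | None = None,
                 config: SolverConfig | None = None,
                 u0: np.ndarray | None = None,
                 s_start: float = 0.0) -> SolveResult:
    """Newton-Raphson equilibrium under the given boundary conditions.

    Loads and prescribed displacements are ramped with an incremental load
    factor; failed steps are bisected down to ``min_step_fraction``. The
    returned convergence flag is honest: a non-converged state raises
    ``ConvergenceError`` instead of being returned silently.

    ``s_start`` is the load fraction the warm start ``u0`` corresponds to:
    incremental outer loops pass the previous level's fraction so that
    bisection backtracks toward the warm state instead of toward zero load.
    """
    cfg = config or SolverConfig()
    if not 0.0 <= s_start < 1.0:
        raise ValueError("s_start must lie in [0, 1)")
    bc.validate(mesh.n_nodes)
    asm = _Assembly(mesh, fiber_field, params)
    f_target = bc.force_vector(mesh.n_nodes)
    T, g_unit, constrained = _build_transform(mesh.n_nodes, bc, interface)

    u = np.zeros(asm.ndof) if u0 is None else u0.ravel().copy()
    if u0 is None:
        s_start = 0.0
    total_iters = 0
    steps_done = 0
    s_done = s_start
    ds = (1.0 - s_start) / cfg.n_load_steps
    min_ds = (1.0 - s_start) * cfg.min_step_fraction
    fext_ref = np.linalg.norm(T.T @ f_target)

    has_presc = np.abs(g_unit).max() > 0
    while s_done < 1.0 - 1e-12:
        s = min(1.0, s_done + ds)
        f_ext = s * f_target
        # impose constrained values for this step, keep free part of u
        q = np.asarray(_extract_q(T, u)).ravel()
        u_trial = T @ q + g_unit * s
        if has_presc:
            # incremental predictor: move the interior consistently with
            # the boundary-displacement increment before evaluating the
            # (exponentially stiff) material at a boundary-crushed state
            try:
                K0 = asm.tangent(u)
                r0 = T.T @ (f_ext - asm.internal_force(u)) \
                    - T.T @ (K0 @ (g_unit * (s - s_done)))
                dq0 = spla.spsolve((T.T @ K0 @ T).tocsc(), r0)
                for _ in range(6):
                    try:
                        asm.internal_force(T @ (q + dq0) + g_unit * s)
                        q = q + dq0
                        u_trial = T @ q + g_unit * s
                        break
                    except _InversionError:
                        dq0 = 0.5 * dq0
            except (_InversionError, RuntimeError):
                pass
        ok = True
        res_norm = np.inf
        prev_res = np.inf
        solve_lu = None
        for it in range(cfg.max_iter):
            try:
                f_int = asm.internal_force(u_trial)
            except _InversionError:
                ok = False
                break
            r = T.T @ (f_int - f_ext)
            res_norm = np.linalg.norm(r)
            ref = max(fext_ref * s, np.linalg.norm(f_int[constrained]), 1.0)
            if res_norm <= cfg.tol_rel * ref + cfg.tol_abs:
                total_iters += it
                break
            # modified Newton: refactor the tangent only while progress is
            # slow; quadratic-phase iterations reuse the last factorization
            if solve_lu is None or res_norm > 0.2 * prev_res:
                K = asm.tangent(u_trial)
                Kq = (T.T @ K @ T).tocsc()
                try:
                    solve_lu = spla.factorized(Kq)
                except RuntimeError:
                    ok = False
                    break
            prev_res = res_norm
            try:
                dq = solve_lu(-r)
            except RuntimeError:
                ok = False
                break
            if not np.all(np.isfinite(dq)):
                ok = False
                break
            # backtracking update: full Newton steps unless the move is
            # pathologically large; halve on inversion or residual blow-up
            du = T @ dq
            mx = np.abs(du).max()
            alpha = min(1.0, 2.0 * asm.char_len / mx) if mx > 0 else 1.0
            accepted = False
            for _ in range(8):
                u_try = T @ (q + alpha * dq) + g_unit * s
                try:
                    r_try = T.T @ (asm.internal_force(u_try) - f_ext)
                except _InversionError:
                    alpha *= 0.5
                    continue
                if np.linalg.norm(r_try) < 2.0 * res_norm or alpha < 0.2:
                    accepted = True
                    break
                alpha *= 0.5
            if not accepted:
                ok = False
                break
            q = q + alpha * dq
            u_trial = T @ q + g_unit * s
        else:
            ok = False

        if ok:
            u = u_trial
            s_done = s
            steps_done += 1
        else:
            ds /= 2.0
            if ds < min_ds:
                raise ConvergenceError(
                    f"load stepping failed at fraction {s_done:.4f} "
                    f"(residual {res_norm:.3e})",
                    last_converged_fraction=s_done,
                    diagnostics={"residual": res_norm, "steps": steps_done},
                )

    sig, vm = asm.stresses(u)
    f_int = asm.internal_force(u)
    reactions = np.where(constrained, f_int - f_target, 0.0).reshape(-1, 3)
    return SolveResult(
        nodal_displacements=u.reshape(-1, 3),
        gauss_cauchy_stress=sig, gauss_von_mises=vm,
        converged=True, newton_iterations=total_iters,
        load_steps=steps_done, reactions=reactions,
        residual_norm=float(np.linalg.norm(T.T @ (f_int - f_target))),
    )


def _extract_q(T: sp.csr_matrix, u: np.ndarray):
    """Generalized coordinates best matching a displacement state (warm start)."""
    # T has orthogonal-ish columns (disjoint supports except slave couplings);
    # least squares via the normal equations is exact and cheap
    A = (T.T @ T).tocsc()
    return spla.spsolve(A, T.T @ u)


def split_subtendon_mesh(mesh: TendonMesh):
    """Duplicate interface nodes of a two-way labeled mesh for sliding.

    Elements keep their labels; nodes shared between the SOL and GAS element
    sets are duplicated (GAS side becomes the slave) and returned as a
    ``SlidingInterface`` with per-pair reference facet normals. In bonded
    mode the split model reproduces the monolithic solution exactly.
    """
    if mesh.subtendon_scheme != "two_way":
        raise ValueError("mesh must carry a two_way sub-tendon labeling")
    lab = mesh.subtendon_label
    gas_elems = np.where(lab == 1)[0]
    sol_elems = np.where(lab == 0)[0]
    gas_nodes = np.unique(mesh.hexes[gas_elems])
    sol_nodes = np.unique(mesh.hexes[sol_elems])
    shared = np.intersect1d(gas_nodes, sol_nodes)
    if shared.size == 0:
        raise ValueError("sub-tendon meshes are not coincident")

    n_old = mesh.n_nodes
    new_ids = {int(n): n_old + k for k, n in enumerate(shared)}
    coords = np.vstack([mesh.node_coords, mesh.node_coords[shared]])
    hexes = mesh.hexes.copy()
    for e in gas_elems:
        for a in range(8):
            n = int(hexes[e, a])
            if n in new_ids:
                hexes[e, a] = new_ids[n]

    # interface facet normals from SOL-side element faces made of shared nodes
    faces = np.array([[0, 1, 2, 3], [4, 5, 6, 7], [0, 1, 5, 4],
                      [1, 2, 6, 5], [2, 3, 7, 6], [3, 0, 4, 7]])
    shared_set = set(int(x) for x in shared)
    node_normals = {int(n): [] for n in shared}
    for e in sol_elems:
        for f in faces:
            fn = mesh.hexes[e, f]
            if all(int(x) in shared_set for x in fn):
                p = mesh.node_coords[fn]
                nrm = np.cross(p[2] - p[0], p[3] - p[1])
                nn = np.linalg.norm(nrm)
                if nn < 1e-12:
                    continue
                nrm /= nn
                for x in fn:
                    node_normals[int(x)].append(nrm)

    pairs, normals = [], []
    for n in shared:
        n = int(n)
        cand = node_normals[n]
        if not cand:
            # shared node not on any full shared face (edge-only contact):
            # tie it rigidly
            pairs.append([new_ids[n], n])
            normals.append(np.eye(3))
            continue
        # cluster normals: directions within 30 degrees are averaged
        uniq = []
        for v in cand:
            matched = False
            for k, u_ in enumerate(uniq):
                if np.arccos(np.clip(abs(v @ u_), -1, 1)) < np.deg2rad(30.0):
                    uniq[k] = (u_ + np.sign(v @ u_) * v)
                    uniq[k] = uniq[k] / np.linalg.norm(uniq[k])
                    matched = True
                    break
            if not matched:
                uniq.append(v)
        pairs.append([new_ids[n], n])
        normals.append(np.array(uniq))

    out = mesh.copy()
    out.node_coords = coords
    out.hexes = hexes
    out.duplicate_of = {v: k for k, v in new_ids.items()}
    interface = SlidingInterface(pairs=np.array(pairs), normals=normals,
                                 mode="bonded")
    return out, interface


def expand_node_set(mesh: TendonMesh, nodes: np.ndarray) -> np.ndarray:
    """Add a split mesh's duplicated interface nodes whose originals are in
    the set (so clamped end sections grip both sub-tendons)."""
    dup = getattr(mesh, "duplicate_of", None)
    if not dup:
        return np.asarray(nodes)
    base = set(int(n) for n in np.atleast_1d(nodes))
    extra = [d for d, orig in dup.items() if orig in base]
    return np.array(sorted(base | set(extra)))


def locate_points(mesh: TendonMesh, pts: np.ndarray, tol: float = 1e-6):
    """Containing element and local coordinates for each physical point.

    Inverse trilinear map by per-element Newton iteration; candidates are
    tried nearest-centroid-first. Points outside every element within
    tolerance raise ValueError.
    """
    pts = np.atleast_2d(pts)
    cent = mesh.node_coords[mesh.hexes].mean(axis=1)
    elems = np.empty(pts.shape[0], dtype=int)
    xis = np.empty((pts.shape[0], 3))
    from .element import shape_gradients

    for k, p in enumerate(pts):
        order = np.argsort(np.linalg.norm(cent - p, axis=1))[:12]
        found = False
        for e in order:
            Xe = mesh.node_coords[mesh.hexes[e]]
            xi = np.zeros(3)
            for _ in range(30):
                r = shape_functions(xi) @ Xe - p
                Jm = np.einsum("ai,aj->ji", shape_gradients(xi), Xe).T
                try:
                    dxi = np.linalg.solve(Jm.T, -r)
                except np.linalg.LinAlgError:
                    break
                xi = np.clip(xi + dxi, -1.5, 1.5)
                if np.linalg.norm(dxi) < 1e-12:
                    break
            if np.all(np.abs(xi) <= 1.0 + 1e-8) and \
               np.linalg.norm(shape_functions(xi) @ Xe - p) < tol * max(1.0, np.abs(p).max()):
                elems[k], xis[k] = e, np.clip(xi, -1.0, 1.0)
                found = True
                break
        if not found:
            raise ValueError(f"point {p} lies outside the mesh")
    return elems, xis


def default_markers(mesh: TendonMesh, n: int = 6) -> np.ndarray:
    """Surface marker positions: n equidistant points along the posterior
    surface line from the distal to the proximal end of the free tendon."""
    ring = mesh.boundary_ring
    post_xy = mesh.node_coords[mesh.section_boundary(0)][:, :2]
    c = mesh.section_centroid(0)[:2]
    k_post = int(np.argmin((post_xy - c)[:, 1]))  # most posterior (-y)
    line = np.array([mesh.node_coords[mesh.section_boundary(s)[k_post]]
                     for s in range(mesh.n_sections)])
    zq = np.linspace(line[0, 2], line[-1, 2], n)
    out = np.column_stack([
        np.interp(zq, line[:, 2], line[:, 0]),
        np.interp(zq, line[:, 2], line[:, 1]),
        zq,
    ])
    return out


def track_markers(mesh: TendonMesh, result: SolveResult,
                  marker_positions: np.ndarray) -> np.ndarray:
    """Convect surface markers with the interpolated displacement field."""
    pts = np.atleast_2d(marker_positions)
    elems, xis = locate_points(mesh, pts)
    N = shape_functions(xis)  # (nm, 8)
    u = np.einsum("ma,mai->mi", N, result.nodal_displacements[mesh.hexes[elems]])
    return pts + u


def _principal_angle(xy: np.ndarray) -> tuple[float, float]:
    """In-plane principal axis angle and aspect ratio of a point ring."""
    d = xy - xy.mean(axis=0)
    M = d.T @ d / d.shape[0]
    evals, evecs = np.linalg.eigh(M)
    v = evecs[:, -1]
    ang = np.arctan2(v[1], v[0])
    aspect = np.sqrt(evals[-1] / max(evals[0], 1e-30))
    return ang, aspect


def _wrap_half(a):
    """Wrap angle to (-pi/2, pi/2] (principal axes are directionless)."""
    return (a + np.pi / 2.0) % np.pi - np.pi / 2.0


def transverse_rotation(mesh: TendonMesh, result: SolveResult) -> float:
    """Rotation (degrees) of the proximal section's in-plane principal axis
    relative to the distal section's, positive counter-clockwise about +z.

    For near-circular sections (deformed aspect ratio < 1.05) the principal
    axis is degenerate and the mean azimuthal rotation of the boundary node
    ring is used instead.
    """
    u = result.nodal_displacements
    out = []
    for s in (0, mesh.n_axial):
        ids = mesh.section_boundary(s)
        ref = mesh.node_coords[ids][:, :2]
        cur = ref + u[ids][:, :2]
        ang_ref, _ = _principal_angle(ref)
        ang_cur, aspect = _principal_angle(cur)
        if aspect < 1.05:
            c_ref, c_cur = ref.mean(axis=0), cur.mean(axis=0)
            th = np.arctan2((cur - c_cur)[:, 1], (cur - c_cur)[:, 0]) \
                - np.arctan2((ref - c_ref)[:, 1], (ref - c_ref)[:, 0])
            rot = np.arctan2(np.sin(th), np.cos(th)).mean()
        else:
            rot = _wrap_half(ang_cur - ang_ref)
        out.append(rot)
    return float(np.rad2deg(_wrap_half(out[1] - out[0])))
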