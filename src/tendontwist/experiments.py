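"""In-silico tendon studies: the rupture experiment under differential
triceps-surae loading, compartmental stress analysis, and the four-case
sub-tendon sliding comparison.

Rupture criterion: the tendon is considered ruptured when 15 or more
consecutive Gauss points along an axial Gauss-point column carry von Mises
stress above 100 MPa (a run corresponding to a few millimetres of tissue;
the physical run length for the actual mesh is recorded in the result).
Load is applied in 100 N increments split 6:2:1 between the soleus, medial
gastrocnemius and lateral gastrocnemius sub-tendon node sets, the
physiological cross-sectional-area ratio of the triceps surae.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constitutive import MaterialParams
from .geometry import TendonMesh, MEDIAL, LATERAL
from .fiber import FiberField, fiber_field_from_twist
from .element import gauss_points
from .solver import (
    BoundaryConditions,
    ConvergenceError,
    SolveResult,
    SolverConfig,
    SlidingInterface,
    solve_static,
    split_subtendon_mesh,
    expand_node_set,
)

__all__ = [
    "LoadSplit",
    "RuptureResult",
    "SlidingComparison",
    "run_rupture",
    "compartment_stress_summary",
    "run_sliding_study",
    "nodal_stress_r2",
    "axial_gauss_columns",
    "longest_threshold_run",
    "subtendon_force_bc",
    "nodal_von_mises",
]


@dataclass(frozen=True)
class LoadSplit:
    """Fractions of the total force carried by each sub-tendon (sum to 1)."""

    soleus_fraction: float = 2.0 / 3.0
    mg_fraction: float = 2.0 / 9.0
    lg_fraction: float = 1.0 / 9.0

    def __post_init__(self):
        s = self.soleus_fraction + self.mg_fraction + self.lg_fraction
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"load split fractions sum to {s}, not 1")
        if min(self.soleus_fraction, self.mg_fraction, self.lg_fraction) < 0:
            raise ValueError("load split fractions must be non-negative")

    def fractions(self) -> dict:
        return {0: self.soleus_fraction, 1: self.mg_fraction, 2: self.lg_fraction}


@dataclass
class RuptureResult:
    """Outcome of the incremental-load rupture experiment."""

    rupture_load: float | None        # N; None if no rupture
    load_history: list                # (applied N, max consecutive run)
    threshold: float                  # MPa
    run_length_required: int
    run_length_mm: float              # physical length of the required run
    compartment_history: list = field(default_factory=list)
    status: str = "ruptured"          # ruptured | no_rupture_max_load | solver_failure
    last_converged_load: float = 0.0
    final_result: SolveResult | None = None


@dataclass
class SlidingComparison:
    """Failure strains and stress-field agreement of the four sliding cases."""

    failure_strain: dict              # case label -> strain (or None)
    nodal_vm: dict                    # case label -> per-node von Mises at ref strain
    r2: dict                          # pair label -> squared Pearson correlation
    reference_strain: float
    cases: tuple = ("straight_bonded", "straight_sliding",
                    "twisted_bonded", "twisted_sliding")


def axial_gauss_columns(mesh: TendonMesh) -> np.ndarray:
    """Element/Gauss-point index stacks forming axial Gauss columns.

    Returns (n_columns, 2*n_axial, 2): for each in-plane quad and each of
    the four in-plane Gauss positions, the (element, gauss point) pairs
    ordered distal to proximal. The tensor-product Gauss rule orders points
    z-slowest, so in-plane position q sits at point ``4*iz + q``.
    """
    if mesh.gauss_order != 2:
        raise NotImplementedError("axial columns assume the 2x2x2 rule")
    nq = mesh.elems_per_section
    cols = np.empty((nq * 4, 2 * mesh.n_axial, 2), dtype=int)
    for p in range(nq):
        for q in range(4):
            k = p * 4 + q
            for s in range(mesh.n_axial):
                e = s * nq + p
                cols[k, 2 * s] = (e, q)
                cols[k, 2 * s + 1] = (e, 4 + q)
    return cols


def longest_threshold_run(values: np.ndarray, threshold: float) -> int:
    """Length of the longest run of consecutive entries above threshold."""
    v = np.asarray(values) > threshold
    best = cur = 0
    for x in v:
        cur = cur + 1 if x else 0
        best = max(best, cur)
    return best


def _max_column_run(mesh: TendonMesh, vm: np.ndarray, threshold: float,
                    columns: np.ndarray) -> int:
    runs = [longest_threshold_run(vm[c[:, 0], c[:, 1]], threshold)
            for c in columns]
    return int(max(runs))


def _column_spacing_mm(mesh: TendonMesh) -> float:
    """Mean axial spacing between consecutive Gauss points in a column."""
    L = float(mesh.node_coords[:, 2].max() - mesh.node_coords[:, 2].min())
    return L / (2 * mesh.n_axial)


def subtendon_force_bc(mesh: TendonMesh, total_force: float,
                       split: LoadSplit) -> BoundaryConditions:
    """Distal clamp plus differential proximal loading.

    Each sub-tendon's share of the axial force is spread over its proximal
    nodes with tributary-area weights (a quarter of each proximal face quad
    goes to each of its corner nodes).
    """
    if mesh.subtendon_label is None or mesh.subtendon_scheme != "three_way":
        raise ValueError("rupture loading needs a three_way labeled mesh")
    bc = BoundaryConditions()
    bc.fix_nodes(expand_node_set(mesh, mesh.distal_node_set))

    top = mesh.n_axial - 1
    nq = mesh.elems_per_section
    frac = split.fractions()
    # per-code node weights from the proximal faces of the top element slab
    weights = {c: {} for c in frac}
    for p in range(nq):
        e = top * nq + p
        code = int(mesh.subtendon_label[e])
        face = mesh.hexes[e, 4:]  # proximal face of the extruded hex
        pts = mesh.node_coords[face][:, :2]
        d1, d2 = pts[2] - pts[0], pts[3] - pts[1]
        area = 0.5 * abs(d1[0] * d2[1] - d1[1] * d2[0])
        for n in face:
            weights[code][int(n)] = weights[code].get(int(n), 0.0) + area / 4.0
    for code, w in weights.items():
        if not w:
            raise ValueError(f"sub-tendon {code} has no proximal nodes")
        tot = sum(w.values())
        for n, wi in w.items():
            bc.add_forces([n], [0.0, 0.0, total_force * frac[code] * wi / tot])
    return bc


def run_rupture(mesh: TendonMesh, fiber_field: FiberField,
                params: MaterialParams, split: LoadSplit | None = None,
                increment: float = 100.0, threshold: float = 100.0,
                run_length: int = 15, max_load: float = 10000.0,
                solver_config: SolverConfig | None = None,
                vtk_dir: str | None = None) -> RuptureResult:
    """Incremental-load rupture experiment.

    The total force climbs in ``increment`` steps; after each converged
    solve the longest over-threshold run along every axial Gauss column is
    measured. The first load whose run reaches ``run_length`` is the
    rupture load; reaching ``max_load`` first gives an explicit no-rupture
    outcome, and solver failure reports the last converged load.
    """
    if increment <= 0:
        raise ValueError("increment must be positive")
    if 2 * mesh.n_axial < run_length:
        raise ValueError(
            f"axial resolution too coarse: columns hold {2 * mesh.n_axial} "
            f"Gauss points, fewer than the required run of {run_length}")
    split = split or LoadSplit()
    columns = axial_gauss_columns(mesh)
    run_mm = run_length * _column_spacing_mm(mesh)
    cfg = solver_config or SolverConfig(n_load_steps=2)
    step_cfg = replace(cfg, n_load_steps=1)

    history, comp_hist = [], []
    u0 = None
    F = 0.0
    last_ok = 0.0
    result = None
    while F < max_load - 1e-9:
        F = min(F + increment, max_load)
        bc = subtendon_force_bc(mesh, F, split)
        try:
            result = solve_static(mesh, fiber_field, params, bc,
                                  config=cfg if u0 is None else step_cfg,
                                  u0=u0,
                                  s_start=0.0 if u0 is None else last_ok / F)
        except ConvergenceError:
            return RuptureResult(
                rupture_load=None, load_history=history, threshold=threshold,
                run_length_required=run_length, run_length_mm=run_mm,
                compartment_history=comp_hist, status="solver_failure",
                last_converged_load=last_ok, final_result=None,
            )
        u0 = result.nodal_displacements
        last_ok = F
        if vtk_dir is not None:
            from pathlib import Path

            from .io import write_result_vtk

            Path(vtk_dir).mkdir(parents=True, exist_ok=True)
            write_result_vtk(
                Path(vtk_dir) / f"rupture_{int(round(F)):06d}N.vtk",
                mesh, result, fiber_field)
        run = _max_column_run(mesh, result.gauss_von_mises, threshold, columns)
        history.append((F, run))
        if mesh.compartment_label is not None:
            comp_hist.append((F,) + compartment_stress_summary(mesh, result))
        if run >= run_length:
            return RuptureResult(
                rupture_load=F, load_history=history, threshold=threshold,
                run_length_required=run_length, run_length_mm=run_mm,
                compartment_history=comp_hist, status="ruptured",
                last_converged_load=F, final_result=result,
            )
    return RuptureResult(
        rupture_load=None, load_history=history, threshold=threshold,
        run_length_required=run_length, run_length_mm=run_mm,
        compartment_history=comp_hist, status="no_rupture_max_load",
        last_converged_load=last_ok, final_result=result,
    )


def compartment_stress_summary(mesh: TendonMesh, result: SolveResult):
    """Volume-weighted mean von Mises stress per compartment.

    Returns (medial mean, lateral mean, percent difference); the percent
    difference is (medial - lateral)/lateral * 100, infinite (flagged by
    the value itself) when the lateral compartment is unstressed.
    """
    if mesh.compartment_label is None:
        raise ValueError("mesh has no compartment labels")
    xi, w = gauss_points(mesh.gauss_order)
    from .element import jacobians

    detJ, _ = jacobians(mesh.node_coords, mesh.hexes, xi)
    wdet = detJ * w
    vm = result.gauss_von_mises
    means = {}
    for lab, name in ((MEDIAL, "medial"), (LATERAL, "lateral")):
        m = mesh.compartment_label == lab
        if not m.any():
            raise ValueError(f"empty {name} compartment")
        means[name] = float((vm[m] * wdet[m]).sum() / wdet[m].sum())
    med, lat = means["medial"], means["lateral"]
    pct = np.inf if lat == 0.0 else (med - lat) / lat * 100.0
    return med, lat, float(pct)


def nodal_von_mises(mesh: TendonMesh, result: SolveResult) -> np.ndarray:
    """Element-averaged von Mises stress scattered to nodes (simple patch
    recovery: each node averages its adjacent elements' Gauss means).

    On a split sub-tendon mesh, duplicated interface nodes are folded back
    onto their originals so the field is comparable with monolithic solves.
    """
    evm = result.gauss_von_mises.mean(axis=1)
    acc = np.zeros(mesh.n_nodes)
    cnt = np.zeros(mesh.n_nodes)
    np.add.at(acc, mesh.hexes.ravel(), np.repeat(evm, 8))
    np.add.at(cnt, mesh.hexes.ravel(), 1.0)
    dup = getattr(mesh, "duplicate_of", None)
    if dup:
        for d, orig in dup.items():
            acc[orig] += acc[d]
            cnt[orig] += cnt[d]
            acc[d], cnt[d] = acc[orig], cnt[orig]
    return acc / np.maximum(cnt, 1.0)


def nodal_stress_r2(field_a: np.ndarray, field_b: np.ndarray) -> float:
    """Squared Pearson correlation between paired nodal scalar fields."""
    a = np.asarray(field_a, dtype=float).ravel()
    b = np.asarray(field_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("node sets do not match")
    if a.std() == 0.0 or b.std() == 0.0:
        raise ValueError("zero-variance stress field")
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def _stretch_to_failure(mesh, fiber_field, params, interface, threshold,
                        run_length, columns, strain_step, max_strain,
                        ref_strain, solver_config):
    """Displacement-controlled ramp; returns (failure strain, vm at ref)."""
    L = mesh.profile.length
    prox = expand_node_set(mesh, mesh.proximal_node_set)
    dist = expand_node_set(mesh, mesh.distal_node_set)
    cfg = solver_config or SolverConfig(n_load_steps=2)
    step_cfg = replace(cfg, n_load_steps=1)
    u0 = None
    vm_ref = None
    failure = None
    strain = 0.0
    while strain < max_strain - 1e-12:
        strain = min(strain + strain_step, max_strain)
        bc = BoundaryConditions()
        bc.fix_nodes(dist)
        bc.fix_nodes(prox, [0, 1])
        bc.prescribe(prox, 2, strain * L)
        res = solve_static(mesh, fiber_field, params, bc, interface=interface,
                           config=cfg if u0 is None else step_cfg, u0=u0,
                           s_start=0.0 if u0 is None
                           else (strain - strain_step) / strain)
        res_last = res
        u0 = res.nodal_displacements
        if vm_ref is None and strain >= ref_strain - 1e-12:
            vm_ref = nodal_von_mises(mesh, res)
        run = _max_column_run(mesh, res.gauss_von_mises, threshold, columns)
        if run >= run_length and failure is None:
            failure = strain
            if vm_ref is not None:
                break
    if vm_ref is None and u0 is not None:
        vm_ref = nodal_von_mises(mesh, res_last)
    return failure, vm_ref


def run_sliding_study(mesh: TendonMesh, params: MaterialParams,
                      twist_angle: float = 30.0,
                      strain_step: float = 0.01, max_strain: float = 0.30,
                      reference_strain: float = 0.10,
                      threshold: float = 100.0, run_length: int = 15,
                      solver_config: SolverConfig | None = None) -> SlidingComparison:
    """Four-case sub-tendon comparison: (straight | twisted) x (bonded |
    frictionless sliding) under displacement-controlled stretch to failure.

    Failure uses the same von Mises run-length criterion as the rupture
    experiment. Nodal stress fields are sampled at ``reference_strain`` for
    the case-to-case r^2 comparisons, including sliding-vs-embedded-twist
    (the monolithic mesh with the fitted twist field).
    """
    if mesh.subtendon_scheme != "two_way":
        raise ValueError("sliding study needs a two_way labeled mesh")
    if 2 * mesh.n_axial < run_length:
        raise ValueError(
            f"axial resolution too coarse: columns hold {2 * mesh.n_axial} "
            f"Gauss points, fewer than the required run of {run_length}")
    smesh, interface = split_subtendon_mesh(mesh)
    columns = axial_gauss_columns(mesh)

    fields = {
        "straight": fiber_field_from_twist(mesh, 0.0),
        "twisted": fiber_field_from_twist(mesh, twist_angle),
    }
    failure, nodal = {}, {}
    for geom in ("straight", "twisted"):
        for mode, iface_mode in (("bonded", "bonded"),
                                 ("sliding", "frictionless_sliding")):
            label = f"{geom}_{mode}"
            iface = replace(interface, mode=iface_mode)
            f, vm = _stretch_to_failure(
                smesh, fields[geom], params, iface, threshold, run_length,
                columns, strain_step, max_strain, reference_strain,
                solver_config,
            )
            failure[label] = f
            # restrict to original (master) nodes for cross-case comparison
            nodal[label] = vm[: mesh.n_nodes]

    # monolithic solves at the reference strain: the straight one is the
    # exactness oracle for the bonded split model, the embedded-twist one
    # (fitted Euler field) is the continuum stand-in for sliding
    _, vm_mono = _stretch_to_failure(
        mesh, fields["straight"], params, None, threshold, run_length,
        columns, strain_step, reference_strain, reference_strain,
        solver_config,
    )
    nodal["straight_monolithic"] = vm_mono
    _, vm_embedded = _stretch_to_failure(
        mesh, fiber_field_from_twist(mesh, twist_angle, fitted=True), params,
        None, threshold, run_length, columns, strain_step, reference_strain,
        reference_strain, solver_config,
    )
    nodal["embedded_twist"] = vm_embedded

    r2 = {
        "straight_bonded_vs_monolithic": nodal_stress_r2(
            nodal["straight_bonded"], nodal["straight_monolithic"]),
        "straight_bonded_vs_sliding": nodal_stress_r2(
            nodal["straight_bonded"], nodal["straight_sliding"]),
        "twisted_bonded_vs_sliding": nodal_stress_r2(
            nodal["twisted_bonded"], nodal["twisted_sliding"]),
        "twisted_sliding_vs_embedded": nodal_stress_r2(
            nodal["twisted_sliding"], nodal["embedded_twist"]),
        "twisted_bonded_vs_embedded": nodal_stress_r2(
            nodal["twisted_bonded"], nodal["embedded_twist"]),
    }
    return SlidingComparison(failure_strain=failure, nodal_vm=nodal, r2=r2,
                             reference_strain=reference_strain)
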