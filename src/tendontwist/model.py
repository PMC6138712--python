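"""Model/Results interface tying the pipeline together.

``TendonModel`` wraps a tendon mesh, a fascicle-twist field and a
cyclic-test record; ``fit()`` runs the inverse material estimation and
returns a ``TendonFitResults`` carrying the coefficient estimates, fit
quality and diagnostics, with the in-silico studies (rupture, compartment
stress, sensitivity) and forward simulation hanging off the results
object.

Example
-------
>>> model = TendonModel.from_subject(seed=1, twist_angle=0.0)
>>> res = model.fit()
>>> print(res.summary())          # doctest: +SKIP
>>> rupture = res.run_rupture()   # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constitutive import MaterialParams
from .geometry import (
    TendonMesh,
    build_mesh,
    label_compartments,
    label_subtendons,
)
from .fiber import FiberField, fiber_field_from_twist
from .solver import SolverConfig
from .synthetic import (
    ANATOMICAL_AREA_FRACTIONS,
    ExperimentRecord,
    LoadProtocol,
    PopulationModel,
    draw_subject,
    simulate_experiment,
)
from .calibration import CalibrationResult, calibrate_subject, rms_marker_error
from .experiments import LoadSplit, RuptureResult, run_rupture

__all__ = ["TendonModel", "TendonFitResults"]


@dataclass
class TendonModel:
    """A subject-specific tendon model bound to an experiment record."""

    mesh: TendonMesh
    fiber_field: FiberField
    record: ExperimentRecord | None = None
    twist_angle: float = 0.0
    lambda_star: float = 1.03
    subject_id: int | str = 0
    true_params: MaterialParams | None = None
    solver_config: SolverConfig | None = None

    @classmethod
    def from_subject(cls, seed: int, twist_angle: float | None = None,
                     population: PopulationModel | None = None,
                     n_axial: int = 4, n_circ: int = 12, n_radial: int = 1,
                     noise_sd: float = 0.1,
                     protocol: LoadProtocol | None = None,
                     simulate: bool = True) -> "TendonModel":
        """Draw a synthetic subject and (optionally) its cyclic-test record.

        ``twist_angle=None`` uses the subject's own drawn twist; the
        calibration meshes default to the coarse working resolution.
        """
        population = population or PopulationModel()
        profile, params, twist = draw_subject(population, seed)
        angle = twist if twist_angle is None else float(twist_angle)
        mesh = build_mesh(profile, n_axial=n_axial, n_circ=n_circ,
                          n_radial=n_radial)
        mesh = label_subtendons(label_compartments(mesh), "three_way",
                                fractions=ANATOMICAL_AREA_FRACTIONS)
        ff = fiber_field_from_twist(mesh, angle)
        record = None
        if simulate:
            record = simulate_experiment(
                mesh, ff, params,
                protocol=protocol or LoadProtocol(target_strain=0.08),
                noise_sd=noise_sd, seed=seed,
            )
        return cls(mesh=mesh, fiber_field=ff, record=record,
                   twist_angle=angle, subject_id=seed, true_params=params)

    def fit(self, seed: int = 0, n_starts: int = 2,
            max_nfev: int = 60) -> "TendonFitResults":
        """Calibrate (C1, C3, C4, C5) against the bound record."""
        if self.record is None:
            raise ValueError("model has no experiment record to fit")
        cal = calibrate_subject(
            self.record, self.mesh, self.fiber_field,
            lambda_star=self.lambda_star, seed=seed, n_starts=n_starts,
            solver_config=self.solver_config, max_nfev=max_nfev,
        )
        return TendonFitResults(model=self, calibration=cal)

    def simulate(self, params: MaterialParams,
                 protocol: LoadProtocol | None = None,
                 noise_sd: float = 0.0, seed: int = 0) -> ExperimentRecord:
        """Forward-simulate a cyclic test with the given coefficients."""
        return simulate_experiment(
            self.mesh, self.fiber_field, params,
            protocol=protocol or LoadProtocol(target_strain=0.08),
            noise_sd=noise_sd, seed=seed,
            solver_config=self.solver_config,
        )


@dataclass
class TendonFitResults:
    """Estimates, fit quality and downstream studies of a fitted model."""

    model: TendonModel
    calibration: CalibrationResult

    @property
    def params(self) -> MaterialParams:
        return self.calibration.fitted_params

    @property
    def rms_error(self) -> float:
        return self.calibration.rms_error

    def summary(self) -> str:
        p = self.params
        t = self.model.true_params
        rows = []
        for k in ("c1", "c3", "c4", "c5", "c6", "lambda_star", "kappa"):
            row = {"coefficient": k, "estimate": getattr(p, k)}
            if t is not None:
                row["truth"] = getattr(t, k)
            rows.append(row)
        df = pd.DataFrame(rows).set_index("coefficient")
        head = (
            f"Tendon material fit (subject {self.model.subject_id}, "
            f"twist {self.model.twist_angle:.1f} deg)\n"
            f"marker RMS error: {self.rms_error:.4f} mm | forward "
            f"evaluations: {self.calibration.iterations}\n"
        )
        return head + df.to_string(float_format=lambda v: f"{v:.4g}")

    def params_frame(self) -> pd.DataFrame:
        d = self.params.to_dict()
        d.update(subject=self.model.subject_id,
                 twist_deg=self.model.twist_angle,
                 rms_mm=self.rms_error)
        return pd.DataFrame([d])

    def run_rupture(self, split: LoadSplit | None = None,
                    increment: float = 100.0, threshold: float = 100.0,
                    run_length: int = 15,
                    mesh: TendonMesh | None = None,
                    fiber_field: FiberField | None = None) -> RuptureResult:
        """Rupture experiment with the fitted coefficients.

        A finer rupture mesh (and its matching fiber field) may be passed
        in; by default the calibration mesh is reused.
        """
        m = mesh if mesh is not None else self.model.mesh
        ff = fiber_field if fiber_field is not None else (
            fiber_field_from_twist(m, self.model.twist_angle)
            if mesh is not None else self.model.fiber_field)
        return run_rupture(m, ff, self.params, split=split,
                           increment=increment, threshold=threshold,
                           run_length=run_length,
                           solver_config=self.model.solver_config)

    def plot_fit(self, ax=None):
        """Force versus marker-span stretch: record against fitted model."""
        import matplotlib.pyplot as plt

        from .calibration import _forward_markers, _span_stretch

        rec = self.model.record
        sim_traj = _forward_markers(self.model.mesh, self.model.fiber_field,
                                    self.params, rec,
                                    self.model.solver_config)
        if ax is None:
            _, ax = plt.subplots()

        def span(traj):
            d = np.linalg.norm(traj[:, -1] - traj[:, 1], axis=1)
            return d / d[0]

        ax.plot(span(rec.marker_trajectories), rec.applied_force, "o",
                label="record")
        ax.plot(span(sim_traj), rec.applied_force, "-", label="fitted model")
        ax.set_xlabel("marker-span stretch")
        ax.set_ylabel("applied force (N)")
        ax.legend()
        return ax

    def plot_rupture(self, rupture: RuptureResult, ax=None):
        """Load staircase against the over-threshold run length."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        hist = np.array(rupture.load_history)
        ax.step(hist[:, 0], hist[:, 1], where="post")
        ax.axhline(rupture.run_length_required, ls="--", color="k",
                   label=f"rupture run ({rupture.run_length_mm:.0f} mm)")
        ax.set_xlabel("applied force (N)")
        ax.set_ylabel("longest over-threshold Gauss run")
        ax.legend()
        return ax

    def recompute_rms(self) -> float:
        """Idempotence check: one forward run of the record's force levels
        at the fitted coefficients reproduces the stored RMS error."""
        from .calibration import _forward_markers

        traj = _forward_markers(self.model.mesh, self.model.fiber_field,
                                self.params, self.model.record,
                                self.model.solver_config)
        return rms_marker_error(traj[1:],
                                self.model.record.marker_trajectories[1:])
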