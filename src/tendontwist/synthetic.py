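"""Synthetic stand-ins for the cadaver inputs: population draws of tendon
geometry/material/twist, and simulated cyclic uniaxial stretch experiments
with tracked surface markers.

The population model emulates the spread reported for human Achilles
tendons: cross-sectional area ~70 +/- 15 mm^2, straightened-collagen
modulus on the order of 1 GPa, and fascicle twist 37 +/- 14 degrees
(anatomical surveys report an 11-65 degree range). Positive quantities are
drawn log-normally so every subject is physically admissible.

A simulated experiment clamps the distal end, ramps an axial force at the
proximal end, solves the forward FE problem at each sampled load level and
records the six surface-marker positions, optionally with additive i.i.d.
Gaussian measurement noise (CCD marker-tracking error).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constitutive import MaterialParams
from .geometry import CrossSectionProfile, TendonMesh, build_mesh
from .fiber import FiberField
from .solver import (
    BoundaryConditions,
    SolverConfig,
    default_markers,
    solve_static,
    track_markers,
    expand_node_set,
)

__all__ = [
    "PopulationModel",
    "ExperimentRecord",
    "LoadProtocol",
    "ANATOMICAL_AREA_FRACTIONS",
    "draw_subject",
    "simulate_experiment",
    "subject_profile",
    "build_subject_mesh",
]

# anatomical sub-tendon cross-section shares (soleus, medial gastrocnemius,
# lateral gastrocnemius): unlike the 6:2:1 muscle-PCSA *load* split, the
# sub-tendons occupy roughly 52/35/13 percent of the tendon cross-section,
# and that mismatch is what differential loading concentrates
ANATOMICAL_AREA_FRACTIONS = (0.52, 0.35, 0.13)


@dataclass(frozen=True)
class PopulationModel:
    """Subject-to-subject variability of the synthetic cohort.

    Means and standard deviations parameterize log-normal draws for the
    positive quantities; twist is drawn normally and clamped to [0, 90]
    degrees. ``c1``/``c3``/``c4`` spreads cover the ranges observed in
    published per-subject calibrations.
    """

    csa_mean: float = 70.0      # mm^2
    csa_sd: float = 15.0        # mm^2
    c5_mean: float = 1000.0     # MPa
    c5_sd: float = 250.0        # MPa
    twist_mean: float = 37.0    # degrees
    twist_sd: float = 14.0      # degrees
    c1_mean: float = 45.0       # MPa
    c1_sd: float = 15.0         # MPa
    c3_mean: float = 10.0       # MPa
    c3_sd: float = 4.0          # MPa
    c4_mean: float = 40.0       # dimensionless
    c4_sd: float = 12.0         # dimensionless
    aspect_ratio: float = 2.0   # medial-lateral over anterior-posterior axis
    length: float = 60.0        # mm free tendon
    lateral_bow: float = 1.2    # mm lateral offset of the mid-section centroid

    def __post_init__(self):
        for name in ("csa_sd", "c5_sd", "twist_sd", "c1_sd", "c3_sd", "c4_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _lognormal(rng, mean, sd):
    """Log-normal draw with the given arithmetic mean and SD (exact moments)."""
    if sd == 0:
        return mean
    s2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - 0.5 * s2
    return float(np.exp(rng.normal(mu, np.sqrt(s2))))


def subject_profile(csa: float, aspect: float, length: float,
                    lateral_bow: float = 0.0,
                    taper: tuple = (1.08, 0.96, 0.92, 1.0)) -> CrossSectionProfile:
    """Cross-section profile for a subject of given mid-tendon CSA.

    Four stations at 0/20/40/60 mm (the distal insertion plus the planes
    mirroring 2/4/6 cm ultrasound sections). The tendon tapers to its
    narrowest 2-4 cm above the insertion and the mid-section centroid bows
    laterally, the geometric asymmetry that concentrates stress medially
    under load when no fascicle twist is present.
    """
    z = np.linspace(0.0, length, 4)
    st = []
    for zi, tk in zip(z, taper):
        area = csa * tk
        b = np.sqrt(area / (np.pi * aspect))
        a = aspect * b
        bow = -lateral_bow * np.sin(np.pi * zi / length)  # -x = lateral
        st.append([zi, a, b, bow, 0.0])
    return CrossSectionProfile(np.array(st))


def draw_subject(population: PopulationModel, seed: int):
    """One synthetic subject: (CrossSectionProfile, MaterialParams, twist deg).

    Deterministic given the seed; twist is clamped to [0, 90] degrees.
    """
    rng = np.random.default_rng(seed)
    csa = _lognormal(rng, population.csa_mean, population.csa_sd)
    c1 = _lognormal(rng, population.c1_mean, population.c1_sd)
    c3 = _lognormal(rng, population.c3_mean, population.c3_sd)
    c4 = _lognormal(rng, population.c4_mean, population.c4_sd)
    c5 = _lognormal(rng, population.c5_mean, population.c5_sd)
    if population.twist_sd == 0:
        twist = population.twist_mean
    else:
        twist = float(rng.normal(population.twist_mean, population.twist_sd))
    twist = float(np.clip(twist, 0.0, 90.0))
    profile = subject_profile(csa, population.aspect_ratio, population.length,
                              population.lateral_bow)
    params = MaterialParams(c1=c1, c3=c3, c4=c4, c5=c5)
    return profile, params, twist


@dataclass(frozen=True)
class LoadProtocol:
    """Uniaxial ramp protocol of the simulated material test.

    When ``peak_force`` is None the experiment is ramped to ``target_strain``
    end-to-end (the way a displacement-controlled materials test is run) and
    the corresponding peak force is measured from the machine reaction
    before the force-sampled ramp is recorded. The 6% default strain ends
    well past collagen uncrimping, where the stress/strain gradient reads
    the straightened-collagen modulus.
    """

    peak_force: float | None = None  # N
    target_strain: float = 0.06
    n_samples: int = 10

    def force_levels(self, peak: float | None = None) -> np.ndarray:
        p = self.peak_force if peak is None else peak
        if p is None:
            raise ValueError("peak force not resolved")
        return np.linspace(0.0, p, self.n_samples + 1)[1:]


@dataclass
class ExperimentRecord:
    """A synthetic cyclic-test record: force history plus marker tracks.

    ``marker_trajectories`` has shape (n_samples+1, 6, 3) and starts at the
    reference marker positions (zero force); ``true_params`` carries the
    generating ground truth, hidden from calibration by default.
    """

    time: np.ndarray                 # s
    applied_force: np.ndarray        # N, starts at 0
    marker_trajectories: np.ndarray  # (nt, nm, 3) mm
    noise_sd: float                  # mm
    reference_csa: float             # mm^2, distal station
    reference_markers: np.ndarray    # (nm, 3) mm, noiseless reference
    true_params: MaterialParams | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.applied_force[0] != 0.0:
            raise ValueError("force history must start at zero")
        if self.marker_trajectories.shape[0] != self.applied_force.shape[0]:
            raise ValueError("trajectory/force sample mismatch")
        if not np.allclose(self.marker_trajectories[0], self.reference_markers):
            raise ValueError("trajectories must start at the reference markers")


def simulate_experiment(mesh: TendonMesh, fiber_field: FiberField,
                        true_params: MaterialParams,
                        protocol: LoadProtocol | None = None,
                        noise_sd: float = 0.1, seed: int = 0,
                        markers: np.ndarray | None = None,
                        solver_config: SolverConfig | None = None) -> ExperimentRecord:
    """Forward-simulate the clamped uniaxial marker-tracking experiment.

    The distal section is fully fixed (the calcaneal clamp); the sampled
    axial force is spread uniformly over the proximal nodes. Marker
    positions at each level are convected with the FE displacement field
    and perturbed by i.i.d. Gaussian noise of ``noise_sd`` mm.
    """
    protocol = protocol or LoadProtocol()
    rng = np.random.default_rng(seed)
    mk0 = default_markers(mesh) if markers is None else np.atleast_2d(markers)
    prox = expand_node_set(mesh, mesh.proximal_node_set)
    dist = expand_node_set(mesh, mesh.distal_node_set)

    peak = protocol.peak_force
    if peak is None:
        # displacement-controlled pre-run: pull to the target strain and
        # read the peak force off the machine reaction
        L = mesh.profile.length
        bc = BoundaryConditions()
        bc.fix_nodes(dist)
        bc.fix_nodes(prox, [0, 1])
        bc.prescribe(prox, 2, protocol.target_strain * L)
        pre = solve_static(mesh, fiber_field, true_params, bc,
                           config=solver_config or SolverConfig())
        peak = float(-pre.reactions.reshape(-1, 3)[dist, 2].sum())
    levels = protocol.force_levels(peak)

    traj = np.empty((levels.size + 1, mk0.shape[0], 3))
    traj[0] = mk0
    u0 = None
    cfg = solver_config or SolverConfig(n_load_steps=2)
    step_cfg = SolverConfig(**{**cfg.__dict__, "n_load_steps": 1})
    for k, F in enumerate(levels):
        bc = BoundaryConditions()
        bc.fix_nodes(dist)
        bc.add_forces(prox, [0.0, 0.0, F / prox.size])
        res = solve_static(mesh, fiber_field, true_params, bc,
                           config=cfg if k == 0 else step_cfg, u0=u0,
                           s_start=0.0 if k == 0 else levels[k - 1] / F)
        u0 = res.nodal_displacements
        traj[k + 1] = track_markers(mesh, res, mk0)

    if noise_sd > 0:
        # the rest state defines the reference frame and stays exact
        traj[1:] += rng.normal(0.0, noise_sd, size=traj[1:].shape)

    from .geometry import section_area

    force = np.concatenate([[0.0], levels])
    return ExperimentRecord(
        time=np.arange(force.size, dtype=float),
        applied_force=force,
        marker_trajectories=traj,
        noise_sd=noise_sd,
        reference_csa=section_area(mesh, 0),
        reference_markers=mk0,
        true_params=true_params,
        seed=seed,
    )


def build_subject_mesh(profile: CrossSectionProfile, n_axial: int = 4,
                       n_circ: int = 12, n_radial: int = 1) -> TendonMesh:
    """Convenience mesh builder at the cohort study's working resolution."""
    return build_mesh(profile, n_axial=n_axial, n_circ=n_circ, n_radial=n_radial)
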