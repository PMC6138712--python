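"""Transversely isotropic hyperelastic material model for tendon.

The tendon is modelled as a neo-Hookean ground-substance matrix reinforced
by a single family of collagen fibers:

    W = F1(I1) + F2(lambda) + U(J)

where ``F1 = c1/2 (I1 - 3)`` is the matrix energy as a function of the first
invariant of the (isochoric) right Cauchy-Green tensor, ``F2`` is the fiber
energy as a function of fiber stretch ``lambda``, and ``U(J) = kappa/2 (ln J)^2``
is a volumetric penalty enforcing near-incompressibility.

The fiber stress law is piecewise (toe / uncrimping / linear):

    lam * dF2/dlam = 0                              for lam <= 1
    lam * dF2/dlam = c3 [exp(c4 (lam-1)) - 1]       for 1 <= lam <= lam*
    lam * dF2/dlam = c5 lam + c6                    for lam >= lam*

with c6 fixed by continuity at the uncrimping stretch ``lam*``:

    c6 = c3 (exp(c4 (lam*-1)) - 1) - c5 lam*

Units are fixed package-wide: mm, N, MPa.

All point-wise functions accept batched inputs (leading axes broadcast), so
the FE solver can evaluate whole Gauss-point arrays at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expi

__all__ = [
    "MaterialParams",
    "DeformationState",
    "c6_from_continuity",
    "fiber_stress",
    "fiber_energy",
    "strain_energy",
    "pk1_stress",
    "cauchy_stress",
    "uniaxial_closed_form",
    "uniaxial_tangent_modulus",
    "von_mises",
]


def c6_from_continuity(c3: float, c4: float, c5: float, lambda_star: float) -> float:
    """Linear-branch offset that makes the fiber stress law continuous at lam*."""
    if lambda_star <= 1.0:
        raise ValueError(f"lambda_star must exceed 1, got {lambda_star}")
    return c3 * (np.exp(c4 * (lambda_star - 1.0)) - 1.0) - c5 * lambda_star


@dataclass(frozen=True)
class MaterialParams:
    """The five fitted coefficients plus uncrimping stretch and bulk penalty.

    Parameters
    ----------
    c1 : float
        Ground-substance (neo-Hookean) shear modulus, MPa.
    c3 : float
        Scale of the exponential fiber uncrimping stress, MPa.
    c4 : float
        Fiber uncrimping rate, dimensionless.
    c5 : float
        Modulus of straightened collagen (linear branch slope), MPa.
    lambda_star : float
        Stretch at which crimped collagen straightens (> 1).
    kappa : float
        Volumetric penalty stiffness, MPa. Defaults to 1000*c1, which makes
        the incompressible closed forms accurate oracles.
    c6 : float
        Linear-branch offset, MPa; derived from the other coefficients and
        never free. Constructing with an inconsistent value is an error.
    """

    c1: float
    c3: float
    c4: float
    c5: float
    lambda_star: float = 1.03
    kappa: float | None = None
    c6: float | None = None

    def __post_init__(self):
        if self.c1 <= 0:
            raise ValueError(f"c1 must be positive, got {self.c1}")
        if self.c3 < 0:
            raise ValueError(f"c3 must be non-negative, got {self.c3}")
        if self.c4 <= 0:
            raise ValueError(f"c4 must be positive, got {self.c4}")
        if self.c5 < 0:
            raise ValueError(f"c5 must be non-negative, got {self.c5}")
        if self.lambda_star <= 1.0:
            raise ValueError(f"lambda_star must exceed 1, got {self.lambda_star}")
        if self.kappa is None:
            object.__setattr__(self, "kappa", 1000.0 * self.c1)
        elif self.kappa <= 0:
            raise ValueError(f"kappa must be positive, got {self.kappa}")
        c6_req = c6_from_continuity(self.c3, self.c4, self.c5, self.lambda_star)
        if self.c6 is None:
            object.__setattr__(self, "c6", c6_req)
        elif not np.isclose(self.c6, c6_req, rtol=1e-10, atol=1e-10 * max(1.0, abs(c6_req))):
            raise ValueError(
                f"c6={self.c6} violates branch continuity; required {c6_req}"
            )

    def replace(self, **kw) -> "MaterialParams":
        """Return a copy with fields changed; c6 is rederived unless given."""
        kw.setdefault("c6", None)
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {
            "c1": self.c1, "c3": self.c3, "c4": self.c4, "c5": self.c5,
            "c6": self.c6, "lambda_star": self.lambda_star, "kappa": self.kappa,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MaterialParams":
        return cls(
            c1=float(d["c1"]), c3=float(d["c3"]), c4=float(d["c4"]),
            c5=float(d["c5"]), lambda_star=float(d["lambda_star"]),
            kappa=float(d["kappa"]) if d.get("kappa") is not None else None,
            c6=float(d["c6"]) if d.get("c6") is not None else None,
        )


@dataclass
class DeformationState:
    """A material point's deformation gradient and reference fiber direction."""

    F: np.ndarray
    fiber_dir: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self):
        self.F = np.asarray(self.F, dtype=float)
        self.fiber_dir = np.asarray(self.fiber_dir, dtype=float)
        if self.F.shape[-2:] != (3, 3):
            raise ValueError("F must be 3x3")
        if np.any(np.linalg.det(self.F) <= 0):
            raise ValueError("det(F) must be positive")
        n = np.linalg.norm(self.fiber_dir, axis=-1)
        if not np.allclose(n, 1.0, atol=1e-8):
            raise ValueError("fiber_dir must be a unit vector")


def fiber_stress(params: MaterialParams, lam):
    """Fiber stress ``lam * dF2/dlam`` (MPa) of the piecewise uncrimping law.

    Zero in the toe region (lam <= 1), exponential while uncrimping, linear
    once straightened; continuous across both branch points.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("fiber stretch must be positive")
    toe = lam <= 1.0
    lin = lam >= params.lambda_star
    exp_branch = params.c3 * (np.exp(params.c4 * (lam - 1.0)) - 1.0)
    lin_branch = params.c5 * lam + params.c6
    out = np.where(toe, 0.0, np.where(lin, lin_branch, exp_branch))
    return out if out.ndim else float(out)


def fiber_energy(params: MaterialParams, lam):
    """Fiber strain energy F2(lam) (MPa), with F2(1) = 0.

    Antiderivative of ``dF2/dlam = fiber_stress / lam``; the exponential
    branch integrates to an exponential-integral term, the linear branch to
    ``c5 lam + c6 ln lam`` plus matching constants so F2 is C1 at lam*.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("fiber stretch must be positive")
    c3, c4, c5, c6 = params.c3, params.c4, params.c5, params.c6
    ls = params.lambda_star

    def exp_part(x):
        # int_1^x c3 (e^{c4(s-1)} - 1)/s ds
        return c3 * np.exp(-c4) * (expi(c4 * x) - expi(c4)) - c3 * np.log(x)

    lam_c = np.clip(lam, 1.0, None)
    lam_e = np.clip(lam_c, None, ls)
    e = exp_part(lam_e)
    f2_star = exp_part(ls)
    lin = f2_star + c5 * (lam_c - ls) + c6 * np.log(lam_c / ls)
    out = np.where(lam_c >= ls, lin, e)
    out = np.where(lam <= 1.0, 0.0, out)
    return out if out.ndim else float(out)


def _det3(F):
    """Determinant of batched 3x3 matrices (much faster than np.linalg.det
    for the small-matrix batches the FE assembly produces)."""
    return (
        F[..., 0, 0] * (F[..., 1, 1] * F[..., 2, 2] - F[..., 1, 2] * F[..., 2, 1])
        - F[..., 0, 1] * (F[..., 1, 0] * F[..., 2, 2] - F[..., 1, 2] * F[..., 2, 0])
        + F[..., 0, 2] * (F[..., 1, 0] * F[..., 2, 1] - F[..., 1, 1] * F[..., 2, 0])
    )


def _invT3(F, det):
    """Transposed inverse of batched 3x3 matrices via the adjugate."""
    out = np.empty_like(F)
    out[..., 0, 0] = F[..., 1, 1] * F[..., 2, 2] - F[..., 1, 2] * F[..., 2, 1]
    out[..., 0, 1] = F[..., 1, 2] * F[..., 2, 0] - F[..., 1, 0] * F[..., 2, 2]
    out[..., 0, 2] = F[..., 1, 0] * F[..., 2, 1] - F[..., 1, 1] * F[..., 2, 0]
    out[..., 1, 0] = F[..., 0, 2] * F[..., 2, 1] - F[..., 0, 1] * F[..., 2, 2]
    out[..., 1, 1] = F[..., 0, 0] * F[..., 2, 2] - F[..., 0, 2] * F[..., 2, 0]
    out[..., 1, 2] = F[..., 0, 1] * F[..., 2, 0] - F[..., 0, 0] * F[..., 2, 1]
    out[..., 2, 0] = F[..., 0, 1] * F[..., 1, 2] - F[..., 0, 2] * F[..., 1, 1]
    out[..., 2, 1] = F[..., 0, 2] * F[..., 1, 0] - F[..., 0, 0] * F[..., 1, 2]
    out[..., 2, 2] = F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]
    return out / det[..., None, None]


def _split(F, fiber_dir):
    """Isochoric invariants: J, I1_bar and fiber stretch lam_bar (batched)."""
    F = np.asarray(F, dtype=float)
    a0 = np.asarray(fiber_dir, dtype=float)
    J = _det3(F)
    if np.any(J <= 0):
        raise ValueError("det(F) must be positive")
    I1 = np.einsum("...ij,...ij->...", F, F)
    Fa = np.einsum("...ij,...j->...i", F, a0)
    lam2 = np.einsum("...i,...i->...", Fa, Fa)
    Jm23 = J ** (-2.0 / 3.0)
    return J, I1, Jm23 * I1, np.sqrt(Jm23 * lam2)


def strain_energy(params: MaterialParams, state: DeformationState) -> float:
    """Strain-energy density W (MPa) at a material point.

    The isochoric matrix and fiber parts use the volume-preserving split
    (I1_bar, lam_bar); the volumetric penalty is kappa/2 (ln J)^2. Zero in
    the reference state and under pure rotation.
    """
    J, _, I1b, lamb = _split(state.F, state.fiber_dir)
    W = params.c1 / 2.0 * (I1b - 3.0) + fiber_energy(params, lamb)
    W = W + params.kappa / 2.0 * np.log(J) ** 2
    return float(W) if np.ndim(W) == 0 else W


def pk1_stress(F, fiber_dir, params: MaterialParams, jbar=None):
    """First Piola-Kirchhoff stress P = dW/dF (MPa), batched over leading axes.

    ``jbar`` substitutes an element-averaged volume ratio in the volumetric
    term (mean-dilatation treatment used by the FE solver); by default the
    point-wise J is used, which is what the stand-alone Cauchy stress does.
    """
    F = np.asarray(F, dtype=float)
    a0 = np.asarray(fiber_dir, dtype=float)
    J, I1, I1b, lamb = _split(F, a0)
    Jm23 = J ** (-2.0 / 3.0)
    FinvT = _invT3(F, J)

    # matrix: c1/2 * dI1_bar/dF = c1 * J^{-2/3} (F - I1/3 F^{-T})
    P = params.c1 * Jm23[..., None, None] * (
        F - (I1 / 3.0)[..., None, None] * FinvT
    )

    # fiber: f2'(lamb) * dlamb/dF
    t = fiber_stress(params, lamb)  # = lamb * f2'(lamb)
    Fa = np.einsum("...ij,...j->...i", F, a0)
    lam2_full = np.einsum("...i,...i->...", Fa, Fa)
    aa = np.einsum("...i,...j->...ij", Fa, np.broadcast_to(a0, Fa.shape))
    coef = np.where(lamb > 0, t / np.maximum(lamb, 1e-300) ** 2, 0.0)
    P = P + coef[..., None, None] * Jm23[..., None, None] * (
        aa - (lam2_full / 3.0)[..., None, None] * FinvT
    )

    # volumetric: U'(Jv) * J * F^{-T}
    Jv = J if jbar is None else np.broadcast_to(np.asarray(jbar, float), J.shape)
    Up = params.kappa * np.log(Jv) / Jv
    P = P + (Up * J)[..., None, None] * FinvT
    return P


def cauchy_stress(params: MaterialParams, state: DeformationState) -> np.ndarray:
    """Cauchy stress tensor (MPa): sigma = P F^T / J, symmetrized."""
    F = state.F
    P = pk1_stress(F, state.fiber_dir, params)
    J = np.linalg.det(F)
    sig = np.einsum("...ij,...kj->...ik", P, F) / J[..., None, None]
    return 0.5 * (sig + np.swapaxes(sig, -1, -2))


def uniaxial_closed_form(params: MaterialParams, lam):
    """Incompressible uniaxial Cauchy stress with the fiber along the load axis.

    sigma = c1 (lam^2 - 1/lam) + fiber_stress(lam). Serves as the analytic
    oracle for single-element FE solves and for the C5 gradient extraction.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    out = params.c1 * (lam**2 - 1.0 / lam) + fiber_stress(params, lam)
    return float(out) if out.ndim == 0 else out


def uniaxial_tangent_modulus(params: MaterialParams, lam):
    """d(sigma)/d(lam) of the incompressible uniaxial response.

    For lam >> lam* this tends to c5 plus the matrix term c1 (2 lam + 1/lam^2);
    used when backing C5 out of an experimental stress/strain gradient.
    """
    lam = np.asarray(lam, dtype=float)
    mat = params.c1 * (2.0 * lam + 1.0 / lam**2)
    toe = lam <= 1.0
    lin = lam >= params.lambda_star
    dfib = np.where(
        toe,
        0.0,
        np.where(lin, params.c5, params.c3 * params.c4 * np.exp(params.c4 * (lam - 1.0))),
    )
    out = mat + dfib
    return float(out) if out.ndim == 0 else out


def von_mises(sigma: np.ndarray, sym_tol: float = 1e-6) -> np.ndarray:
    """Von Mises equivalent stress sqrt(3/2 dev(sigma):dev(sigma)), batched.

    Raises if the input is asymmetric beyond ``sym_tol`` (relative to its
    largest entry).
    """
    sigma = np.asarray(sigma, dtype=float)
    asym = np.abs(sigma - np.swapaxes(sigma, -1, -2)).max()
    scale = max(np.abs(sigma).max(), 1.0)
    if asym > sym_tol * scale:
        raise ValueError("stress tensor is not symmetric")
    tr = np.trace(sigma, axis1=-2, axis2=-1)
    dev = sigma - (tr / 3.0)[..., None, None] * np.eye(3)
    vm = np.sqrt(1.5 * np.einsum("...ij,...ij->...", dev, dev))
    return float(vm) if vm.ndim == 0 else vm
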