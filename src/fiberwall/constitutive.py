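"""Invariant-based anisotropic hyperelastic models for planar biaxial arteries.

Both models sum a neo-Hookean ground substance and exponential fiber
contributions whose anisotropy enters through generalized structure tensors

    H_i = A I + B M_i (x) M_i + (1 - 3A - B) M_n (x) M_n,

with A = 2 kappa_op kappa_ip and B = 2 kappa_op (1 - 2 kappa_ip) condensing
the measured in-plane/out-of-plane fiber dispersions, M_i the mean in-plane
fiber directions at +/-alpha from the circumferential axis and M_n the radial
normal.  The fiber strain-like quantity for deformation C = diag(l_t^2,
l_z^2, l_r^2) is

    E = H : (C - I) = A I1 + B I_i + (1 - 3A - B) I_n - 1,

identical for both symmetric collagen families.  The material is
incompressible (l_r = 1/(l_t l_z)); the Lagrange pressure is eliminated
through the traction-free radial stress of the planar biaxial test.

Two-fiber family model (collagen only):

    Psi = c2/2 (I1 - 3) + sum_{2 families} k1/(2 k2) [exp(k2 E^2) - 1]
    s_tt = [c2 + 4 (A + B cos^2 a) psi'] l_t^2 - p,   psi' = k1 E exp(k2 E^2)

Four-fiber family model adds perfectly aligned longitudinal elastin
(E_el = l_z^2 - 1) and circumferential smooth muscle (E_smc = l_t^2 - 1),
each with prefactor k1/(4 k2) so the collagen stress coefficient halves to
2 (A + B cos^2 a) psi'_col with psi'_col = k1col E exp(k2col E^2).

Stresses are Cauchy stresses in kPa; stretches are dimensionless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DeformationState",
    "StructuralConstants",
    "TwoFiberParams",
    "FourFiberParams",
    "StressPair",
    "fiber_strain",
    "cauchy_two_fiber",
    "cauchy_four_fiber",
    "strain_energy",
]


@dataclass(frozen=True)
class DeformationState:
    """Principal stretches of an incompressible planar biaxial deformation.

    The radial stretch is determined by incompressibility,
    lambda_r = 1 / (lambda_theta * lambda_z).  Fields may be scalars or
    equal-shaped arrays.
    """

    lambda_theta: np.ndarray | float
    lambda_z: np.ndarray | float

    def __post_init__(self) -> None:
        lt = np.asarray(self.lambda_theta, dtype=float)
        lz = np.asarray(self.lambda_z, dtype=float)
        if np.any(lt <= 0) or np.any(lz <= 0):
            raise ValueError("stretches must be positive")
        object.__setattr__(self, "lambda_theta", lt if lt.ndim else float(lt))
        object.__setattr__(self, "lambda_z", lz if lz.ndim else float(lz))

    @property
    def lambda_r(self):
        return 1.0 / (np.asarray(self.lambda_theta) * np.asarray(self.lambda_z))


@dataclass(frozen=True)
class StructuralConstants:
    """Fixed structural input to the models: mean fiber angle and dispersions.

    ``alpha`` is in radians internally; use :meth:`from_degrees` at external
    boundaries.  ``A = 2 kappa_op kappa_ip`` and
    ``B = 2 kappa_op (1 - 2 kappa_ip)`` are derived, not stored.
    """

    alpha: float
    kappa_ip: float
    kappa_op: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa_ip <= 1.0:
            raise ValueError("kappa_ip must lie in [0, 1]")
        if not 0.0 <= self.kappa_op <= 0.5:
            raise ValueError("kappa_op must lie in [0, 1/2]")

    @classmethod
    def from_degrees(cls, alpha_deg: float, kappa_ip: float, kappa_op: float):
        return cls(math.radians(alpha_deg), kappa_ip, kappa_op)

    @property
    def A(self) -> float:
        return 2.0 * self.kappa_op * self.kappa_ip

    @property
    def B(self) -> float:
        return 2.0 * self.kappa_op * (1.0 - 2.0 * self.kappa_ip)

    @property
    def alpha_deg(self) -> float:
        return math.degrees(self.alpha)


# Perfectly aligned single-family constants (kappa_ip=0, kappa_op=1/2 give
# A=0, B=1): used for the elastin and smooth-muscle families.
PERFECT_ALIGNMENT_A = 0.0
PERFECT_ALIGNMENT_B = 1.0


@dataclass(frozen=True)
class TwoFiberParams:
    """Material constants of the two-fiber family model (stresses in kPa)."""

    c2: float
    k1: float
    k2: float

    def __post_init__(self) -> None:
        if min(self.c2, self.k1, self.k2) < 0:
            raise ValueError("two-fiber parameters must be nonnegative")

    def to_dict(self) -> dict:
        return {"c2": self.c2, "k1": self.k1, "k2": self.k2}


@dataclass(frozen=True)
class FourFiberParams:
    """Material constants of the four-fiber family model (kPa / dimensionless)."""

    c4: float
    k1_col: float
    k2_col: float
    k1_el: float
    k2_el: float
    k1_smc: float
    k2_smc: float

    def __post_init__(self) -> None:
        vals = (self.c4, self.k1_col, self.k2_col, self.k1_el, self.k2_el,
                self.k1_smc, self.k2_smc)
        if min(vals) < 0:
            raise ValueError("four-fiber parameters must be nonnegative")

    def to_dict(self) -> dict:
        return {
            "c4": self.c4, "k1col": self.k1_col, "k2col": self.k2_col,
            "k1el": self.k1_el, "k2el": self.k2_el,
            "k1smc": self.k1_smc, "k2smc": self.k2_smc,
        }


@dataclass(frozen=True)
class StressPair:
    """Circumferential and longitudinal Cauchy stresses (kPa)."""

    sigma_theta: np.ndarray | float
    sigma_z: np.ndarray | float


# --------------------------------------------------------------------------
# kinematics and fiber strain
# --------------------------------------------------------------------------

def _invariants(state: DeformationState):
    lt2 = np.asarray(state.lambda_theta) ** 2
    lz2 = np.asarray(state.lambda_z) ** 2
    lr2 = state.lambda_r ** 2
    return lt2, lz2, lr2


def fiber_strain(state: DeformationState, sc: StructuralConstants):
    """Green-Lagrange strain-like quantity E = H : (C - I) of the dispersed
    collagen families (identical for the +alpha and -alpha families)."""
    lt2, lz2, lr2 = _invariants(state)
    A, B = sc.A, sc.B
    i1 = lt2 + lz2 + lr2
    ii = lt2 * math.cos(sc.alpha) ** 2 + lz2 * math.sin(sc.alpha) ** 2
    return A * i1 + B * ii + (1.0 - 3.0 * A - B) * lr2 - 1.0


def _psi_prime(k1: float, k2: float, E, tension_only: bool):
    """Fiber stress derivative psi' = k1 E exp(k2 E^2)."""
    out = k1 * E * np.exp(k2 * np.square(E))
    if tension_only:
        out = np.where(np.asarray(E) > 0, out, 0.0)
    return out


# --------------------------------------------------------------------------
# Cauchy stresses
# --------------------------------------------------------------------------

def cauchy_two_fiber(
    state: DeformationState,
    params: TwoFiberParams,
    sc: StructuralConstants,
    tension_only: bool = False,
) -> StressPair:
    """Planar biaxial Cauchy stresses of the two-fiber family model.

    The radial normal stress vanishes in the planar biaxial test, which
    fixes the Lagrange pressure p = [c2 + 4(1-2A-B) psi'] lambda_r^2.
    ``tension_only`` optionally excludes fiber contributions at E < 0
    (off by default: the model as formulated carries no switch).
    """
    lt2, lz2, lr2 = _invariants(state)
    A, B = sc.A, sc.B
    ca2 = math.cos(sc.alpha) ** 2
    sa2 = math.sin(sc.alpha) ** 2
    psi = _psi_prime(params.k1, params.k2, fiber_strain(state, sc), tension_only)
    p = (params.c2 + 4.0 * (1.0 - 2.0 * A - B) * psi) * lr2
    s_t = (params.c2 + 4.0 * (A + B * ca2) * psi) * lt2 - p
    s_z = (params.c2 + 4.0 * (A + B * sa2) * psi) * lz2 - p
    return StressPair(s_t, s_z)


def cauchy_four_fiber(
    state: DeformationState,
    params: FourFiberParams,
    sc: StructuralConstants,
    tension_only: bool = False,
) -> StressPair:
    """Planar biaxial Cauchy stresses of the four-fiber family model.

    Adds perfectly aligned longitudinal elastin and circumferential smooth
    muscle to the dispersed collagen pair.  The collagen stress coefficient
    is 2(A + B cos^2 a) psi'_col, half the two-fiber coefficient, because
    the four-fiber energy uses the k1/(4 k2) fiber prefactor.
    """
    lt2, lz2, lr2 = _invariants(state)
    A, B = sc.A, sc.B
    ca2 = math.cos(sc.alpha) ** 2
    sa2 = math.sin(sc.alpha) ** 2
    psi_col = _psi_prime(
        params.k1_col, params.k2_col, fiber_strain(state, sc), tension_only
    )
    e_smc = lt2 - 1.0
    e_el = lz2 - 1.0
    smc = _psi_prime(params.k1_smc, params.k2_smc, e_smc, tension_only)
    el = _psi_prime(params.k1_el, params.k2_el, e_el, tension_only)
    p = (params.c4 + 2.0 * (1.0 - 2.0 * A - B) * psi_col) * lr2
    s_t = (params.c4 + 2.0 * (A + B * ca2) * psi_col + smc) * lt2 - p
    s_z = (params.c4 + 2.0 * (A + B * sa2) * psi_col + el) * lz2 - p
    return StressPair(s_t, s_z)


# --------------------------------------------------------------------------
# strain energy (drives the finite-difference consistency oracle)
# --------------------------------------------------------------------------

def _fiber_energy(k1: float, k2: float, E, denom: float, tension_only: bool):
    """k1/(denom*k2) [exp(k2 E^2) - 1], with the k2 -> 0 limit k1 E^2/denom."""
    E2 = np.square(E)
    if k2 < 1e-12:
        out = k1 * E2 / denom
    else:
        out = k1 / (denom * k2) * (np.exp(k2 * E2) - 1.0)
    if tension_only:
        out = np.where(np.asarray(E) > 0, out, 0.0)
    return out


def strain_energy(
    state: DeformationState,
    params: TwoFiberParams | FourFiberParams,
    sc: StructuralConstants,
    tension_only: bool = False,
):
    """Total strain-energy density Psi (kPa) for either model.

    The model is selected by the parameter type.  Zero at the identity
    deformation for all admissible parameters.
    """
    lt2, lz2, lr2 = _invariants(state)
    i1 = lt2 + lz2 + lr2
    E = fiber_strain(state, sc)
    if isinstance(params, TwoFiberParams):
        # two identical collagen families, each k1/(2 k2)[exp(k2 E^2)-1]
        return params.c2 / 2.0 * (i1 - 3.0) + 2.0 * _fiber_energy(
            params.k1, params.k2, E, 2.0, tension_only
        )
    if isinstance(params, FourFiberParams):
        psi = params.c4 / 2.0 * (i1 - 3.0)
        psi = psi + 2.0 * _fiber_energy(
            params.k1_col, params.k2_col, E, 4.0, tension_only
        )
        psi = psi + _fiber_energy(
            params.k1_el, params.k2_el, lz2 - 1.0, 4.0, tension_only
        )
        psi = psi + _fiber_energy(
            params.k1_smc, params.k2_smc, lt2 - 1.0, 4.0, tension_only
        )
        return psi
    raise TypeError(f"unsupported parameter type {type(params).__name__}")
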