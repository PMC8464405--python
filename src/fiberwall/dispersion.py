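"""Bivariate von Mises model of collagen fiber orientation and dispersion.

The fiber direction in the arterial wall is described by a unit vector

    N(Phi, Theta) = cosTheta*cosPhi e_theta + cosTheta*sinPhi e_z + sinTheta e_r

with in-plane angle Phi (circumferential-longitudinal plane) and out-of-plane
angle Theta (elevation toward the radial direction).  The orientation density
factorizes into independent in-plane and out-of-plane von Mises-type
distributions with concentration parameters ``a`` and ``b``:

    rho_ip(Phi)   = exp[a cos 2(Phi - alpha)] / I0(a)
    rho_op(Theta) = 2 sqrt(2b/pi) exp[b (cos 2Theta - 1)] / erf(sqrt(2b))

normalized so that (1/2pi) int rho_ip dPhi = 1 over a full turn and
(1/2) int rho_op cosTheta dTheta = 1 over [-pi/2, pi/2].  Two scalar
dispersion parameters condense each density:

    kappa_ip = 1/2 - I1(a) / (2 I0(a))                   in [0, 1]
    kappa_op = 1/2 - 1/(8b)
               + (1/4) sqrt(2/(pi b)) exp(-2b)/erf(sqrt(2b))   in [0, 1/2]

Perfect alignment corresponds to kappa_ip = 0, kappa_op = 1/2; an isotropic
in-plane density gives kappa_ip = 1/2 and the b -> 0 limit of kappa_op is 1/3.

This module also fits the concentration parameters to wedge-binned angular
amplitude distributions extracted from texture images, classifies images as
isotropic or anisotropic, and aggregates per-image results into a specimen
level :class:`DispersionSet`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, special

__all__ = [
    "FiberDirection",
    "InPlaneVonMises",
    "OutOfPlaneVonMises",
    "AngularDistribution",
    "DispersionSet",
    "ImageOrientation",
    "rho_ip",
    "rho_ip_mixture",
    "rho_op",
    "kappa_ip",
    "kappa_op",
    "fit_inplane",
    "fit_outofplane",
    "classify_isotropy",
    "aggregate_stack",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FiberDirection:
    """A single fiber direction given by in-plane and out-of-plane angles.

    Parameters
    ----------
    phi : float
        In-plane angle (radians), measured from the circumferential axis,
        in [0, 2*pi).
    theta : float
        Out-of-plane elevation (radians) toward the radial axis,
        in [-pi/2, pi/2].
    """

    phi: float
    theta: float

    def unit_vector(self) -> np.ndarray:
        """Cartesian components (e_theta, e_z, e_r) of the direction."""
        ct = math.cos(self.theta)
        return np.array(
            [ct * math.cos(self.phi), ct * math.sin(self.phi), math.sin(self.theta)]
        )


@dataclass(frozen=True)
class InPlaneVonMises:
    """In-plane pi-periodic von Mises density with concentration ``a``
    and mean angle ``alpha`` (radians, folded into [0, pi/2] at interfaces)."""

    a: float
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError(f"concentration parameter a must be >= 0, got {self.a}")

    def density(self, phi):
        return rho_ip(phi, self.a, self.alpha)


@dataclass(frozen=True)
class OutOfPlaneVonMises:
    """Out-of-plane even von Mises-type density with concentration ``b``."""

    b: float

    def __post_init__(self) -> None:
        if self.b < 0:
            raise ValueError(f"concentration parameter b must be >= 0, got {self.b}")

    def density(self, theta):
        return rho_op(theta, self.b)


@dataclass(frozen=True)
class AngularDistribution:
    """Wedge-binned relative fiber amplitudes over half a turn.

    ``wedge_centers`` are in degrees on [0, 180) with constant spacing equal
    to the wedge width; ``amplitudes`` are nonnegative and are normalized to
    sum to one on construction.
    """

    wedge_centers: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        centers = np.asarray(self.wedge_centers, dtype=float)
        amps = np.asarray(self.amplitudes, dtype=float)
        if centers.ndim != 1 or centers.shape != amps.shape:
            raise ValueError("wedge_centers and amplitudes must be equal-length 1-D")
        if np.any(amps < 0) or not np.all(np.isfinite(amps)):
            raise ValueError("amplitudes must be finite and >= 0")
        total = amps.sum()
        if total > 0:
            amps = amps / total
        object.__setattr__(self, "wedge_centers", centers)
        object.__setattr__(self, "amplitudes", amps)

    @property
    def wedge_width(self) -> float:
        return float(self.wedge_centers[1] - self.wedge_centers[0])

    @property
    def is_degenerate(self) -> bool:
        return bool(np.all(self.amplitudes == 0))


@dataclass(frozen=True)
class ImageOrientation:
    """Per-image orientation summary feeding the stack aggregation.

    ``peak_deg`` is the fitted in-plane peak location (None for isotropic or
    out-of-plane images), ``a``/``b`` the fitted concentration parameters
    (None when the image does not constrain them).
    """

    peak_deg: float | None = None
    a: float | None = None
    b: float | None = None
    isotropic: bool = False


@dataclass(frozen=True)
class DispersionSet:
    """Specimen-level structural parameters from an image stack."""

    alpha_deg: float | None
    alpha_sd_deg: float | None
    kappa_ip: float | None
    kappa_op: float | None
    a_mean: float | None
    b_mean: float | None
    n_images: int = 0
    n_isotropic: int = 0

    def to_dict(self) -> dict:
        return {
            "alpha_deg": self.alpha_deg,
            "alpha_sd_deg": self.alpha_sd_deg,
            "kappa_ip": self.kappa_ip,
            "kappa_op": self.kappa_op,
            "a_mean": self.a_mean,
            "b_mean": self.b_mean,
            "n_images": self.n_images,
            "n_isotropic": self.n_isotropic,
        }


# --------------------------------------------------------------------------
# densities and dispersion parameters
# --------------------------------------------------------------------------

def rho_ip(phi, a: float, alpha: float = 0.0):
    """In-plane von Mises density exp[a cos 2(Phi-alpha)] / I0(a).

    pi-periodic in ``phi``; normalized so its mean over a full turn is 1.
    """
    if a < 0:
        raise ValueError(f"concentration parameter a must be >= 0, got {a}")
    phi = np.asarray(phi, dtype=float)
    # i0e avoids overflow of I0 for large a: exp(a cos2d)/I0(a)
    #   = exp(a (cos2d - 1)) / (I0(a) exp(-a))
    out = np.exp(a * (np.cos(2.0 * (phi - alpha)) - 1.0)) / special.i0e(a)
    return out if out.ndim else float(out)


def rho_ip_mixture(phi, a: float, alpha: float):
    """Symmetric two-family in-plane density, equal-weight mixture of the
    +alpha and -alpha von Mises components.

    The two collagen families share concentration ``a`` and mirror angles
    +/-alpha about the circumferential axis.
    """
    return 0.5 * (rho_ip(phi, a, alpha) + rho_ip(phi, a, -alpha))


def rho_op(theta, b: float):
    """Out-of-plane density 2 sqrt(2b/pi) exp[b(cos 2Theta - 1)] / erf(sqrt(2b)).

    Even in ``theta``; normalized with the spherical area weight so that
    (1/2) int rho_op cosTheta dTheta = 1 on [-pi/2, pi/2].  The b -> 0 limit
    is the constant density 1.
    """
    if b < 0:
        raise ValueError(f"concentration parameter b must be >= 0, got {b}")
    theta = np.asarray(theta, dtype=float)
    if np.any((theta < -np.pi / 2 - 1e-12) | (theta > np.pi / 2 + 1e-12)):
        raise ValueError("theta must lie in [-pi/2, pi/2]")
    if b < 1e-12:
        out = np.ones_like(theta)
    else:
        norm = 2.0 * math.sqrt(2.0 * b / math.pi) / special.erf(math.sqrt(2.0 * b))
        out = norm * np.exp(b * (np.cos(2.0 * theta) - 1.0))
    return out if out.ndim else float(out)


def kappa_ip(a):
    """In-plane dispersion kappa_ip = 1/2 - I1(a)/(2 I0(a)).

    Strictly decreasing from 1/2 (isotropic, a=0) to 0 (perfect alignment,
    a -> inf).  Accepts scalars or arrays.
    """
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ValueError("concentration parameter a must be >= 0")
    # scaled Bessel ratio i1e/i0e == I1/I0, stable for large a
    out = 0.5 - special.i1e(a) / (2.0 * special.i0e(a))
    return out if out.ndim else float(out)


def kappa_op(b):
    """Out-of-plane dispersion
    kappa_op = 1/2 - 1/(8b) + (1/4) sqrt(2/(pi b)) exp(-2b)/erf(sqrt(2b)).

    Strictly increasing from 1/3 (b -> 0, analytic limit) to 1/2 (perfect
    in-plane alignment, b -> inf).  Accepts scalars or arrays.
    """
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("concentration parameter b must be >= 0")
    small = b < 1e-8
    bs = np.where(small, 1.0, b)  # placeholder, overwritten below
    with np.errstate(divide="ignore", invalid="ignore"):
        val = (
            0.5
            - 1.0 / (8.0 * bs)
            + 0.25 * np.sqrt(2.0 / (np.pi * bs)) * np.exp(-2.0 * bs)
            / special.erf(np.sqrt(2.0 * bs))
        )
    # series about b=0: kappa_op = 1/3 + 4b/45 + O(b^2)
    out = np.where(small, 1.0 / 3.0 + 4.0 * b / 45.0, val)
    return out if out.ndim else float(out)


# --------------------------------------------------------------------------
# fitting wedge profiles
# --------------------------------------------------------------------------

def _profile_r2(observed: np.ndarray, predicted: np.ndarray) -> float:
    ss_res = float(np.sum((observed - predicted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_inplane(
    dist: AngularDistribution,
    symmetric: bool = False,
    isotropy_r2: float | None = None,
) -> tuple[InPlaneVonMises, dict]:
    """Fit (a, alpha) of the in-plane von Mises density to a wedge profile.

    The normalized amplitude profile is compared against the model density
    evaluated at the wedge centers and renormalized over the same grid, so
    the fit is insensitive to the wedge width.  With ``symmetric=True`` the
    +/-alpha two-family mixture is fitted instead of a single component.

    If ``isotropy_r2`` is given, the profile is first screened with
    :func:`classify_isotropy`; isotropic profiles return a = 0 and no peak.

    Returns the fitted model and a dict with keys ``alpha_deg`` (peak folded
    into [0, 90], None if isotropic), ``r2`` (profile goodness of fit) and
    ``isotropic``.
    """
    if dist.is_degenerate:
        raise ValueError("all-zero amplitude profile: nothing to fit")
    if isotropy_r2 is not None and classify_isotropy(dist, isotropy_r2):
        return InPlaneVonMises(0.0, 0.0), {
            "alpha_deg": None, "r2": 1.0, "isotropic": True,
        }

    phi = np.deg2rad(dist.wedge_centers)
    obs = dist.amplitudes
    density = rho_ip_mixture if symmetric else rho_ip

    def residuals(x):
        a, alpha = x
        prof = density(phi, max(a, 0.0), alpha)
        return prof / prof.sum() - obs

    # multi-start over peak location; coarse init from the observed argmax
    peak0 = phi[int(np.argmax(obs))]
    best = None
    for alpha0 in {peak0, np.pi / 6, np.pi / 3, np.pi / 2}:
        for a0 in (0.5, 3.0, 10.0):
            sol = optimize.least_squares(
                residuals, x0=[a0, alpha0],
                bounds=([0.0, -np.pi], [np.inf, 2.0 * np.pi]),
                xtol=1e-14, ftol=1e-14,
            )
            if best is None or sol.cost < best.cost:
                best = sol
    a_hat = float(best.x[0])
    alpha_hat = float(best.x[1]) % np.pi
    alpha_deg = math.degrees(alpha_hat)
    if alpha_deg > 90.0:  # fold mirrored peak into [0, 90]
        alpha_deg = 180.0 - alpha_deg
    pred = density(phi, a_hat, best.x[1])
    pred = pred / pred.sum()
    info = {
        "alpha_deg": None if a_hat < 1e-3 else alpha_deg,
        "r2": _profile_r2(obs, pred),
        "isotropic": a_hat < 1e-3,
    }
    return InPlaneVonMises(a_hat, alpha_hat), info


def fit_outofplane(
    dist: AngularDistribution,
    isotropy_r2: float | None = None,
) -> tuple[OutOfPlaneVonMises, dict]:
    """Fit the out-of-plane concentration ``b`` to a wedge profile.

    Wedge centers (degrees on [0, 180), with 0 = the circumferential and
    90 = the radial image axis) are wrapped to elevations
    Theta = ((center + 90) mod 180) - 90 in [-90, 90), so the density peak
    is constrained to Theta = 0, i.e. to the circumferential axis.
    """
    if dist.is_degenerate:
        raise ValueError("all-zero amplitude profile: nothing to fit")
    if isotropy_r2 is not None and classify_isotropy(dist, isotropy_r2):
        return OutOfPlaneVonMises(0.0), {"r2": 1.0, "isotropic": True}

    theta = np.deg2rad((dist.wedge_centers + 90.0) % 180.0 - 90.0)
    obs = dist.amplitudes

    def residuals(x):
        prof = rho_op(theta, max(float(x[0]), 0.0))
        return prof / prof.sum() - obs

    best = None
    for b0 in (0.5, 3.0, 10.0):
        sol = optimize.least_squares(
            residuals, x0=[b0], bounds=([0.0], [np.inf]), xtol=1e-14, ftol=1e-14
        )
        if best is None or sol.cost < best.cost:
            best = sol
    b_hat = float(best.x[0])
    prof = rho_op(theta, b_hat)
    prof = prof / prof.sum()
    return OutOfPlaneVonMises(b_hat), {
        "r2": _profile_r2(obs, prof),
        "isotropic": b_hat < 1e-3,
    }


def classify_isotropy(dist: AngularDistribution, r2_threshold: float = 0.9998) -> bool:
    """Classify a wedge profile as isotropic via cumulative-distribution linearity.

    A uniform angular density has an exactly linear cumulative amplitude
    curve; a first-order polynomial is fitted to the cumulative profile and
    the image is called isotropic when its coefficient of determination is at
    least ``r2_threshold``.  Peaked profiles bend the cumulative curve into a
    sigmoid and fail the test.
    """
    cum = np.cumsum(dist.amplitudes)
    x = np.arange(cum.size, dtype=float)
    coef = np.polyfit(x, cum, 1)
    return _profile_r2(cum, np.polyval(coef, x)) >= r2_threshold


# --------------------------------------------------------------------------
# stack aggregation
# --------------------------------------------------------------------------

def aggregate_stack(
    per_image: Sequence[ImageOrientation | tuple],
    include_isotropic_in_means: bool = True,
) -> DispersionSet:
    """Combine per-image orientation fits into specimen-level parameters.

    The specimen mean fiber angle is the mean of the anisotropic in-plane
    peak locations and its spread their standard deviation; the dispersion
    parameters are evaluated at the mean concentration parameters,
    kappa_ip(mean a) and kappa_op(mean b).  Isotropic images carry a = 0
    (or b = 0) into the means by default, matching the convention that an
    isotropic image is assigned zero concentration; set
    ``include_isotropic_in_means=False`` to average anisotropic images only.
    """
    items = [
        it if isinstance(it, ImageOrientation) else ImageOrientation(*it)
        for it in per_image
    ]
    if not items:
        raise ValueError("empty image stack")

    peaks = [it.peak_deg for it in items if it.peak_deg is not None and not it.isotropic]
    # isotropic images carry zero concentration; callers set a=0 / b=0 for them
    a_vals = [
        it.a for it in items
        if it.a is not None and (include_isotropic_in_means or not it.isotropic)
    ]
    b_vals = [
        it.b for it in items
        if it.b is not None and (include_isotropic_in_means or not it.isotropic)
    ]

    a_mean = float(np.mean(a_vals)) if a_vals else None
    b_mean = float(np.mean(b_vals)) if b_vals else None
    alpha = float(np.mean(peaks)) if peaks else None
    alpha_sd = float(np.std(peaks, ddof=1)) if len(peaks) > 1 else (0.0 if peaks else None)
    return DispersionSet(
        alpha_deg=alpha,
        alpha_sd_deg=alpha_sd,
        kappa_ip=kappa_ip(a_mean) if a_mean is not None else None,
        kappa_op=kappa_op(b_mean) if b_mean is not None else None,
        a_mean=a_mean,
        b_mean=b_mean,
        n_images=len(items),
        n_isotropic=sum(1 for it in items if it.isotropic),
    )
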