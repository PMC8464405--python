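"""Synthetic inputs for the pipeline: biaxial datasets, fiber images, cohorts.

The raw mechanical and imaging data of the study this pipeline targets are
not deposited anywhere, so every test and demonstration input is generated
here from known ground truth:

* multi-ratio stretch-controlled planar biaxial protocols (19 ratio paths
  from circumferential:longitudinal 1:0.1 ... 1:0.9 and 0.9:1 ... 0.1:1 in
  0.1 steps, plus three equibiaxial repeats, 21 in total) evaluated through
  the forward constitutive models with multiplicative + additive Gaussian
  measurement noise;
* grayscale fibrous-texture images whose fiber chord orientations are drawn
  from the +/-alpha in-plane von Mises mixture (or the out-of-plane density),
  with optional sinusoidal undulation, for exercising the orientation
  pipeline;
* synthetic cohorts with an imposed linear age trend in the out-of-plane
  dispersion.

Every generator is a pure function of its seed and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constitutive import (
    DeformationState,
    FourFiberParams,
    StructuralConstants,
    TwoFiberParams,
    cauchy_four_fiber,
    cauchy_two_fiber,
)
from .dispersion import rho_ip_mixture, rho_op
from .fitting import BiaxialDataset
from .imaging import TextureImage

__all__ = [
    "ProtocolSpec",
    "NoiseModel",
    "make_protocols",
    "simulate_biaxial",
    "render_fiber_image",
    "synth_cohort",
]


@dataclass(frozen=True)
class ProtocolSpec:
    """One stretch-controlled loading path.

    The axis with ratio 1 ramps linearly from 1 to its maximum stretch; the
    other axis ramps to 1 + ratio * (lambda_max - 1).
    """

    name: str
    ratio_theta: float
    ratio_z: float
    lambda_max_theta: float
    lambda_max_z: float
    n_steps: int = 50

    def path(self) -> tuple[np.ndarray, np.ndarray]:
        t = np.linspace(0.0, 1.0, self.n_steps + 1)[1:]  # exclude unloaded state
        lt = 1.0 + t * self.ratio_theta * (self.lambda_max_theta - 1.0)
        lz = 1.0 + t * self.ratio_z * (self.lambda_max_z - 1.0)
        return lt, lz


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian measurement noise: sigma * (1 + eps_rel) + eps_abs.

    Defaults emulate load-cell / marker-tracking error: 2% multiplicative
    plus 0.5 kPa additive."""

    relative_sd: float = 0.02
    absolute_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_sd < 0 or self.absolute_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


def make_protocols(
    lambda_max_theta: float = 1.3,
    lambda_max_z: float = 1.3,
    n_steps: int = 50,
) -> list[ProtocolSpec]:
    """The 21 multi-ratio stretch protocols of a full biaxial test.

    Nineteen ratio protocols (1:0.1 ... 1:0.9, 1:1, 0.9:1 ... 0.1:1) plus
    two extra equibiaxial repeats, mirroring the equibiaxial checks run at
    the beginning, middle and end of a test sequence.
    """
    if lambda_max_theta <= 1.0 or lambda_max_z <= 1.0:
        raise ValueError("maximum stretches must exceed 1")
    ratios = [(1.0, round(0.1 * k, 1)) for k in range(1, 10)]
    ratios += [(1.0, 1.0)]
    ratios += [(round(0.1 * k, 1), 1.0) for k in range(9, 0, -1)]
    protocols = [
        ProtocolSpec(f"{rt:g}:{rz:g}", rt, rz, lambda_max_theta, lambda_max_z, n_steps)
        for rt, rz in ratios
    ]
    for tag in ("1:1-mid", "1:1-end"):
        protocols.append(
            ProtocolSpec(tag, 1.0, 1.0, lambda_max_theta, lambda_max_z, n_steps)
        )
    return protocols


def simulate_biaxial(
    params: TwoFiberParams | FourFiberParams,
    sc: StructuralConstants,
    protocols: list[ProtocolSpec] | None = None,
    noise: NoiseModel | None = None,
    specimen_id: str = "synthetic",
) -> BiaxialDataset:
    """Forward-simulate a multi-protocol biaxial test from known parameters."""
    if protocols is None:
        protocols = make_protocols()
    stress_fn = cauchy_two_fiber if isinstance(params, TwoFiberParams) else cauchy_four_fiber
    names, lts, lzs = [], [], []
    for p in protocols:
        lt, lz = p.path()
        names.extend([p.name] * lt.size)
        lts.append(lt)
        lzs.append(lz)
    lt = np.concatenate(lts)
    lz = np.concatenate(lzs)
    pair = stress_fn(DeformationState(lt, lz), params, sc)
    st = np.asarray(pair.sigma_theta, dtype=float).copy()
    sz = np.asarray(pair.sigma_z, dtype=float).copy()
    if noise is not None and (noise.relative_sd > 0 or noise.absolute_sd > 0):
        rng = np.random.default_rng(noise.seed)
        for s in (st, sz):
            s *= 1.0 + rng.normal(0.0, noise.relative_sd, size=s.size)
            s += rng.normal(0.0, noise.absolute_sd, size=s.size)
    return BiaxialDataset(
        np.array(names, dtype=object), lt, lz, st, sz, sc, specimen_id
    )


# --------------------------------------------------------------------------
# fiber texture rendering
# --------------------------------------------------------------------------

def _sample_angles(density, lo, hi, n, rng) -> np.ndarray:
    """Rejection-sample n angles from an arbitrary bounded density."""
    grid = np.linspace(lo, hi, 2048)
    fmax = float(np.max(density(grid))) * 1.05
    out = np.empty(n)
    filled = 0
    while filled < n:
        cand = rng.uniform(lo, hi, size=2 * (n - filled))
        keep = cand[rng.uniform(0.0, fmax, size=cand.size) < density(cand)]
        take = min(keep.size, n - filled)
        out[filled:filled + take] = keep[:take]
        filled += take
    return out


def render_fiber_image(
    a: float,
    alpha_deg: float,
    n_fibers: int = 200,
    undulation_amplitude: float = 0.0,
    size_px: int = 256,
    seed: int = 0,
    plane: str = "in_plane",
    b: float | None = None,
    background_noise: float = 0.05,
) -> TextureImage:
    """Draw bright anti-aliased fiber curves on a dark noisy background.

    Chord orientations are sampled from the symmetric +/-alpha in-plane von
    Mises mixture with concentration ``a`` (or, when ``b`` is given, from
    the out-of-plane density centred on the circumferential axis, for
    out-of-plane test images).  ``undulation_amplitude`` (pixels) adds
    sinusoidal waviness transverse to each fiber chord.
    """
    from skimage.draw import line_aa  # local import keeps module load light

    if a < 0:
        raise ValueError("concentration parameter a must be >= 0")
    rng = np.random.default_rng(seed)
    alpha = np.deg2rad(alpha_deg)
    if b is not None:
        angles = _sample_angles(lambda t: rho_op(t, b), -np.pi / 2, np.pi / 2,
                                n_fibers, rng)
    elif a == 0:
        angles = rng.uniform(0.0, np.pi, size=n_fibers)
    else:
        angles = _sample_angles(
            lambda t: rho_ip_mixture(t, a, alpha), 0.0, np.pi, n_fibers, rng
        )

    img = np.zeros((size_px, size_px), dtype=float)
    half = 0.75 * size_px  # chords span the frame so orientation dominates
    for ang in angles:
        cx, cy = rng.uniform(0.0, size_px, size=2)
        # image row = longitudinal axis increasing upward: row ~ -sin(ang)
        dx, dy = np.cos(ang), -np.sin(ang)
        t = np.linspace(-half, half, int(3 * half))
        x = cx + t * dx
        y = cy + t * dy
        if undulation_amplitude > 0:
            period = rng.uniform(30.0, 80.0)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            off = undulation_amplitude * np.sin(2.0 * np.pi * t / period + phase)
            x = x - off * dy
            y = y + off * dx
        inside = (x >= 0) & (x < size_px - 1) & (y >= 0) & (y < size_px - 1)
        if inside.sum() < 2:
            continue
        xs, ys = x[inside], y[inside]
        step = xs.size - 1 if undulation_amplitude == 0 else 8
        for i in range(0, xs.size - 1, step):
            j = min(i + step, xs.size - 1)
            rr, cc, val = line_aa(int(ys[i]), int(xs[i]), int(ys[j]), int(xs[j]))
            ok = (rr >= 0) & (rr < size_px) & (cc >= 0) & (cc < size_px)
            img[rr[ok], cc[ok]] = np.maximum(img[rr[ok], cc[ok]], val[ok])

    if background_noise > 0:
        img = img + np.abs(rng.normal(0.0, background_noise, size=img.shape))
    img = np.clip(img, 0.0, img.max() if img.max() > 0 else 1.0)
    return TextureImage(img, pixel_size=1.0, plane=plane)


# --------------------------------------------------------------------------
# synthetic cohorts
# --------------------------------------------------------------------------

def synth_cohort(
    n: int,
    slope: float = 0.0011,
    intercept: float = 0.37,
    noise_sd: float = 0.02,
    seed: int = 0,
    alpha_slope: float = -0.2,
    alpha_intercept: float = 55.0,
    alpha_noise_sd: float = 8.0,
    kappa_ip_mean: float = 0.16,
    kappa_ip_sd: float = 0.02,
) -> pd.DataFrame:
    """Generate a specimen table with an imposed linear age trend in the
    out-of-plane dispersion (kappa_op = slope * age + intercept + noise).

    Ages are uniform on [12, 70] years; the mean fiber angle carries its own
    configurable linear trend and kappa_ip is trend-free by default,
    mirroring the qualitative structure of an ageing arterial cohort.
    """
    if n < 3:
        raise ValueError("a cohort needs at least 3 specimens")
    rng = np.random.default_rng(seed)
    age = rng.uniform(12.0, 70.0, size=n)
    kop = slope * age + intercept + rng.normal(0.0, noise_sd, size=n)
    kip = np.clip(rng.normal(kappa_ip_mean, kappa_ip_sd, size=n), 0.0, 1.0)
    alpha = np.clip(
        alpha_intercept + alpha_slope * age + rng.normal(0.0, alpha_noise_sd, size=n),
        0.0, 90.0,
    )
    return pd.DataFrame({
        "id": np.arange(1, n + 1),
        "age": age,
        "sex": rng.choice(["M", "F"], size=n),
        "alpha_deg": alpha,
        "kappa_ip": kip,
        "kappa_op": np.clip(kop, 0.0, 0.5),
    })
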