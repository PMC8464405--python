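"""Constitutive parameter estimation from multi-protocol planar biaxial data.

The error function is the summed squared stress residual over all
stress-stretch points and both loading directions,

    e = sum_i (s_tt^exp,i - s_tt^th,i)^2 + (s_zz^exp,i - s_zz^th,i)^2  [kPa^2],

minimized by damped least squares (trust-region reflective, the bounded
member of the Levenberg-Marquardt family) with multi-start initialization;
the structural constants (alpha, kappa_ip, kappa_op) come from imaging and
are held fixed, never fitted.  Identifiability is probed with a
non-parametric bootstrap: records are resampled with replacement and refitted,
and each parameter is reported either as the highest-density mode of its
bootstrap marginal or as the best-SSE draw.  Goodness of fit is the standard
coefficient of determination per loading direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import gaussian_kde

from .constitutive import (
    DeformationState,
    FourFiberParams,
    StressPair,
    StructuralConstants,
    TwoFiberParams,
    cauchy_four_fiber,
    cauchy_two_fiber,
)

__all__ = [
    "BiaxialDataset",
    "FitResult",
    "objective",
    "predict_stresses",
    "fit",
    "bootstrap",
    "r_squared",
]

ModelName = Literal["two_fiber", "four_fiber"]

_PARAM_NAMES = {
    "two_fiber": ("c2", "k1", "k2"),
    "four_fiber": ("c4", "k1_col", "k2_col", "k1_el", "k2_el", "k1_smc", "k2_smc"),
}
# stiffness-like parameters (kPa) vs dimensionless exponential exponents:
# multi-start draws are log-uniform on [1e-2, 1e3] and [1e-2, 1e2] respectively
_IS_EXPONENT = {
    "two_fiber": (False, False, True),
    "four_fiber": (False, False, True, False, True, False, True),
}


@dataclass(frozen=True)
class BiaxialDataset:
    """Multi-protocol planar biaxial stress-stretch records for one specimen.

    Arrays are aligned per record; stresses are Cauchy stresses in kPa.
    ``structural`` carries the imaging-derived constants used by the models.
    """

    protocol: np.ndarray
    lambda_theta: np.ndarray
    lambda_z: np.ndarray
    sigma_theta: np.ndarray
    sigma_z: np.ndarray
    structural: StructuralConstants
    specimen_id: str = ""

    def __post_init__(self) -> None:
        arrays = {}
        n = None
        for name in ("protocol", "lambda_theta", "lambda_z", "sigma_theta", "sigma_z"):
            arr = np.asarray(getattr(self, name))
            if name != "protocol":
                arr = arr.astype(float)
            if n is None:
                n = arr.size
            elif arr.size != n:
                raise ValueError("all record columns must have equal length")
            arrays[name] = arr
        if np.any(arrays["lambda_theta"] <= 0) or np.any(arrays["lambda_z"] <= 0):
            raise ValueError("stretches must be positive")
        for name in ("sigma_theta", "sigma_z"):
            if not np.all(np.isfinite(arrays[name])):
                raise ValueError(f"{name} contains non-finite values")
        for name, arr in arrays.items():
            object.__setattr__(self, name, arr)

    @property
    def n_points(self) -> int:
        return int(self.lambda_theta.size)

    @property
    def state(self) -> DeformationState:
        return DeformationState(self.lambda_theta, self.lambda_z)

    def subset(self, idx: np.ndarray) -> "BiaxialDataset":
        return BiaxialDataset(
            self.protocol[idx], self.lambda_theta[idx], self.lambda_z[idx],
            self.sigma_theta[idx], self.sigma_z[idx],
            self.structural, self.specimen_id,
        )


@dataclass
class FitResult:
    """Best-fit constitutive parameters with goodness of fit and, when a
    bootstrap was run, per-parameter sample distributions."""

    params: TwoFiberParams | FourFiberParams
    model: str
    r2_theta: float
    r2_z: float
    sse: float
    n_points: int
    converged: bool = True
    bootstrap_samples: dict[str, np.ndarray] | None = None

    def to_dict(self) -> dict:
        out = {
            "model": self.model,
            "params": self.params.to_dict(),
            "r2_theta": self.r2_theta,
            "r2_z": self.r2_z,
            "sse": self.sse,
            "n_points": self.n_points,
            "converged": self.converged,
        }
        if self.bootstrap_samples is not None:
            out["bootstrap"] = {k: v.tolist() for k, v in self.bootstrap_samples.items()}
        return out


# --------------------------------------------------------------------------
# forward prediction and objective
# --------------------------------------------------------------------------

def _params_from_vector(x: np.ndarray, model: ModelName):
    x = np.maximum(np.asarray(x, dtype=float), 0.0)
    if model == "two_fiber":
        return TwoFiberParams(*x)
    if model == "four_fiber":
        return FourFiberParams(*x)
    raise ValueError(f"unknown model {model!r}")


def _vector_from_params(params) -> np.ndarray:
    if isinstance(params, TwoFiberParams):
        return np.array([params.c2, params.k1, params.k2])
    return np.array([params.c4, params.k1_col, params.k2_col,
                     params.k1_el, params.k2_el, params.k1_smc, params.k2_smc])


def _model_of(params) -> ModelName:
    return "two_fiber" if isinstance(params, TwoFiberParams) else "four_fiber"


def predict_stresses(params, dataset: BiaxialDataset) -> StressPair:
    """Model Cauchy stresses at every record of the dataset."""
    stress_fn = cauchy_two_fiber if isinstance(params, TwoFiberParams) else cauchy_four_fiber
    return stress_fn(dataset.state, params, dataset.structural)


def _residuals(x: np.ndarray, dataset: BiaxialDataset, model: ModelName) -> np.ndarray:
    pred = predict_stresses(_params_from_vector(x, model), dataset)
    return np.concatenate(
        [pred.sigma_theta - dataset.sigma_theta, pred.sigma_z - dataset.sigma_z]
    )


def objective(params, dataset: BiaxialDataset) -> float:
    """Summed squared stress residual e (kPa^2) over both directions."""
    pred = predict_stresses(params, dataset)
    return float(
        np.sum((dataset.sigma_theta - pred.sigma_theta) ** 2)
        + np.sum((dataset.sigma_z - pred.sigma_z) ** 2)
    )


def r_squared(dataset: BiaxialDataset, params) -> tuple[float, float]:
    """Coefficients of determination (R^2_theta, R^2_z), one per direction.

    R^2 = 1 - SS_res/SS_tot with squared residuals and squared deviations
    from the directional mean experimental stress.  Raises for a constant
    experimental stress column (undefined total sum of squares).
    """
    pred = predict_stresses(params, dataset)
    out = []
    for exp, th in (
        (dataset.sigma_theta, pred.sigma_theta),
        (dataset.sigma_z, pred.sigma_z),
    ):
        ss_tot = float(np.sum((exp - exp.mean()) ** 2))
        if ss_tot == 0.0:
            raise ValueError("constant experimental stresses: R^2 undefined")
        out.append(1.0 - float(np.sum((exp - th) ** 2)) / ss_tot)
    return out[0], out[1]


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

def _draw_starts(model: ModelName, n_starts: int, rng: np.random.Generator):
    is_exp = np.array(_IS_EXPONENT[model])
    lo = np.where(is_exp, -2.0, -2.0)
    hi = np.where(is_exp, 2.0, 3.0)
    starts = [np.full(is_exp.size, 1.0)]  # one deterministic moderate start
    for _ in range(max(n_starts - 1, 0)):
        starts.append(10.0 ** rng.uniform(lo, hi))
    return starts


def _solve(x0, dataset, model, max_nfev=2000):
    return optimize.least_squares(
        _residuals, x0=np.asarray(x0, dtype=float),
        bounds=(0.0, np.inf), method="trf",
        args=(dataset, model),
        ftol=1e-10, xtol=1e-12, gtol=1e-12, max_nfev=max_nfev,
    )


def fit(
    dataset: BiaxialDataset,
    model: ModelName = "two_fiber",
    n_starts: int = 20,
    seed: int | None = 0,
    x0: Sequence[float] | None = None,
) -> FitResult:
    """Fit constitutive parameters by bounded damped least squares.

    Multi-start initialization guards against the local minima of the
    exponential stress terms: stiffness-like parameters are drawn
    log-uniformly on [1e-2, 1e3] kPa and exponents on [1e-2, 1e2], plus one
    deterministic unit start and, optionally, a caller-supplied ``x0``.
    Structural constants are fixed throughout.
    """
    rng = np.random.default_rng(seed)
    starts = _draw_starts(model, n_starts, rng)
    if x0 is not None:
        starts.insert(0, np.asarray(x0, dtype=float))
    best = None
    for s in starts:
        try:
            sol = _solve(s, dataset, model)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all fitting starts failed")
    params = _params_from_vector(best.x, model)
    r2t, r2z = r_squared(dataset, params)
    return FitResult(
        params=params, model=model, r2_theta=r2t, r2_z=r2z,
        sse=objective(params, dataset), n_points=dataset.n_points,
        converged=bool(best.status > 0),
    )


# --------------------------------------------------------------------------
# bootstrap identifiability
# --------------------------------------------------------------------------

def _marginal_mode(samples: np.ndarray) -> float:
    """Highest-density point of a bootstrap marginal via Gaussian KDE."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        return float("nan")
    if np.ptp(samples) < 1e-12 * (1.0 + abs(float(samples[0]))):
        return float(samples[0])
    try:
        kde = gaussian_kde(samples)
    except np.linalg.LinAlgError:
        return float(np.median(samples))
    grid = np.linspace(samples.min(), samples.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def bootstrap(
    dataset: BiaxialDataset,
    model: ModelName = "two_fiber",
    n_iter: int = 2000,
    seed: int | None = 0,
    estimate: Literal["mode", "best_sse"] = "mode",
    block_by_protocol: bool = False,
    n_starts_point: int = 20,
) -> FitResult:
    """Non-parametric bootstrap of the constitutive fit.

    Records (or whole protocols with ``block_by_protocol``) are resampled
    with replacement ``n_iter`` times and refitted, each refit starting from
    a randomly perturbed copy of the point estimate.  The selected estimate
    is, per parameter, the highest-density mode of its bootstrap marginal
    (``estimate="mode"``), approximating the globally identified minimum, or
    the single resample fit with the lowest point-data SSE
    (``estimate="best_sse"``).
    """
    if n_iter < 2:
        raise ValueError("bootstrap needs n_iter >= 2")
    rng = np.random.default_rng(seed)
    point = fit(dataset, model, n_starts=n_starts_point,
                seed=int(rng.integers(2**31 - 1)))
    x_point = _vector_from_params(point.params)
    names = _PARAM_NAMES[model]

    samples = np.empty((n_iter, x_point.size))
    protocols = np.unique(dataset.protocol)
    for it in range(n_iter):
        if block_by_protocol:
            chosen = rng.choice(protocols, size=protocols.size, replace=True)
            idx = np.concatenate([np.flatnonzero(dataset.protocol == p) for p in chosen])
        else:
            idx = rng.integers(0, dataset.n_points, size=dataset.n_points)
        resample = dataset.subset(idx)
        x0 = x_point * rng.uniform(0.5, 2.0, size=x_point.size)
        sol = _solve(x0, resample, model, max_nfev=500)
        samples[it] = np.maximum(sol.x, 0.0)

    if estimate == "mode":
        x_est = np.array([_marginal_mode(samples[:, j]) for j in range(x_point.size)])
    elif estimate == "best_sse":
        sses = [objective(_params_from_vector(samples[i], model), dataset)
                for i in range(n_iter)]
        x_est = samples[int(np.argmin(sses))]
    else:
        raise ValueError(f"unknown estimate {estimate!r}")

    params = _params_from_vector(x_est, model)
    r2t, r2z = r_squared(dataset, params)
    return FitResult(
        params=params, model=model, r2_theta=r2t, r2_z=r2z,
        sse=objective(params, dataset), n_points=dataset.n_points,
        converged=point.converged,
        bootstrap_samples={nm: samples[:, j] for j, nm in enumerate(names)},
    )
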