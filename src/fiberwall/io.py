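"""Readers, writers, run configuration, and the pipeline driver.

Interchange formats are deliberately plain: biaxial records travel as CSV
with the header ``protocol,lambda_theta,lambda_z,sigma_theta_kpa,sigma_z_kpa``
(stresses in kPa), images as single- or multi-page grayscale TIFF, and all
results as JSON.  Angles are in degrees and stresses in kPa at every
external boundary.  A run is reproducible from its inputs plus a
:class:`RunConfig`; all randomness flows from the configured seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constitutive import StructuralConstants
from .fitting import BiaxialDataset

logger = logging.getLogger("fiberwall")

__all__ = [
    "RunConfig",
    "read_biaxial_csv",
    "write_biaxial_csv",
    "read_image_stack",
    "run_pipeline",
]

BIAXIAL_COLUMNS = ("protocol", "lambda_theta", "lambda_z",
                   "sigma_theta_kpa", "sigma_z_kpa")


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    # inputs (paths; any subset of stages may be configured)
    image_stack: str | None = None
    image_plane: str = "in_plane"
    out_of_plane_stack: str | None = None
    biaxial_csv: str | None = None
    cohort_csv: str | None = None
    # structural constants when no imaging stage runs
    alpha_deg: float | None = None
    kappa_ip: float | None = None
    kappa_op: float | None = None
    # stage knobs
    wedge_width_deg: float = 5.0
    isotropy_r2: float = 0.9998
    model: str = "four_fiber"
    n_starts: int = 20
    bootstrap_iterations: int = 0
    seed: int = 0
    out_dir: str = "fiberwall_results"

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def read_biaxial_csv(
    path: str | Path,
    structural: StructuralConstants,
    specimen_id: str = "",
) -> BiaxialDataset:
    """Load and validate a biaxial CSV into a dataset.

    Malformed rows (nonpositive stretches, non-finite stresses) are rejected
    with their 1-based data line numbers; missing columns raise a schema
    error.
    """
    df = pd.read_csv(path)
    missing = [c for c in BIAXIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    lam_t = df["lambda_theta"].to_numpy(dtype=float)
    lam_z = df["lambda_z"].to_numpy(dtype=float)
    sig_t = df["sigma_theta_kpa"].to_numpy(dtype=float)
    sig_z = df["sigma_z_kpa"].to_numpy(dtype=float)
    bad = ~(
        (lam_t > 0) & (lam_z > 0)
        & np.isfinite(lam_t) & np.isfinite(lam_z)
        & np.isfinite(sig_t) & np.isfinite(sig_z)
    )
    if bad.any():
        lines = (np.flatnonzero(bad) + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"{path}: invalid records at lines {lines}")
    return BiaxialDataset(
        df["protocol"].to_numpy(dtype=object), lam_t, lam_z, sig_t, sig_z,
        structural, specimen_id or str(path),
    )


def write_biaxial_csv(dataset: BiaxialDataset, path: str | Path) -> None:
    pd.DataFrame({
        "protocol": dataset.protocol,
        "lambda_theta": dataset.lambda_theta,
        "lambda_z": dataset.lambda_z,
        "sigma_theta_kpa": dataset.sigma_theta,
        "sigma_z_kpa": dataset.sigma_z,
    }).to_csv(path, index=False, float_format="%.12g")


def read_image_stack(path: str | Path, plane: str = "in_plane", pixel_size: float = 1.0):
    """Read a single- or multi-page grayscale TIFF into texture images."""
    import tifffile

    from .imaging import TextureImage

    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(
            f"{path}: expected grayscale pages, got shape {arr.shape}; "
            "select a single channel before loading RGB data"
        )
    return [TextureImage(page.astype(float), pixel_size, plane) for page in arr]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages: orient -> dispersion -> fit -> cohort.

    Returns the result bundle (also written to ``out_dir/results.json``).
    Partial results are preserved if a later stage fails.
    """
    from . import cohort as cohort_mod
    from .imaging import ImagingConfig, stack_pipeline

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    from . import __version__
    results: dict = {"config_hash": config.config_hash(), "version": __version__}
    results_path = out_dir / "results.json"

    def checkpoint():
        results_path.write_text(json.dumps(results, indent=2, default=float))

    try:
        structural = None
        if config.image_stack:
            stack = read_image_stack(config.image_stack, config.image_plane)
            if config.out_of_plane_stack:
                stack += read_image_stack(config.out_of_plane_stack, "out_of_plane")
            cfg = ImagingConfig(wedge_width_deg=config.wedge_width_deg,
                                isotropy_r2=config.isotropy_r2)
            dispersion = stack_pipeline(stack, cfg)
            results["dispersion"] = dispersion.to_dict()
            logger.info("orientation stage: %s", results["dispersion"])
            if dispersion.alpha_deg is not None:
                structural = StructuralConstants.from_degrees(
                    dispersion.alpha_deg,
                    dispersion.kappa_ip if dispersion.kappa_ip is not None else 0.5,
                    dispersion.kappa_op if dispersion.kappa_op is not None else 1 / 3,
                )
            checkpoint()
        if structural is None and config.alpha_deg is not None:
            structural = StructuralConstants.from_degrees(
                config.alpha_deg, config.kappa_ip, config.kappa_op
            )

        if config.biaxial_csv:
            if structural is None:
                raise ValueError(
                    "fitting requires structural constants: configure an image "
                    "stack or alpha_deg/kappa_ip/kappa_op"
                )
            from .fitting import bootstrap as run_bootstrap, fit as run_fit

            dataset = read_biaxial_csv(config.biaxial_csv, structural)
            if config.bootstrap_iterations > 0:
                fit_res = run_bootstrap(dataset, config.model,
                                        n_iter=config.bootstrap_iterations,
                                        seed=config.seed)
            else:
                fit_res = run_fit(dataset, config.model,
                                  n_starts=config.n_starts, seed=config.seed)
            results["fit"] = fit_res.to_dict()
            checkpoint()

        if config.cohort_csv:
            table = pd.read_csv(config.cohort_csv)
            results["cohort"] = {
                "summary": cohort_mod.cohort_summary(table),
                "age_trends": {
                    col: cohort_mod.pearson_with_age(table, col).to_dict()
                    for col in ("alpha_deg", "kappa_ip", "kappa_op")
                    if col in table.columns
                },
            }
            checkpoint()
    except Exception:
        checkpoint()
        raise
    checkpoint()
    return results
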