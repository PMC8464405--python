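"""Cohort-level statistics: age trends of arterial structural parameters.

Packaged with the module are transcriptions of the study cohort tables for a
set of 14 human superficial femoral arteries (ages 12-70 years): subject
demographics/risk factors and, per specimen, the measured collagen fiber
angle and dispersions plus the fitted two- and four-fiber constitutive
parameters with their coefficients of determination.

Age associations are quantified with the Pearson correlation coefficient;
significance is the two-sided test of zero correlation via the exact
t transform t = r sqrt(n-2)/sqrt(1-r^2) with n-2 degrees of freedom, and
linear age trends are ordinary least squares.  Summaries use the sample
(n-1) standard deviation.  Missing values (e.g. one unrecorded BMI) are
excluded pairwise, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "load_table1",
    "load_table2",
    "pearson_with_age",
    "age_trend_kop",
    "cohort_summary",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of a specimen field with age, plus the OLS line
    (slope in field-units per year)."""

    r: float
    p: float
    n: int
    slope: float
    intercept: float

    def to_dict(self) -> dict:
        return {"r": self.r, "p": self.p, "n": self.n,
                "slope": self.slope, "intercept": self.intercept}


def _packaged_csv(name: str) -> pd.DataFrame:
    with resources.files("fiberwall.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_table1() -> pd.DataFrame:
    """Subject demographics and risk factors (14 specimens)."""
    return _packaged_csv("table1.csv")


def load_table2() -> pd.DataFrame:
    """Per-specimen structural parameters and constitutive fits."""
    return _packaged_csv("table2.csv")


def pearson_with_age(records: pd.DataFrame, column: str) -> CorrelationResult:
    """Correlate a specimen column with age across the cohort.

    Requires at least three complete (age, value) pairs; rows with a missing
    value in either column are dropped pairwise.  A constant column has no
    defined correlation and raises.
    """
    sub = records[["age", column]].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 complete (age, value) pairs")
    age = sub["age"].to_numpy(dtype=float)
    y = sub[column].to_numpy(dtype=float)
    if np.ptp(y) == 0 or np.ptp(age) == 0:
        raise ValueError(f"constant column {column!r}: correlation undefined")
    r, p = stats.pearsonr(age, y)
    ols = stats.linregress(age, y)
    return CorrelationResult(r=float(r), p=float(p), n=len(sub),
                             slope=float(ols.slope), intercept=float(ols.intercept))


def age_trend_kop(records: pd.DataFrame) -> CorrelationResult:
    """OLS age trend of the out-of-plane dispersion kappa_op."""
    return pearson_with_age(records, "kappa_op")


def cohort_summary(records: pd.DataFrame, table1: pd.DataFrame | None = None) -> dict:
    """Mean +/- sample SD for age and every R^2 column, plus sex/risk counts.

    A single-specimen table reports SD as NaN (flagged, not zero).
    """
    out: dict = {"n": int(len(records))}

    def mean_sd(values: pd.Series) -> dict:
        vals = values.dropna().to_numpy(dtype=float)
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan")
        return {"mean": float(np.mean(vals)), "sd": sd, "n": int(vals.size)}

    out["age"] = mean_sd(records["age"])
    for col in records.columns:
        if col.startswith("r2_"):
            out[col] = mean_sd(records[col])
    if "sex" in records.columns:
        out["sex_counts"] = records["sex"].value_counts().to_dict()
    if table1 is not None:
        for risk in ("htn", "dm", "dyslipidemia", "cad"):
            if risk in table1.columns:
                out[f"{risk}_yes"] = int((table1[risk] == "Yes").sum())
        if "smoker" in table1.columns:
            out["smoker_counts"] = table1["smoker"].value_counts().to_dict()
    return out
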