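"""Study-specific laboratory calibration.

Local-laboratory biomarker values W are systematically shifted and
scaled relative to the reference laboratory's X.  For each study a
linear calibration model

    E(X | W, control) = a_co + b_co * W

is fitted by ordinary least squares among the *controls* of the
calibration subset (cases are rarely re-assayed and are rejected here).
The fitted line imputes a reference-scale value for subjects without a
reference measurement.  Three imputation rules are supported:

``naive``
    No calibration: use W as-is (negative control in evaluations).
``full``
    Use ``a_co + b_co * W`` for *every* subject of a local-laboratory
    study, including those with an observed X.  Controls-only fitting
    biases the intercept slightly, but under full calibration that bias
    is common to all subjects of the study and cancels inside the
    matched-set likelihood, which only sees within-stratum differences.
``internalized``
    Use the observed X when available, the imputed value otherwise.

Matching factors (or nonlinear transforms of W) may be added to the
calibration model as extra pre-computed columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import PooledDataset
from .exceptions import CalibrationError

__all__ = [
    "CalibrationFit",
    "ImputedBiomarker",
    "fit_calibration",
    "fit_all_calibrations",
    "impute_biomarker",
    "calibration_table",
    "METHODS",
]

METHODS = ("internalized", "full", "naive")


@dataclass(frozen=True)
class CalibrationFit:
    """OLS calibration line for one study, fitted among controls."""

    study_id: object
    intercept: float           # a_co, biomarker units
    slope: float               # b_co, dimensionless
    extra_coef: tuple = ()     # matching-factor / transformed-W coefficients
    se_intercept: float = float("nan")
    se_slope: float = float("nan")
    residual_variance: float = float("nan")
    n_cal: int = 0
    extra_cols: tuple = ()

    def predict(self, w, extra=None) -> np.ndarray:
        w = np.asarray(w, dtype=float)
        out = self.intercept + self.slope * w
        if self.extra_cols:
            extra = np.asarray(extra, dtype=float)
            out = out + extra @ np.asarray(self.extra_coef)
        return out


@dataclass(frozen=True)
class ImputedBiomarker:
    """Reference-scale biomarker for every subject under one rule."""

    values: np.ndarray          # aligned with the dataset's row order
    method: str                 # internalized | full | naive
    source: np.ndarray          # 'reference' | 'imputed' | 'local' per subject

    def __post_init__(self):
        if len(self.values) != len(self.source):
            raise ValueError("values and source must be aligned")


def fit_calibration(study_table: pd.DataFrame, *, study_id=None, extra_cols=()) -> CalibrationFit:
    """OLS of reference X on local W among calibration-subset controls.

    ``study_table`` is one study's slice of the pooled table (columns
    ``case``, ``local_value``, ``reference_value``, ``in_calibration``
    and any ``extra_cols``).  Raises :class:`CalibrationError` when the
    subset contains cases, is too small, or has no spread in W.
    """
    extra_cols = tuple(extra_cols)
    if study_id is None and "study" in study_table.columns and len(study_table):
        study_id = study_table["study"].iloc[0]
    sub = study_table[study_table["in_calibration"].astype(bool)]
    if (sub["case"] == 1).any():
        raise CalibrationError(
            f"study {study_id!r}: cases found in the calibration subset; "
            "only controls may be re-assayed"
        )
    n_min = 2 + len(extra_cols)
    if len(sub) < n_min:
        raise CalibrationError(
            f"study {study_id!r}: calibration subset has {len(sub)} subjects, "
            f"need at least {n_min}"
        )
    w = sub["local_value"].to_numpy(dtype=float)
    x = sub["reference_value"].to_numpy(dtype=float)
    if not (np.isfinite(w).all() and np.isfinite(x).all()):
        raise CalibrationError(f"study {study_id!r}: non-finite W or X in calibration subset")
    if np.ptp(w) == 0:
        raise CalibrationError(f"study {study_id!r}: zero variance in W within calibration subset")
    cols = [np.ones_like(w), w]
    for c in extra_cols:
        cols.append(sub[c].to_numpy(dtype=float))
    design = np.column_stack(cols)
    coef, _, rank, _ = np.linalg.lstsq(design, x, rcond=None)
    if rank < design.shape[1]:
        raise CalibrationError(f"study {study_id!r}: singular calibration design matrix")
    resid = x - design @ coef
    dof = len(sub) - design.shape[1]
    s2 = float(resid @ resid / dof) if dof > 0 else 0.0
    cov = s2 * np.linalg.inv(design.T @ design)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return CalibrationFit(
        study_id=study_id,
        intercept=float(coef[0]),
        slope=float(coef[1]),
        extra_coef=tuple(float(c) for c in coef[2:]),
        se_intercept=float(se[0]),
        se_slope=float(se[1]),
        residual_variance=s2,
        n_cal=len(sub),
        extra_cols=extra_cols,
    )


def fit_all_calibrations(dataset: PooledDataset, extra_cols=()) -> dict:
    """One :class:`CalibrationFit` per local-laboratory study."""
    return {
        sid: fit_calibration(dataset.study_table(sid), study_id=sid, extra_cols=extra_cols)
        for sid in dataset.local_studies
    }


def impute_biomarker(dataset: PooledDataset, fits: dict, method: str) -> ImputedBiomarker:
    """Reference-scale biomarker for every subject under ``method``.

    Reference-laboratory studies keep their observed X under every rule.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    df = dataset.table
    n = len(df)
    values = np.full(n, np.nan)
    source = np.empty(n, dtype=object)
    study = df["study"].to_numpy()
    w = df["local_value"].to_numpy(dtype=float)
    x = df["reference_value"].to_numpy(dtype=float)
    for sid in dataset.study_ids:
        mask = study == sid
        if sid in dataset.reference_studies:
            values[mask] = x[mask]
            source[mask] = "reference"
            continue
        if method == "naive":
            values[mask] = w[mask]
            source[mask] = "local"
            continue
        if sid not in fits:
            raise CalibrationError(f"no calibration fit supplied for local study {sid!r}")
        fit = fits[sid]
        extra = (
            df.loc[mask, list(fit.extra_cols)].to_numpy(dtype=float)
            if fit.extra_cols
            else None
        )
        pred = fit.predict(w[mask], extra)
        if method == "full":
            values[mask] = pred
            source[mask] = "imputed"
        else:  # internalized
            have_x = np.isfinite(x) & mask
            values[mask] = pred
            source[mask] = "imputed"
            values[have_x] = x[have_x]
            source[have_x] = "reference"
    if not np.isfinite(values).all():
        raise CalibrationError("imputation produced non-finite values (missing W?)")
    return ImputedBiomarker(values=values, method=method, source=np.asarray(source))


def calibration_table(fits: dict) -> pd.DataFrame:
    """Serializable summary of per-study calibration fits."""
    rows = [
        {
            "study": f.study_id,
            "a": f.intercept,
            "se_a": f.se_intercept,
            "b": f.slope,
            "se_b": f.se_slope,
            "residual_variance": f.residual_variance,
            "n_cal": f.n_cal,
        }
        for f in fits.values()
    ]
    return pd.DataFrame(rows)
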