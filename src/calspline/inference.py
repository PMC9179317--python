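"""Inference for the two-step pseudo-ML fit.

Variance estimation treats the calibration coefficients and the
dose-response coefficients jointly: each matched set (stratum)
contributes a stacked estimating-function vector

    psi_j = (psi_a, psi_b for each calibrated study, psi_beta),

where the calibration components are the OLS normal-equation scores of
the re-assayed controls in that stratum and ``psi_beta`` is the
stratum's conditional-likelihood score.  Strata are independent by
design, so the usual M-estimation sandwich ``A^{-1} B A^{-T}`` with
``A = -sum_j d psi_j / d theta'`` and ``B = sum_j psi_j psi_j'``
captures both the plug-in uncertainty from step 1 and the
within-stratum correlation between calibration and likelihood scores.
``A`` is assembled analytically (the cross block by the chain rule
through ``X~ = a + b W``); a central-difference mode is available as a
cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import _engine
from .calibration import impute_biomarker
from .conditional_likelihood import DoseResponseFit
from .data import PooledDataset
from .splines import SplineBasis, eval_basis

__all__ = [
    "StackedScore",
    "SandwichCovariance",
    "WaldResult",
    "LogRRCurve",
    "stacked_scores",
    "sandwich_covariance",
    "wald_test",
    "nonlinearity_test",
    "log_rr_curve",
]


@dataclass(frozen=True)
class StackedScore:
    """Per-stratum stacked estimating-function contributions."""

    contributions: np.ndarray    # (J, 2Q + dim(beta))
    param_names: list

    @property
    def total(self) -> np.ndarray:
        return self.contributions.sum(axis=0)


@dataclass(frozen=True)
class SandwichCovariance:
    full: np.ndarray             # covariance of (a, b, beta)
    beta_block: np.ndarray
    bread: np.ndarray
    meat: np.ndarray
    param_names: list


@dataclass(frozen=True)
class WaldResult:
    statistic: float
    df: int
    p_value: float
    z: float | None = None       # signed z, single-component tests only


@dataclass(frozen=True)
class LogRRCurve:
    """Dose-response curve on the log relative-risk scale."""

    x_ref: float
    grid: np.ndarray
    log_rr: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "x": self.grid,
                "log_rr": self.log_rr,
                "lower95": self.lower95,
                "upper95": self.upper95,
            }
        )


# ----------------------------------------------------------------------
def _rebuild_model(fit: DoseResponseFit, calibration_fits: dict, dataset: PooledDataset):
    cal = {} if fit.method == "naive" else (calibration_fits or {})
    imputation = impute_biomarker(dataset, cal, fit.method)
    design = _engine.build_design(dataset, imputation, fit.basis)
    return _engine.ConditionalModel(design), cal


def stacked_scores(fit: DoseResponseFit, calibration_fits: dict,
                   dataset: PooledDataset) -> StackedScore:
    """Per-stratum stacked scores at the fitted parameters (sum ~ 0)."""
    model, cal = _rebuild_model(fit, calibration_fits, dataset)
    stacked = _engine.compute_sandwich(model, fit.beta, cal)
    return StackedScore(contributions=stacked.psi, param_names=stacked.param_names)


def sandwich_covariance(fit: DoseResponseFit, calibration_fits: dict,
                        dataset: PooledDataset, deriv: str = "analytic") -> SandwichCovariance:
    """Stacked-equation sandwich covariance for (a, b, beta).

    For the naive method (or all-reference data) the system contains no
    calibration parameters and reduces to the likelihood-only sandwich.
    """
    model, cal = _rebuild_model(fit, calibration_fits, dataset)
    stacked = _engine.compute_sandwich(model, fit.beta, cal, deriv=deriv)
    return SandwichCovariance(
        full=stacked.cov,
        beta_block=stacked.beta_cov,
        bread=stacked.bread,
        meat=stacked.meat,
        param_names=stacked.param_names,
    )


def wald_test(fit: DoseResponseFit, component_indices) -> WaldResult:
    """Wald test of H0: selected beta components are jointly zero.

    ``component_indices`` index the concatenated ``(beta_x, beta_z)``
    vector; the sandwich covariance is used.  For a single component the
    signed ``z`` statistic is also reported.
    """
    idx = np.atleast_1d(np.asarray(component_indices, dtype=int))
    beta = fit.beta
    if np.any(idx < 0) or np.any(idx >= len(beta)):
        raise IndexError(f"component indices {idx.tolist()} out of range for "
                         f"{len(beta)} coefficients")
    b = beta[idx]
    V = fit.sandwich_cov[np.ix_(idx, idx)]
    stat = float(b @ np.linalg.solve(V, b))
    df = len(idx)
    p = float(stats.chi2.sf(stat, df))
    z = float(b[0] / np.sqrt(V[0, 0])) if df == 1 else None
    return WaldResult(statistic=stat, df=df, p_value=p, z=z)


def nonlinearity_test(fit: DoseResponseFit) -> WaldResult:
    """Wald test that every nonlinear spline coefficient is zero."""
    d = len(fit.beta_x)
    if d < 2:
        raise ValueError("model has no nonlinear spline terms")
    return wald_test(fit, list(range(1, d)))


def log_rr_curve(fit: DoseResponseFit, basis: SplineBasis | None = None,
                 grid=None, x_ref: float | None = None) -> LogRRCurve:
    """Log relative risk across ``grid`` relative to ``x_ref``.

    ``log RR(x) = beta_x' (f(x) - f(x_ref))`` with pointwise normal 95%
    intervals from the sandwich covariance of ``beta_x``.  ``x_ref``
    defaults to the smallest grid value (the convention of anchoring the
    curve at the minimum observed biomarker level).
    """
    basis = basis or fit.basis
    grid = np.asarray(grid, dtype=float).ravel()
    if grid.size == 0:
        raise ValueError("empty grid")
    if x_ref is None:
        x_ref = float(grid.min())
    d = len(fit.beta_x)
    c = eval_basis(basis, grid) - eval_basis(basis, float(x_ref))  # (n, d)
    log_rr = c @ fit.beta_x
    cov_x = fit.sandwich_cov[:d, :d]
    var = np.einsum("ij,jk,ik->i", c, cov_x, c)
    half = _engine._Z975 * np.sqrt(np.maximum(var, 0.0))
    return LogRRCurve(
        x_ref=float(x_ref),
        grid=grid,
        log_rr=log_rr,
        lower95=log_rr - half,
        upper95=log_rr + half,
    )
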