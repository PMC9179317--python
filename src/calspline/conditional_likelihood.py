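"""Approximate conditional likelihood and the two-step pseudo-ML fit.

The risk model for subject ``i`` of stratum ``j`` in study ``s`` is

    logit P(Y = 1 | X, Z) = beta0_sj + beta_x' f(X) + beta_z' Z,

with ``f`` a restricted cubic spline basis.  Conditioning on the number
of cases in each matched set removes the stratum intercepts, leaving a
conditional likelihood that depends only on within-stratum differences
of ``f(X)`` and ``Z``.  When X is unobserved for some subjects it is
replaced by its calibrated conditional expectation ``X~`` (a first-order
Taylor argument), giving the approximate conditional likelihood that is
maximized here.

Estimation is two-step pseudo-maximum-likelihood: the calibration lines
are fitted first among re-assayed controls, then ``beta`` maximizes the
likelihood with the imputed values plugged in.  The reported sandwich
covariance (see :mod:`calspline.inference`) propagates the first-step
uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import _engine
from .calibration import (
    METHODS,
    CalibrationFit,
    ImputedBiomarker,
    fit_all_calibrations,
    impute_biomarker,
)
from .data import PooledDataset
from .exceptions import ValidationError
from .splines import SplineBasis, eval_basis, knots_from_quantiles

__all__ = [
    "PooledDataset",
    "DoseResponseFit",
    "stratum_loglik",
    "total_negloglik",
    "score",
    "hessian",
    "fit_dose_response",
]


@dataclass
class DoseResponseFit:
    """Result of the two-step pseudo-ML dose-response fit."""

    method: str
    basis: SplineBasis
    beta_x: np.ndarray
    beta_z: np.ndarray
    model_cov: np.ndarray        # inverse observed information, beta block only
    sandwich_cov: np.ndarray     # beta block of the stacked sandwich
    full_sandwich_cov: np.ndarray
    theta_names: list
    loglik: float
    n_iterations: int
    converged: bool
    calibration_fits: dict = field(default_factory=dict)
    covariate_names: tuple = ()
    n_strata: int = 0
    n_subjects: int = 0

    @property
    def beta(self) -> np.ndarray:
        return np.concatenate([self.beta_x, self.beta_z])

    @property
    def param_names(self) -> list:
        return [f"x{i + 1}" for i in range(len(self.beta_x))] + list(self.covariate_names)

    def se(self, kind: str = "sandwich") -> np.ndarray:
        cov = self.sandwich_cov if kind == "sandwich" else self.model_cov
        return np.sqrt(np.maximum(np.diag(cov), 0.0))

    def conf_int(self, level: float = 0.95, kind: str = "sandwich") -> np.ndarray:
        z = stats.norm.ppf(0.5 + level / 2.0)
        se = self.se(kind)
        b = self.beta
        return np.column_stack([b - z * se, b + z * se])

    def summary(self) -> dict:
        ci = self.conf_int()
        se = self.se()
        return {
            "method": self.method,
            "converged": bool(self.converged),
            "n_iterations": int(self.n_iterations),
            "loglik": float(self.loglik),
            "knots": list(self.basis.knots),
            "n_strata": int(self.n_strata),
            "n_subjects": int(self.n_subjects),
            "coefficients": [
                {
                    "name": name,
                    "estimate": float(b),
                    "se_sandwich": float(s),
                    "ci_lower": float(lo),
                    "ci_upper": float(hi),
                }
                for name, b, s, (lo, hi) in zip(self.param_names, self.beta, se, ci)
            ],
        }


# ----------------------------------------------------------------------
def _single_stratum_model(beta_x, beta_z, y, f_x, z=None):
    beta_x = np.atleast_1d(np.asarray(beta_x, dtype=float))
    y = np.asarray(y, dtype=np.int8)
    f_x = np.asarray(f_x, dtype=float)
    if f_x.ndim == 1:
        f_x = f_x[:, None]
    if z is None:
        z = np.empty((len(y), 0))
        beta_z = np.empty(0)
    else:
        z = np.asarray(z, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
        beta_z = np.atleast_1d(np.asarray(beta_z, dtype=float))
    if not (np.isfinite(f_x).all() and np.isfinite(z).all()):
        raise ValidationError("non-finite f(X~) or Z in stratum")
    G = np.hstack([f_x, z])
    M, row_stratum, row_seg_start = _engine._build_M(y, np.array([0]))
    D = np.asarray(M @ G)
    beta = np.concatenate([beta_x, beta_z])
    eta = D @ beta
    a = max(float(eta.max(initial=0.0)), 0.0)
    return -(a + np.log(np.exp(-a) + np.exp(eta - a).sum()))


def stratum_loglik(beta_x, beta_z, y, f_x, z=None) -> float:
    """Log approximate conditional likelihood of one matched set.

    Parameters: case indicators ``y``, spline-basis values ``f_x``
    (rows aligned with ``y``) and optional covariates ``z``.  The value
    is ``-log(1 + sum over non-case subsets of exp(...))``; at beta = 0
    it equals ``-log C(n+m, n)``.
    """
    return float(_single_stratum_model(beta_x, beta_z, y, f_x, z))


def _model_from_dataset(dataset, imputation, basis):
    design = _engine.build_design(dataset, imputation, basis)
    return _engine.ConditionalModel(design)


def total_negloglik(beta, dataset: PooledDataset, imputation: ImputedBiomarker,
                    basis: SplineBasis) -> float:
    """Negative pooled log-likelihood at ``beta = (beta_x, beta_z)``."""
    return _model_from_dataset(dataset, imputation, basis).negloglik(beta)


def score(beta, dataset: PooledDataset, imputation: ImputedBiomarker,
          basis: SplineBasis) -> np.ndarray:
    """Gradient of the pooled log-likelihood at ``beta``."""
    return _model_from_dataset(dataset, imputation, basis).score(beta)


def hessian(beta, dataset: PooledDataset, imputation: ImputedBiomarker,
            basis: SplineBasis) -> np.ndarray:
    """Hessian of the pooled log-likelihood at ``beta`` (negative semi-definite)."""
    return _model_from_dataset(dataset, imputation, basis).hessian(beta)


# ----------------------------------------------------------------------
def fit_dose_response(
    dataset: PooledDataset,
    basis: SplineBasis | None = None,
    method: str = "full",
    *,
    knots=None,
    knot_probs=(0.25, 0.5, 0.75),
    calibration_extra_cols=(),
    tol: float = 1e-8,
    max_iter: int = 100,
    compute_sandwich: bool = True,
    sandwich_deriv: str = "analytic",
) -> DoseResponseFit:
    """Two-step pseudo-ML fit of the spline dose-response model.

    Step 1 fits the per-study calibration lines among re-assayed
    controls (skipped for ``method='naive'`` and for reference-lab
    studies); step 2 maximizes the approximate conditional likelihood by
    Newton-Raphson at the imputed biomarker values.

    Knots are taken from ``basis`` if given, else from ``knots``, else
    placed at the ``knot_probs`` quantiles of the imputed values.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if method == "naive" or not dataset.local_studies:
        cal_fits: dict = {}
    else:
        cal_fits = fit_all_calibrations(dataset, extra_cols=calibration_extra_cols)
    imputation = impute_biomarker(dataset, cal_fits, method)
    if basis is None:
        if knots is None:
            knots = knots_from_quantiles(imputation.values, knot_probs)
        basis = SplineBasis(tuple(np.asarray(knots, dtype=float)))

    design = _engine.build_design(dataset, imputation, basis)
    model = _engine.ConditionalModel(design)
    beta, loglik, n_iter, converged = model.fit(tol=tol, max_iter=max_iter)

    q = model.n_params
    d = basis.dim
    info = model.neg_hessian(beta)
    model_cov = np.linalg.inv(info)

    if compute_sandwich:
        stacked = _engine.compute_sandwich(
            model, beta, cal_fits if method != "naive" else {}, deriv=sandwich_deriv
        )
        sandwich_cov = stacked.beta_cov
        full_cov = stacked.cov
        theta_names = stacked.param_names
    else:
        sandwich_cov = np.full((q, q), np.nan)
        full_cov = sandwich_cov
        theta_names = []

    return DoseResponseFit(
        method=method,
        basis=basis,
        beta_x=beta[:d],
        beta_z=beta[d:],
        model_cov=model_cov,
        sandwich_cov=sandwich_cov,
        full_sandwich_cov=full_cov,
        theta_names=theta_names,
        loglik=loglik,
        n_iterations=n_iter,
        converged=converged,
        calibration_fits=cal_fits,
        covariate_names=tuple(dataset.covariates),
        n_strata=dataset.n_strata,
        n_subjects=dataset.n_subjects,
    )
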