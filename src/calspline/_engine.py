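"""Computational core shared by the likelihood and inference modules.

The conditional likelihood of a matched set with ``n`` cases and ``m``
controls is ``1 / (1 + sum_k exp(eta_k))`` where ``k`` runs over the
non-case subsets of size ``n`` and ``eta_k = beta' u_k`` with ``u_k``
the difference between the subset's summed design rows and the cases'
summed design rows.  We materialize the linear map from subject design
rows to subset-difference rows as a sparse matrix ``M`` (one row per
subset, +1 on subset members, -1 on cases), so that the whole pooled
log-likelihood, score, Hessian, per-stratum score contributions and the
chain-rule derivatives with respect to the calibration parameters are
dense segment operations on ``D = M @ G``.

For 1:1 matched pairs (one subset per stratum) this reduces to a plain
paired-difference logistic likelihood and everything is vectorized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import sparse

from .exceptions import SeparationError, ValidationError
from .splines import SplineBasis, eval_basis, eval_basis_deriv

MAX_SET_SIZE = 20
MAX_SUBSETS = 10**6

_Z975 = 1.959963984540054


# ----------------------------------------------------------------------
# design arrays
# ----------------------------------------------------------------------
@dataclass
class Design:
    """Per-subject arrays sorted so strata are contiguous."""

    y: np.ndarray               # 0/1
    w: np.ndarray               # local value (may be nan in reference studies)
    x_obs: np.ndarray           # observed reference value (nan if absent)
    x_tilde: np.ndarray         # biomarker entering the likelihood
    F: np.ndarray               # spline basis of x_tilde, (n, d)
    Z: np.ndarray               # covariates, (n, p)
    stratum: np.ndarray         # contiguous codes 0..J-1, sorted
    seg_start: np.ndarray       # first subject row of each stratum, (J,)
    local_code: np.ndarray      # index into local_ids, -1 for reference studies
    imputed: np.ndarray         # bool, x_tilde depends on calibration params
    cal: np.ndarray             # bool, member of a calibration subset
    local_ids: list
    basis: SplineBasis

    @property
    def G(self) -> np.ndarray:
        return np.hstack([self.F, self.Z]) if self.Z.shape[1] else self.F

    @property
    def n_strata(self) -> int:
        return len(self.seg_start)

    @property
    def dim_x(self) -> int:
        return self.F.shape[1]


def build_design(dataset, imputation, basis: SplineBasis) -> Design:
    df = dataset.table
    study = df["study"].to_numpy()
    strat_key = pd.Series(list(zip(study, df["stratum"].to_numpy())))
    codes, _ = pd.factorize(strat_key, sort=False)
    order = np.argsort(codes, kind="stable")

    y = df["case"].to_numpy(dtype=np.int8)[order]
    w = df["local_value"].to_numpy(dtype=float)[order]
    x_obs = df["reference_value"].to_numpy(dtype=float)[order]
    xt = np.asarray(imputation.values, dtype=float)[order]
    Z = dataset.z_matrix()[order]
    cal = df["in_calibration"].to_numpy(dtype=bool)[order]
    imputed = (np.asarray(imputation.source) == "imputed")[order]
    local_ids = dataset.local_studies
    local_index = {sid: k for k, sid in enumerate(local_ids)}
    local_code = np.array([local_index.get(s, -1) for s in study[order]], dtype=np.int64)

    stratum = codes[order]
    seg_start = np.flatnonzero(np.r_[True, np.diff(stratum) != 0])
    F = eval_basis(basis, xt)
    if not np.isfinite(xt).all():
        raise ValidationError("non-finite imputed biomarker values")
    if Z.size and not np.isfinite(Z).all():
        raise ValidationError("non-finite covariate values")
    return Design(
        y=y, w=w, x_obs=x_obs, x_tilde=xt, F=F, Z=Z,
        stratum=stratum, seg_start=seg_start, local_code=local_code,
        imputed=imputed, cal=cal, local_ids=local_ids, basis=basis,
    )


# ----------------------------------------------------------------------
# subset-difference operator
# ----------------------------------------------------------------------
def _build_M(y: np.ndarray, seg_start: np.ndarray):
    """Sparse (R, n) operator mapping subject rows to subset differences."""
    n = len(y)
    seg_end = np.r_[seg_start[1:], n]
    sizes = seg_end - seg_start
    n_cases = np.add.reduceat(y.astype(np.int64), seg_start)

    if np.all(sizes == 2) and np.all(n_cases == 1):
        # 1:1 matched pairs: one row per stratum, +control -case
        first = seg_start
        second = seg_start + 1
        case = np.where(y[first] == 1, first, second)
        ctrl = first + second - case
        R = len(seg_start)
        rows = np.repeat(np.arange(R), 2)
        cols = np.column_stack([ctrl, case]).ravel()
        vals = np.tile([1.0, -1.0], R)
        M = sparse.csr_matrix((vals, (rows, cols)), shape=(R, n))
        row_stratum = np.arange(R)
        row_seg_start = np.arange(R)
        return M, row_stratum, row_seg_start

    rows, cols, vals = [], [], []
    row_stratum = []
    r = 0
    for j, (a, b) in enumerate(zip(seg_start, seg_end)):
        members = np.arange(a, b)
        ncase = int(y[a:b].sum())
        size = b - a
        if ncase == 0 or ncase == size:
            raise ValidationError(f"stratum {j} lacks a case or a control")
        if size > MAX_SET_SIZE or math.comb(size, ncase) > MAX_SUBSETS:
            raise ValidationError(
                f"stratum {j} has {size} subjects with {ncase} cases; "
                f"subset enumeration would exceed the supported size"
            )
        case_idx = members[y[a:b] == 1]
        case_set = frozenset(case_idx.tolist())
        for subset in combinations(members.tolist(), ncase):
            if frozenset(subset) == case_set:
                continue
            for i in subset:
                rows.append(r)
                cols.append(i)
                vals.append(1.0)
            for i in case_idx:
                rows.append(r)
                cols.append(int(i))
                vals.append(-1.0)
            row_stratum.append(j)
            r += 1
    M = sparse.csr_matrix(
        (np.asarray(vals), (np.asarray(rows), np.asarray(cols))), shape=(r, n)
    )
    M.sum_duplicates()
    row_stratum = np.asarray(row_stratum, dtype=np.int64)
    row_seg_start = np.flatnonzero(np.r_[True, np.diff(row_stratum) != 0])
    return M, row_stratum, row_seg_start


# ----------------------------------------------------------------------
# conditional likelihood
# ----------------------------------------------------------------------
class ConditionalModel:
    """Pooled approximate conditional likelihood at fixed imputed values."""

    def __init__(self, design: Design):
        self.design = design
        self.M, self.row_stratum, self.row_seg_start = _build_M(
            design.y, design.seg_start
        )
        self.D = np.asarray(self.M @ design.G)
        self.n_params = self.D.shape[1]

    # -- pieces ---------------------------------------------------------
    def _p(self, beta: np.ndarray):
        """Subset probabilities p_k = exp(eta_k - lse_j) and per-stratum lse."""
        eta = self.D @ beta
        segmax = np.maximum.reduceat(eta, self.row_seg_start)
        a = np.maximum(segmax, 0.0)
        ex = np.exp(eta - a[self.row_stratum])
        sumex = np.add.reduceat(ex, self.row_seg_start)
        lse = a + np.log(np.exp(-a) + sumex)
        p = ex * np.exp((a - lse)[self.row_stratum])
        return p, lse

    def negloglik(self, beta) -> float:
        _, lse = self._p(np.asarray(beta, dtype=float))
        return float(lse.sum())

    def loglik(self, beta) -> float:
        return -self.negloglik(beta)

    def score(self, beta) -> np.ndarray:
        """Gradient of the log-likelihood."""
        p, _ = self._p(np.asarray(beta, dtype=float))
        return -(self.D.T @ p)

    def per_stratum_score(self, beta) -> np.ndarray:
        """(J, q) matrix of per-stratum score contributions."""
        p, _ = self._p(np.asarray(beta, dtype=float))
        return -np.add.reduceat(p[:, None] * self.D, self.row_seg_start, axis=0)

    def neg_hessian(self, beta) -> np.ndarray:
        """Observed information (negative Hessian of the log-likelihood)."""
        p, _ = self._p(np.asarray(beta, dtype=float))
        m = np.add.reduceat(p[:, None] * self.D, self.row_seg_start, axis=0)
        return self.D.T @ (self.D * p[:, None]) - m.T @ m

    def hessian(self, beta) -> np.ndarray:
        return -self.neg_hessian(beta)

    # -- Newton-Raphson ---------------------------------------------------
    def fit(self, beta0=None, tol: float = 1e-8, max_iter: int = 100):
        """Maximize the log-likelihood; returns (beta, loglik, iters, converged)."""
        q = self.n_params
        beta = np.zeros(q) if beta0 is None else np.asarray(beta0, dtype=float).copy()
        nll = self.negloglik(beta)
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            g = self.D.T @ self._p(beta)[0]  # gradient of the NEGATIVE loglik
            if np.max(np.abs(g)) <= tol:
                converged = True
                it -= 1
                break
            H = self.neg_hessian(beta)
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                step = np.linalg.solve(H + 1e-10 * np.eye(q), g)
            t = 1.0
            improved = False
            for _ in range(40):
                cand = beta - t * step
                cand_nll = self.negloglik(cand)
                if cand_nll <= nll + 1e-12:
                    improved = True
                    break
                t *= 0.5
            if not improved:
                break
            beta, nll = cand, cand_nll
            if np.linalg.norm(beta) > 1e4:
                raise SeparationError(
                    "estimates diverging (||beta|| > 1e4); the conditional "
                    "likelihood appears unbounded (separation)"
                )
        else:
            it = max_iter
        if not converged and np.max(np.abs(self.score(beta))) <= tol:
            converged = True
        # a conditional likelihood of ~1 at a large beta means every stratum's
        # case set is separated from the alternatives: the MLE is at infinity
        if nll < 1e-8 * max(self.design.n_strata, 1):
            raise SeparationError(
                "the conditional likelihood is unbounded (perfect separation: "
                f"log-likelihood {-nll:.3g} at ||beta|| = {np.linalg.norm(beta):.3g})"
            )
        return beta, -nll, it, converged


# ----------------------------------------------------------------------
# stacked estimating equations / sandwich
# ----------------------------------------------------------------------
@dataclass
class Stacked:
    """Stacked M-estimation pieces for theta = (a_1, b_1, ..., a_Q, b_Q, beta)."""

    psi: np.ndarray             # (J, dim) per-stratum estimating-function values
    bread: np.ndarray           # A = -sum_j d psi_j / d theta'
    meat: np.ndarray            # B = sum_j psi_j psi_j'
    cov: np.ndarray             # A^{-1} B A^{-T}
    beta_cov: np.ndarray        # beta block of cov
    param_names: list
    n_cal_params: int = field(default=0)


def _calibration_blocks(design: Design, cal_fits: dict):
    """Per-study calibration design info: (study_id, fit, idx, U, cal_mask)."""
    blocks = []
    for k, sid in enumerate(design.local_ids):
        if sid not in cal_fits:
            continue
        fit = cal_fits[sid]
        idx = np.flatnonzero(design.local_code == k)
        cols = [np.ones(len(idx)), design.w[idx]]
        if fit.extra_cols:
            raise NotImplementedError(
                "sandwich variance with extra calibration covariates is not implemented"
            )
        U = np.column_stack(cols)
        blocks.append((sid, fit, idx, U, design.cal[idx]))
    return blocks


def compute_sandwich(
    model: ConditionalModel,
    beta: np.ndarray,
    cal_fits: dict | None = None,
    deriv: str = "analytic",
) -> Stacked:
    """Sandwich covariance of (calibration params, beta) over strata.

    ``cal_fits`` maps local study ids to their :class:`CalibrationFit`;
    pass None/empty for the naive method or all-reference data, in which
    case the stacked system is the likelihood-only sandwich.
    """
    design = model.design
    beta = np.asarray(beta, dtype=float)
    cal_fits = cal_fits or {}
    blocks = _calibration_blocks(design, cal_fits)
    P = 2 * len(blocks)
    q = model.n_params
    J = design.n_strata
    dim = P + q

    names = []
    for sid, *_ in blocks:
        names += [f"a[{sid}]", f"b[{sid}]"]
    names += [f"x{i + 1}" for i in range(design.dim_x)]
    names += [f"z{i + 1}" for i in range(q - design.dim_x)]

    psi = np.zeros((J, dim))
    psi[:, P:] = model.per_stratum_score(beta)

    A = np.zeros((dim, dim))
    A[P:, P:] = model.neg_hessian(beta)

    p, _ = model._p(beta)
    fprime = eval_basis_deriv(design.basis, design.x_tilde)  # (n, d)

    for s, (sid, fit, idx, U, cal_mask) in enumerate(blocks):
        off = 2 * s
        coef = np.array([fit.intercept, fit.slope])
        ci = idx[cal_mask]
        Uc = U[cal_mask]
        r = design.x_obs[ci] - Uc @ coef
        # per-stratum OLS scores
        strat = design.stratum[ci]
        for t in range(2):
            np.add.at(psi[:, off + t], strat, r * Uc[:, t])
        # calibration block of the bread
        A[off:off + 2, off:off + 2] = Uc.T @ Uc
        # cross block d psi_beta / d (a_s, b_s) via the chain rule
        if deriv == "analytic":
            imp = idx[design.imputed[idx]]
            if imp.size:
                n = len(design.y)
                for t in range(2):
                    dG = np.zeros((n, q))
                    ut = U[design.imputed[idx], t]
                    dG[imp, : design.dim_x] = fprime[imp] * ut[:, None]
                    dU = np.asarray(model.M @ dG)
                    deta = dU @ beta
                    seg = np.add.reduceat(p * deta, model.row_seg_start)
                    dp = p * (deta - seg[model.row_stratum])
                    C = dp[:, None] * model.D + p[:, None] * dU
                    A[P:, off + t] = C.sum(axis=0)

    if deriv == "numeric":
        theta = np.concatenate(
            [np.array([f.intercept, f.slope]) for _, f, *_ in blocks] + [beta]
        ) if blocks else beta.copy()
        A = _numeric_bread(model, theta, blocks)

    B = psi.T @ psi
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"singular bread matrix in the sandwich variance (condition number {cond:.3g})"
        )
    Ainv_B = np.linalg.solve(A, B)
    cov = np.linalg.solve(A, Ainv_B.T).T
    cov = 0.5 * (cov + cov.T)
    return Stacked(
        psi=psi, bread=A, meat=B, cov=cov,
        beta_cov=cov[P:, P:], param_names=names, n_cal_params=P,
    )


def _stacked_total_score(model: ConditionalModel, theta: np.ndarray, blocks):
    """Total stacked estimating function at theta (used for numeric bread)."""
    design = model.design
    P = 2 * len(blocks)
    beta = theta[P:]
    xt = design.x_tilde.copy()
    for s, (sid, fit, idx, U, cal_mask) in enumerate(blocks):
        coef = theta[2 * s: 2 * s + 2]
        imp_local = design.imputed[idx]
        xt[idx[imp_local]] = U[imp_local] @ coef
    F = eval_basis(design.basis, xt)
    G = np.hstack([F, design.Z]) if design.Z.shape[1] else F
    D = np.asarray(model.M @ G)
    eta = D @ beta
    segmax = np.maximum.reduceat(eta, model.row_seg_start)
    a = np.maximum(segmax, 0.0)
    ex = np.exp(eta - a[model.row_stratum])
    sumex = np.add.reduceat(ex, model.row_seg_start)
    lse = a + np.log(np.exp(-a) + sumex)
    p = ex * np.exp((a - lse)[model.row_stratum])
    out = np.zeros(P + len(beta))
    out[P:] = -(D.T @ p)
    for s, (sid, fit, idx, U, cal_mask) in enumerate(blocks):
        coef = theta[2 * s: 2 * s + 2]
        Uc = U[cal_mask]
        r = design.x_obs[idx[cal_mask]] - Uc @ coef
        out[2 * s: 2 * s + 2] = Uc.T @ r
    return out


def _numeric_bread(model: ConditionalModel, theta: np.ndarray, blocks) -> np.ndarray:
    dim = len(theta)
    A = np.zeros((dim, dim))
    for t in range(dim):
        h = 1e-6 * (1.0 + abs(theta[t]))
        e = np.zeros(dim)
        e[t] = h
        plus = _stacked_total_score(model, theta + e, blocks)
        minus = _stacked_total_score(model, theta - e, blocks)
        A[:, t] = -(plus - minus) / (2 * h)
    return A
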