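"""Monte-Carlo engine for 1:1 matched case-control pooling experiments.

Data generation mimics a pooling project in which every study measures
the biomarker at its own local laboratory.  For each study ``s`` the
reference-scale value X, the local value W and the calibration error
are jointly Gaussian with

    E(X) = mu_x,  Var(X) = sigma2_x,
    E(W) = (mu_x - a_s) / b_s,  Var(W) = sigma2_w[s],
    Cov(X, W) = b_s * sigma2_w[s],

which yields exactly the linear calibration model
``E(X | W) = a_s + b_s W`` with residual variance
``sigma2_x - b_s^2 sigma2_w[s]``.  Within each stratum a random
intercept ``beta0 ~ N(0, beta0_variance)`` is drawn, candidate subjects
are sampled until the stratum contains at least one case and one
control (``Y ~ Bernoulli(expit(beta0 + beta_x' f(X)))``), and one case
and one control are then chosen uniformly at random.  A simple random
sample of each study's controls (``calibration_proportion``, at least
3 subjects) is re-assayed, i.e. gets its X revealed.

``run_simulation`` repeats generation + fitting over independent
replicate streams and tabulates mean relative bias, empirical SD and
95%-interval coverage per method (internalized / full / naive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from ._engine import _Z975
from .conditional_likelihood import fit_dose_response
from .data import PooledDataset
from .exceptions import ValidationError
from .splines import SplineBasis, eval_basis

__all__ = [
    "SimulationConfig",
    "SimulationSummary",
    "default_scenario",
    "draw_biomarkers",
    "generate_pooled_data",
    "run_replicate",
    "run_simulation",
]

_DEF_KNOTS = tuple(stats.norm.ppf([0.25, 0.5, 0.75]))


@dataclass(frozen=True)
class SimulationConfig:
    """Generator + experiment parameters (defaults: the standard scenario).

    Defaults describe four pooled studies of 500 matched pairs whose
    local laboratories differ widely in location and scale, a standard
    normal reference-scale biomarker, a small stratum-intercept variance
    and restricted-cubic-spline knots at the N(0,1) quartiles.
    """

    n_studies: int = 4
    pairs_per_study: int = 500
    mu_x: float = 0.0
    sigma2_x: float = 1.0
    a: tuple = (-3.0, 1.0, -1.0, 3.0)
    b: tuple = (0.5, 0.75, 1.25, 1.5)
    sigma2_w: tuple = (3.8, 1.7, 0.6, 0.4)
    beta0_variance: float = 0.01
    beta_x: tuple = (-math.log(1.25), 0.08)
    knots: tuple = _DEF_KNOTS
    calibration_proportion: float = 0.05
    n_replicates: int = 1000
    seed: int = 0
    methods: tuple = ("internalized", "full", "naive")
    max_candidates: int = 100_000

    def __post_init__(self):
        for name in ("a", "b", "sigma2_w"):
            vals = getattr(self, name)
            if len(vals) != self.n_studies:
                raise ValidationError(f"{name} must have length n_studies={self.n_studies}")
        for s in range(self.n_studies):
            if self.sigma2_w[s] <= 0 or self.sigma2_x <= 0:
                raise ValidationError("variances must be positive")
            if self.sigma2_x - self.b[s] ** 2 * self.sigma2_w[s] < -1e-12:
                raise ValidationError(
                    f"study {s}: sigma2_x - b^2 sigma2_w = "
                    f"{self.sigma2_x - self.b[s] ** 2 * self.sigma2_w[s]:.4g} < 0; "
                    "the (X, W) covariance is invalid"
                )
        if not (0 < self.calibration_proportion <= 1):
            raise ValidationError("calibration_proportion must be in (0, 1]")
        if self.beta0_variance < 0:
            raise ValidationError("beta0_variance must be >= 0")
        if self.pairs_per_study < 3:
            raise ValidationError("need at least 3 pairs per study for calibration")


def default_scenario(**overrides) -> SimulationConfig:
    """The standard four-study scenario, with optional field overrides."""
    return replace(SimulationConfig(), **overrides) if overrides else SimulationConfig()


@dataclass
class SimulationSummary:
    """Per-method operating characteristics over the completed replicates."""

    config: SimulationConfig
    truth: np.ndarray
    methods: tuple
    param_names: tuple
    mean_rel_bias_pct: dict          # method -> (d,) array, percent
    empirical_sd: dict               # method -> (d,) array (raw scale)
    coverage: dict                   # method -> (d,) array in [0, 1]
    mean_sandwich_se: dict           # method -> (d,) array
    rejection_rate_nonlinear: dict   # method -> float, alpha = 0.05 Wald
    n_replicates: int = 0
    n_nonconverged: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for method in self.methods:
            for k, name in enumerate(self.param_names):
                rows.append(
                    {
                        "method": method,
                        "parameter": name,
                        "true_value": float(self.truth[k]),
                        "rel_bias_pct": float(self.mean_rel_bias_pct[method][k]),
                        "sd_x1000": float(self.empirical_sd[method][k] * 1e3),
                        "coverage": float(self.coverage[method][k]),
                        "mean_sandwich_se": float(self.mean_sandwich_se[method][k]),
                    }
                )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "n_nonconverged": {m: int(v) for m, v in self.n_nonconverged.items()},
            "truth": self.truth.tolist(),
            "parameters": list(self.param_names),
            "methods": {
                m: {
                    "rel_bias_pct": self.mean_rel_bias_pct[m].tolist(),
                    "sd": self.empirical_sd[m].tolist(),
                    "coverage": self.coverage[m].tolist(),
                    "mean_sandwich_se": self.mean_sandwich_se[m].tolist(),
                    "nonlinear_rejection_rate": float(self.rejection_rate_nonlinear[m]),
                }
                for m in self.methods
            },
        }


# ----------------------------------------------------------------------
# data generation
# ----------------------------------------------------------------------
def draw_biomarkers(config: SimulationConfig, study_index: int, size, rng):
    """Draw (X, W) for candidate subjects of one study."""
    s = study_index
    b = config.b[s]
    s2w = config.sigma2_w[s]
    mean_w = (config.mu_x - config.a[s]) / b
    w = rng.normal(mean_w, math.sqrt(s2w), size=size)
    resid_sd = math.sqrt(max(config.sigma2_x - b * b * s2w, 0.0))
    x = config.a[s] + b * w + rng.normal(0.0, resid_sd, size=size)
    return x, w


def _pick(rng, mask, keys):
    """Column index of a uniformly random True entry per row (rows with any)."""
    scored = np.where(mask, keys, -1.0)
    return np.argmax(scored, axis=1)


def generate_pooled_data(
    config: SimulationConfig, seed=None, include_latent: bool = False
) -> PooledDataset:
    """One pooled dataset of 1:1 matched pairs under ``config``.

    ``seed`` may be an integer or a ``numpy.random.Generator``.  With
    ``include_latent=True`` the generator's true reference-scale value is
    carried along in a ``latent_x`` column (useful for fixtures and
    diagnostics; it is not used by any estimator).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    basis = SplineBasis(config.knots)
    beta_x = np.asarray(config.beta_x, dtype=float)
    if len(beta_x) != basis.dim:
        raise ValidationError(
            f"beta_x has length {len(beta_x)} but the {basis.n_knots}-knot basis "
            f"has dimension {basis.dim}"
        )
    frames = []
    for s in range(config.n_studies):
        J = config.pairs_per_study
        beta0 = rng.normal(0.0, math.sqrt(config.beta0_variance), size=J)
        case_x = np.full(J, np.nan)
        case_w = np.full(J, np.nan)
        ctrl_x = np.full(J, np.nan)
        ctrl_w = np.full(J, np.nan)
        need_case = np.ones(J, dtype=bool)
        need_ctrl = np.ones(J, dtype=bool)
        drawn = np.zeros(J, dtype=np.int64)
        batch = 16
        while need_case.any() or need_ctrl.any():
            active = np.flatnonzero(need_case | need_ctrl)
            if np.any(drawn[active] >= config.max_candidates):
                j = active[np.argmax(drawn[active])]
                raise ValidationError(
                    f"study {s + 1}, stratum {j + 1}: exceeded "
                    f"{config.max_candidates} candidate draws without obtaining "
                    "both a case and a control (pathological configuration?)"
                )
            x, w = draw_biomarkers(config, s, (len(active), batch), rng)
            eta = beta0[active][:, None] + eval_basis(basis, x) @ beta_x
            y = rng.random((len(active), batch)) < expit(eta)
            keys = rng.random((len(active), batch))
            drawn[active] += batch

            got_case = y.any(axis=1)
            sel = _pick(rng, y, keys)
            take = need_case[active] & got_case
            rows = active[take]
            case_x[rows] = x[take, sel[take]]
            case_w[rows] = w[take, sel[take]]
            need_case[rows] = False

            got_ctrl = (~y).any(axis=1)
            sel = _pick(rng, ~y, keys)
            take = need_ctrl[active] & got_ctrl
            rows = active[take]
            ctrl_x[rows] = x[take, sel[take]]
            ctrl_w[rows] = w[take, sel[take]]
            need_ctrl[rows] = False

        n_cal = max(3, int(round(config.calibration_proportion * J)))
        cal_idx = rng.choice(J, size=min(n_cal, J), replace=False)
        in_cal = np.zeros(J, dtype=bool)
        in_cal[cal_idx] = True

        stratum = np.arange(1, J + 1)
        frame = pd.DataFrame(
            {
                "study": f"study_{s + 1}",
                "stratum": np.concatenate([stratum, stratum]),
                "case": np.r_[np.zeros(J, dtype=np.int8), np.ones(J, dtype=np.int8)],
                "local_value": np.concatenate([ctrl_w, case_w]),
                "reference_value": np.concatenate(
                    [np.where(in_cal, ctrl_x, np.nan), np.full(J, np.nan)]
                ),
                "in_calibration": np.concatenate([in_cal, np.zeros(J, dtype=bool)]),
            }
        )
        if include_latent:
            frame["latent_x"] = np.concatenate([ctrl_x, case_x])
        frame = frame.sort_values("stratum", kind="stable").reset_index(drop=True)
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    return PooledDataset(table=table, covariates=(), reference_studies=frozenset())


# ----------------------------------------------------------------------
# replicates
# ----------------------------------------------------------------------
def run_replicate(config: SimulationConfig, seed=None) -> dict:
    """Generate one dataset and fit the requested methods on it.

    Returns ``{method: {"estimate", "se", "covered", "converged",
    "p_nonlinear"}}`` where ``covered`` flags whether each coefficient's
    95% sandwich Wald interval contains the truth.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    data = generate_pooled_data(config, rng)
    basis = SplineBasis(config.knots)
    truth = np.asarray(config.beta_x, dtype=float)
    out = {}
    for method in config.methods:
        fit = fit_dose_response(data, basis=basis, method=method)
        est = fit.beta_x
        se = fit.se("sandwich")[: len(est)]
        covered = np.abs(est - truth) <= _Z975 * se
        d = len(est)
        if d >= 2:
            from .inference import nonlinearity_test

            p_nl = nonlinearity_test(fit).p_value
        else:
            p_nl = np.nan
        out[method] = {
            "estimate": est,
            "se": se,
            "covered": covered,
            "converged": bool(fit.converged),
            "p_nonlinear": p_nl,
        }
    return out


def run_simulation(config: SimulationConfig, progress=None) -> SimulationSummary:
    """Aggregate :func:`run_replicate` over independent replicate streams.

    Replicate r uses the r-th child stream of ``config.seed`` so results
    are reproducible and order-independent.  Non-converged fits are
    excluded from the summaries and counted.
    """
    if config.n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    d = len(config.beta_x)
    truth = np.asarray(config.beta_x, dtype=float)
    children = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
    est = {m: np.full((config.n_replicates, d), np.nan) for m in config.methods}
    se = {m: np.full((config.n_replicates, d), np.nan) for m in config.methods}
    cov = {m: np.zeros((config.n_replicates, d), dtype=bool) for m in config.methods}
    ok = {m: np.zeros(config.n_replicates, dtype=bool) for m in config.methods}
    pnl = {m: np.full(config.n_replicates, np.nan) for m in config.methods}
    for r, child in enumerate(children):
        rep = run_replicate(config, np.random.default_rng(child))
        for m in config.methods:
            est[m][r] = rep[m]["estimate"]
            se[m][r] = rep[m]["se"]
            cov[m][r] = rep[m]["covered"]
            ok[m][r] = rep[m]["converged"]
            pnl[m][r] = rep[m]["p_nonlinear"]
        if progress is not None:
            progress(r + 1, config.n_replicates)

    bias, sd, coverage, mean_se, rej, bad = {}, {}, {}, {}, {}, {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for m in config.methods:
            keep = ok[m]
            bad[m] = int((~keep).sum())
            e = est[m][keep]
            rel = (e - truth) / np.where(truth != 0, truth, np.nan)
            bias[m] = rel.mean(axis=0) * 100.0
            sd[m] = e.std(axis=0, ddof=1) if keep.sum() > 1 else np.full(d, np.nan)
            coverage[m] = cov[m][keep].mean(axis=0)
            mean_se[m] = se[m][keep].mean(axis=0)
            p = pnl[m][keep]
            rej[m] = float(np.mean(p < 0.05)) if np.isfinite(p).any() else float("nan")
    return SimulationSummary(
        config=config,
        truth=truth,
        methods=tuple(config.methods),
        param_names=tuple(f"beta_x{i + 1}" for i in range(d)),
        mean_rel_bias_pct=bias,
        empirical_sd=sd,
        coverage=coverage,
        mean_sandwich_se=mean_se,
        rejection_rate_nonlinear=rej,
        n_replicates=config.n_replicates,
        n_nonconverged=bad,
    )
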