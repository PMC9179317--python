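"""Restricted cubic spline basis for dose-response modelling.

A restricted cubic spline with K knots ``t1 < t2 < ... < tK`` is a
piecewise-cubic function constrained to be linear below the first and
above the last knot.  The basis used here has ``K - 1`` components: the
identity (linear) term plus ``K - 2`` nonlinear terms

    g_k(x) = (x - t_k)_+^3
             - (x - t_{K-1})_+^3 (t_K - t_k) / (t_K - t_{K-1})
             + (x - t_K)_+^3 (t_{K-1} - t_k) / (t_K - t_{K-1}),

for k = 1, ..., K-2, where (u)_+ = max(u, 0).  Each g_k vanishes
identically for x <= t_k and is linear for x >= t_K, so a zero
coefficient on every nonlinear term reduces the fitted log relative
risk to a straight line.  No numerical rescaling (such as dividing by
the squared knot range) is applied; an optional ``normalize`` flag is
available for users who prefer scale-free nonlinear columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateKnotsError

__all__ = ["SplineBasis", "knots_from_quantiles", "eval_basis", "eval_basis_deriv"]


@dataclass(frozen=True)
class SplineBasis:
    """Knot locations and the restricted cubic basis they induce.

    Parameters
    ----------
    knots
        Strictly increasing knot locations, length K >= 3 (biomarker units).
    normalize
        If True, divide each nonlinear component by ``(t_K - t_1)**2`` so
        that all columns share the scale of the linear term.  Off by
        default.
    """

    knots: tuple[float, ...]
    normalize: bool = False
    dim: int = field(init=False)

    def __post_init__(self) -> None:
        knots = tuple(float(t) for t in np.asarray(self.knots, dtype=float).ravel())
        if len(knots) < 3:
            raise DegenerateKnotsError(f"need at least 3 knots, got {len(knots)}")
        if not all(np.isfinite(knots)):
            raise DegenerateKnotsError("knots must be finite")
        if any(b <= a for a, b in zip(knots, knots[1:])):
            raise DegenerateKnotsError(f"knots must be strictly increasing, got {knots}")
        object.__setattr__(self, "knots", knots)
        object.__setattr__(self, "dim", len(knots) - 1)

    @property
    def n_knots(self) -> int:
        return len(self.knots)

    def __call__(self, x):
        return eval_basis(self, x)

    def deriv(self, x):
        return eval_basis_deriv(self, x)


def knots_from_quantiles(values, probs=(0.25, 0.5, 0.75)) -> np.ndarray:
    """Empirical quantiles of ``values`` to be used as knot locations.

    Uses the median-unbiased quantile convention (numpy's
    ``method="median_unbiased"``), a reasonable default for continuous
    biomarker distributions.  Raises :class:`DegenerateKnotsError` when
    ties in the data produce non-distinct knots.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("values must be non-empty")
    probs = np.asarray(probs, dtype=float).ravel()
    if probs.size == 0 or np.any(probs <= 0) or np.any(probs >= 1):
        raise ValueError("probs must lie strictly inside (0, 1)")
    if np.any(np.diff(probs) <= 0):
        raise ValueError("probs must be strictly increasing")
    knots = np.quantile(values, probs, method="median_unbiased")
    if np.any(np.diff(knots) <= 0):
        raise DegenerateKnotsError(
            f"quantiles {probs.tolist()} of the data are not distinct: {knots.tolist()}"
        )
    return knots


def _pieces(basis: SplineBasis, x: np.ndarray) -> np.ndarray:
    """Nonlinear components, shape (..., K-2)."""
    t = np.asarray(basis.knots)
    K = t.size
    tk = t[: K - 2]                       # inner knots driving each component
    d = t[K - 1] - t[K - 2]
    cub = np.maximum(x[..., None] - tk, 0.0) ** 3
    cub_pen = np.maximum(x[..., None] - t[K - 2], 0.0) ** 3
    cub_last = np.maximum(x[..., None] - t[K - 1], 0.0) ** 3
    out = cub - cub_pen * ((t[K - 1] - tk) / d) + cub_last * ((t[K - 2] - tk) / d)
    if basis.normalize:
        out = out / (t[K - 1] - t[0]) ** 2
    return out


def _pieces_deriv(basis: SplineBasis, x: np.ndarray) -> np.ndarray:
    t = np.asarray(basis.knots)
    K = t.size
    tk = t[: K - 2]
    d = t[K - 1] - t[K - 2]
    sq = np.maximum(x[..., None] - tk, 0.0) ** 2
    sq_pen = np.maximum(x[..., None] - t[K - 2], 0.0) ** 2
    sq_last = np.maximum(x[..., None] - t[K - 1], 0.0) ** 2
    out = 3.0 * (sq - sq_pen * ((t[K - 1] - tk) / d) + sq_last * ((t[K - 2] - tk) / d))
    if basis.normalize:
        out = out / (t[K - 1] - t[0]) ** 2
    return out


def eval_basis(basis: SplineBasis, x) -> np.ndarray:
    """Evaluate the basis at ``x``.

    Returns an array whose last axis has length ``basis.dim``; the first
    component is ``x`` itself, the remaining components are the
    restricted-cubic terms.  Scalars in give a 1-D vector out.
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    xv = np.atleast_1d(x)
    out = np.concatenate([xv[..., None], _pieces(basis, xv)], axis=-1)
    return out[0] if scalar else out


def eval_basis_deriv(basis: SplineBasis, x) -> np.ndarray:
    """First derivative of every basis component at ``x`` (same shape rules)."""
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    xv = np.atleast_1d(x)
    out = np.concatenate(
        [np.ones_like(xv)[..., None], _pieces_deriv(basis, xv)], axis=-1
    )
    return out[0] if scalar else out
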