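"""Penalized B-spline representation of stride-cycle curves.

Curves defined on 0-100% of the stride cycle are represented as linear
combinations of B-spline basis functions, either an ordinary (clamped) cubic
B-spline basis or a cyclic basis whose functions wrap smoothly across the
0/100% seam.  Smoothing is penalized least squares with an integrated
squared-second-derivative penalty; the smoothing parameter can be chosen by
generalized cross-validation (GCV) averaged over a set of curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "BasisSpec",
    "FunctionalFit",
    "eval_basis",
    "penalty_matrix",
    "gram_matrix",
    "smooth_curve",
    "smoother_matrix",
    "gcv_select",
]

_KINDS = ("bspline", "cyclic")


@dataclass(frozen=True)
class BasisSpec:
    """Description of a spline basis on the stride-cycle domain [0, 100].

    Parameters
    ----------
    kind:
        ``"bspline"`` for a clamped (open) basis, ``"cyclic"`` for a periodic
        basis whose functions satisfy ``f(0) = f(100)`` together with matching
        first and second derivatives at the seam.
    order:
        Spline order (4 = cubic).
    n_basis:
        Number of basis functions (for the cyclic kind this equals the number
        of free periodic coefficients).
    """

    kind: str = "bspline"
    order: int = 4
    n_basis: int = 21
    domain: tuple[float, float] = (0.0, 100.0)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.order < 2:
            raise ValueError("order must be >= 2")
        if self.n_basis < self.order:
            raise ValueError(
                f"n_basis ({self.n_basis}) must be >= order ({self.order})"
            )
        if not self.domain[1] > self.domain[0]:
            raise ValueError("domain must be an increasing interval")

    @property
    def degree(self) -> int:
        return self.order - 1

    def knots(self) -> np.ndarray:
        """Full (unwrapped) knot vector used for evaluation."""
        a, b = self.domain
        k = self.degree
        if self.kind == "bspline":
            interior = np.linspace(a, b, self.n_basis - k + 1)
            return np.concatenate([np.full(k, a), interior, np.full(k, b)])
        h = (b - a) / self.n_basis
        return a + h * np.arange(-k, self.n_basis + k + 1)


def _unwrapped_design(spec: BasisSpec, x: np.ndarray, deriv: int = 0) -> np.ndarray:
    t = spec.knots()
    k = spec.degree
    m = len(t) - k - 1
    spl = BSpline(t, np.eye(m), k, extrapolate=True)
    if deriv:
        spl = spl.derivative(deriv)
    return spl(x)


def eval_basis(spec: BasisSpec, grid: np.ndarray, deriv: int = 0) -> np.ndarray:
    """Evaluate all basis functions (or a derivative) at the given points.

    Returns an array of shape ``(len(grid), spec.n_basis)``.  For the
    ``bspline`` kind rows sum to one (partition of unity); for the ``cyclic``
    kind every column takes equal values at the two domain endpoints.
    """
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    a, b = spec.domain
    if grid.min() < a - 1e-12 or grid.max() > b + 1e-12:
        raise ValueError(f"evaluation points must lie within [{a}, {b}]")
    grid = np.clip(grid, a, b)
    D = _unwrapped_design(spec, grid, deriv)
    if spec.kind == "bspline":
        return D
    # wrap: unwrapped functions j and j + n_basis are translates by one period
    n = spec.n_basis
    P = np.zeros((len(grid), n))
    for j in range(D.shape[1]):
        P[:, j % n] += D[:, j]
    return P


def _quad_points(spec: BasisSpec, npts: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights on every knot span inside the domain."""
    a, b = spec.domain
    t = spec.knots()
    breaks = np.unique(t[(t >= a - 1e-12) & (t <= b + 1e-12)])
    xg, wg = np.polynomial.legendre.leggauss(npts)
    nodes, weights = [], []
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        half = (hi - lo) / 2.0
        nodes.append(half * xg + (hi + lo) / 2.0)
        weights.append(half * wg)
    return np.concatenate(nodes), np.concatenate(weights)


def penalty_matrix(spec: BasisSpec) -> np.ndarray:
    """Gram matrix of second derivatives: R_ij = int phi_i'' phi_j'' du.

    Computed exactly by per-span Gauss quadrature (the integrand is piecewise
    polynomial of degree ``2*(order-3)``).
    """
    x, w = _quad_points(spec, max(2, spec.order - 1))
    D2 = eval_basis(spec, x, deriv=2)
    return (D2 * w[:, None]).T @ D2


def gram_matrix(spec: BasisSpec) -> np.ndarray:
    """Gram matrix of the basis functions themselves: G_ij = int phi_i phi_j du."""
    x, w = _quad_points(spec, spec.order)
    D = eval_basis(spec, x)
    return (D * w[:, None]).T @ D


@dataclass
class FunctionalFit:
    """A smooth curve: basis spec plus coefficient vector plus its lambda."""

    basis: BasisSpec
    coefficients: np.ndarray
    lam: float = 0.0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (self.basis.n_basis,):
            raise ValueError(
                f"coefficient length {self.coefficients.shape} does not match "
                f"basis dimension {self.basis.n_basis}"
            )

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return eval_basis(self.basis, x) @ self.coefficients

    def second_derivative_energy(self) -> float:
        """Integrated squared second derivative of the fitted curve."""
        R = penalty_matrix(self.basis)
        return float(self.coefficients @ R @ self.coefficients)


def _penalized_normal_matrix(
    Phi: np.ndarray, R: np.ndarray, lam: float
) -> np.ndarray:
    return Phi.T @ Phi + lam * R


def smooth_curve(
    y: np.ndarray,
    grid: np.ndarray,
    spec: BasisSpec,
    lam: float,
) -> FunctionalFit:
    """Penalized least-squares smooth of sampled values.

    Coefficients minimize ``||y - Phi c||^2 + lam * c' R c`` with ``R`` the
    second-derivative penalty Gram matrix.

    Raises
    ------
    ValueError
        If the normal equations are singular (e.g. ``lam = 0`` with more basis
        functions than data points).
    """
    y = np.asarray(y, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if y.shape != grid.shape:
        raise ValueError("y and grid must have the same length")
    Phi = eval_basis(spec, grid)
    if lam == 0.0:
        if spec.n_basis > len(y):
            raise ValueError(
                "singular penalized normal equations; raise lam above 0 or choose "
                f"n_basis <= {len(y)}"
            )
        # direct least squares: avoids squaring the condition number at the
        # interpolation limit; one step of iterative refinement for accuracy
        c, *_ = np.linalg.lstsq(Phi, y, rcond=None)
        dc, *_ = np.linalg.lstsq(Phi, y - Phi @ c, rcond=None)
        return FunctionalFit(spec, c + dc, 0.0)
    R = penalty_matrix(spec)
    A = _penalized_normal_matrix(Phi, R, lam)
    try:
        c = cho_solve(cho_factor(A), Phi.T @ y)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - message path
        raise ValueError(
            "singular penalized normal equations; raise lam above 0 or choose "
            f"n_basis <= {len(y)}"
        ) from exc
    if not np.all(np.isfinite(c)):
        raise ValueError(
            "singular penalized normal equations; raise lam above 0 or choose "
            f"n_basis <= {len(y)}"
        )
    return FunctionalFit(spec, c, lam)


def smoother_matrix(spec: BasisSpec, grid: np.ndarray, lam: float) -> np.ndarray:
    """Hat matrix S with fitted = S @ y for data sampled on ``grid``."""
    grid = np.asarray(grid, dtype=float)
    Phi = eval_basis(spec, grid)
    R = penalty_matrix(spec)
    A = _penalized_normal_matrix(Phi, R, lam)
    return Phi @ cho_solve(cho_factor(A), Phi.T)


def gcv_select(
    curves: np.ndarray,
    grid: np.ndarray,
    spec: BasisSpec,
    lambda_grid: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Choose the smoothing parameter minimizing the mean GCV score.

    The per-curve score is the Craven-Wahba form ``(RSS/n) / (1 - tr(S)/n)^2``
    and scores are averaged across curves.  Ties are broken toward the larger
    lambda.

    Returns the selected lambda and the vector of mean scores (one per grid
    value).
    """
    lambda_grid = np.atleast_1d(np.asarray(lambda_grid, dtype=float))
    if lambda_grid.size == 0:
        raise ValueError("lambda_grid must be non-empty")
    Y = np.atleast_2d(np.asarray(curves, dtype=float))  # (n_curves, n_points)
    n = Y.shape[1]
    scores = np.empty(lambda_grid.size)
    for i, lam in enumerate(lambda_grid):
        S = smoother_matrix(spec, grid, lam)
        tr = np.trace(S)
        resid = Y - Y @ S.T
        rss = np.sum(resid**2, axis=1)
        scores[i] = np.mean((rss / n) / (1.0 - tr / n) ** 2)
    best = scores.min()
    # ties (within floating fuzz) broken toward the larger lambda
    idx = np.flatnonzero(scores <= best * (1 + 1e-12))
    order = np.argsort(lambda_grid[idx])
    return float(lambda_grid[idx[order[-1]]]), scores
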