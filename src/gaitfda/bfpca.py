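"""Bivariate functional PCA of concurrent joint-angle couples.

Each run contributes a pair of smoothed curves (e.g. hip and knee over the
stride cycle).  The pair is represented by stacked B-spline coefficient
vectors; principal components are eigenfunctions of the sample covariance in
the inner product induced by the basis Gram matrix, so components are
orthonormal as *functions*, not merely as coefficient vectors.  The leading
components can be varimax-rotated (on their grid-discretized values) for
interpretability, and each component is visualized by perturbing the
bivariate mean by +/- a multiple of the component-score SD.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from statsmodels.multivariate.factor_rotation import rotate_factors

from .fdsmooth import BasisSpec, eval_basis, gram_matrix, smooth_curve
from .types import GRID, StrideCurve

__all__ = [
    "BivariateFit",
    "BfpcaResult",
    "fit_bivariate",
    "decompose",
    "varimax_rotate",
    "perturbation_curves",
    "condition_mean_scores",
]


@dataclass
class BivariateFit:
    """Smoothed coefficient pair for one run's joint couple."""

    basis: BasisSpec
    coefA: np.ndarray
    coefB: np.ndarray
    participant: str = ""
    condition: str = ""
    run: int = 0

    def stacked(self) -> np.ndarray:
        return np.concatenate([self.coefA, self.coefB])


def fit_bivariate(
    curvesA: list[StrideCurve],
    curvesB: list[StrideCurve],
    lam: float,
    spec: BasisSpec | None = None,
) -> list[BivariateFit]:
    """Smooth matched curve pairs with a shared basis and smoothing parameter.

    Runs are matched on (participant, condition, run); unmatched runs on
    either side are rejected with a list of the orphans.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if spec is None:
        spec = BasisSpec(kind="bspline", order=4, n_basis=15)
    keyA = {(c.participant, c.condition, c.run): c for c in curvesA}
    keyB = {(c.participant, c.condition, c.run): c for c in curvesB}
    orphans = set(keyA) ^ set(keyB)
    if orphans:
        raise ValueError(f"unmatched runs between the two joints: {sorted(orphans)}")
    fits = []
    for key in sorted(keyA):
        a, b = keyA[key], keyB[key]
        fa = smooth_curve(a.values, a.grid, spec, lam)
        fb = smooth_curve(b.values, b.grid, spec, lam)
        fits.append(
            BivariateFit(spec, fa.coefficients, fb.coefficients, *key)
        )
    return fits


@dataclass
class BfpcaResult:
    """Bivariate functional PCA decomposition (optionally varimax-rotated)."""

    basis: BasisSpec
    mean: np.ndarray  # stacked mean coefficients (2M,)
    components: np.ndarray  # (2M, K) stacked component coefficients
    raw_eigenvalues: np.ndarray  # variances before any rotation
    var_explained: np.ndarray  # proportion per current component
    scores: np.ndarray  # (n_runs, K)
    total_variance: float
    rotation: np.ndarray | None = None  # orthogonal matrix applied to leading comps
    metadata: pd.DataFrame | None = None

    @property
    def K(self) -> int:
        return self.components.shape[1]

    def _split(self, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        m = self.basis.n_basis
        return v[:m], v[m:]

    def mean_on_grid(self, grid: np.ndarray = GRID) -> tuple[np.ndarray, np.ndarray]:
        Phi = eval_basis(self.basis, grid)
        a, b = self._split(self.mean)
        return Phi @ a, Phi @ b

    def component_on_grid(
        self, k: int, grid: np.ndarray = GRID
    ) -> tuple[np.ndarray, np.ndarray]:
        Phi = eval_basis(self.basis, grid)
        a, b = self._split(self.components[:, k])
        return Phi @ a, Phi @ b


def _bivariate_gram(spec: BasisSpec) -> np.ndarray:
    G = gram_matrix(spec)
    m = spec.n_basis
    W = np.zeros((2 * m, 2 * m))
    W[:m, :m] = G
    W[m:, m:] = G
    return W


def _canonical_signs(result: BfpcaResult) -> BfpcaResult:
    """Orient each component so its largest-magnitude grid value is positive."""
    comps = result.components.copy()
    scores = result.scores.copy()
    Phi = eval_basis(result.basis, GRID)
    m = result.basis.n_basis
    for k in range(comps.shape[1]):
        vals = np.concatenate([Phi @ comps[:m, k], Phi @ comps[m:, k]])
        if vals[np.argmax(np.abs(vals))] < 0:
            comps[:, k] *= -1.0
            scores[:, k] *= -1.0
    return replace(result, components=comps, scores=scores)


def decompose(fits: list[BivariateFit], K: int = 4) -> BfpcaResult:
    """Eigendecomposition of the bivariate covariance in the Gram metric.

    Scores are projections of the centered fits onto the components under the
    bivariate functional inner product; eigenvalues are non-increasing and sum
    to the total functional variance.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    n = len(fits)
    if n < K + 1:
        raise ValueError(f"need at least K+1 = {K + 1} runs, got {n}")
    spec = fits[0].basis
    C = np.array([f.stacked() for f in fits])
    mean = C.mean(axis=0)
    Cc = C - mean
    W = _bivariate_gram(spec)
    L = np.linalg.cholesky(W)
    Y = Cc @ L  # coordinates in the W-metric
    cov = Y.T @ Y / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    rank = min(n - 1, 2 * spec.n_basis)
    if K > rank:
        raise ValueError(f"K = {K} exceeds the available rank {rank}")
    comps = np.linalg.solve(L.T, evecs[:, :K])
    scores = Y @ evecs[:, :K]
    total = float(evals.sum())
    meta = pd.DataFrame(
        {
            "participant": [f.participant for f in fits],
            "condition": [f.condition for f in fits],
            "run": [f.run for f in fits],
        }
    )
    result = BfpcaResult(
        basis=spec,
        mean=mean,
        components=comps,
        raw_eigenvalues=evals[:K].copy(),
        var_explained=evals[:K] / total,
        scores=scores,
        total_variance=total,
        metadata=meta,
    )
    return _canonical_signs(result)


def varimax_rotate(result: BfpcaResult, K_rot: int = 2) -> BfpcaResult:
    """Varimax-rotate the leading components (and their scores).

    The rotation is computed on the component functions discretized to the
    101-point grid with both joints stacked (no Kaiser normalization).  The
    spanned subspace, the total variance in it, and Gram-orthonormality are
    preserved; per-component explained variance is recomputed from the rotated
    score variances and components are reordered by decreasing variance.
    """
    if K_rot < 1:
        raise ValueError("K_rot must be >= 1")
    if K_rot > result.K:
        raise ValueError(f"K_rot = {K_rot} exceeds available components {result.K}")
    if K_rot == 1:
        return replace(result, rotation=np.eye(1))
    Phi = eval_basis(result.basis, GRID)
    m = result.basis.n_basis
    Lmb = np.vstack(
        [Phi @ result.components[:m, :K_rot], Phi @ result.components[m:, :K_rot]]
    )
    _, T = rotate_factors(Lmb, "varimax")
    comps = result.components.copy()
    scores = result.scores.copy()
    comps[:, :K_rot] = comps[:, :K_rot] @ T
    scores[:, :K_rot] = scores[:, :K_rot] @ T
    # reorder the rotated block by decreasing score variance
    v = scores[:, :K_rot].var(axis=0, ddof=1)
    order = np.argsort(v)[::-1]
    comps[:, :K_rot] = comps[:, order]
    scores[:, :K_rot] = scores[:, order]
    var_explained = scores.var(axis=0, ddof=1) / result.total_variance
    rotated = replace(
        result,
        components=comps,
        scores=scores,
        var_explained=var_explained,
        rotation=T[:, order],
    )
    return _canonical_signs(rotated)


def perturbation_curves(
    result: BfpcaResult, component_index: int, sd_mult: float = 2.0, grid: np.ndarray = GRID
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Mean and mean +/- ``sd_mult`` score-SDs along one component.

    Returns ``{"mean": (A, B), "plus": (A, B), "minus": (A, B)}`` evaluated on
    the grid for both joints of the couple.
    """
    if not 0 <= component_index < result.K:
        raise ValueError("component does not exist")
    sd = float(result.scores[:, component_index].std(ddof=1))
    mA, mB = result.mean_on_grid(grid)
    cA, cB = result.component_on_grid(component_index, grid)
    return {
        "mean": (mA, mB),
        "plus": (mA + sd_mult * sd * cA, mB + sd_mult * sd * cB),
        "minus": (mA - sd_mult * sd * cA, mB - sd_mult * sd * cB),
    }


def condition_mean_scores(result: BfpcaResult, n_components: int = 2) -> pd.DataFrame:
    """Mean component scores within each participant-condition cell."""
    if result.metadata is None:
        raise ValueError("result carries no run metadata")
    df = result.metadata.copy()
    for k in range(min(n_components, result.K)):
        df[f"score{k + 1}"] = result.scores[:, k]
    return (
        df.groupby(["participant", "condition"], sort=True)
        .mean(numeric_only=True)
        .drop(columns=["run"])
        .reset_index()
    )
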