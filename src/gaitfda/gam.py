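"""Additive models for stride-cycle angle data with run random effects.

One model per joint: angle = intercept + condition offsets + per-condition
cyclic smooths of %-cycle + per-run random intercepts + residual noise.  The
smooths use cyclic cubic regression splines (value and first two derivatives
match across the 0/100% seam) with a sum-to-zero constraint so the parametric
condition offsets remain identifiable.  Smoothing parameters and the
run-intercept variance are selected by restricted maximum likelihood (REML)
through the mixed-model representation of penalized splines; the run
intercepts are recovered as shrunken (BLUP-style) estimates whose spread
within a participant-condition cell quantifies between-run movement
variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.linalg import cho_factor, cho_solve, null_space

from .fdsmooth import BasisSpec, eval_basis, penalty_matrix
from .types import StrideCurve

__all__ = [
    "cyclic_basis",
    "GAMDesign",
    "GAMFit",
    "build_design",
    "fit_gam",
    "select_knots",
    "run_variability",
]


def cyclic_basis(n_knots: int) -> tuple[BasisSpec, np.ndarray]:
    """Cyclic cubic regression-spline basis on [0, 100] with its penalty.

    ``n_knots`` is the number of free periodic basis functions.  The penalty
    is the integrated squared second derivative on the circle; its null space
    is the constant function.
    """
    if n_knots < 4:
        raise ValueError("n_knots must be >= 4 for a cyclic cubic basis")
    spec = BasisSpec(kind="cyclic", order=4, n_basis=n_knots)
    return spec, penalty_matrix(spec)


@dataclass
class GAMDesign:
    """Stacked long-format data for one joint plus the model layout."""

    y: np.ndarray
    pct: np.ndarray
    condition: np.ndarray
    run_id: np.ndarray
    baseline: str = "BW"
    n_knots: int = 10

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.pct = np.asarray(self.pct, dtype=float)
        self.condition = np.asarray(self.condition)
        self.run_id = np.asarray(self.run_id)
        n = self.y.size
        if not (self.pct.size == n and self.condition.size == n and self.run_id.size == n):
            raise ValueError("y, pct, condition and run_id must be aligned")
        if self.baseline not in set(self.condition):
            raise ValueError(f"baseline {self.baseline!r} absent from condition column")

    @property
    def conditions(self) -> list[str]:
        others = sorted(set(map(str, self.condition)) - {self.baseline})
        return [self.baseline] + others


def design_from_strides(
    strides: list[StrideCurve], joint: str, baseline: str = "BW", n_knots: int = 10
) -> GAMDesign:
    """Stack all strides of one joint into a long-format GAM design."""
    rows = [s for s in strides if s.joint == joint]
    if not rows:
        raise ValueError(f"no strides for joint {joint!r}")
    m = rows[0].values.size
    grid = rows[0].grid
    y = np.concatenate([s.values for s in rows])
    pct = np.tile(grid, len(rows))
    cond = np.repeat([s.condition for s in rows], m)
    run = np.repeat([f"{s.participant}|{s.condition}|{s.run}" for s in rows], m)
    return GAMDesign(y, pct, cond, run, baseline=baseline, n_knots=n_knots)


@dataclass
class _Assembled:
    """Precomputed pieces of the penalized normal equations."""

    WtW: np.ndarray
    Wty: np.ndarray
    yty: float
    n: int
    p: int  # unpenalized (parametric) columns
    smooth_slices: list[slice]
    run_slice: slice
    penalties: list[np.ndarray]
    logdet_pen: list[float]
    W: sparse.csr_matrix
    conditions: list[str]
    run_levels: np.ndarray
    Q: list[np.ndarray]  # constraint null-space bases per smooth


def build_design(design: GAMDesign) -> _Assembled:
    """Assemble the sparse model matrix and penalty blocks.

    Layout of coefficients: [intercept, condition offsets (non-baseline),
    constrained cyclic smooth per condition (baseline first), run intercepts].
    Each smooth carries a sum-to-zero constraint absorbed by a null-space
    reparameterization, which makes its penalty positive definite.
    """
    conds = design.conditions
    n = design.y.size
    spec, R = cyclic_basis(design.n_knots)
    k = design.n_knots

    cols: list[sparse.spmatrix] = []
    # parametric block
    X = np.ones((n, len(conds)))
    for j, c in enumerate(conds[1:], start=1):
        X[:, j] = (design.condition == c).astype(float)
    cols.append(sparse.csr_matrix(X))
    p = len(conds)

    smooth_slices: list[slice] = []
    penalties: list[np.ndarray] = []
    logdet_pen: list[float] = []
    Qs: list[np.ndarray] = []
    offset = p
    B_full_cache: dict[bytes, np.ndarray] = {}
    for c in conds:
        mask = np.asarray(design.condition == c)
        pts = design.pct[mask]
        key = pts.tobytes()
        if key not in B_full_cache:
            B_full_cache[key] = eval_basis(spec, pts)
        B = B_full_cache[key]
        q = B.sum(axis=0)[:, None]  # sum-to-zero constraint direction
        Q = null_space(q.T)  # (k, k-1)
        Bq = B @ Q
        Rq = Q.T @ R @ Q
        block = sparse.lil_matrix((n, k - 1))
        block[np.flatnonzero(mask), :] = Bq
        cols.append(block.tocsr())
        smooth_slices.append(slice(offset, offset + k - 1))
        penalties.append(Rq)
        sign, ld = np.linalg.slogdet(Rq)
        if sign <= 0:
            raise ValueError("constrained cyclic penalty not positive definite")
        logdet_pen.append(ld)
        Qs.append(Q)
        offset += k - 1

    run_levels, run_codes = np.unique(design.run_id, return_inverse=True)
    Z = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), run_codes)), shape=(n, len(run_levels))
    )
    cols.append(Z)
    run_slice = slice(offset, offset + len(run_levels))

    W = sparse.hstack(cols).tocsr()
    WtW = np.asarray((W.T @ W).todense())
    Wty = W.T @ design.y
    return _Assembled(
        WtW=WtW,
        Wty=np.asarray(Wty).ravel(),
        yty=float(design.y @ design.y),
        n=n,
        p=p,
        smooth_slices=smooth_slices,
        run_slice=run_slice,
        penalties=penalties,
        logdet_pen=logdet_pen,
        W=W,
        conditions=conds,
        run_levels=run_levels,
        Q=Qs,
    )


def _penalty_total(asm: _Assembled, theta: np.ndarray) -> tuple[np.ndarray, float]:
    """Total penalty matrix S(theta) and log pseudo-determinant log|S|_+.

    ``theta`` holds log-lambdas per smooth followed by log-gamma for the run
    block (gamma = sigma^2 / sigma_run^2).
    """
    m = asm.WtW.shape[0]
    S = np.zeros((m, m))
    logdet = 0.0
    for i, sl in enumerate(asm.smooth_slices):
        lam = np.exp(theta[i])
        S[sl, sl] += lam * asm.penalties[i]
        kk = sl.stop - sl.start
        logdet += kk * theta[i] + asm.logdet_pen[i]
    gamma = np.exp(theta[-1])
    rs = asm.run_slice
    S[rs, rs] += gamma * np.eye(rs.stop - rs.start)
    logdet += (rs.stop - rs.start) * theta[-1]
    return S, logdet


def _reml(asm: _Assembled, theta: np.ndarray) -> tuple[float, np.ndarray, float]:
    """-2 * restricted log-likelihood (profiled over sigma^2), coefs, sigma^2.

    Uses the identity -2 l_r = (n - p) log(2 pi sigma^2) + Dp / sigma^2
    + log|W'W + S| - log|S|_+ with Dp the minimized penalized sum of squares
    and p the number of unpenalized coefficients.
    """
    S, logdet_S = _penalty_total(asm, theta)
    A = asm.WtW + S
    try:
        cf = cho_factor(A)
    except np.linalg.LinAlgError:
        return np.inf, np.zeros(A.shape[0]), np.nan
    delta = cho_solve(cf, asm.Wty)
    Dp = asm.yty - float(delta @ asm.Wty)
    Dp = max(Dp, 1e-300)
    nmp = asm.n - asm.p
    sigma2 = Dp / nmp
    logdet_A = 2.0 * np.sum(np.log(np.diag(cf[0])))
    crit = nmp * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdet_A - logdet_S
    return crit, delta, sigma2


@dataclass
class GAMFit:
    """Fitted additive model for one joint."""

    conditions: list[str]
    intercept: float
    offsets: dict[str, float]
    se: dict[str, float]
    t_values: dict[str, float]
    edf: dict[str, float]
    lambdas: dict[str, float]
    sigma2: float  # residual variance (deg^2)
    sigma_run2: float  # run-intercept variance component (deg^2)
    random_effects: pd.DataFrame  # participant, condition, run, estimate
    deviance_explained: float
    coefficients: np.ndarray
    reml_criterion: float
    criterion_trace: list[float]
    design: GAMDesign = field(repr=False, default=None)
    _assembled: _Assembled = field(repr=False, default=None)

    def smooth_values(self, condition: str, grid: np.ndarray) -> np.ndarray:
        """Evaluate the fitted (centered) cyclic smooth for one condition."""
        asm = self._assembled
        i = asm.conditions.index(condition)
        spec, _ = cyclic_basis(self.design.n_knots)
        B = eval_basis(spec, grid)
        sl = asm.smooth_slices[i]
        return B @ (asm.Q[i] @ self.coefficients[sl])

    def fitted_mean_curve(self, condition: str, grid: np.ndarray) -> np.ndarray:
        """Population-level fitted curve for one condition."""
        out = self.intercept + self.smooth_values(condition, grid)
        if condition in self.offsets:
            out = out + self.offsets[condition]
        return out


def fit_gam(
    design: GAMDesign,
    n_starts: int = 3,
    maxiter: int = 200,
    tol: float = 1e-6,
) -> GAMFit:
    """Fit the penalized additive model by REML.

    Smoothing parameters (one per condition smooth) and the run-intercept
    variance are chosen to maximize the restricted likelihood; optimization is
    quasi-Newton on the log scale with multiple starts to guard against local
    optima.
    """
    counts = pd.Series(design.run_id).groupby(pd.Series(design.condition)).nunique()
    if (counts < 2).any():
        raise ValueError("need at least 2 runs per condition")
    asm = build_design(design)
    n_theta = len(asm.smooth_slices) + 1
    starts = [np.zeros(n_theta), np.full(n_theta, 4.0), np.full(n_theta, -4.0)][:n_starts]
    trace: list[float] = []

    def objective(theta: np.ndarray) -> float:
        crit, _, _ = _reml(asm, theta)
        trace.append(crit)
        return crit

    best = None
    for x0 in starts:
        res = optimize.minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=[(-18.0, 18.0)] * n_theta,
            options={"maxiter": maxiter, "ftol": tol, "eps": 1e-4},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(
            f"REML optimization failed to converge; criterion trace: {trace[-20:]}"
        )
    theta = best.x
    crit, delta, sigma2 = _reml(asm, theta)

    S, _ = _penalty_total(asm, theta)
    A = asm.WtW + S
    cf = cho_factor(A)
    Ainv_WtW = cho_solve(cf, asm.WtW)
    edf_per_coef = np.diag(Ainv_WtW)
    edf_total = float(edf_per_coef.sum())

    delta = cho_solve(cf, asm.Wty)
    fitted = asm.W @ delta
    rss = float(np.sum((design.y - fitted) ** 2))
    # reported residual variance: RSS / (n - total EDF), the usual GAM scale
    scale = rss / (asm.n - edf_total)
    Vb = scale * cho_solve(cf, np.eye(A.shape[0]))
    se_all = np.sqrt(np.clip(np.diag(Vb), 0, None))

    conds = asm.conditions
    names = ["(Intercept)"] + conds[1:]
    est = {nm: float(delta[j]) for j, nm in enumerate(names)}
    se = {nm: float(se_all[j]) for j, nm in enumerate(names)}
    tv = {nm: est[nm] / se[nm] if se[nm] > 0 else np.nan for nm in names}
    edf = {
        c: float(edf_per_coef[sl].sum())
        for c, sl in zip(conds, asm.smooth_slices)
    }
    lambdas = {c: float(np.exp(theta[i])) for i, c in enumerate(conds)}
    gamma = float(np.exp(theta[-1]))

    tss = float(np.sum((design.y - design.y.mean()) ** 2))
    dev_expl = 1.0 - rss / tss if tss > 0 else np.nan

    b = delta[asm.run_slice]
    meta = []
    for lv in asm.run_levels:
        parts = str(lv).split("|")
        if len(parts) == 3:
            meta.append(parts)
        else:
            meta.append(["", "", str(lv)])
    ranef = pd.DataFrame(
        {
            "participant": [m[0] for m in meta],
            "condition": [m[1] for m in meta],
            "run": [int(m[2]) if m[2].lstrip("-").isdigit() else m[2] for m in meta],
            "estimate": b,
        }
    )

    return GAMFit(
        conditions=conds,
        intercept=est["(Intercept)"],
        offsets={c: est[c] for c in conds[1:]},
        se=se,
        t_values=tv,
        edf=edf,
        lambdas=lambdas,
        sigma2=float(scale),
        sigma_run2=float(sigma2 / gamma),
        random_effects=ranef,
        deviance_explained=float(dev_expl),
        coefficients=delta,
        reml_criterion=float(crit),
        criterion_trace=trace,
        design=design,
        _assembled=asm,
    )


def select_knots(
    design: GAMDesign,
    max_knots: int = 30,
    min_knots: int = 5,
    step: int = 1,
    tol_pp: float = 0.05,
    n_starts: int = 1,
) -> int:
    """Escalate the knot count until deviance explained stops improving.

    Refits with increasing ``n_knots`` and stops as soon as the gain in
    deviance explained falls below ``tol_pp`` percentage points, returning the
    smallest such knot count.
    """
    if max_knots < 5:
        raise ValueError("max_knots must be >= 5")
    prev_dev = None
    prev_k = None
    for k in range(min_knots, max_knots + 1, step):
        d = GAMDesign(
            design.y, design.pct, design.condition, design.run_id,
            baseline=design.baseline, n_knots=k,
        )
        fit = fit_gam(d, n_starts=n_starts)
        if prev_dev is not None and (fit.deviance_explained - prev_dev) * 100.0 < tol_pp:
            return prev_k
        prev_dev, prev_k = fit.deviance_explained, k
    return prev_k


def run_variability(fit: GAMFit) -> pd.DataFrame:
    """SD of estimated run intercepts within each participant-condition cell.

    Cells with a single run are flagged and reported with a missing SD.
    """
    df = fit.random_effects
    out = (
        df.groupby(["participant", "condition"], sort=True)["estimate"]
        .agg(sd=lambda s: s.std(ddof=1) if len(s) > 1 else np.nan, n_runs="size")
        .reset_index()
    )
    out["singleton"] = out["n_runs"] < 2
    return out
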