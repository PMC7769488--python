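"""Cyclic-spline additive models with run random intercepts (REML)."""


import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from gaitfda.fdsmooth import eval_basis
from gaitfda.gam import (
    GAMDesign,
    _penalty_total,
    _reml,
    build_design,
    cyclic_basis,
    design_from_strides,
    fit_gam,
    run_variability,
    select_knots,
)
from gaitfda.synthetic import SimConfig, generate_strides
from gaitfda.types import GRID


def _simulate(seed=0, **kw):
    defaults = dict(
        n_participants=2, n_runs_per_condition=4,
        conditions=("BW", "1%", "3%", "5%"), baseline="BW",
        sigma_participant=0.0, joints=("hip",), seed=seed,
    )
    defaults.update(kw)
    return generate_strides(SimConfig(**defaults))


class TestCyclicBasis:
    def test_requires_at_least_four_knots(self):
        with pytest.raises(ValueError, match=">= 4"):
            cyclic_basis(3)

    def test_fitted_smooth_periodic_to_machine_precision(self, rng):
        spec, R = cyclic_basis(10)
        c = rng.normal(size=10)
        B = eval_basis(spec, np.array([0.0, 100.0]))
        assert abs(B[0] @ c - B[1] @ c) < 1e-10

    def test_first_derivative_matches_across_seam(self, rng):
        """Finite-difference oracle across the 0/100 wrap."""
        spec, _ = cyclic_basis(12)
        c = rng.normal(size=12)
        h = 1e-4
        f = lambda u: (eval_basis(spec, np.atleast_1d(u)) @ c)[0]
        fd_across_seam = (f(h) - f(100.0 - h)) / (2 * h)  # central, wrapping
        analytic = (eval_basis(spec, np.array([0.0]), deriv=1) @ c)[0]
        assert abs(fd_across_seam - analytic) < 1e-6

    def test_constant_is_penalty_free(self):
        spec, R = cyclic_basis(8)
        ones = np.ones(8)
        assert abs(ones @ R @ ones) < 1e-9
        # and exactly representable: basis sums to one
        B = eval_basis(spec, GRID)
        assert np.allclose(B @ ones, 1.0, atol=1e-12)


class TestFitGam:
    def test_noiseless_offset_recovery(self):
        """Known condition offsets with zero random effects and noise are
        recovered to within 0.01 degrees."""
        ds = _simulate(
            sigma_run=0.0, sigma_noise=0.0,
            condition_offsets=(("1%", -0.7), ("3%", -0.1), ("5%", -0.7)),
        )
        fit = fit_gam(design_from_strides(ds.strides, "hip", n_knots=10))
        assert fit.offsets["1%"] == pytest.approx(-0.7, abs=0.01)
        assert fit.offsets["3%"] == pytest.approx(-0.1, abs=0.01)
        assert fit.offsets["5%"] == pytest.approx(-0.7, abs=0.01)

    def test_blup_recovery_correlates_with_truth(self):
        ds = _simulate(seed=5, n_participants=2, n_runs_per_condition=5,
                       sigma_run=2.0, sigma_noise=1.0)
        fit = fit_gam(design_from_strides(ds.strides, "hip", n_knots=10))
        truth = {
            (p, c, r): v for (p, c, r, j), v in ds.run_intercepts.items()
        }
        tv = [truth[(row.participant, row.condition, row.run)]
              for row in fit.random_effects.itertuples()]
        assert np.corrcoef(fit.random_effects["estimate"], tv)[0, 1] >= 0.9

    def test_zero_between_run_variance_shrinks_blups(self):
        # near-white noise so the generating model matches the fitted one
        ds = _simulate(seed=6, sigma_run=0.0, sigma_noise=1.0, noise_bandwidth=1e-3)
        fit = fit_gam(design_from_strides(ds.strides, "hip", n_knots=8))
        assert np.abs(fit.random_effects["estimate"]).max() < 0.05

    def test_edf_bounds_and_deviance_range(self):
        ds = _simulate(seed=7, sigma_run=1.0, sigma_noise=1.0)
        fit = fit_gam(design_from_strides(ds.strides, "hip", n_knots=9))
        for c, e in fit.edf.items():
            assert 0.0 <= e <= 9.0
        assert 0.0 <= fit.deviance_explained <= 1.0

    def test_requires_two_runs_per_condition(self):
        ds = _simulate(seed=8, n_participants=1, n_runs_per_condition=1,
                       sigma_run=0, sigma_noise=0.5)
        with pytest.raises(ValueError, match="2 runs"):
            fit_gam(design_from_strides(ds.strides, "hip"))

    def test_unpenalized_limit_matches_least_squares(self):
        """With lambda -> 0 and the run block unshrunken the penalized fit
        equals ordinary least squares (small-design oracle)."""
        ds = _simulate(seed=9, n_participants=1, n_runs_per_condition=3,
                       conditions=("BW", "5%"), sigma_run=1.0, sigma_noise=1.0)
        d = design_from_strides(ds.strides, "hip", n_knots=6)
        asm = build_design(d)
        theta = np.full(3, -16.0)  # tiny lambdas and gamma
        _, delta, _ = _reml(asm, theta)
        W = asm.W.toarray()
        ls, *_ = np.linalg.lstsq(W, d.y, rcond=None)
        # the run-indicator block is collinear with the intercept, so compare
        # fitted values rather than coefficients
        assert np.allclose(W @ delta, W @ ls, atol=1e-6)

    def test_reml_optimum_beats_random_draws(self):
        ds = _simulate(seed=10, n_participants=1, n_runs_per_condition=3,
                       conditions=("BW", "5%"), sigma_run=1.0, sigma_noise=1.0)
        d = design_from_strides(ds.strides, "hip", n_knots=7)
        fit = fit_gam(d)
        asm = build_design(d)
        opt = fit.reml_criterion
        rng = np.random.default_rng(0)
        for _ in range(10):
            crit, _, _ = _reml(asm, rng.uniform(-8, 8, size=3))
            assert opt <= crit + 1e-6

    def test_edf_decreases_with_lambda(self):
        ds = _simulate(seed=11, n_participants=1, n_runs_per_condition=3,
                       conditions=("BW",), sigma_run=0.5, sigma_noise=1.0)
        d = design_from_strides(ds.strides, "hip", n_knots=10)
        asm = build_design(d)

        def edf_at(loglam):
            S, _ = _penalty_total(asm, np.array([loglam, 2.0]))
            A = asm.WtW + S
            M = np.linalg.solve(A, asm.WtW)
            sl = asm.smooth_slices[0]
            return np.trace(M[sl, sl])

        vals = [edf_at(l) for l in (-6.0, -2.0, 2.0, 6.0)]
        assert all(a >= b - 1e-8 for a, b in zip(vals, vals[1:]))

    def test_baseline_relabel_contrast_consistency(self):
        ds = _simulate(seed=12, n_participants=1, n_runs_per_condition=4,
                       conditions=("BW", "5%"), sigma_run=1.0, sigma_noise=1.0)
        f1 = fit_gam(design_from_strides(ds.strides, "hip", baseline="BW", n_knots=8))
        f2 = fit_gam(design_from_strides(ds.strides, "hip", baseline="5%", n_knots=8))
        assert f2.offsets["BW"] == pytest.approx(-f1.offsets["5%"], abs=0.02)
        assert f2.intercept == pytest.approx(f1.intercept + f1.offsets["5%"], abs=0.02)


class TestSelectKnots:
    def test_constant_data_keeps_minimal_knots(self):
        rng = np.random.default_rng(1)
        n_runs = 4
        y = np.concatenate([10.0 + 0.01 * rng.standard_normal(101) for _ in range(n_runs)])
        pct = np.tile(GRID, n_runs)
        cond = np.repeat(["BW"] * n_runs, 101)
        run = np.repeat(np.arange(n_runs).astype(str), 101)
        d = GAMDesign(y, pct, cond, run, baseline="BW")
        assert select_knots(d, max_knots=9, min_knots=5) == 5

    def test_template_data_self_consistent_with_exhaustive_fit(self):
        ds = _simulate(seed=13, n_participants=1, n_runs_per_condition=4,
                       conditions=("BW",), sigma_run=0.0, sigma_noise=0.5)
        d = design_from_strides(ds.strides, "hip", n_knots=5)
        k = select_knots(d, max_knots=14, min_knots=5)
        assert 5 <= k <= 14
        dev_k = fit_gam(GAMDesign(d.y, d.pct, d.condition, d.run_id,
                                  n_knots=k, baseline="BW"), n_starts=1).deviance_explained
        dev_max = fit_gam(GAMDesign(d.y, d.pct, d.condition, d.run_id,
                                    n_knots=14, baseline="BW"), n_starts=1).deviance_explained
        assert dev_max - dev_k < 0.001

    def test_deviance_monotone_in_knots(self):
        ds = _simulate(seed=14, n_participants=1, n_runs_per_condition=3,
                       conditions=("BW",), sigma_run=0.0, sigma_noise=1.0)
        devs = []
        for k in (5, 8, 12):
            d = design_from_strides(ds.strides, "hip", n_knots=k)
            devs.append(fit_gam(d, n_starts=1).deviance_explained)
        assert all(b >= a - 5e-3 for a, b in zip(devs, devs[1:]))


class TestRunVariability:
    def test_location_invariance_and_zero_sd(self):
        ds = _simulate(seed=15, sigma_run=1.5, sigma_noise=0.5)
        fit = fit_gam(design_from_strides(ds.strides, "hip", n_knots=8))
        rv = run_variability(fit)
        assert not rv["singleton"].any()
        # location invariance: shift every angle by a constant
        shifted = [type(s)(s.values + 3.0, joint=s.joint, participant=s.participant,
                           condition=s.condition, run=s.run) for s in ds.strides]
        fit2 = fit_gam(design_from_strides(shifted, "hip", n_knots=8))
        rv2 = run_variability(fit2)
        assert np.allclose(rv["sd"], rv2["sd"], atol=1e-3)

    def test_doubled_sigma_run_detected_in_most_replicates(self):
        wins, total = 0, 40
        for rep in range(total):
            ds = generate_strides(SimConfig(
                n_participants=1, n_runs_per_condition=10,
                conditions=("BW", "5%"), baseline="BW",
                sigma_run=1.0, sigma_participant=0.0, sigma_noise=1.0,
                joints=("hip",), seed=2000 + rep,
            ))
            # double the run spread in the loaded condition
            doubled = []
            truth = ds.run_intercepts
            for s in ds.strides:
                v = s.values.copy()
                if s.condition == "5%":
                    v = v + truth[(s.participant, s.condition, s.run, s.joint)]
                doubled.append(type(s)(v, joint=s.joint, participant=s.participant,
                                       condition=s.condition, run=s.run))
            fit = fit_gam(design_from_strides(doubled, "hip", n_knots=6), n_starts=1)
            rv = run_variability(fit).set_index("condition")
            if rv.loc["5%", "sd"] > rv.loc["BW", "sd"]:
                wins += 1
        assert wins >= 0.9 * total


def test_matches_mgcv_reference_fit(tmp_path):
    """Independent oracle: the same model structure fit by R mgcv (per-
    condition cyclic smooths + run random intercepts, REML) agrees on the
    parametric terms, their standard errors and the variance components."""
    ds = _simulate(seed=21, n_participants=3, n_runs_per_condition=4,
                   conditions=("BW", "5%"), sigma_run=1.5, sigma_noise=1.0,
                   condition_offsets=(("5%", -0.7),))
    d = design_from_strides(ds.strides, "hip", n_knots=8)
    fit = fit_gam(d)
    csv = tmp_path / "dat.csv"
    pd.DataFrame({"y": d.y, "pct": d.pct, "cond": d.condition, "run": d.run_id}).to_csv(
        csv, index=False
    )
    script = tmp_path / "fit.R"
    script.write_text(textwrap.dedent(f"""
        library(mgcv)
        d <- read.csv("{csv}")
        d$cond <- factor(d$cond, levels=c("BW","5%"))
        d$run <- factor(d$run)
        m <- gam(y ~ cond + s(pct, bs="cc", by=cond, k=8) + s(run, bs="re"),
                 data=d, method="REML", knots=list(pct=seq(0,100,length=8)))
        pt <- summary(m)$p.table
        vc <- gam.vcomp(m)
        cat(pt[1,1], pt[2,1], pt[1,2], pt[2,2], vc["s(run)",1], sep="\\n")
    """))
    out = subprocess.run(
        ["Rscript", str(script)], capture_output=True, text=True, timeout=300
    )
    assert out.returncode == 0, out.stderr
    ref = [float(x) for x in out.stdout.strip().splitlines()[-5:]]
    assert fit.intercept == pytest.approx(ref[0], abs=1e-3)
    assert fit.offsets["5%"] == pytest.approx(ref[1], abs=1e-3)
    assert fit.se["(Intercept)"] == pytest.approx(ref[2], rel=0.02)
    assert fit.se["5%"] == pytest.approx(ref[3], rel=0.02)
    assert np.sqrt(fit.sigma_run2) == pytest.approx(ref[4], rel=0.02)
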