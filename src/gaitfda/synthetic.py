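"""Synthetic gait-curve generator with known ground truth.

Produces stride-cycle joint-angle datasets with the statistical structure the
downstream analyses assume: a fixed periodic template per joint, localized
condition effects (wrapped Gaussian bumps in %-cycle coordinates), a random
baseline offset per participant, a random intercept per run, and smooth
periodic within-curve noise.  Everything is a pure function of the
configuration, including its seed, so every curve can be reproduced exactly.

Also provides raw-signal fixtures (toe-marker vertical displacement and
periodic angle trials) for testing the event-detection and time-normalization
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .types import JOINTS, GRID, AngleSeries, StrideCurve

__all__ = [
    "EffectSpec",
    "SimConfig",
    "SyntheticDataset",
    "MarkerTrial",
    "joint_template",
    "joint_template_fn",
    "generate_strides",
    "generate_marker_trial",
    "generate_angle_trial",
]

# Fourier templates per joint (degrees): mean, then (amplitude, phase) per
# harmonic of the stride cycle.  Shapes are qualitative: the hip makes one
# flexion-extension oscillation per stride, the knee has two flexion peaks
# (swing and weight acceptance), the ankle alternates dorsi-/plantarflexion.
_TEMPLATES: dict[str, tuple[float, tuple[tuple[float, float], ...]]] = {
    "hip": (14.0, ((18.0, 5.0), (2.5, 2.2))),
    "knee": (40.0, ((4.0, 0.0), (12.0, 0.0), (0.8, 1.2))),
    "ankle": (-5.0, ((10.0, 4.0), (7.0, 1.0), (1.5, 0.5))),
}


def joint_template_fn(joint: str) -> Callable[[np.ndarray], np.ndarray]:
    """Continuous periodic template for a joint, callable on %-cycle values."""
    if joint not in _TEMPLATES:
        raise ValueError(
            f"unknown joint {joint!r}; valid joints are {', '.join(JOINTS)}"
        )
    mean, harmonics = _TEMPLATES[joint]

    def f(u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        theta = 2.0 * np.pi * u / 100.0
        out = np.full(u.shape, mean)
        for h, (amp, phase) in enumerate(harmonics, start=1):
            out = out + amp * np.cos(h * theta - phase)
        return out

    return f


def joint_template(joint: str) -> StrideCurve:
    """The joint's noiseless template sampled on the 101-point cycle grid."""
    v = joint_template_fn(joint)(GRID)
    v[100] = v[0]  # close the cycle exactly despite rounding in cos(2*pi)
    return StrideCurve(v, joint=joint)


@dataclass(frozen=True)
class EffectSpec:
    """A localized condition effect: a wrapped Gaussian bump in %-cycle.

    ``amplitude`` is signed in degrees; positive means more flexion
    (hip/knee) or dorsiflexion (ankle).
    """

    joint: str
    condition: str
    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.joint not in JOINTS:
            raise ValueError(f"joint must be one of {JOINTS}")
        if not 0.0 <= self.center <= 100.0:
            raise ValueError("center must lie in [0, 100]")
        if not self.width > 0:
            raise ValueError("width must be positive")
        if not np.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")

    def bump(self, u: np.ndarray) -> np.ndarray:
        """Evaluate the periodically wrapped bump at %-cycle points."""
        u = np.asarray(u, dtype=float)
        out = np.zeros(u.shape)
        for m in range(-3, 4):
            out += np.exp(-((u - self.center + 100.0 * m) ** 2) / (2.0 * self.width**2))
        return self.amplitude * out


@dataclass(frozen=True)
class SimConfig:
    """Design of a synthetic gait study.

    Defaults mirror the study design this generator emulates: four loading
    conditions with an unloaded baseline and ten runs per condition per
    participant.  All standard deviations are in degrees.
    """

    n_participants: int = 14
    n_runs_per_condition: int = 10
    conditions: tuple[str, ...] = ("BW", "1%", "3%", "5%")
    baseline: str = "BW"
    effects: tuple[EffectSpec, ...] = ()
    condition_offsets: tuple[tuple[str, float], ...] = ()  # constant shifts (deg)
    sigma_run: float = 2.0
    sigma_participant: float = 2.0
    sigma_noise: float = 2.0
    noise_bandwidth: float = 3.0  # % of cycle; SD of the periodic smoothing kernel
    joints: tuple[str, ...] = JOINTS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_runs_per_condition < 1:
            raise ValueError("counts must be >= 1")
        if self.baseline not in self.conditions:
            raise ValueError("baseline must be one of conditions")
        for s in (self.sigma_run, self.sigma_participant, self.sigma_noise):
            if s < 0:
                raise ValueError("standard deviations must be >= 0")
        for e in self.effects:
            if e.condition not in self.conditions:
                raise ValueError(
                    f"effect references condition {e.condition!r} not in "
                    f"{self.conditions}"
                )
            if e.joint not in self.joints:
                raise ValueError(f"effect references joint {e.joint!r} not generated")
        for c, _ in self.condition_offsets:
            if c not in self.conditions:
                raise ValueError(f"condition offset references unknown condition {c!r}")


@dataclass
class SyntheticDataset:
    """Generated stride curves plus the realized ground truth."""

    strides: list[StrideCurve]
    config: SimConfig
    participant_offsets: dict[tuple[str, str], float]  # (participant, joint) -> deg
    run_intercepts: dict[tuple[str, str, int, str], float]  # (p, cond, run, joint)

    def curves(self, joint: str, condition: str | None = None) -> np.ndarray:
        """Stack matching curves into an (n, 101) array."""
        sel = [
            s.values
            for s in self.strides
            if s.joint == joint and (condition is None or s.condition == condition)
        ]
        return np.array(sel)

    def metadata(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "participant_id": s.participant,
                    "condition": s.condition,
                    "run_index": s.run,
                    "joint": s.joint,
                }
                for s in self.strides
            ]
        )


def _smooth_periodic_noise(rng: np.random.Generator, sigma: float, bandwidth: float) -> np.ndarray:
    """Periodic noise on the 101-point grid with pointwise SD ``sigma``.

    White noise on the 100 unique phases is circularly convolved with a
    Gaussian kernel (SD ``bandwidth`` in % cycle) normalized to unit energy so
    the marginal SD is preserved; point 100 repeats point 0.
    """
    n = 100
    w = rng.standard_normal(n)
    if sigma == 0:
        return np.zeros(101)
    d = np.arange(n, dtype=float)
    d = np.minimum(d, n - d)  # circular distance
    kern = np.exp(-(d**2) / (2.0 * bandwidth**2))
    kern /= np.sqrt(np.sum(kern**2))
    smooth = np.real(np.fft.ifft(np.fft.fft(w) * np.fft.fft(kern)))
    out = sigma * smooth
    return np.concatenate([out, out[:1]])


def generate_strides(cfg: SimConfig) -> SyntheticDataset:
    """Generate the full synthetic dataset described by ``cfg``.

    Each stride is ``participant offset + joint template + condition bumps +
    run intercept + smooth periodic noise``.  The same configuration (same
    seed) always yields the identical dataset.
    """
    rng = np.random.default_rng(cfg.seed)
    participants = [f"P{i + 1:02d}" for i in range(cfg.n_participants)]
    templates = {j: joint_template(j).values for j in cfg.joints}
    bumps: dict[tuple[str, str], np.ndarray] = {}
    for e in cfg.effects:
        key = (e.joint, e.condition)
        b = e.bump(GRID)
        b[100] = b[0]  # exact periodic closure
        bumps[key] = bumps.get(key, 0.0) + b

    cond_shift = dict(cfg.condition_offsets)
    strides: list[StrideCurve] = []
    p_offsets: dict[tuple[str, str], float] = {}
    r_intercepts: dict[tuple[str, str, int, str], float] = {}
    for p in participants:
        for j in cfg.joints:
            p_offsets[(p, j)] = cfg.sigma_participant * rng.standard_normal()
        for cond in cfg.conditions:
            for run in range(cfg.n_runs_per_condition):
                for j in cfg.joints:
                    b = cfg.sigma_run * rng.standard_normal()
                    r_intercepts[(p, cond, run, j)] = b
                    noise = _smooth_periodic_noise(rng, cfg.sigma_noise, cfg.noise_bandwidth)
                    values = (
                        templates[j]
                        + p_offsets[(p, j)]
                        + bumps.get((j, cond), 0.0)
                        + cond_shift.get(cond, 0.0)
                        + b
                        + noise
                    )
                    strides.append(
                        StrideCurve(values, joint=j, participant=p, condition=cond, run=run)
                    )
    return SyntheticDataset(strides, cfg, p_offsets, r_intercepts)


@dataclass
class MarkerTrial:
    """Toe-marker vertical-displacement fixture with known minima."""

    z: np.ndarray
    fs: float
    true_minima: np.ndarray  # frame indices of the per-stride lowest points


def generate_marker_trial(
    duration_s: float,
    stride_rate_hz: float = 1.4,
    fs: float = 250.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    amplitude: float = 0.05,
) -> MarkerTrial:
    """Periodic toe-height signal with one unambiguous minimum per stride.

    The waveform is ``amplitude * (1 + cos(2 pi f t)) / 2`` (meters), so the
    analytic minima sit at ``t = (k + 1/2) / f``.
    """
    if duration_s <= 0 or stride_rate_hz <= 0 or fs <= 0:
        raise ValueError("duration, stride rate and sampling rate must be positive")
    if fs <= 2.0 * stride_rate_hz:
        raise ValueError("fs must exceed twice the stride rate")
    if duration_s <= 1.0 / stride_rate_hz:
        raise ValueError("duration must cover at least one stride")
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    z = amplitude * (1.0 + np.cos(2.0 * np.pi * stride_rate_hz * t)) / 2.0
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        z = z + noise_sd * rng.standard_normal(n)
    k = np.arange(int(np.ceil(duration_s * stride_rate_hz)) + 1)
    idx = np.round(fs * (k + 0.5) / stride_rate_hz).astype(int)
    return MarkerTrial(z, fs, idx[idx < n])


def generate_angle_trial(
    joint: str,
    duration_s: float,
    stride_rate_hz: float = 1.25,
    fs: float = 250.0,
) -> AngleSeries:
    """Continuous angle signal whose phase is locked to the marker fixture.

    Phase 0% of the cycle coincides with the marker trial's minima (toe-off),
    i.e. with ``t = (k + 1/2) / stride_rate_hz``.
    """
    if duration_s <= 0 or stride_rate_hz <= 0 or fs <= 0:
        raise ValueError("duration, stride rate and sampling rate must be positive")
    f = joint_template_fn(joint)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    phase = ((t - 0.5 / stride_rate_hz) * stride_rate_hz) % 1.0
    return AngleSeries(f(100.0 * phase), fs=fs, joint=joint)
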