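"""Raw signal to time-normalized stride curves.

The processing chain mirrors standard gait-lab practice: zero-lag low-pass
Butterworth filtering, toe-off detection from the toe marker's vertical
displacement (lowest point followed by a sustained rise), segmentation into
strides between consecutive toe-offs, and interpolation of each stride onto a
101-point 0-100% cycle grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt, find_peaks

from .types import AngleSeries, StrideCurve

__all__ = [
    "butterworth_lowpass",
    "detect_toe_off",
    "segment_strides",
    "time_normalize",
    "extract_stride_curves",
    "PreprocessResult",
    "preprocess_runs",
]

#: Cutoff correction for a dual-pass (forward-backward) filter: each pass of an
#: order-n Butterworth must be designed at cutoff / (2**(1/2) - 1)**(1/(2n)) so
#: the combined response is -3 dB at the nominal cutoff (Winter's convention).
_DUAL_PASS_ORDER = 2  # two passes of order 2 -> effective 4th order


def _corrected_cutoff(cutoff: float) -> float:
    return cutoff / (2.0 ** (1.0 / 2.0) - 1.0) ** (1.0 / (2.0 * _DUAL_PASS_ORDER))


def butterworth_lowpass(x: np.ndarray, fs: float, cutoff: float = 10.0) -> np.ndarray:
    """Zero-phase effective 4th-order low-pass Butterworth filter.

    Implemented as a forward-backward pass of a 2nd-order filter whose design
    cutoff is raised by the dual-pass correction factor, so the combined
    response has its -3 dB point at ``cutoff``.
    """
    x = np.asarray(x, dtype=float)
    if not 0.0 < cutoff < fs / 2.0:
        raise ValueError(f"cutoff must lie in (0, {fs / 2.0}) Hz (Nyquist)")
    fc = _corrected_cutoff(cutoff)
    if fc >= fs / 2.0:
        raise ValueError(
            f"corrected cutoff {fc:.2f} Hz reaches the Nyquist frequency; "
            "lower the cutoff or raise fs"
        )
    min_len = 3 * 2 * _DUAL_PASS_ORDER + 1
    if len(x) <= min_len:
        raise ValueError(f"signal too short to filter; need more than {min_len} samples")
    b, a = butter(_DUAL_PASS_ORDER, fc / (fs / 2.0), btype="low")
    return filtfilt(b, a, x)


def detect_toe_off(
    toe_z: np.ndarray,
    fs: float,
    min_rise_samples: int = 5,
    prominence_frac: float = 0.10,
    refractory_s: float = 0.25,
) -> np.ndarray:
    """Toe-off events: local minima of toe height followed by a sustained rise.

    A candidate minimum qualifies if its prominence is at least
    ``prominence_frac`` of the signal range and it is followed by
    ``min_rise_samples`` strictly rising samples.  Events closer together than
    ``refractory_s`` seconds are merged, keeping the deeper minimum.  Returns a
    strictly increasing array of frame indices (possibly empty).
    """
    z = np.asarray(toe_z, dtype=float)
    if fs <= 0:
        raise ValueError("fs must be positive")
    if z.size < 3:
        return np.array([], dtype=int)
    rng = z.max() - z.min()
    if rng == 0:
        return np.array([], dtype=int)
    cand, _ = find_peaks(-z, prominence=prominence_frac * rng)
    good = []
    for i in cand:
        seg = z[i : i + min_rise_samples + 1]
        if len(seg) == min_rise_samples + 1 and np.all(np.diff(seg) > 0):
            good.append(i)
    if not good:
        return np.array([], dtype=int)
    # refractory merge: keep the deeper of any pair closer than the window
    merged = [good[0]]
    window = refractory_s * fs
    for i in good[1:]:
        if i - merged[-1] < window:
            if z[i] < z[merged[-1]]:
                merged[-1] = i
        else:
            merged.append(i)
    return np.array(merged, dtype=int)


def segment_strides(
    x: np.ndarray, events: np.ndarray, include_end: bool = False
) -> list[np.ndarray]:
    """Split a signal into strides between consecutive events.

    Segment ``k`` spans ``[events[k], events[k+1])``; with ``include_end=True``
    the closing event frame is appended so 0% and 100% of the normalized cycle
    refer to the same gait event.  Fewer than two events yields an empty list.
    """
    x = np.asarray(x, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(events) < 2:
        return []
    if np.any(np.diff(events) <= 0):
        raise ValueError("events must be strictly increasing")
    if events[0] < 0 or events[-1] >= len(x) + (0 if include_end else 1):
        raise ValueError("events out of signal bounds")
    end = 1 if include_end else 0
    return [x[events[k] : events[k + 1] + end] for k in range(len(events) - 1)]


def time_normalize(segment: np.ndarray, n_points: int = 101) -> np.ndarray:
    """Interpolate one raw stride onto an even grid spanning the segment.

    Piecewise-cubic interpolation; the segment endpoints map exactly to the
    first and last grid points.
    """
    seg = np.asarray(segment, dtype=float)
    if seg.size < 4:
        raise ValueError("segment too short to normalize; need at least 4 samples")
    u = np.linspace(0.0, seg.size - 1.0, n_points)
    out = CubicSpline(np.arange(seg.size), seg)(u)
    out[0], out[-1] = seg[0], seg[-1]
    return out


def extract_stride_curves(
    angle: AngleSeries,
    toe_z: np.ndarray,
    cutoff: float = 10.0,
    n_points: int = 101,
) -> list[StrideCurve]:
    """Full per-run chain: filter, detect toe-offs, segment, time-normalize."""
    zf = butterworth_lowpass(toe_z, angle.fs, cutoff)
    af = butterworth_lowpass(angle.samples, angle.fs, cutoff)
    events = detect_toe_off(zf, angle.fs)
    segments = segment_strides(af, events, include_end=True)
    curves = []
    for seg in segments:
        if seg.size < 4:
            continue
        curves.append(
            StrideCurve(
                time_normalize(seg, n_points),
                joint=angle.joint,
                participant=angle.participant,
                condition=angle.condition,
                run=angle.run,
            )
        )
    return curves


@dataclass
class PreprocessResult:
    """Stride curves plus run-exclusion bookkeeping."""

    curves: list[StrideCurve]
    excluded: list[tuple[str, str, int, str, str]]  # (participant, cond, run, joint, reason)

    @property
    def n_input_runs(self) -> int:
        return len({c.key() for c in self.curves}) + len(
            {e[:4] for e in self.excluded}
        )


def _bridge_gaps(x: np.ndarray, max_gap: int) -> np.ndarray | None:
    """Linearly bridge short NaN gaps; return None if any gap exceeds max_gap."""
    x = np.asarray(x, dtype=float).copy()
    isnan = np.isnan(x)
    if not isnan.any():
        return x
    # locate runs of NaN
    idx = np.flatnonzero(np.diff(np.r_[0, isnan.view(np.int8), 0]))
    starts, stops = idx[::2], idx[1::2]
    if np.any(stops - starts > max_gap) or starts[0] == 0 or stops[-1] == len(x):
        return None
    valid = ~isnan
    x[isnan] = np.interp(np.flatnonzero(isnan), np.flatnonzero(valid), x[valid])
    return x


def preprocess_runs(
    runs: list[tuple[AngleSeries, np.ndarray]],
    cutoff: float = 10.0,
    max_gap_frames: int = 10,
) -> PreprocessResult:
    """Process many runs with the exclusion policy for missing samples.

    Each item pairs an angle series with the matching toe-height signal.  Runs
    with a NaN gap longer than ``max_gap_frames`` (or gaps touching the signal
    edges) are excluded; shorter gaps are linearly bridged before filtering.
    """
    curves: list[StrideCurve] = []
    excluded: list[tuple[str, str, int, str, str]] = []
    for angle, toe_z in runs:
        key = (angle.participant, angle.condition, angle.run, angle.joint)
        samples = _bridge_gaps(angle.samples, max_gap_frames)
        z = _bridge_gaps(np.asarray(toe_z, dtype=float), max_gap_frames)
        if samples is None or z is None:
            excluded.append((*key, "irrecoverable marker gap"))
            continue
        fixed = AngleSeries(
            samples,
            fs=angle.fs,
            joint=angle.joint,
            participant=angle.participant,
            condition=angle.condition,
            run=angle.run,
        )
        got = extract_stride_curves(fixed, z, cutoff=cutoff)
        if not got:
            excluded.append((*key, "no complete stride detected"))
            continue
        curves.extend(got)
    return PreprocessResult(curves, excluded)
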