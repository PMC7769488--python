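"""Shared container types for stride-cycle kinematic data."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

JOINTS = ("hip", "knee", "ankle")
GRID = np.arange(101, dtype=float)  # 0..100 % of stride cycle


@dataclass
class AngleSeries:
    """One run's time-continuous sagittal joint angle in degrees.

    Positive angles are hip flexion, knee flexion and ankle dorsiflexion
    relative to upright standing; negative angles are extension /
    plantarflexion.
    """

    samples: np.ndarray
    fs: float = 250.0
    joint: str = "hip"
    participant: str = ""
    condition: str = ""
    run: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.samples.size == 0:
            raise ValueError("samples must be non-empty")


@dataclass
class StrideCurve:
    """One stride normalized to the 0-100% cycle grid (101 points, degrees)."""

    values: np.ndarray
    joint: str = "hip"
    participant: str = ""
    condition: str = ""
    run: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (101,):
            raise ValueError(
                f"StrideCurve requires exactly 101 values, got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("StrideCurve values must be finite")

    @property
    def grid(self) -> np.ndarray:
        return GRID

    def key(self) -> tuple[str, str, int, str]:
        return (self.participant, self.condition, self.run, self.joint)
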