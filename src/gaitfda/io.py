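"""CSV / YAML input-output for stride data and ground-truth sidecars.

The canonical on-disk format is a long-format CSV with one row per grid
point: ``participant_id, condition, run_index, joint, cycle_pct, angle_deg``
(plus an optional ``sex_label`` column, carried through untouched).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml

from .synthetic import EffectSpec, SimConfig, SyntheticDataset
from .types import StrideCurve

__all__ = [
    "strides_to_frame",
    "frame_to_strides",
    "write_strides_csv",
    "read_strides_csv",
    "write_truth_sidecar",
    "read_truth_sidecar",
]

LONG_COLUMNS = ["participant_id", "condition", "run_index", "joint", "cycle_pct", "angle_deg"]


def strides_to_frame(strides: list[StrideCurve]) -> pd.DataFrame:
    frames = []
    for s in strides:
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": s.participant,
                    "condition": s.condition,
                    "run_index": s.run,
                    "joint": s.joint,
                    "cycle_pct": s.grid.astype(int),
                    "angle_deg": s.values,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def frame_to_strides(df: pd.DataFrame) -> list[StrideCurve]:
    missing = set(LONG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"long-format table missing columns: {sorted(missing)}")
    out = []
    keys = ["participant_id", "condition", "run_index", "joint"]
    for (p, c, r, j), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("cycle_pct")
        out.append(
            StrideCurve(
                grp["angle_deg"].to_numpy(),
                joint=j,
                participant=str(p),
                condition=str(c),
                run=int(r),
            )
        )
    return out


def write_strides_csv(strides: list[StrideCurve], path: str | Path) -> None:
    strides_to_frame(strides).to_csv(path, index=False, float_format="%.10g")


def read_strides_csv(path: str | Path) -> list[StrideCurve]:
    return frame_to_strides(pd.read_csv(path))


def write_truth_sidecar(dataset: SyntheticDataset, path: str | Path) -> None:
    """Write the generating configuration plus realized random effects."""
    cfg = dataclasses.asdict(dataset.config)
    cfg["effects"] = [dataclasses.asdict(e) for e in dataset.config.effects]
    doc = {
        "config": cfg,
        "participant_offsets": {
            f"{p}|{j}": float(v) for (p, j), v in dataset.participant_offsets.items()
        },
        "run_intercepts": {
            f"{p}|{c}|{r}|{j}": float(v)
            for (p, c, r, j), v in dataset.run_intercepts.items()
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_truth_sidecar(path: str | Path) -> SyntheticDataset:
    """Reconstruct the dataset (deterministically) from its truth sidecar."""
    from .synthetic import generate_strides

    doc = yaml.safe_load(Path(path).read_text())
    cfg = doc["config"]
    cfg["effects"] = tuple(EffectSpec(**e) for e in cfg["effects"])
    for key in ("conditions", "joints"):
        cfg[key] = tuple(cfg[key])
    cfg["condition_offsets"] = tuple(tuple(x) for x in cfg.get("condition_offsets", ()))
    return generate_strides(SimConfig(**cfg))
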