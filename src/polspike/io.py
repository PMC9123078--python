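"""Readers and writers for the package's on-disk recording format.

A recording is stored as three sibling plain-text files sharing a base
path ``<base>``:

* ``<base>.spikes.csv`` — header ``time_s``, one spike time per row,
  microsecond resolution;
* ``<base>.events.csv`` — one row per polarizer rotation with columns
  ``epoch_id,t_on_s,t_off_s,dop,rot_t_start_s,direction,start_angle_deg,
  speed_deg_s,sweep_deg`` (rows of one epoch grouped and repeated in the
  epoch columns);
* ``<base>.meta.json`` — neuron_id, cell_type, session_duration, the
  sign convention for rotation direction, and free-form metadata.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .types import (
    AnalysisConfig,
    PolarizerRotation,
    Recording,
    SpikeTrain,
    StimulusEpoch,
    ValidationError,
)

__all__ = ["read_recording", "write_recording", "read_config", "write_config"]

_EVENT_COLUMNS = [
    "epoch_id",
    "t_on_s",
    "t_off_s",
    "dop",
    "rot_t_start_s",
    "direction",
    "start_angle_deg",
    "speed_deg_s",
    "sweep_deg",
]


class ParseError(ValueError):
    """A file row could not be parsed; the message names the file and line."""


def _base_path(path: str | Path) -> Path:
    p = Path(path)
    name = p.name
    for suffix in (".spikes.csv", ".events.csv", ".meta.json"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)])
    return p


def read_recording(path: str | Path) -> Recording:
    """Load a validated :class:`Recording` from its on-disk triple.

    ``path`` may be the base path or any of the three member files.
    """
    base = _base_path(path)
    spikes_path = base.with_name(base.name + ".spikes.csv")
    events_path = base.with_name(base.name + ".events.csv")
    meta_path = base.with_name(base.name + ".meta.json")
    for p in (spikes_path, events_path, meta_path):
        if not p.exists():
            raise FileNotFoundError(f"missing recording file: {p}")

    with open(meta_path) as fh:
        meta = json.load(fh)

    times = _read_spike_times(spikes_path)
    train = SpikeTrain(
        neuron_id=str(meta["neuron_id"]),
        cell_type=meta["cell_type"],
        spike_times=times,
        session_duration=float(meta["session_duration"]),
    )
    epochs = _read_epochs(events_path)
    return Recording(spike_train=train, epochs=epochs, metadata=meta.get("metadata", {}))


def _read_spike_times(path: Path) -> np.ndarray:
    rows: list[float] = []
    with open(path) as fh:
        header = fh.readline().strip()
        if header != "time_s":
            raise ParseError(f"{path}, line 1: expected header 'time_s', got {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            try:
                rows.append(float(line))
            except ValueError as exc:
                raise ParseError(f"{path}, line {lineno}: not a number: {line!r}") from exc
    return np.asarray(rows, dtype=float)


def _read_epochs(path: Path) -> list[StimulusEpoch]:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise ParseError(f"{path}: {exc}") from exc
    if df.empty:
        return []
    missing = [c for c in _EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    epochs = []
    for epoch_id, grp in df.groupby("epoch_id", sort=False):
        rotations = [
            PolarizerRotation(
                t_start=float(row.rot_t_start_s),
                direction=row.direction,
                start_angle=float(row.start_angle_deg),
                speed=float(row.speed_deg_s),
                sweep=float(row.sweep_deg),
            )
            for row in grp.itertuples()
        ]
        epochs.append(
            StimulusEpoch(
                t_on=float(grp["t_on_s"].iloc[0]),
                t_off=float(grp["t_off_s"].iloc[0]),
                dop=float(grp["dop"].iloc[0]),
                rotations=rotations,
                label=str(epoch_id),
            )
        )
    return epochs


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write ``rec`` to the three-file format; round-trips at 1 µs resolution."""
    base = _base_path(path)
    base.parent.mkdir(parents=True, exist_ok=True)

    with open(base.with_name(base.name + ".spikes.csv"), "w") as fh:
        fh.write("time_s\n")
        for t in rec.spike_train.spike_times:
            fh.write(f"{t:.6f}\n")

    rows = []
    seen: set[str] = set()
    for i, epoch in enumerate(rec.epochs):
        label = epoch.label or f"epoch{i}"
        if label in seen:  # epoch_id must be unique or epochs merge on read
            label = f"{label}#{i}"
        seen.add(label)
        for rot in epoch.rotations:
            rows.append(
                {
                    "epoch_id": label,
                    "t_on_s": f"{epoch.t_on:.6f}",
                    "t_off_s": f"{epoch.t_off:.6f}",
                    "dop": repr(epoch.dop),
                    "rot_t_start_s": f"{rot.t_start:.6f}",
                    "direction": rot.direction.value,
                    "start_angle_deg": f"{rot.start_angle:.6f}",
                    "speed_deg_s": repr(rot.speed),
                    "sweep_deg": repr(rot.sweep),
                }
            )
    pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(
        base.with_name(base.name + ".events.csv"), index=False
    )

    meta = {
        "neuron_id": rec.spike_train.neuron_id,
        "cell_type": rec.spike_train.cell_type.value,
        "session_duration": rec.spike_train.session_duration,
        "direction_convention": "CW increases polarizer angle; CCW decreases",
        "metadata": _jsonable(rec.metadata),
    }
    with open(base.with_name(base.name + ".meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def read_config(path: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from YAML or JSON; unknown keys error."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValidationError(f"config file {path}: expected a mapping")
    return AnalysisConfig.from_dict(data)


def write_config(cfg: AnalysisConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
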