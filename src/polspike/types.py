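"""Domain types for polarization-stimulus spike-train recordings.

Conventions used throughout the package:

* time in seconds (float) from session start,
* angles in degrees; polarizer orientation lives on the full circle
  [0, 360), while the angle of polarization (AoP) is axial with a 180
  degree period and is always reported in [0, 180),
* clockwise (CW) rotation increases the polarizer angle, counterclockwise
  (CCW) decreases it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Any

import numpy as np

__all__ = [
    "CellType",
    "Direction",
    "SpikeTrain",
    "PolarizerRotation",
    "StimulusEpoch",
    "Recording",
    "AnalysisConfig",
    "ValidationError",
]


class ValidationError(ValueError):
    """An invariant of a domain type is violated; the message names the field."""


class CellType(str, Enum):
    TL2 = "TL2"
    TL3 = "TL3"
    CL1A = "CL1a"
    TB1 = "TB1"
    CPU1 = "CPU1"
    CPU2 = "CPU2"
    OTHER = "OTHER"

    @classmethod
    def coerce(cls, value: "CellType | str") -> "CellType":
        if isinstance(value, cls):
            return value
        for member in cls:
            if member.value.lower() == str(value).lower():
                return member
        raise ValidationError(f"cell_type: unknown label {value!r}")


class Direction(str, Enum):
    CW = "CW"
    CCW = "CCW"

    @classmethod
    def coerce(cls, value: "Direction | str") -> "Direction":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).upper())
        except ValueError as exc:
            raise ValidationError(f"direction: unknown value {value!r}") from exc


@dataclass
class SpikeTrain:
    """Ordered spike times of one neuron over one recording session."""

    neuron_id: str
    cell_type: CellType
    spike_times: np.ndarray
    session_duration: float

    def __post_init__(self) -> None:
        self.cell_type = CellType.coerce(self.cell_type)
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.ndim != 1:
            raise ValidationError("spike_times: must be one-dimensional")
        if self.spike_times.size and np.any(np.diff(self.spike_times) <= 0):
            raise ValidationError("spike_times: must be strictly increasing")
        if self.session_duration <= 0:
            raise ValidationError("session_duration: must be positive")
        if self.spike_times.size and (
            self.spike_times[0] < 0 or self.spike_times[-1] > self.session_duration
        ):
            raise ValidationError(
                "spike_times: must lie within [0, session_duration]"
            )

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


@dataclass
class PolarizerRotation:
    """One 360-degree sweep of the polarizer at constant angular speed."""

    t_start: float
    direction: Direction
    start_angle: float
    speed: float
    sweep: float = 360.0

    def __post_init__(self) -> None:
        self.direction = Direction.coerce(self.direction)
        if not 0.0 <= self.start_angle < 360.0:
            raise ValidationError("start_angle: must lie in [0, 360)")
        if self.speed <= 0:
            raise ValidationError("speed: must be positive")
        if self.sweep <= 0:
            raise ValidationError("sweep: must be positive")

    @property
    def duration(self) -> float:
        return self.sweep / self.speed

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration

    def contains(self, t: np.ndarray | float) -> np.ndarray | bool:
        t = np.asarray(t, dtype=float)
        return (t >= self.t_start) & (t <= self.t_end)

    def angle_at(self, t: np.ndarray | float) -> np.ndarray:
        """Polarizer angle (degrees in [0, 360)) at time ``t``.

        Defined only for t within the rotation interval; values outside
        are still computed from the linear law, callers must mask.
        """
        t = np.asarray(t, dtype=float)
        sign = 1.0 if self.direction is Direction.CW else -1.0
        return np.mod(self.start_angle + sign * self.speed * (t - self.t_start), 360.0)

    @property
    def end_angle(self) -> float:
        return float(self.angle_at(self.t_end))


@dataclass
class StimulusEpoch:
    """One light-on window with a degree of polarization and its rotations."""

    t_on: float
    t_off: float
    dop: float
    rotations: list[PolarizerRotation] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        if not self.t_on < self.t_off:
            raise ValidationError("t_off: must exceed t_on")
        if not 0.0 <= self.dop <= 1.0:
            raise ValidationError("dop: must lie in [0, 1]")
        rots = sorted(self.rotations, key=lambda r: r.t_start)
        for rot in rots:
            if rot.t_start < self.t_on or rot.t_end > self.t_off:
                raise ValidationError(
                    "rotations: every rotation interval must lie within [t_on, t_off]"
                )
        for a, b in zip(rots, rots[1:]):
            if b.t_start < a.t_end:
                raise ValidationError("rotations: must be non-overlapping")
        self.rotations = rots

    @property
    def directions(self) -> set[Direction]:
        return {r.direction for r in self.rotations}

    def has_both_directions(self) -> bool:
        return Direction.CW in self.directions and Direction.CCW in self.directions


@dataclass
class Recording:
    """A spike train plus its stimulus-epoch annotations."""

    spike_train: SpikeTrain
    epochs: list[StimulusEpoch] = field(default_factory=list)
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        eps = sorted(self.epochs, key=lambda e: e.t_on)
        for a, b in zip(eps, eps[1:]):
            if b.t_on < a.t_off:
                raise ValidationError("epochs: must be non-overlapping")
        self.epochs = eps

    def pre_epoch_gap(self, epoch: StimulusEpoch) -> float:
        """Stimulus-free time directly before ``epoch`` (for background windows)."""
        prev_end = 0.0
        for e in self.epochs:
            if e is epoch or e.t_on >= epoch.t_on:
                break
            prev_end = max(prev_end, e.t_off)
        return epoch.t_on - prev_end

    def spikes_in(self, t0: float, t1: float) -> np.ndarray:
        st = self.spike_train.spike_times
        return st[(st >= t0) & (st < t1)]


@dataclass
class AnalysisConfig:
    """Tunable parameters of the response analysis.

    bin_width must divide aop_period (10 into 180 at the defaults, giving
    the 18 axial bins all statistics assume).
    """

    bin_width: float = 10.0
    aop_period: float = 180.0
    ba_window: float = 5.0
    ba_bin: float = 1.0
    alpha: float = 0.05
    min_spikes: int = 10
    ci_level: float = 0.95
    p_method: str = "asymptotic"
    n_perm: int = 1000
    rng_seed: int = 0
    control_source: str = "pre_stimulus"  # or "lowest_dop"
    log_transform: str = "predictor"  # or "response", for DoP regressions
    pool_controls: bool = False  # pool no-stimulus controls across cell types

    def __post_init__(self) -> None:
        if not np.isclose(360.0 % self.aop_period, 0.0):
            raise ValidationError("aop_period: must divide 360")
        n = self.aop_period / self.bin_width
        if not np.isclose(n, round(n)):
            raise ValidationError("bin_width: must divide aop_period")
        if self.p_method not in ("asymptotic", "permutation"):
            raise ValidationError("p_method: must be 'asymptotic' or 'permutation'")
        if self.p_method == "permutation" and self.n_perm < 100:
            raise ValidationError("n_perm: must be >= 100 for the permutation test")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha: must lie in (0, 1)")
        if not 0 < self.ci_level < 1:
            raise ValidationError("ci_level: must lie in (0, 1)")

    @property
    def n_bins(self) -> int:
        return int(round(self.aop_period / self.bin_width))

    def to_dict(self) -> dict[str, Any]:
        return {
            "bin_width": self.bin_width,
            "aop_period": self.aop_period,
            "ba_window": self.ba_window,
            "ba_bin": self.ba_bin,
            "alpha": self.alpha,
            "min_spikes": self.min_spikes,
            "ci_level": self.ci_level,
            "p_method": self.p_method,
            "n_perm": self.n_perm,
            "rng_seed": self.rng_seed,
            "control_source": self.control_source,
            "log_transform": self.log_transform,
            "pool_controls": self.pool_controls,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AnalysisConfig":
        known = set(cls().to_dict())
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"config: unknown key(s) {sorted(unknown)}")
        return cls(**d)
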