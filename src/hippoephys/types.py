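"""Core in-memory containers shared across the analysis modules.

Times are seconds (double precision); voltages are arbitrary units — no
volt calibration is attempted. Signals are uniformly sampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EVENT_TYPES = frozenset(
    {"trial_start", "teleport", "reward", "lick", "lock_start", "lock_end"}
)


@dataclass
class ContinuousSignal:
    """A uniformly sampled voltage trace.

    Attributes
    ----------
    samples : ndarray
        Voltage samples (a.u.), finite.
    fs : float
        Sampling rate in Hz.
    t0 : float
        Time of the first sample in seconds.
    channel_id : str
        Free-form channel label.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    channel_id: str = "ch0"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("signal must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("signal contains non-finite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.fs


@dataclass
class SpikeTrain:
    """Ordered spike times (s) for one unit."""

    times: np.ndarray
    unit_id: str = "u0"
    region: str = ""
    spike_width_ms: float | None = None  # width at 90% of peak amplitude

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("spike times must be one-dimensional")
        if len(self.times) > 1 and np.any(np.diff(self.times) < 0):
            raise ValueError(f"spike times of unit {self.unit_id} not sorted")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class SessionBehavior:
    """Behavioral time series for one virtual-corridor session.

    ``position`` is corridor position in meters on [0, corridor_length];
    during the post-run reward lock the position stays at corridor_length.
    ``trials`` has one row per trial with columns
    (trial, start_s, lock_start_s, lock_end_s).
    """

    t: np.ndarray
    position: np.ndarray
    speed: np.ndarray  # cm/s
    corridor_length: float
    trials: pd.DataFrame
    events: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["time_s", "event_type", "value"])
    )

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        if not (len(self.t) == len(self.position) == len(self.speed)):
            raise ValueError("behavior time series lengths differ")
        if self.corridor_length <= 0:
            raise ValueError("corridor length must be positive")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0
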