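"""Fundamental containers: sampled signals, eye traces, spike trains, saccades.

All times are in seconds with t = 0 at the start of the session; angles are in
degrees measured counterclockwise from the positive horizontal axis.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SIMPLE = "simple"
COMPLEX = "complex"


@dataclass
class TimeSeries:
    """A uniformly sampled continuous signal.

    ``samples`` may be 1-D ``(n,)`` (e.g. an LFP channel or eye speed) or 2-D
    ``(n, k)`` for vector signals such as the 2-D eye velocity.
    """

    samples: np.ndarray
    rate: float  # Hz
    t0: float = 0.0  # s

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if len(self.samples) < 2:
            raise ValueError("TimeSeries needs at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.rate

    def index_of(self, t: float) -> int:
        """Nearest sample index for time ``t`` (clipped to the valid range)."""
        i = int(round((t - self.t0) * self.rate))
        return min(max(i, 0), len(self.samples) - 1)


@dataclass
class EyeTrace:
    """Horizontal and vertical eye position (degrees), sharing rate and t0."""

    horizontal: TimeSeries
    vertical: TimeSeries

    def __post_init__(self) -> None:
        if self.horizontal.rate != self.vertical.rate:
            raise ValueError("eye components must share the sampling rate")
        if self.horizontal.t0 != self.vertical.t0:
            raise ValueError("eye components must share t0")

    @property
    def rate(self) -> float:
        return self.horizontal.rate

    @property
    def t0(self) -> float:
        return self.horizontal.t0


@dataclass
class SaccadeEvent:
    """One detected saccade: onset/offset (s), direction, amplitude, duration."""

    onset: float
    offset: float
    angle_theta: float = 0.0  # degrees in [0, 360)
    amplitude: float = 0.0  # degrees
    peak_speed: float = 0.0  # deg/s

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("saccade offset must follow onset")
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        self.angle_theta = float(self.angle_theta) % 360.0

    @property
    def duration_L(self) -> float:
        """Saccade duration in milliseconds."""
        return 1000.0 * (self.offset - self.onset)


@dataclass
class SpikeTrain:
    """Sorted spike times with a per-spike kind label (simple/complex)."""

    times: np.ndarray  # s, strictly increasing
    kinds: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.kinds is None:
            self.kinds = np.full(len(self.times), SIMPLE, dtype=object)
        self.kinds = np.asarray(self.kinds, dtype=object)
        if len(self.kinds) != len(self.times):
            raise ValueError("times and kinds must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def isis(self) -> np.ndarray:
        return np.diff(self.times)

    def simple(self) -> "SpikeTrain":
        """The simple-spike subtrain (complex spikes removed)."""
        m = self.kinds == SIMPLE
        return SpikeTrain(self.times[m], self.kinds[m])

    def subset(self, mask: np.ndarray) -> "SpikeTrain":
        return SpikeTrain(self.times[mask], self.kinds[mask])

    def mean_rate(self, duration: float | None = None) -> float:
        if duration is None:
            duration = self.times[-1] - self.times[0] if len(self) > 1 else 0.0
        if duration <= 0:
            raise ValueError("cannot compute rate over nonpositive duration")
        return len(self) / duration

    def binned(self, rate: float, n_samples: int, t0: float = 0.0) -> np.ndarray:
        """Bin the train into counts on a uniform grid (bin width 1/rate)."""
        idx = np.floor((self.times - t0) * rate).astype(int)
        idx = idx[(idx >= 0) & (idx < n_samples)]
        out = np.zeros(n_samples)
        np.add.at(out, idx, 1.0)
        return out


def wrap_angle(a: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles (radians) to [-pi, pi)."""
    return (np.asarray(a) + np.pi) % (2 * np.pi) - np.pi


def circ_distance_deg(a, b):
    """Signed circular distance a - b in degrees, wrapped to [-180, 180)."""
    return (np.asarray(a) - np.asarray(b) + 180.0) % 360.0 - 180.0
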