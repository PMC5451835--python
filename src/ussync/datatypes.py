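"""Shared in-memory containers for the ultrasound timing toolkit.

All time values are seconds, all image coordinates are pixels with origin at
the top-left corner, x = column index (rightward), y = row index (downward),
0-based.  Displacements are ``position_in_second_frame - position_in_first``.
Missing / undefined scalar values are represented as ``numpy.nan`` ("flagged"
values) throughout, never as silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

TimestampSource = Literal["metadata", "software", "hardware"]


@dataclass
class TimestampSeries:
    """Per-frame acquisition times.

    Parameters
    ----------
    times : ndarray of float, seconds
        Monotonically non-decreasing acquisition time of each frame.
    source : {"metadata", "software", "hardware"}
        Which record produced the times: ``metadata`` are the true frame
        times carried in the vendor file headers, ``software`` are host-side
        read-out timestamps (jittered, possibly with dropped frames) and
        ``hardware`` are electrical per-frame trigger timings.
    quantization : float, seconds
        Resolution the times are quantized to (0 means unquantized).
    """

    times: np.ndarray
    source: TimestampSource = "metadata"
    quantization: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be a 1-D array")
        if self.quantization < 0:
            raise ValueError("quantization must be >= 0")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("timestamps must be non-decreasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class ImageSequence:
    """Ordered grayscale frames plus pixel-spacing metadata."""

    frames: np.ndarray  # (n_frames, height, width), uint8
    pixel_spacing: float = 1.0  # mm per pixel, isotropic

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, h, w) array")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class Feature:
    """A trackable image location with its minimum-eigenvalue quality score."""

    position: tuple[float, float]  # (x, y), sub-pixel
    quality: float


@dataclass
class MotionField:
    """Sparse displacement estimates for one frame transition t -> t+1."""

    transition_index: int
    positions: np.ndarray  # (k, 2) array of (x, y)
    displacements: np.ndarray  # (k, 2) array of (dx, dy)
    tracked_fraction: float = 1.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        self.displacements = np.asarray(self.displacements, dtype=float).reshape(-1, 2)
        if len(self.positions) != len(self.displacements):
            raise ValueError("positions and displacements must have equal length")
        if not 0.0 <= self.tracked_fraction <= 1.0:
            raise ValueError("tracked_fraction must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class TwitchTrace:
    """Frame-by-frame twitch-likelihood signal.

    ``scores[i]`` is the motion-coherence mutual information (bits) of the
    transition between frames i and i+1, assigned to the midpoint of the two
    frame times.  Undefined transitions (too few tracked vectors) carry NaN.
    """

    transition_times: np.ndarray  # seconds
    scores: np.ndarray  # bits, NaN = flagged
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.transition_times = np.asarray(self.transition_times, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.transition_times.shape != self.scores.shape:
            raise ValueError("transition_times and scores must have equal length")

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class EventList:
    """Detected twitch events (peak times of the coherence trace)."""

    event_times: np.ndarray  # seconds, strictly increasing
    event_scores: np.ndarray  # bits

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.event_scores = np.asarray(self.event_scores, dtype=float)
        if self.event_times.shape != self.event_scores.shape:
            raise ValueError("event_times and event_scores must have equal length")
        if len(self.event_times) > 1 and np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.event_times)


@dataclass
class EMGTrace:
    """Uniformly sampled surface-EMG signal (mV)."""

    fs: float  # samples / s
    samples: np.ndarray  # mV

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class IFIReport:
    """Summary diagnostics of an inter-frame-interval record."""

    mode_centres: tuple[float, float]  # frames/s, (dominant, minor)
    mode_fractions: tuple[float, float]  # sum to 1, dominant first
    mean_rate: float  # frames/s, mean of instantaneous rates 1/IFI
    sd_rate: float  # frames/s
    n_frames: int
    dropped_indices: list
    variability_class: str  # "cumulative" | "non-cumulative"
    nominal_rate: float

    def as_flat_dict(self) -> dict:
        return {
            "n_frames": self.n_frames,
            "nominal_rate_fps": self.nominal_rate,
            "mean_rate_fps": self.mean_rate,
            "sd_rate_fps": self.sd_rate,
            "dominant_mode_fps": self.mode_centres[0],
            "minor_mode_fps": self.mode_centres[1],
            "dominant_fraction": self.mode_fractions[0],
            "minor_fraction": self.mode_fractions[1],
            "n_dropped_gaps": len(self.dropped_indices),
            "variability_class": self.variability_class,
        }


@dataclass
class SyncResult:
    """Outcome of aligning the twitch trace against the stimulus schedule."""

    per_stimulus_latencies: np.ndarray  # seconds, NaN = no event matched
    constant_offset: float  # seconds
    drift_series: np.ndarray  # seconds, one entry per frame
    nominal_ifi: float  # seconds

    def __post_init__(self) -> None:
        self.per_stimulus_latencies = np.asarray(
            self.per_stimulus_latencies, dtype=float
        )
        self.drift_series = np.asarray(self.drift_series, dtype=float)


def as_onsets(stimuli: Sequence[float] | np.ndarray) -> np.ndarray:
    """Validate and return a strictly increasing stimulus-onset array."""
    onsets = np.asarray(stimuli, dtype=float).ravel()
    if len(onsets) > 1 and np.any(np.diff(onsets) <= 0):
        raise ValueError("stimulus onsets must be strictly increasing")
    return onsets
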