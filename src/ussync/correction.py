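"""Timing reconstruction and synchronization correction.

Quantifies what the constant-frame-rate assumption does to event timing
(drift = actual frame time minus assumed frame time, the cumulative sum of
per-frame IFI errors), resamples the twitch-likelihood trace onto corrected
time bases, estimates any constant acquisition delay by lag scanning, and
measures stimulus-to-twitch latencies against the stimulus schedule.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .datatypes import EventList, SyncResult, TimestampSeries, TwitchTrace, as_onsets

logger = logging.getLogger(__name__)


def frame_times_assumed(n_frames: int, nominal_rate: float) -> np.ndarray:
    """Frame times under the constant-rate assumption: k / nominal_rate."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if nominal_rate <= 0:
        raise ValueError("nominal_rate must be positive")
    return np.arange(n_frames) / nominal_rate


def drift(assumed_times: np.ndarray, actual_times: np.ndarray) -> np.ndarray:
    """Per-frame timing error of the assumption: actual - assumed.

    Equals the cumulative sum of (actual IFI - assumed IFI) up to each frame,
    plus any initial offset.
    """
    a = np.asarray(assumed_times, dtype=float)
    b = np.asarray(actual_times, dtype=float)
    if a.shape != b.shape:
        raise ValueError("assumed and actual times must have equal length")
    return b - a


def resample_trace(trace: TwitchTrace, target_times: np.ndarray) -> np.ndarray:
    """Linearly interpolate the trace at ``target_times``.

    Flagged (NaN) scores are excluded from the interpolation support; queries
    outside the support of the remaining nodes return NaN (no extrapolation).
    """
    tq = np.asarray(target_times, dtype=float)
    valid = np.isfinite(trace.scores)
    t = trace.transition_times[valid]
    s = trace.scores[valid]
    if len(t) == 0:
        return np.full(tq.shape, np.nan)
    if np.any(np.diff(t) <= 0):
        raise ValueError("trace times must be strictly increasing")
    out = np.interp(tq, t, s)
    out = np.where((tq < t[0]) | (tq > t[-1]), np.nan, out)
    return out


def estimate_constant_offset(
    trace: TwitchTrace,
    stimuli: np.ndarray,
    search_window: float = 0.5,
    step: float = 0.001,
) -> float:
    """Constant acquisition delay estimate by lag-grid cross-correlation.

    Scans lags in [-search_window, +search_window] (spacing ``step``) and
    returns the lag maximizing the summed trace score at (onset + lag) over
    all stimuli; out-of-support samples contribute 0.  Ties are broken
    toward the smallest |lag|, and between +-L toward the negative lag.  A
    degenerate (flat) trace returns 0 with a warning.
    """
    onsets = as_onsets(stimuli)
    if len(onsets) < 2:
        raise ValueError("need at least 2 stimuli")
    valid = trace.scores[np.isfinite(trace.scores)]
    if len(valid) == 0 or np.ptp(valid) == 0.0:
        warnings.warn("flat twitch trace: offset estimate degenerate, returning 0")
        return 0.0
    n_steps = int(round(search_window / step))
    lags = np.arange(-n_steps, n_steps + 1) * step
    scores = np.empty(len(lags))
    for i, lag in enumerate(lags):
        vals = resample_trace(trace, onsets + lag)
        scores[i] = np.nansum(vals)
    best = scores.max()
    tied = np.flatnonzero(scores >= best - 1e-12 * max(1.0, abs(best)))
    # smallest |lag| first; negative before positive on equal magnitude
    key = sorted(tied, key=lambda i: (abs(lags[i]), lags[i]))
    return float(lags[key[0]])


def stimulus_latencies(
    events: EventList,
    stimuli: np.ndarray,
    max_latency: float = 2.5,
    mode: str = "nearest",
) -> np.ndarray:
    """Stimulus-to-twitch latency for each stimulus (NaN when unmatched).

    Positive latency = twitch after its stimulus.  ``mode="causal"`` matches
    each stimulus to the first event in (onset, onset + max_latency];
    ``mode="nearest"`` (default) matches to the nearest event within
    +-max_latency, so apparent acausality (negative latency) produced by
    timing artefacts remains representable.  Stimuli are processed in order
    and each event can serve at most one (the earliest) stimulus.
    """
    if mode not in ("nearest", "causal"):
        raise ValueError("mode must be 'nearest' or 'causal'")
    onsets = as_onsets(stimuli)
    lat = np.full(len(onsets), np.nan)
    used = np.zeros(len(events), dtype=bool)
    et = events.event_times
    for i, onset in enumerate(onsets):
        if mode == "causal":
            mask = (~used) & (et > onset) & (et <= onset + max_latency)
            if mask.any():
                j = int(np.flatnonzero(mask)[0])
                lat[i] = et[j] - onset
                used[j] = True
        else:
            mask = (~used) & (np.abs(et - onset) <= max_latency)
            if mask.any():
                cand = np.flatnonzero(mask)
                j = int(cand[np.argmin(np.abs(et[cand] - onset))])
                lat[i] = et[j] - onset
                used[j] = True
    return lat


def evaluate_synchronization(
    trace: TwitchTrace,
    events: EventList,
    stimuli: np.ndarray,
    assumed_times: np.ndarray,
    actual_times: TimestampSeries | np.ndarray,
    nominal_rate: float,
    max_latency: float = 2.5,
    mode: str = "nearest",
    offset_search_window: float = 0.5,
    offset_step: float = 0.001,
) -> SyncResult:
    """Bundle latencies, drift and the constant-offset estimate."""
    actual = (
        actual_times.times
        if isinstance(actual_times, TimestampSeries)
        else np.asarray(actual_times, float)
    )
    lat = stimulus_latencies(events, stimuli, max_latency=max_latency, mode=mode)
    try:
        offset = estimate_constant_offset(
            trace, stimuli, search_window=offset_search_window, step=offset_step
        )
    except ValueError:
        offset = 0.0
    return SyncResult(
        per_stimulus_latencies=lat,
        constant_offset=offset,
        drift_series=drift(assumed_times, actual),
        nominal_ifi=1.0 / nominal_rate,
    )
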