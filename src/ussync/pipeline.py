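"""Convenience chains tying tracking, scoring and evaluation together."""

from __future__ import annotations

import numpy as np

from .correction import evaluate_synchronization, frame_times_assumed
from .datatypes import ImageSequence, SyncResult, TimestampSeries, TwitchTrace
from .tracking import TrackingParams, track_sequence
from .twitchstat import MIParams, detect_events, twitch_trace


def compute_twitch_trace(
    images: ImageSequence | np.ndarray,
    times: TimestampSeries,
    tracking_params: TrackingParams | None = None,
    mi_params: MIParams | None = None,
) -> TwitchTrace:
    """Frames + frame times -> motion-coherence trace (one score/transition)."""
    frames = images.frames if isinstance(images, ImageSequence) else np.asarray(images)
    fields = track_sequence(frames, tracking_params)
    shape = frames.shape[1:]
    return twitch_trace(fields, times, shape, mi_params)


def evaluate_with_times(
    trace_scores: np.ndarray,
    frame_times: np.ndarray,
    stimuli: np.ndarray,
    nominal_rate: float,
    trace_params: dict | None = None,
    threshold_sds: float = 4.0,
    min_separation: float = 1.0,
    max_latency: float = 2.5,
    mode: str = "nearest",
) -> tuple[SyncResult, TwitchTrace]:
    """Re-time the per-transition scores on a given frame-time base, then
    detect events and measure stimulus latencies against that base.

    ``frame_times`` may be either the assumed constant-rate times or the
    actual (header/hardware) times; the returned drift series compares them
    against the constant-rate assumption either way.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    mid = 0.5 * (frame_times[:-1] + frame_times[1:])
    trace = TwitchTrace(mid, np.asarray(trace_scores, float), trace_params or {})
    events = detect_events(trace, threshold_sds=threshold_sds,
                           min_separation=min_separation)
    assumed = frame_times_assumed(len(frame_times), nominal_rate)
    result = evaluate_synchronization(
        trace, events, stimuli, assumed, frame_times, nominal_rate,
        max_latency=max_latency, mode=mode,
    )
    return result, trace
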