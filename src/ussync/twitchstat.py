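"""Motion-coherence statistic and twitch-event detection.

A muscle twitch moves a localized tissue region coherently, while acquisition
noise moves tracked features independently of where they sit.  The statistic
therefore measures the mutual information between *where* a feature is (its
cell on a coarse spatial grid) and *how* it moved (its displacement vector,
quantized on a joint (dx, dy) grid).  Coherent, spatially localized motion
yields high MI; i.i.d. noise motion yields MI near zero after bias
correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .datatypes import EventList, MotionField, TimestampSeries, TwitchTrace


@dataclass
class MIParams:
    """Binning of the coherence statistic.

    ``spatial_grid`` g partitions the image into g x g cells; displacements
    are quantized into ``displacement_bins`` equal-width bins per axis
    spanning [-max_displacement, +max_displacement], with the grid offset by
    half a bin so that zero displacement falls at a bin centre — the
    no-motion null maps to a single symbol instead of straddling an edge.
    The Miller–Madow correction subtracts the first-order positive bias of
    the plug-in MI estimate (flag kept switchable because upstream
    conventions differ).
    """

    spatial_grid: int = 4
    displacement_bins: int = 8
    max_displacement: float = 5.0
    miller_madow: bool = True


def _entropy_bits(counts: np.ndarray, corrected: bool) -> float:
    n = counts.sum()
    p = counts[counts > 0] / n
    h = float(-(p * np.log2(p)).sum())
    if corrected:
        h += (len(p) - 1) / (2.0 * n * np.log(2.0))
    return h


def motion_mutual_information(
    field: MotionField,
    image_shape: tuple[int, int],
    params: MIParams | None = None,
) -> float:
    """MI (bits) between spatial cell and quantized displacement.

    Returns NaN (flagged) when the field holds fewer than 2 vectors — an
    undefined score, deliberately distinct from a genuine 0.
    """
    p = params or MIParams()
    if len(field) < 2:
        return np.nan
    h, w = image_shape
    g = p.spatial_grid
    x = field.positions[:, 0]
    y = field.positions[:, 1]
    cx = np.clip((x * g / w).astype(int), 0, g - 1)
    cy = np.clip((y * g / h).astype(int), 0, g - 1)
    cell = cy * g + cx

    nb = p.displacement_bins
    width = 2.0 * p.max_displacement / nb
    # half-bin offset: a displacement of exactly 0 sits at a bin centre
    bx = np.clip(
        np.floor((field.displacements[:, 0] + p.max_displacement) / width + 0.5)
        .astype(int),
        0, nb - 1,
    )
    by = np.clip(
        np.floor((field.displacements[:, 1] + p.max_displacement) / width + 0.5)
        .astype(int),
        0, nb - 1,
    )
    dbin = by * nb + bx

    joint = np.zeros((g * g, nb * nb))
    np.add.at(joint, (cell, dbin), 1.0)
    hx = _entropy_bits(joint.sum(axis=1), p.miller_madow)
    hy = _entropy_bits(joint.sum(axis=0), p.miller_madow)
    hxy = _entropy_bits(joint.ravel(), p.miller_madow)
    return max(0.0, hx + hy - hxy)


def twitch_trace(
    fields: list[MotionField],
    times: TimestampSeries,
    image_shape: tuple[int, int],
    params: MIParams | None = None,
) -> TwitchTrace:
    """Score every transition; assign each score the frame-time midpoint."""
    if len(fields) != len(times) - 1:
        raise ValueError(
            f"expected {len(times) - 1} motion fields for {len(times)} frames, "
            f"got {len(fields)}"
        )
    p = params or MIParams()
    t = times.times
    mid = 0.5 * (t[:-1] + t[1:])
    scores = np.array(
        [motion_mutual_information(f, image_shape, p) for f in fields]
    )
    return TwitchTrace(
        transition_times=mid,
        scores=scores,
        params={
            "spatial_grid": p.spatial_grid,
            "displacement_bins": p.displacement_bins,
            "max_displacement": p.max_displacement,
            "miller_madow": p.miller_madow,
        },
    )


def detect_events(
    trace: TwitchTrace,
    threshold_sds: float = 4.0,
    min_separation: float = 1.0,
) -> EventList:
    """Find twitch events: separated local maxima above a robust threshold.

    Threshold = median + ``threshold_sds`` x (1.4826 * MAD) of the valid
    scores.  Candidate peaks closer than ``min_separation`` seconds are
    resolved greedily, keeping the larger score (on ties, the earlier peak).
    """
    scores = trace.scores
    valid = np.isfinite(scores)
    if not valid.any():
        return EventList(np.empty(0), np.empty(0))
    med = np.median(scores[valid])
    mad_sd = 1.4826 * np.median(np.abs(scores[valid] - med))
    threshold = med + threshold_sds * mad_sd

    filled = np.where(valid, scores, -np.inf)
    peaks, _ = find_peaks(filled)
    peaks = peaks[filled[peaks] > threshold]
    if len(peaks) == 0:
        return EventList(np.empty(0), np.empty(0))

    times = trace.transition_times[peaks]
    vals = scores[peaks]
    # greedy suppression: strongest first, earlier wins ties
    order = np.lexsort((times, -vals))
    kept_t: list[float] = []
    kept_v: list[float] = []
    for i in order:
        if all(abs(times[i] - t0) >= min_separation for t0 in kept_t):
            kept_t.append(times[i])
            kept_v.append(vals[i])
    idx = np.argsort(kept_t)
    return EventList(np.array(kept_t)[idx], np.array(kept_v)[idx])
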