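"""Sparse KLT feature tracking between consecutive B-mode frames.

Two stages, matching the classic Kanade–Lucas–Tomasi chain:

1. ``select_features`` — score every pixel by the minimum eigenvalue of the
   local gradient structure tensor (Shi–Tomasi "trackability") and keep the
   strongest, spatially separated maxima.
2. ``track_features`` — per feature, iterative least-squares refinement of a
   pure-translation displacement (Lucas–Kanade normal equations on windowed
   gradients), run until the update falls below a tolerance.

Single-level tracking is the default: evoked muscle twitches move tissue by
a few pixels per transition at most, well within the convergence basin of
one pyramid level at the default 15 px window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .datatypes import Feature, ImageSequence, MotionField

logger = logging.getLogger(__name__)


@dataclass
class TrackingParams:
    """Knobs of the feature selection + tracking chain (pixels throughout)."""

    max_count: int = 200
    window: int = 15
    min_quality_ratio: float = 0.05
    min_separation: int = 8
    max_iterations: int = 20
    convergence_tol: float = 0.01
    max_displacement: float = 5.0


def min_eigenvalue_map(image: np.ndarray, window: int = 15) -> np.ndarray:
    """Shi–Tomasi response: min eigenvalue of the windowed structure tensor.

    Gradients are central differences; tensor entries are summed over a
    ``window`` x ``window`` box around each pixel.
    """
    img = np.asarray(image, dtype=float)
    gy, gx = np.gradient(img)
    size = int(window)
    sxx = ndimage.uniform_filter(gx * gx, size=size) * size**2
    syy = ndimage.uniform_filter(gy * gy, size=size) * size**2
    sxy = ndimage.uniform_filter(gx * gy, size=size) * size**2
    trace = sxx + syy
    disc = np.sqrt((sxx - syy) ** 2 + 4.0 * sxy**2)
    return 0.5 * (trace - disc)


def select_features(
    image: np.ndarray,
    max_count: int = 200,
    window: int = 15,
    min_quality_ratio: float = 0.05,
    min_separation: int = 8,
) -> list[Feature]:
    """Pick up to ``max_count`` well-separated, high-trackability features.

    Returns features sorted by descending quality; qualities are all at
    least ``min_quality_ratio`` times the best, pairwise separation at least
    ``min_separation`` px.  A featureless (flat) image yields an empty list.
    """
    img = np.asarray(image, dtype=float)
    if min(img.shape) < window:
        raise ValueError("image must be at least window x window")
    response = min_eigenvalue_map(img, window=window)
    qmax = float(response.max(initial=0.0))
    if qmax <= 0.0:
        return []
    margin = window // 2 + 1
    h, w = response.shape
    interior = np.zeros_like(response, dtype=bool)
    interior[margin : h - margin, margin : w - margin] = True
    cand = np.flatnonzero(interior.ravel() & (response.ravel() >= min_quality_ratio * qmax))
    order = cand[np.argsort(-response.ravel()[cand], kind="stable")]
    # greedy quality-sorted non-max suppression on a square footprint; a
    # Chebyshev radius of min_separation guarantees Euclidean separation too
    suppressed = np.zeros((h, w), dtype=bool)
    sep = int(min_separation)
    feats: list[Feature] = []
    for flat in order:
        r, c = divmod(int(flat), w)
        if suppressed[r, c]:
            continue
        feats.append(Feature(position=(float(c), float(r)),
                             quality=float(response[r, c])))
        if len(feats) >= max_count:
            break
        suppressed[
            max(0, r - sep + 1) : r + sep, max(0, c - sep + 1) : c + sep
        ] = True
    return feats


def _sample(img: np.ndarray, ys: np.ndarray, xs: np.ndarray, **kw) -> np.ndarray:
    return ndimage.map_coordinates(img, [ys, xs], mode="nearest", **kw)


def track_features(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    features: list[Feature],
    window: int = 15,
    max_iterations: int = 20,
    convergence_tol: float = 0.01,
    max_displacement: float = 5.0,
    transition_index: int = 0,
) -> MotionField:
    """Estimate per-feature displacement from ``frame_a`` to ``frame_b``.

    Forward-additive Lucas–Kanade: the template window and its gradients are
    fixed in ``frame_a``, and each iteration solves the 2x2 normal equations
    for an additive displacement update.  Features whose normal matrix is
    near-singular, whose estimate diverges, or whose displacement exceeds
    ``max_displacement`` are dropped and counted against ``tracked_fraction``.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames must have the same shape")
    if not features:
        return MotionField(transition_index, np.empty((0, 2)), np.empty((0, 2)),
                           tracked_fraction=0.0)

    pos = np.array([f.position for f in features], dtype=float)  # (n, 2) x,y
    n = len(pos)
    half = window // 2
    oy, ox = np.mgrid[-half : half + 1, -half : half + 1]
    ox = ox.ravel()[None, :]  # (1, w2)
    oy = oy.ravel()[None, :]

    xs = pos[:, 0:1] + ox  # (n, w2)
    ys = pos[:, 1:2] + oy
    gy_img, gx_img = np.gradient(a)
    # template values and gradients, fixed across iterations
    a_spl = ndimage.spline_filter(a, order=3, mode="nearest")
    tmpl = _sample(a_spl, ys, xs, order=3, prefilter=False)
    gx = _sample(gx_img, ys, xs, order=1)
    gy = _sample(gy_img, ys, xs, order=1)

    gxx = np.sum(gx * gx, axis=1)
    gxy = np.sum(gx * gy, axis=1)
    gyy = np.sum(gy * gy, axis=1)
    det = gxx * gyy - gxy * gxy
    scale = np.maximum(gxx, gyy) ** 2
    ok = det > 1e-9 * np.maximum(scale, 1e-12)
    if not np.all(ok):
        logger.debug("dropping %d features with singular normal matrix",
                     int(np.count_nonzero(~ok)))

    b_spl = ndimage.spline_filter(b, order=3, mode="nearest")
    d = np.zeros((n, 2))
    active = ok.copy()
    for _ in range(max_iterations):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        warped = _sample(
            b_spl, ys[idx] + d[idx, 1:2], xs[idx] + d[idx, 0:1],
            order=3, prefilter=False,
        )
        err = tmpl[idx] - warped
        bx = np.sum(gx[idx] * err, axis=1)
        by = np.sum(gy[idx] * err, axis=1)
        inv_det = 1.0 / det[idx]
        ddx = (gyy[idx] * bx - gxy[idx] * by) * inv_det
        ddy = (gxx[idx] * by - gxy[idx] * bx) * inv_det
        d[idx, 0] += ddx
        d[idx, 1] += ddy
        step = np.hypot(ddx, ddy)
        still = step >= convergence_tol
        diverged = np.hypot(d[idx, 0], d[idx, 1]) > 2.0 * max_displacement
        ok[idx[diverged]] = False
        active[idx] = still & ~diverged

    norm = np.hypot(d[:, 0], d[:, 1])
    ok &= np.isfinite(norm) & (norm <= max_displacement)
    field = MotionField(
        transition_index,
        pos[ok],
        d[ok],
        tracked_fraction=float(np.count_nonzero(ok)) / n,
    )
    return field


def track_sequence(
    sequence: ImageSequence | np.ndarray,
    params: TrackingParams | None = None,
) -> list[MotionField]:
    """Track every consecutive frame pair; features re-selected per pair.

    Re-selection avoids accumulation of feature drift across the sequence
    and keeps each transition's estimate independent.  Returns
    ``n_frames - 1`` motion fields.
    """
    frames = sequence.frames if isinstance(sequence, ImageSequence) else np.asarray(sequence)
    if frames.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    p = params or TrackingParams()
    fields = []
    for k in range(frames.shape[0] - 1):
        feats = select_features(
            frames[k],
            max_count=p.max_count,
            window=p.window,
            min_quality_ratio=p.min_quality_ratio,
            min_separation=p.min_separation,
        )
        fields.append(
            track_features(
                frames[k],
                frames[k + 1],
                feats,
                window=p.window,
                max_iterations=p.max_iterations,
                convergence_tol=p.convergence_tol,
                max_displacement=p.max_displacement,
                transition_index=k,
            )
        )
    return fields


def motion_fields_to_frame(fields: list[MotionField]):
    """Flatten motion fields to a tidy table (transition_index,x,y,dx,dy)."""
    import pandas as pd

    rows = []
    for f in fields:
        for (x, y), (dx, dy) in zip(f.positions, f.displacements):
            rows.append((f.transition_index, x, y, dx, dy))
    return pd.DataFrame(rows, columns=["transition_index", "x", "y", "dx", "dy"])
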