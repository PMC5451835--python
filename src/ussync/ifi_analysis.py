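"""Inter-frame-interval (IFI) diagnostics.

Tools to audit the frame timing of an ultrasound acquisition: read per-frame
timestamp files, characterize the IFI distribution (bimodality, dropped
frames), test whether deviations from the stated nominal rate accumulate
over a trial, and compare hardware trigger timings against software
timestamps.  Frame rate = 1 / IFI throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .datatypes import IFIReport, TimestampSeries


class TimestampFormatError(ValueError):
    """Raised when a timestamp CSV violates the dialect or monotonicity."""


_VALID_SOURCES = {"metadata", "software", "hardware"}


def read_timestamps(path: str | Path) -> TimestampSeries:
    """Read a ``frame_index,timestamp_s,source`` CSV into a TimestampSeries.

    An optional leading comment line ``# quantization_s=<value>`` carries the
    timestamp resolution; absent, quantization is reported as 0.  Timestamps
    must be non-decreasing; a violation raises :class:`TimestampFormatError`
    naming the offending data row (1-based, excluding header/comment lines).
    """
    path = Path(path)
    quantization = 0.0
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines) and lines[i].startswith("#"):
        line = lines[i].lstrip("#").strip()
        if line.startswith("quantization_s="):
            quantization = float(line.split("=", 1)[1])
        i += 1
    if i >= len(lines):
        raise TimestampFormatError(f"{path}: empty file")
    header = [c.strip() for c in lines[i].split(",")]
    if header[:2] != ["frame_index", "timestamp_s"]:
        raise TimestampFormatError(
            f"{path}: missing or malformed header row "
            "(expected 'frame_index,timestamp_s,source')"
        )
    times: list[float] = []
    source = "metadata"
    for row_no, line in enumerate(lines[i + 1 :], start=1):
        if not line.strip():
            continue
        parts = line.split(",")
        try:
            t = float(parts[1])
        except (IndexError, ValueError) as exc:
            raise TimestampFormatError(
                f"{path}: unparsable timestamp at data row {row_no}"
            ) from exc
        if times and t < times[-1]:
            raise TimestampFormatError(
                f"{path}: timestamp decreases at data row {row_no} "
                f"({t!r} < {times[-1]!r})"
            )
        times.append(t)
        if len(parts) >= 3 and parts[2].strip() in _VALID_SOURCES:
            source = parts[2].strip()
    return TimestampSeries(np.array(times), source=source, quantization=quantization)


def compute_ifis(series: TimestampSeries | np.ndarray) -> np.ndarray:
    """First differences of the frame times (seconds); length n - 1."""
    t = series.times if isinstance(series, TimestampSeries) else np.asarray(series, float)
    if len(t) < 2:
        raise ValueError("need at least 2 timestamps")
    return np.diff(t)


@dataclass
class BimodalFit:
    """Two-class decomposition of an IFI sample, reported as frame rates."""

    mode_rates: tuple[float, float]  # frames/s, dominant first
    mode_fractions: tuple[float, float]  # sum to 1, dominant first
    mode_ifis: tuple[float, float]  # seconds, dominant first
    unimodal: bool


def fit_bimodal(ifis: np.ndarray, quantization: float = 0.0) -> BimodalFit:
    """Two-class 1-D k-means on the IFI values (deterministic min/max init).

    Centres are reported as rates (1/IFI) with the dominant (larger-fraction)
    mode first.  If the converged centres differ by less than twice the IFI
    quantization the sample is declared unimodal (minor fraction 0).
    """
    x = np.asarray(ifis, dtype=float).ravel()
    if len(x) < 10:
        raise ValueError("need at least 10 IFIs")
    c = np.array([x.min(), x.max()])
    if c[0] == c[1]:
        rate = 1.0 / c[0]
        return BimodalFit((rate, rate), (1.0, 0.0), (c[0], c[0]), True)
    assign = np.zeros(len(x), dtype=bool)
    for _ in range(200):
        new_assign = np.abs(x - c[1]) < np.abs(x - c[0])  # True -> class 1
        if new_assign.all() or (~new_assign).all():
            break
        c_new = np.array([x[~new_assign].mean(), x[new_assign].mean()])
        moved = not np.array_equal(new_assign, assign)
        assign = new_assign
        c = c_new
        if not moved:
            break
    frac1 = float(np.count_nonzero(assign)) / len(x)
    centres = (c[0], c[1])
    fractions = (1.0 - frac1, frac1)
    if fractions[1] > fractions[0]:
        centres = centres[::-1]
        fractions = fractions[::-1]
    # unimodal floor: 2x the quantization step, or a relative epsilon so that
    # last-ulp scatter in nominally constant series is not called bimodal
    floor = max(2.0 * quantization, 1e-9 * abs(np.mean(x)))
    if abs(centres[0] - centres[1]) < floor:
        rate = 1.0 / np.mean(x)
        return BimodalFit((rate, rate), (1.0, 0.0), (np.mean(x), np.mean(x)), True)
    return BimodalFit(
        (1.0 / centres[0], 1.0 / centres[1]),
        fractions,
        centres,
        False,
    )


def detect_dropped_frames(
    ifis: np.ndarray, dominant_ifi: float
) -> tuple[np.ndarray, np.ndarray]:
    """Flag IFI gaps betraying dropped frames.

    Gap i is flagged when ``ifis[i] > 1.5 * dominant_ifi`` (halfway between
    one and two frame periods); the estimated number of frames missing in
    that gap is ``round(ifis[i] / dominant_ifi) - 1``.  Returns (indices,
    missing counts).
    """
    if dominant_ifi <= 0:
        raise ValueError("dominant_ifi must be positive")
    x = np.asarray(ifis, dtype=float)
    idx = np.flatnonzero(x > 1.5 * dominant_ifi)
    missing = np.round(x[idx] / dominant_ifi).astype(int) - 1
    return idx, missing


def classify_variability(
    ifis: np.ndarray,
    nominal_rate: float,
    alpha: float = 0.01,
    dominant_ifi: float | None = None,
) -> tuple[str, float, float]:
    """Test whether IFI deviations from the nominal rate accumulate.

    Drop-corrected first: each flagged gap is split into its estimated
    number of equal sub-intervals, so lost frames do not masquerade as rate
    error.  Then a one-sample z-test of mean(IFI) = 1/nominal_rate; a
    rejection at ``alpha`` means timing error accumulates over the trial
    ("cumulative"); otherwise the constant-IFI assumption is unbiased
    ("non-cumulative").  Returns (label, mean deviation in s, p-value).
    """
    x = np.asarray(ifis, dtype=float).ravel()
    if len(x) < 30:
        raise ValueError("need at least 30 IFIs")
    dom = dominant_ifi if dominant_ifi is not None else float(np.median(x))
    idx, missing = detect_dropped_frames(x, dom)
    parts = [np.delete(x, idx)]
    for i, m in zip(idx, missing):
        parts.append(np.full(m + 1, x[i] / (m + 1)))
    corrected = np.concatenate(parts)
    target = 1.0 / nominal_rate
    mean_dev = float(corrected.mean() - target)
    sd = corrected.std(ddof=1)
    if sd == 0.0:
        p = 1.0 if mean_dev == 0.0 else 0.0
    else:
        z = mean_dev / (sd / np.sqrt(len(corrected)))
        p = float(2.0 * stats.norm.sf(abs(z)))
    label = "cumulative" if p < alpha else "non-cumulative"
    return label, mean_dev, p


def summarize(series: TimestampSeries, nominal_rate: float) -> IFIReport:
    """Assemble the full IFI diagnostic report for one timestamp record.

    Mean and SD frame rate are computed over the instantaneous per-transition
    rates 1/IFI (not 1/mean(IFI)); for a bimodal mixture this is the
    fraction-weighted mean of the mode rates.
    """
    ifis = compute_ifis(series)
    rates = 1.0 / ifis
    if len(ifis) >= 10:
        fit = fit_bimodal(ifis, quantization=series.quantization)
    else:  # too few intervals to decompose: report a single mode
        mean_ifi = float(ifis.mean())
        fit = BimodalFit((1.0 / mean_ifi, 1.0 / mean_ifi), (1.0, 0.0),
                         (mean_ifi, mean_ifi), True)
    idx, _ = detect_dropped_frames(ifis, fit.mode_ifis[0])
    label, _, _ = classify_variability(
        ifis, nominal_rate, dominant_ifi=fit.mode_ifis[0]
    ) if len(ifis) >= 30 else ("non-cumulative", 0.0, 1.0)
    return IFIReport(
        mode_centres=fit.mode_rates,
        mode_fractions=fit.mode_fractions,
        mean_rate=float(rates.mean()),
        sd_rate=float(rates.std(ddof=1)) if len(rates) > 1 else 0.0,
        n_frames=len(series),
        dropped_indices=list(map(int, idx)),
        variability_class=label,
        nominal_rate=nominal_rate,
    )


def nominal_ifi(rate: float) -> float:
    """Inter-frame interval (s) implied by a stated constant frame rate."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    return 1.0 / rate


def clock_cycle_period(frequency_hz: float) -> float:
    """Period (s) of one cycle of a clock at ``frequency_hz``."""
    if frequency_hz <= 0:
        raise ValueError("frequency must be positive")
    return 1.0 / frequency_hz


def element_count_rate_model(
    anchor: tuple[float, float], query_elements: float
) -> float:
    """Frame rate predicted from the receive-element count.

    Acquisition time per frame scales with the number of receive elements,
    so rate ~ 1/elements: ``rate = anchor_rate * anchor_elements / query``.
    ``anchor`` is (elements, frames/s).
    """
    anchor_elements, anchor_rate = anchor
    if anchor_elements <= 0 or anchor_rate <= 0 or query_elements <= 0:
        raise ValueError("element counts and rates must be positive")
    return anchor_rate * anchor_elements / query_elements


@dataclass
class HwSwComparison:
    """Hardware-trigger vs software-timestamp comparison for one trial."""

    n_hardware: int
    n_software: int
    dropped_count: int
    ifi_variance_hw: float  # s^2
    ifi_variance_sw: float  # s^2
    hw_verdict: str
    sw_verdict: str


def compare_hw_sw(hw: TimestampSeries, sw: TimestampSeries) -> HwSwComparison:
    """Align a software record to the hardware trigger record.

    Each software frame is matched to its nearest hardware frame (one-to-one,
    in time order); unmatched hardware frames are the dropped count.  IFI
    variances of both records are reported, with verdict strings comparing
    the hardware variance against its measurement accuracy.
    """
    th, ts = hw.times, sw.times
    matched: set[int] = set()
    j = 0
    for t in ts:
        j = int(np.searchsorted(th, t))
        candidates = [k for k in (j - 1, j) if 0 <= k < len(th) and k not in matched]
        if candidates:
            matched.add(min(candidates, key=lambda k: abs(th[k] - t)))
    dropped = len(th) - len(matched)
    var_hw = float(np.var(np.diff(th), ddof=1)) if len(th) > 2 else 0.0
    var_sw = float(np.var(np.diff(ts), ddof=1)) if len(ts) > 2 else 0.0
    q = hw.quantization
    hw_verdict = (
        "hardware IFI variance within measurement accuracy (constant transmission)"
        if q == 0 or var_hw <= q**2
        else "hardware IFI variance exceeds measurement accuracy"
    )
    sw_verdict = (
        "software timestamps show excess IFI variance relative to hardware"
        if var_sw > var_hw
        else "software IFI variance no greater than hardware"
    )
    return HwSwComparison(
        n_hardware=len(th),
        n_software=len(ts),
        dropped_count=dropped,
        ifi_variance_hw=var_hw,
        ifi_variance_sw=var_sw,
        hw_verdict=hw_verdict,
        sw_verdict=sw_verdict,
    )
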