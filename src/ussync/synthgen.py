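"""Synthetic ultrasound / EMG / frame-timing data with known ground truth.

The generator emulates the timing behaviour of clinical B-mode scanners whose
true inter-frame interval (IFI) is *not* the constant value displayed on the
machine: true IFIs are drawn i.i.d. from a two-point (bimodal) mixture, the
software timestamp record adds read-out jitter and may drop frames, and the
hardware trigger record is the true timing quantized at the acquisition-card
resolution.  Imagery is a speckle-like texture warped by localized "twitch"
displacements at scheduled stimulus times, alongside a matched surface-EMG
channel (stimulation artifact + delayed M-wave).  Every stochastic choice is
driven by an explicit seed; one dataset-level seed fans out deterministically
to per-component seeds via ``numpy.random.SeedSequence`` spawn keys.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .datatypes import EMGTrace, ImageSequence, TimestampSeries, as_onsets

logger = logging.getLogger(__name__)

# Component indices used to spawn child seeds from the dataset seed.
_SEED_FRAMES = 0
_SEED_SOFTWARE = 1
_SEED_IMAGES = 2
_SEED_EMG = 3


def _component_rng(seed: int, component: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(component,)))


@dataclass
class TimingModel:
    """Frame-timing behaviour of a simulated scanner.

    ``nominal_rate`` is the constant frame rate stated on the machine;
    ``mode_rates`` are the (dominant, minor) centres of the true bimodal IFI
    distribution and ``mode_weight`` the dominant-mode fraction.  The software
    record adds zero-mean Gaussian jitter (``jitter_sd``) and loses each frame
    independently with probability ``drop_prob``; ``quantization`` is the
    resolution of the metadata timestamps (vendor headers record IFIs to
    100 ns, hence the 1e-7 s default).
    """

    nominal_rate: float = 82.0  # frames/s
    mode_rates: tuple[float, float] = (83.5, 62.5)  # frames/s (dominant, minor)
    mode_weight: float = 0.9272
    jitter_sd: float = 0.0  # s
    drop_prob: float = 0.0
    quantization: float = 1e-7  # s

    def __post_init__(self) -> None:
        if not 0.0 <= self.mode_weight <= 1.0:
            raise ValueError("mode_weight must lie in [0, 1]")
        if min(self.mode_rates) <= 0 or self.nominal_rate <= 0:
            raise ValueError("rates must be positive")
        if self.quantization < 0:
            raise ValueError("quantization must be >= 0")
        if not 0.0 <= self.drop_prob < 1.0:
            raise ValueError("drop_prob must lie in [0, 1)")


@dataclass
class TwitchSchedule:
    """Stimulation schedule and the evoked tissue displacement it causes.

    Each stimulus at ``onsets[i]`` evokes, after ``latency`` seconds, a
    localized displacement of up to ``peak_displacement`` pixels, Gaussian
    windowed in space (centre ``region_centre``, SD ``region_sd``).  The
    temporal profile is an asymmetric twitch: a half-cosine rise over
    ``rise_time`` (fast contraction, default shorter than one frame interval)
    followed by a half-cosine relaxation over the remaining ``duration``.
    """

    onsets: np.ndarray = field(default_factory=lambda: np.arange(5.0, 40.0 + 1e-9, 5.0))
    duration: float = 0.12  # s, total twitch duration
    latency: float = 0.010  # s, stimulus-to-movement delay
    region_centre: tuple[float, float] = (64.0, 64.0)  # (x, y) px
    region_sd: float = 25.0  # px
    peak_displacement: tuple[float, float] = (3.0, 0.0)  # (dx, dy) px
    rise_time: float = 0.004  # s, contraction phase

    def __post_init__(self) -> None:
        self.onsets = as_onsets(self.onsets)
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.latency < 0:
            raise ValueError("latency must be >= 0")
        if not 0 < self.rise_time < self.duration:
            raise ValueError("rise_time must lie in (0, duration)")

    def profile(self, t: np.ndarray | float) -> np.ndarray:
        """Superposed temporal activation in [0, 1] at time(s) ``t``."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        fall = self.duration - self.rise_time
        for onset in self.onsets:
            tau = t - onset - self.latency
            rising = (tau >= 0) & (tau < self.rise_time)
            falling = (tau >= self.rise_time) & (tau <= self.duration)
            out = np.where(
                rising, 0.5 * (1 - np.cos(np.pi * tau / self.rise_time)), out
            )
            out = np.where(
                falling,
                0.5 * (1 + np.cos(np.pi * (tau - self.rise_time) / fall)),
                out,
            )
        return out

    def displacement_at(self, x, y, t) -> tuple[np.ndarray, np.ndarray]:
        """Analytic displacement field (dx, dy) at pixel(s) (x, y), time t."""
        cx, cy = self.region_centre
        r2 = (np.asarray(x, float) - cx) ** 2 + (np.asarray(y, float) - cy) ** 2
        window = np.exp(-r2 / (2.0 * self.region_sd**2))
        p = self.profile(t)
        return (
            self.peak_displacement[0] * window * p,
            self.peak_displacement[1] * window * p,
        )


@dataclass
class EMGModel:
    """Surface-EMG morphology: noise floor, stimulation artifact, M-wave.

    The M-wave (direct muscle response) is modelled as a damped sinusoid
    starting ``mwave_latency`` seconds after each stimulus; the stimulation
    artifact is a 1 ms biphasic pulse at the stimulus itself.
    """

    fs: float = 2000.0  # samples/s
    noise_sd: float = 0.01  # mV
    artifact_amplitude: float = 1.0  # mV
    mwave_amplitude: float = 0.5  # mV
    mwave_latency: float = 0.008  # s
    mwave_freq: float = 250.0  # Hz
    mwave_decay: float = 150.0  # 1/s
    artifact_width: float = 0.001  # s

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        for name in ("noise_sd", "artifact_amplitude", "mwave_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def mwave(self, tau: np.ndarray) -> np.ndarray:
        """Damped-sinusoid M-wave evaluated at time-since-M-wave-onset tau."""
        tau = np.asarray(tau, dtype=float)
        tau_pos = np.maximum(tau, 0.0)
        out = (
            self.mwave_amplitude
            * np.exp(-self.mwave_decay * tau_pos)
            * np.sin(2 * np.pi * self.mwave_freq * tau_pos)
        )
        return np.where(tau >= 0, out, 0.0)


# Presets named after the timing behaviours they emulate: a scanner with a
# bimodal true IFI hidden behind a constant displayed rate (82 / 42 fps
# variants) and a constant-transmission scanner whose software record drops
# frames and jitters.
PRESETS: dict[str, TimingModel] = {
    "telemed82": TimingModel(
        nominal_rate=82.0, mode_rates=(83.5, 62.5), mode_weight=0.9272
    ),
    "telemed42": TimingModel(
        nominal_rate=42.0, mode_rates=(41.5, 36.0), mode_weight=0.8562
    ),
    "sonix-drop": TimingModel(
        nominal_rate=150.7,
        mode_rates=(150.7, 150.7),
        mode_weight=1.0,
        jitter_sd=27.937e-6,
        drop_prob=0.05,
        quantization=1e-7,
    ),
}

HARDWARE_QUANTIZATION = 25e-6  # s, acquisition-card measurement accuracy


def generate_true_frame_times(
    model: TimingModel, duration: float, seed: int
) -> tuple[TimestampSeries, np.ndarray]:
    """Draw true frame times over ``[0, duration]`` from the IFI mixture.

    Returns the metadata-source timestamp series (starting at 0, strictly
    increasing, quantized to ``model.quantization``) and the realized IFIs.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = _component_rng(seed, _SEED_FRAMES)
    ifi_choices = np.array([1.0 / model.mode_rates[0], 1.0 / model.mode_rates[1]])
    # generous upper bound on the frame count, then truncate at duration
    n_max = int(np.ceil(duration * max(model.mode_rates))) + 10
    picks = rng.random(n_max) >= model.mode_weight  # True -> minor mode
    ifis = ifi_choices[picks.astype(int)]
    times = np.concatenate([[0.0], np.cumsum(ifis)])
    if model.quantization > 0:
        times = np.round(times / model.quantization) * model.quantization
    times = times[times <= duration + 1e-12]
    series = TimestampSeries(times, source="metadata", quantization=model.quantization)
    return series, np.diff(times)


def degrade_to_software_timestamps(
    true_times: TimestampSeries,
    model: TimingModel,
    seed: int,
    drop_indices: np.ndarray | None = None,
) -> tuple[TimestampSeries, np.ndarray]:
    """Produce the software-side record: dropped frames plus read-out jitter.

    ``drop_indices`` overrides the Bernoulli(drop_prob) draw (useful for
    constructing exact test cases).  Jitter that would break monotonicity is
    clamped (running-maximum enforcement); the clamp count is logged.
    Returns the software series and the ground-truth dropped frame indices.
    """
    rng = _component_rng(seed, _SEED_SOFTWARE)
    t = true_times.times
    if drop_indices is None:
        dropped = np.flatnonzero(rng.random(len(t)) < model.drop_prob)
    else:
        dropped = np.asarray(drop_indices, dtype=int)
    keep = np.setdiff1d(np.arange(len(t)), dropped)
    out = t[keep] + rng.normal(0.0, model.jitter_sd, size=len(keep))
    clamped = np.maximum.accumulate(out)
    n_clamped = int(np.count_nonzero(clamped > out))
    if n_clamped:
        logger.info("software-timestamp jitter clamped at %d frames", n_clamped)
    series = TimestampSeries(clamped, source="software", quantization=0.0)
    return series, dropped


def hardware_timestamps(
    true_times: TimestampSeries, quantization: float = HARDWARE_QUANTIZATION
) -> TimestampSeries:
    """True transmission times as seen by the acquisition card.

    No drops, no jitter — only quantization to the card's measurement
    accuracy (default 25 µs).
    """
    t = true_times.times
    if quantization > 0:
        t = np.round(t / quantization) * quantization
    return TimestampSeries(t, source="hardware", quantization=quantization)


def _base_texture(
    image_size: tuple[int, int], grain: float, rng: np.random.Generator
) -> np.ndarray:
    """Speckle-like texture: low-pass-filtered white noise, 8-bit range."""
    h, w = image_size
    noise = rng.standard_normal((h, w))
    smooth = ndimage.gaussian_filter(noise, sigma=grain, mode="wrap")
    smooth = (smooth - smooth.mean()) / smooth.std()
    return np.clip(127.0 + 45.0 * smooth, 0, 255)


def generate_speckle_sequence(
    frame_times: TimestampSeries,
    schedule: TwitchSchedule,
    image_size: tuple[int, int] = (128, 128),
    grain: float = 2.0,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> tuple[ImageSequence, np.ndarray]:
    """Render a speckle sequence warped by the scheduled twitches.

    Each frame is the base texture inversely warped by the analytic
    displacement field at that frame's time, plus i.i.d. Gaussian intensity
    noise, rounded to 8 bits.  The second return value is the ground-truth
    per-transition displacement of the twitch-region centre: row k holds
    d(centre, t[k+1]) - d(centre, t[k]) in (dx, dy) pixels.
    """
    h, w = image_size
    if h < 64 or w < 64:
        raise ValueError("image_size must be at least 64x64")
    if grain < 1:
        raise ValueError("grain must be >= 1")
    times = frame_times.times
    last_motion = (
        schedule.onsets[-1] + schedule.latency + schedule.duration
        if len(schedule.onsets)
        else -np.inf
    )
    if len(times) and last_motion > times[-1]:
        logger.warning(
            "twitch window extends past the last frame (%.3f s > %.3f s); truncated",
            last_motion,
            times[-1],
        )
    rng = _component_rng(seed, _SEED_IMAGES)
    base = _base_texture(image_size, grain, rng)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    frames = np.empty((len(times), h, w), dtype=np.uint8)
    for k, t in enumerate(times):
        if schedule.profile(t) > 0:
            dx, dy = schedule.displacement_at(xx, yy, t)
            img = ndimage.map_coordinates(
                base, [yy - dy, xx - dx], order=3, mode="reflect"
            )
        else:
            img = base
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=(h, w))
        frames[k] = np.clip(np.round(img), 0, 255).astype(np.uint8)
    cx, cy = schedule.region_centre
    centre_dx, centre_dy = schedule.displacement_at(cx, cy, times)
    truth = np.column_stack([np.diff(centre_dx), np.diff(centre_dy)])
    return ImageSequence(frames), truth


def generate_emg(
    onsets: np.ndarray, model: EMGModel, duration: float, seed: int
) -> EMGTrace:
    """Simulate the EMG channel: noise + per-stimulus artifact and M-wave."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = _component_rng(seed, _SEED_EMG)
    n = int(round(duration * model.fs))
    t = np.arange(n) / model.fs
    sig = rng.normal(0.0, model.noise_sd, size=n) if model.noise_sd > 0 else np.zeros(n)
    for onset in as_onsets(onsets):
        tau = t - onset
        half = model.artifact_width / 2.0
        sig += np.where(
            (tau >= 0) & (tau < half), model.artifact_amplitude, 0.0
        ) + np.where(
            (tau >= half) & (tau < model.artifact_width),
            -model.artifact_amplitude,
            0.0,
        )
        sig += model.mwave(t - onset - model.mwave_latency)
    return EMGTrace(fs=model.fs, samples=sig)


@dataclass
class SyntheticDataset:
    """In-memory bundle of everything one simulated trial produces."""

    timing: TimingModel
    schedule: TwitchSchedule
    emg_model: EMGModel
    duration: float
    seed: int
    metadata_times: TimestampSeries
    software_times: TimestampSeries
    hardware_times: TimestampSeries
    dropped_indices: np.ndarray
    images: ImageSequence
    transition_truth: np.ndarray  # (n-1, 2) centre displacement per transition
    emg: EMGTrace


def generate_dataset(
    timing: TimingModel | None = None,
    schedule: TwitchSchedule | None = None,
    emg_model: EMGModel | None = None,
    duration: float = 40.0,
    image_size: tuple[int, int] = (128, 128),
    grain: float = 2.0,
    image_noise_sd: float = 2.0,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate one complete synthetic trial (timing, imagery, EMG)."""
    timing = timing or TimingModel()
    emg_model = emg_model or EMGModel()
    if schedule is None:
        cx = image_size[1] / 2.0
        cy = image_size[0] / 2.0
        schedule = TwitchSchedule(region_centre=(cx, cy))
    meta, _ = generate_true_frame_times(timing, duration, seed)
    software, dropped = degrade_to_software_timestamps(meta, timing, seed)
    hardware = hardware_timestamps(meta)
    images, truth = generate_speckle_sequence(
        meta, schedule, image_size=image_size, grain=grain,
        noise_sd=image_noise_sd, seed=seed,
    )
    emg = generate_emg(schedule.onsets, emg_model, duration, seed)
    return SyntheticDataset(
        timing=timing,
        schedule=schedule,
        emg_model=emg_model,
        duration=duration,
        seed=seed,
        metadata_times=meta,
        software_times=software,
        hardware_times=hardware,
        dropped_indices=dropped,
        images=images,
        transition_truth=truth,
        emg=emg,
    )


def _write_timestamp_csv(path: Path, series: TimestampSeries) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(f"# quantization_s={float(series.quantization)!r}\n")
        fh.write("frame_index,timestamp_s,source\n")
        for i, t in enumerate(series.times):
            fh.write(f"{i},{float(t)!r},{series.source}\n")


def write_dataset(output_dir: str | Path, dataset: SyntheticDataset) -> dict[str, Path]:
    """Write a dataset directory (TIFF stack + CSV sidecars + config echo).

    Layout::

        images.tif                 8-bit multi-page TIFF, acquisition order
        timestamps_metadata.csv    frame_index,timestamp_s,source
        timestamps_software.csv    (same dialect; dropped frames absent)
        timestamps_hardware.csv
        emg.csv                    time_s,emg_mV
        stimuli.csv                stim_index,onset_s
        ground_truth_twitches.csv  twitch_index,onset_s,movement_onset_s
        ground_truth_dropped.csv   dropped_frame_index
        ground_truth_motion.csv    transition_index,dx_px,dy_px
        config.json                all generation parameters and the seed
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["images"] = out / "images.tif"
    tifffile.imwrite(paths["images"], dataset.images.frames, photometric="minisblack")

    for name, series in (
        ("metadata", dataset.metadata_times),
        ("software", dataset.software_times),
        ("hardware", dataset.hardware_times),
    ):
        p = out / f"timestamps_{name}.csv"
        _write_timestamp_csv(p, series)
        paths[f"timestamps_{name}"] = p

    emg_df = pd.DataFrame(
        {"time_s": dataset.emg.times, "emg_mV": dataset.emg.samples}
    )
    paths["emg"] = out / "emg.csv"
    emg_df.to_csv(paths["emg"], index=False, lineterminator="\n")

    onsets = dataset.schedule.onsets
    paths["stimuli"] = out / "stimuli.csv"
    pd.DataFrame({"stim_index": np.arange(len(onsets)), "onset_s": onsets}).to_csv(
        paths["stimuli"], index=False, lineterminator="\n"
    )

    paths["gt_twitches"] = out / "ground_truth_twitches.csv"
    pd.DataFrame(
        {
            "twitch_index": np.arange(len(onsets)),
            "onset_s": onsets,
            "movement_onset_s": onsets + dataset.schedule.latency,
        }
    ).to_csv(paths["gt_twitches"], index=False, lineterminator="\n")

    paths["gt_dropped"] = out / "ground_truth_dropped.csv"
    pd.DataFrame({"dropped_frame_index": dataset.dropped_indices}).to_csv(
        paths["gt_dropped"], index=False, lineterminator="\n"
    )

    paths["gt_motion"] = out / "ground_truth_motion.csv"
    pd.DataFrame(
        {
            "transition_index": np.arange(len(dataset.transition_truth)),
            "dx_px": dataset.transition_truth[:, 0],
            "dy_px": dataset.transition_truth[:, 1],
        }
    ).to_csv(paths["gt_motion"], index=False, lineterminator="\n")

    config = {
        "seed": dataset.seed,
        "duration_s": dataset.duration,
        "timing": asdict(dataset.timing),
        "schedule": {
            **asdict(dataset.schedule),
            "onsets": list(map(float, dataset.schedule.onsets)),
        },
        "emg_model": asdict(dataset.emg_model),
        "image_shape": list(dataset.images.frames.shape),
    }
    paths["config"] = out / "config.json"
    with open(paths["config"], "w", newline="\n") as fh:
        json.dump(config, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
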