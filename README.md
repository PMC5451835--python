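# ussync

**Inter-frame-interval auditing and synchronization correction for dynamic
ultrasound imaging.**

## The problem

B-mode ultrasound is increasingly used to measure tissue *dynamics* — muscle
twitches, fascicle strain, tendon displacement — not just static anatomy.
Those analyses almost always assume the constant frame rate displayed on the
machine. In practice the inter-frame interval (IFI, with frame rate = 1/IFI)
of clinical scanners can vary substantially within a single acquisition:
true IFIs may follow a bimodal distribution around the stated rate, software
timestamps jitter and silently drop frames, and only hardware trigger
signals reflect the actual transmission timing. When the constant-IFI
assumption is wrong in the mean, the timing error *accumulates* over a
trial. Within tens of seconds a measured tissue response can appear to
precede the stimulus that evoked it — a physiological impossibility that is
purely a synchronization artefact.

`ussync` provides, for researchers doing dynamic ultrasound with
synchronized EMG/stimulation:

- **IFI diagnostics** (`ussync.ifi_analysis`): read per-frame timestamp
  records, decompose the IFI distribution into its modes (deterministic 1-D
  two-class k-means), detect dropped frames (gaps > 1.5× the dominant IFI),
  test whether timing error accumulates (one-sample test of mean IFI against
  the nominal rate), and compare hardware vs software records.
- **Twitch detection** (`ussync.tracking`, `ussync.twitchstat`): sparse KLT
  feature tracking (Shi–Tomasi minimum-eigenvalue selection + iterative
  Lucas–Kanade refinement) between consecutive frames, converted to a
  per-transition twitch-likelihood score: the mutual information *I(X; Y)*
  between a feature's spatial cell *X* and its quantized displacement *Y*.
  Coherent localized motion gives high MI; acquisition noise gives MI ≈ 0.
- **Correction** (`ussync.correction`): drift accounting
  (drift\[k\] = t_actual\[k\] − k/f_nominal), trace resampling onto corrected
  time bases, constant-delay estimation by lag scanning, and
  stimulus-to-twitch latency measurement.
- **Synthetic data** (`ussync.synthgen`): fully ground-truthed simulated
  trials — bimodal frame timing, software jitter/drops, hardware quantization,
  speckle imagery warped by scheduled twitches, and a matched EMG channel —
  so the entire chain is testable without any ultrasound device.

## Worked example

Simulate a 20 s trial on the 82 fps bimodal-timing preset (dominant mode
83.5 fps, minor mode 62.5 fps, dominant fraction 0.9272 — the behaviour of a
scanner whose display says "82 fps"), with nerve stimulation every 5 s:

```python
import numpy as np
from ussync import synthgen, pipeline
from ussync.ifi_analysis import summarize
from ussync.correction import frame_times_assumed, stimulus_latencies
from ussync.twitchstat import detect_events
from ussync.datatypes import TwitchTrace

ds = synthgen.generate_dataset(
    schedule=synthgen.TwitchSchedule(onsets=np.arange(5.0, 20.0, 5.0)),
    duration=20.0, seed=7,
)

report = summarize(ds.metadata_times, nominal_rate=82.0)
print(f"frames: {report.n_frames}")
print(f"mode rates: {report.mode_centres[0]:.2f} / {report.mode_centres[1]:.2f} fps")
print(f"mode fractions: {report.mode_fractions[0]:.4f} / {report.mode_fractions[1]:.4f}")
print(f"mean rate: {report.mean_rate:.2f} +/- {report.sd_rate:.2f} fps")
print(f"variability: {report.variability_class}")

trace = pipeline.compute_twitch_trace(ds.images, ds.metadata_times)
for label, base in [
    ("assumed 82 fps", frame_times_assumed(len(ds.metadata_times), 82.0)),
    ("per-frame IFIs", ds.metadata_times.times),
]:
    mid = 0.5 * (base[:-1] + base[1:])
    events = detect_events(TwitchTrace(mid, trace.scores))
    lat = stimulus_latencies(events, ds.schedule.onsets)
    print(f"{label}: latencies (ms) =", np.round(lat * 1e3, 1))
```

Output:

```
frames: 1631
mode rates: 83.50 / 62.50 fps
mode fractions: 0.9276 / 0.0724
mean rate: 81.98 +/- 5.44 fps
variability: cumulative
assumed 82 fps: latencies (ms) = [-18.3 -67.1 -79.3]
per-frame IFIs: latencies (ms) = [ 8.9 16.  10.8]
```

Reading this: the bimodal fit recovers the generator's timing mixture; the
mean IFI is *larger* than 1/82 s, so the deviation is classified
`cumulative` — the constant-rate assumption accrues error over the trial.
Under that assumption the measured stimulus-to-twitch latencies drift
negative (the twitch *appears to precede its stimulus* by 79 ms at the third
stimulus). Re-timing the same twitch-likelihood trace with the per-frame
IFIs restores causal latencies, each below one frame interval (12.2 ms)
plus the simulated 10 ms physiological delay.

## Command line

```bash
ussync --set seed=1 simulate -o trial/          # ground-truthed dataset
ussync track trial/ -o trial/trace.csv          # KLT + MI twitch trace
ussync report trial/timestamps_metadata.csv --nominal-rate 82
ussync evaluate trial/ -o trial/eval/           # latencies, both assumptions
```

All commands accept `--config file.ini` and repeatable `--set key=value`
overrides, echo the fully resolved configuration into the output directory,
and are byte-deterministic for a given config + seed.

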