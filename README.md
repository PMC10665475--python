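# respfusion

Respiratory-rate monitoring inside a driving car, for researchers working on
unobtrusive in-vehicle vital-sign sensing.  The package implements the full
multimodal pipeline around a redundant cabin sensor set — a piezoelectric
pressure sensor in the seat belt, a seat-belt accelerometer paired with a
seat accelerometer that records vehicle noise only, and two video-derived
traces (mean green intensity of fixed regions over the belt and chest) —
with a chest belt as ground truth.  Snippets of the fused signals are
classified as containing a breathing event or not by small CNNs under four
fusion strategies, evaluated leave-one-subject-out.

## What it computes

**Reference-channel spectral denoising.**  With X₁(k) the spectrum of the
band-passed, PCA-combined seat-belt accelerometer (respiration + noise) and
X₂(k) that of the seat accelerometer (noise only):

    SF(k)     = exp(−|X₂(k)| / μ(|X₁|))
    X_supp(k) = SF(k) · X₁(k)

inverse-transformed back to the time domain (applied per Blackman-windowed
segment by default; see `docs/methods.md` for the numerical reasoning).

**Video ROI traces.**  Per frame, color_avg = (1/(w·h)) Σ Pixel over the
green channel of a fixed rectangle; ROI positions are verified against the
first frame by local-contrast maximization.

**Snippet classification.**  All channels are resampled to 200 Hz, median
filtered, normalized to [−1, 1] and cut into 201-sample windows (training
overlap 190, test overlap 200).  A window is positive when a chest-belt
breathing peak falls within ±0.25 s of its center.  Four strategies share
the same branch topology, conv(4 × 20) → dropout(0.5) → max-pool → dense
sigmoid:

| strategy | branches |
| --- | --- |
| early fusion | 1, convolving all channels jointly |
| signal-based late fusion | one per signal |
| sensor-based late fusion | two per signal |
| hybrid | 2-of-3 majority vote over the other three |

**Evaluation.**  P = (PPV + S)/2 in percent, with PPV = TP/(TP+FP) and
S = TP/(TP+FN), per leave-one-subject-out fold, scenario (city / highway /
countryside), strategy and signal subset; scenario means and an overall
Mean_P per strategy.

A synthetic study generator produces multimodal recordings with exact
ground-truth peak trains (shared vehicle noise across the two
accelerometers, native sensor rates, configurable per-scenario noise), so
the entire pipeline runs and is tested without any data download.

## Worked example

```python
import numpy as np
import respfusion as rf

# one synthetic subject driving in the city
subject = rf.SimSubject("demo", breathing_rate_bpm=15.0, seed=0)
sim = rf.simulate_recording(subject, rf.SCENARIO_PROFILES["city"], duration_s=120.0)
clean = sim.clean_respiration.samples[::2]          # clean respiration at 100 Hz

acc1 = tuple(sim.recording[f"acc1_{a}"] for a in "xyz")   # seat belt: signal + noise
acc2 = tuple(sim.recording[f"acc2_{a}"] for a in "xyz")   # seat: noise reference

raw = rf.pca_axis_combine(*acc1)                     # no denoising
den = rf.denoise_accelerometer(acc1, acc2)           # band-pass + PCA + suppression

r_raw = abs(np.corrcoef(raw.samples, clean)[0, 1])
r_den = abs(np.corrcoef(den.samples, clean)[0, 1])
print(f"correlation with clean respiration: raw PC1 {r_raw:.3f} -> denoised {r_den:.3f}")

peaks = rf.detect_reference_peaks(rf.resample_to(sim.recording["reference"], 200.0))
print(f"breathing peaks found on the chest belt: {len(peaks)} "
      f"(ground truth: {len(sim.peaks)})")
```

prints

```
correlation with clean respiration: raw PC1 0.290 -> denoised 0.922
breathing peaks found on the chest belt: 29 (ground truth: 29)
```

The raw first principal component of the seat-belt accelerometer is
dominated by road vibration (correlation 0.29 with the true breathing
waveform); after band-passing and suppressing the spectrum against the
seat sensor, the denoised trace follows the breathing at correlation 0.92.
The chest-belt detector recovers all 29 breathing peaks of the two-minute
drive (15 breaths/min with slow rate wander).

A full experiment over a simulated cohort:

```python
recs = rf.simulate_study(6, rf.SCENARIOS, duration_s=180.0, master_seed=7)
cfg = rf.PipelineConfig(epochs=5, seed=1)
table = rf.run_experiment(recs, strategies=["signal_late"], config=cfg)
print(rf.aggregate_scenarios(table))
```

There is also a CLI (`respfusion simulate / preprocess / video2trace /
snippets / train / evaluate`); `respfusion --help` lists the subcommands.

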