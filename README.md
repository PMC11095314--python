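# phyloemg

Analysis of locomotor electromyography (EMG) from signal to phylogeny: burst
detection in raw muscle recordings, stride-cycle normalization, posture/speed
regression of burst amplitude, and quantitative cross-species comparison of
muscle activation phases.

The package is aimed at comparative biomechanists who record fine-wire EMG
during locomotion (e.g. forelimb muscles of a walking crocodylian) and want
to (a) extract burst onset/offset times and amplitudes reproducibly, without
hand-picked thresholds, and (b) place multiple species — each with its own
gait and published timing conventions — into a common "phylo-EMG space".

## What it computes

**Burst detection.** Signals are conditioned (order-2 Butterworth 10–500 Hz
bandpass, rectification, 10 Hz envelope, decimation to 500 Hz; zero-phase by
default) and thresholded by randomization: 50 equally spaced thresholds are
applied to the envelope, supra-threshold *runs* are counted for the original
series and for random shuffles of its samples, and the optimal threshold
maximizes the excess of shuffled over original runs. Onsets/offsets are then
refined to the 50% baseline-to-plateau crossing, which is unbiased under
symmetric smoothing. Mean burst amplitude is ∫|EMG| dt / duration (µV).

**Stride normalization and regression.** Event times become relative stride
time in [0, 1): stance maps onto [0, 0.71), swing onto [0.71, 1). Burst
amplitude (or normalized duration) is regressed per channel on mean-centered
shoulder adduction angle and dimensionless speed v/√(g·h), with interaction.

**Cross-taxon phases.** Each species' timings are remapped onto a common
0.5/0.5 cycle; the mid burst phase is the circular midpoint
onset + (offset − onset)/2 (mod 1); per-muscle dissimilarity between taxa is
the wrapped distance 2·min(|Δ|, 1 − |Δ|); and the overall taxon × taxon
matrix is the maximum observable rescaled distance (MORD),
√(Σ dᵢ²)/√m over the m shared muscles — a strict 0–1 scale.

**Ordination.** The MORD matrix is embedded by principal coordinates
(classical scaling, n − 1 axes, Cailliez additive correction when
non-Euclidean), and internal nodes of a time-calibrated phylogeny get
maximum-likelihood Brownian-motion ancestral positions per axis.

A synthetic-data module generates EMG recordings (amplitude-modulated
band-limited Gaussian noise with 10 ms cosine-ramped bursts), strides,
posture covariates, and multi-taxon timing tables with known ground truth,
so every stage is testable end to end. See `docs/methods.md` for the full
model description and design rationale.

## Worked example

Simulate a 6-stride bout with one 300 ms burst per stride at 5× background
noise, then detect the bursts (`examples/01_simulate_and_detect.py`):

```python
import phyloemg as pe

strides = pe.gen_stride_events(6, stance_s=0.5, swing_s=0.2, jitter_frac=0.1,
                               seed=0, start_s=0.5)
schedule = pe.stride_burst_schedule("PEC_sim_ch1", strides, gain=25.0,
                                    background_rms=5.0)
rec, truth = pe.gen_emg_recording(schedule, fs=5000.0,
                                  duration=float(strides.touchdowns[-1] + 0.5),
                                  seed=1)
cfg = pe.RunConfig(seed=1)
bursts, scan = pe.detect_channel(pe.process_emg(rec, cfg)["PEC_sim_ch1"], cfg)
```

Output:

```
optimal threshold: 4.18 uV (scan of 50 levels, 10 shuffles)
 true onset  true offset  det onset  det offset  amp uV
      0.500        0.808      0.504       0.814   19.89
      1.204        1.477      1.200       1.476   20.01
      1.839        2.158      1.840       2.160   21.34
      ...
```

Detected edges sit within ~10 ms of the planted times, and the recovered
mean amplitudes (~20 µV) match the planted in-burst RMS of
background + gain = 30 µV times 2/π ≈ 0.64, the rectified-Gaussian mean.

The other examples walk through stride normalization and timing summaries
(`02`), posture/speed regression with planted coefficients (`03`), burst
rules → mid phases → MORD (`04`), and PCO plus ancestral states on the
packaged reference topology (`05`). Each prints the quantities it computes
and a line on how to read them. A thin CLI mirrors the same steps
(`phyloemg simulate|process|detect|strides|regress|compare|ordinate`, each
with `--config`, `--seed`, `--out-dir`), writing CSV outputs and a JSON run
log sufficient to reproduce a run bit-identically.

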