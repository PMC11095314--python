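# Methods

This note documents the models, algorithms, and design choices behind
`phyloemg`, in the order the pipeline applies them.

## Signal conditioning

Raw multichannel EMG (µV, nominally 5000 Hz) is processed per channel in a
fixed order: order-2 Butterworth bandpass (default 10–500 Hz) → full-wave
rectification → order-2 Butterworth lowpass (default 10 Hz) to extract the
envelope → decimation to 500 Hz. Two branches are retained at the target
rate: the rectified band-passed signal feeds amplitude metrics (area under
the curve per unit burst duration), and the smoothed envelope feeds burst
detection. The upstream hardware acquisition filter (30–6000 Hz) is treated
as a property of the input, not re-applied.

Filters are applied zero-phase (forward–backward, `sosfiltfilt` with 1 s
reflective padding, or the signal length if shorter) because onset/offset
timing is the scientific payload and causal filters delay the envelope by
their group delay (~15–30 ms at these cutoffs); note the effective order
doubles. A causal mode (`RunConfig(zero_phase=False)`) is exposed for
sensitivity analysis — the choice moves absolute onset estimates by roughly
10–30 ms. Envelope samples driven below zero by filter ringing are clipped
to 0 because thresholds assume a nonnegative envelope. Decimation keeps
every k-th sample and relies on the preceding 10 Hz lowpass as the
anti-alias guard; the decimation ratio must be integral.

## Randomization-threshold burst detection

The detector avoids a hand-picked activity threshold. Fifty equally spaced
thresholds (2% increments of the observed envelope range, from min + 2% to
the maximum) are applied to the envelope, and the number of supra-threshold
*runs* (maximal contiguous segments strictly above threshold) is counted.
The same counts are taken on random shuffles of the envelope's samples
(sampling without replacement preserves the amplitude distribution but
destroys temporal structure); the optimal threshold maximizes the mean
excess of shuffled over original runs, with ties broken toward the lowest
threshold. A sustained burst is one run in the original series but scatters
into hundreds of runs when shuffled, so the excess peaks where activity
separates from noise. The default averages 10 shuffles; a single shuffle
reproduces the stricter single-randomization reading and lands within a few
grid steps on the same plateau.

Run counting happens on the 500 Hz envelope (after downsampling, matching
the stated stage order). The vectorized scan (counting, for each rising
sample pair, how many thresholds it crosses) is verified in the tests
against a naive per-threshold loop.

Detected supra-threshold intervals are post-processed deterministically, as
a stand-in for the manual inspection step practitioners otherwise apply:

1. **Merge** intervals separated by ≤ 50 ms, then **drop** intervals shorter
   than 30 ms (in that order).
2. **Edge refinement**: each interval's onset (offset) is moved inward to
   the first (last) sample at or above the 50% level between the local
   baseline (median of all sub-threshold envelope samples) and the burst
   plateau (median of the interval's central half). The optimal threshold
   typically sits just above the noise ceiling — a low fraction of the
   burst height — and the 10 Hz envelope spreads each edge over tens of
   milliseconds, so raw threshold crossings are systematically ~25–30 ms
   early (onset) and late (offset). The 50% crossing of a transition
   smoothed by any *symmetric* (zero-phase) filter coincides with the true
   edge, making the refined times unbiased; with the defaults, measured
   errors at SNR 5 are ≤ ~15 ms. Refinement leaves intervals unchanged when
   the midpoint level does not exceed the detection threshold (e.g. weak or
   noise-level intervals) and is exact on noise-free square envelopes.

Mean burst amplitude is the trapezoidal integral of the rectified signal
over exactly [onset, offset] (endpoint-interpolated) divided by the burst
duration. For biphasic muscles the primary burst maximizes mean amplitude,
with ties broken by longer duration, then earlier onset.

## Stride-cycle normalization

Stride events are alternating touchdown/liftoff times; cycle *i* spans
touchdown *i* to touchdown *i+1*. Event times map piecewise-linearly onto
relative stride time: stance onto [0, sf), swing onto [sf, 1), with the
stance fraction sf fixed study-wide (default 0.71) rather than per stride,
so strides of different absolute duration are comparable. Each burst is
assigned to the stride containing its midpoint — robust for bursts that
wrap touchdown (e.g. a pectoralis-like burst starting in late swing, whose
onset then appears as a cycle time near 1). Normalized duration is
(offset − onset) mod 1. Bursts spanning more than two cycles, or lying
outside the recorded strides (beyond a one-cycle extension of the first and
last stride's timing pattern), are excluded with a log entry.

Timing summaries report mean ± SE (sd/√n) of onset and offset cycle times.
Linear averaging is the default — appropriate when values cluster away from
a wrap collapse, and matching how such tables are conventionally reported —
with circular (mean-direction) averaging available for distributions
straddling 0/1. Strides are the unit of replication; distinct channel and
animal counts are reported alongside when present.

## Posture/speed regression

Walking speed is normalized as dimensionless (Froude-type) speed
v/√(g·h), with h the extended hindlimb length (m) and g = 9.81 m/s².
For each channel, mean burst amplitude (or normalized burst duration) is
regressed by OLS on shoulder adduction angle (degrees; abduction positive)
and dimensionless speed, both centered on their sample means, plus their
product. Centering reduces collinearity with the interaction term and
leaves main-effect slopes of the interaction-free model unchanged (verified
numerically in the tests). Two-sided t-test p-values are reported per
coefficient with no multiple-testing correction (raw p at α = 0.05),
documented here as a caveat. Pooling channels is deliberately unsupported:
amplitudes are not comparable across electrode placements or gains. A
degenerate constant response returns zero slopes with p = 1.

## Cross-taxon phase comparison

Timings from different species, each on its own declared stance fraction,
are remapped endpoint-wise onto a common 0.5 stance / 0.5 swing cycle
(piecewise-linear in the same way as stride normalization). Declarative
burst rules then clean multi-burst muscles: `group` replaces bursts 1 and 2
by one burst from the first onset to the second offset (mod 1);
`drop_secondary` keeps burst 1. The packaged default rules file encodes the
four cleaning actions used in the sauropsid comparison; rules are config,
not hard-coded taxa.

The mid burst phase is the circular midpoint onset + (offset − onset)/2,
computed mod 1 (offset advanced by a cycle when the burst wraps touchdown).
Pairwise per-muscle dissimilarity is the wrapped distance
2·min(|Δ|, 1 − |Δ|): a true metric on the circle (verified exhaustively on
a 0.01 grid) scaled so antiphase = 1. The overall taxon × taxon matrix is
the maximum observable rescaled distance (MORD): over the m muscles a pair
shares, √(Σ dᵢ²)/√m, where √m is the Euclidean distance attained when every
shared muscle is at the antiphase maximum — hence a strict 0–1 scale.
Missing muscles are handled pairwise; pairs sharing fewer than
`min_shared_muscles` (default 3) are excluded (NaN) and reported, and
`MordResult.drop_excluded_taxa()` returns the largest complete submatrix.

## Ordination and phylo-EMG space

The MORD matrix is embedded by classical scaling into n − 1 axes:
double-center −D²/2, eigendecompose, scale eigenvectors by √eigenvalue.
Axes with numerically nonpositive eigenvalues contribute zero coordinates.
When the matrix is non-Euclidean and correction is requested, the Cailliez
additive constant — the largest real eigenvalue of the 2n × 2n block matrix
[[0, 2Δ₁], [−I, −4Δ₂]], the smallest constant whose addition to all
off-diagonal dissimilarities makes them Euclidean — is applied first and
recorded on the result. Coordinates are unique only up to orthogonal
transforms, so reconstructed inter-point distances, not raw coordinates,
are the tested contract (cross-checked against scikit-bio's implementation
on Euclidean inputs).

Trees are Newick with positive branch lengths in Ma (dendropy underneath);
a root stem length of 1 Ma is carried as metadata. A packaged four-taxon
tree with topology ((Trachemys,(Alligator,Sturnus)),Varanus) and *synthetic
placeholder* branch lengths ships for tests and examples — it is not a
published time calibration. Ancestral positions are computed per axis as
maximum-likelihood Brownian-motion estimates: the joint ML states minimize
the branch-length-weighted sum of squared changes Σ(x_parent − x_child)²/ℓ
with tips fixed, a sparse linear system solved directly. This equals the
GLS/re-rooting construction (verified in the tests against an independent
covariance-matrix implementation), makes each internal estimate a convex
combination of tip values, and is translation-equivariant. The phylo-EMG
space output is a plain table of tip and internal-node coordinates plus the
edge list; no rendering is performed.

## Synthetic data

The generator emulates the features the pipeline's assumptions rest on, not
EMG biophysics. Signals are zero-mean Gaussian noise band-limited to a
30–500 Hz carrier, scaled so the local RMS equals the background level
(default 5 µV) outside bursts and background + gain inside, with 10 ms
cosine ramps at burst edges; the ramp midpoint defines the true
onset/offset. Defaults plant 300 ms bursts at gain 25 µV (SNR 5 as
gain/background). Strides default to 0.5 s stance / 0.2 s swing (stance
fraction ≈ 0.714, matching the study-scale ~0.71), with optional
multiplicative jitter per phase. Posture datasets draw angle and
dimensionless speed uniformly (defaults: −60° to −20°, 0.05–0.35) and build
amplitude from planted centered-model coefficients plus Gaussian noise.
Timing tables place each (taxon, muscle) burst symmetrically around
base + shift, so true mid phases are known exactly. All randomness flows
from one explicit seed per call.

What this does *not* emulate: motor-unit superposition and firing
statistics, cross-talk between channels, amplitude drift within bursts,
non-Gaussian noise, or movement artefact. Passing the recovery tests
therefore shows the chain is correct and unbiased under its own model
assumptions, not that it is robust to every pathology of real recordings.

## Problem sizes and determinism

The test suite exercises the full detection chain on 100 seeded replicates
of a 6-stride bout (≈ 4.8 s at 5000 Hz each), the regression recovery on
200 replicates at n = 50, the threshold scan against a naive oracle on 50
short envelopes, and the ordination oracles on random 6–8 point
configurations and 6-taxon trees — sizes chosen so the whole suite runs in
well under a minute while keeping the Monte-Carlo rates stable. Every
stochastic test and the command-line interface take explicit integer seeds;
identical seeds reproduce results bit-identically, and each CLI run writes
a JSON log of its configuration and seed.

## Known limitations

- The randomization optimum sits on a gentle plateau of the runs-difference
  curve; different shuffle counts can move it a grid step or two. Detection
  results are stable because downstream intervals barely change, but the
  threshold value itself should not be over-interpreted.
- With the threshold near the noise ceiling, occasional 30–50 ms noise
  excursions survive the minimum-duration filter as spurious low-amplitude
  bursts; downstream analyses that assume one burst per stride should
  select the primary burst.
- Cross-taxon comparison inherits the literature timings' own
  normalization; the per-source stance fractions must be supplied and are
  remapped, but digitization error in those sources is not modeled.
- Ancestral-state uncertainty (confidence intervals) is not computed.
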