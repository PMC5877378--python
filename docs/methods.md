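# Methods

## The generative model

Each synthetic subject is a continuous 61-channel recording at 512 Hz:
an eyes-closed resting span, then for each of 18 clips a 5 s pre-trial
baseline, a movie trial block and a recall trial block. Trial blocks are
generated `trial_seconds + trial_margin_seconds` long (the margin mimics
the variable stimulus length; only the final `trial_seconds` are
analysed, mirroring a protocol that keeps the last 50 s of each movie
and of the 1-minute recall). Presentation order of the clips is
randomized per subject; clip → emotion assignment is fixed (clips 1–3
joy, …, 16–18 fear).

Per channel the signal is

    x(t) = background_sd · n_1/f(t) + oscillation_sd · A_c(t) · g_band(t)

with `n_1/f` spectrally shaped Gaussian noise (power ∝ 1/f^exponent,
flattened below 0.5 Hz; default exponent 1.0 — the standard EEG
surrogate), and `g_band` unit-variance Gaussian noise FFT-masked to the
effect band (default gamma, 30–64 Hz). The envelope `A_c(t)` is 1
everywhere except at the five effect channels during trial blocks, where
it takes the class multiplier

| class   | temporal/occipital sites | prefrontal sites |
|---------|--------------------------|------------------|
| joy     | 2.0                      | 1.2              |
| neutral | 1.0                      | 1.0              |
| sad     | 1.25                     | 1.25             |
| disgust | 1.3                      | 2.0              |
| anger   | 1.5                      | 1.5              |
| fear    | 1.4                      | 1.4              |

scaled as `1 + effect_size · attenuation · (m − 1)` with
`attenuation = 1` for movie trials and `recall_attenuation` (default
0.7) for recall trials — recalled emotion shares the movie pattern but
more weakly, which is what makes cross-paradigm transfer succeed yet lag
within-paradigm accuracy. The multipliers are design choices, not
measured quantities: joy peaks over temporal/occipital sites and disgust
over prefrontal sites with neutral lowest everywhere, the qualitative
topography the feature analysis should recover; their magnitudes
(≈0.2–0.6 nats of gamma-DE separation against an epoch-level estimator
noise of ≈0.12 nats) were chosen once to land binary accuracy in the
high-80s/90s range that separable emotional EEG shows, and are exposed
as `SimConfig` knobs.

With default amplitudes (background 10 µV, oscillation 2 µV) the 1/f
background contributes ≈12 % of its variance to the gamma band, so the
class effect rides on a realistic broadband floor rather than a clean
carrier.

Blink artifacts are Poisson events (default 6/min) of a 0.4 s Gaussian
bump (spectral content < 4 Hz), ~120 µV at the prefrontal sites and
decaying posteriorly with the square of the projected anterior
coordinate. Event times are stored as ground truth so cleaning can be
scored.

What the generator does **not** emulate: cortical source dynamics and
volume conduction (channels are independent except for the shared label
structure), non-stationary arousal drifts, muscle/line noise, and any
relation between clip content and signal. Consequences for what passing
tests mean are discussed under *Known limitations*.

## Preprocessing

Band-pass: 4th-order Butterworth 0.1–80 Hz as second-order sections,
applied forward–backward (`sosfiltfilt`) — zero phase, squared
magnitude response. EOG removal: FastICA into `n_channels` sources; a
component is flagged ocular when its time course correlates
(|r| > 0.7) with a surrogate EOG — the 0.5–4 Hz band-limited mean of
Fp1/Fp2 — and flagged components are zeroed before reconstruction. The
criterion is an automated, reproducible stand-in for the visual
component selection typical of such studies. The unmixing is fitted on
an even subsample capped at 50 000 samples and at most 200 fixed-point
iterations; FastICA's convergence tolerance is rarely met on
near-Gaussian backgrounds, but the rotation it reaches isolates the
sparse ocular sources, which is all the cleaning step needs (verified in
the test suite: blink correlation at Fp1 drops from > 0.7 to < 0.3 while
artifact-free channels are preserved at r > 0.95).

Baseline handling discards data: the retained signal is, per trial, the
last `analysis_seconds` of its span; resting baselines, pre-trial spans
and early-trial padding are dropped (no mean subtraction). Epochs of 2 s
with 50 % overlap are cut strictly within trial boundaries:
`floor((L − W)/(W(1 − overlap))) + 1` per trial, i.e. 49 for a 50 s trial
and 882 per subject and paradigm.

## Features

The STFT uses 128-sample Hamming windows with 50 % overlap; frames that
would overrun the epoch are dropped. A band's power in a frame sums the
bins with `low < f_k ≤ high` — half-open so adjacent bands from the band
table (δ 1–4, θ 4–8, α 8–12, β 12–30, γ 30–64 Hz) never share a bin at
the 4 Hz bin pitch of 512 Hz / 128 samples. One DE per band per epoch is
the natural log of the frame-averaged band power: averaging over frames
(rather than per-frame logs) makes the value invariant to frame count,
and the log turns the amplitude-scaling identity DE(a·x) = DE(x) +
log a² exact, which the tests assert to machine precision. Zero band
power is floored at 1e-30 and flagged; the flag never fires on synthetic
data.

EMD sifting: envelopes are natural cubic splines through the local
extrema with two extrema mirrored about each boundary; sifting stops
when |envelope mean| / envelope amplitude < 0.05 at ≥ 95 % of samples
(hard cap 100 sifts); decomposition stops at 8 IMFs or a monotone
residue; signals with fewer than four extrema are residue-only. Because
IMFs are removed by exact subtraction, ΣIMF + residue reconstructs the
input to machine precision by construction — the suite checks
< 1e-8 × range on every epoch. The inner loop (extrema detection, banded
Thomas solve for the spline, evaluation) is numba-compiled; the
envelope kernel is validated against scipy's natural `CubicSpline` on
identical knots, and IMF1 recovery is validated on two-tone signals
(r > 0.95 against the fast tone). Only IMF1 feeds the feature
`log D_t`; a `first_imf` fast path avoids decomposing the remaining
modes during cohort extraction.

Feature order is fixed: the 305-entry DE block (channel-major, bands
δ→γ), then the 61-entry EMD block; names are `<channel>_DE_<band>` and
`<channel>_EMD_Dt`.

## Feature selection

Mutual information is the plug-in estimate from the joint contingency
table of discretized features (3 levels split at μ ± σ, following
original MRMR practice; equal-frequency binning is available). The
greedy step maximizes relevance minus mean redundancy with the selected
set; ties break toward the lower feature index so rankings are
deterministic. Per-subject rankings (the study design is
subject-dependent) are aggregated by counting appearances in each
subject's top-n list, ordering by count, then mean within-list rank,
then index — the package's documented choice for building a
subject-independent top-20 table from per-subject rankings.

## Classification

Linear-kernel SVC with library-default regularization (mirroring a
stock LIBSVM setup), preceded by a StandardScaler fitted on the
training fold only. Folds always split by clip so temporally adjacent,
strongly correlated epochs of one clip can never straddle train and
test. The six-class protocol folds on clip position within emotion; the
binary protocol excludes neutral (3 positive joy clips vs. 12 negative
clips). Cross-paradigm trains on all movie epochs and tests on all
recall epochs; its binary variant restricts both sides to the 15
eligible clips — consistent with pooled binary totals of
30 × 15 × 49 = 22 050 epochs in the reference tables. ROC points sweep
the unique pooled decision values; AUC is trapezoidal; both are
cross-checked against scikit-learn in the tests but computed by the
package's own sweep.

### Chance level

Under label-independent features a trained SVM is *not* a pure
majority-class predictor — it emits a minority-class guess on a
fraction of epochs. The appropriate chance rate is therefore the
marginal expected agreement p_e = Σ_c q_pred(c) · p_true(c) (the chance
term of Cohen's kappa), estimated from the pooled confusion matrix; for
the binary task p_e ≈ 0.71 rather than the majority rate 0.80. The
chance band is the 95 % binomial interval around p_e with the *clip*
(fold) as the unit — epochs within a clip are strongly correlated, so
clip count is the defensible effective n.

## Validation experiments and problem sizes

The standard recovery experiments (`emoeeg.experiments`) keep the full
trial structure — 18 + 18 trials, 6 emotions, 61 channels, 512 Hz — and
scale the per-trial analysis span and cohort size so that a complete
multi-cohort validation runs in minutes on one CPU: 5 subjects with 20 s
spans (test suite and acceptance script), 3-subject cohorts for the
attenuation sweep, and 3 subjects with 20 s spans in the analysis
drivers. The generator's *defaults* keep the emulated study protocol
(30 subjects, 50 s spans, 240 s rest). Chance and attenuation cohorts
run without blinks/ICA, which are label-independent and only add
runtime there.

Observed outcomes at these sizes (seed 1): all five effect channels'
gamma DEs appear in the aggregated MRMR top-20 in both paradigms;
within-paradigm binary accuracy ≈ 96 % (movie) and ≈ 90 % (recall);
with `effect_size = 0` accuracy falls inside the clip-level chance band
around p_e; cross-paradigm binary accuracy rises strictly with the
recall attenuation (80.0 → 85.3 → 98.3 % at 0.3 / 0.7 / 1.0).

### The feature-count curve inverts on sparse synthetic effects

On the study's real recordings, accuracy grows with the number of
MRMR-selected features (top-10 ≈ 85 % → all-366 ≈ 87 % in the binary
task). On the synthetic cohorts the curve runs the other way (top-10
≈ 98 % ≥ all-366 ≈ 90 %): the injected effect lives in ~10 features
(five channels × {DE_γ, EMD_Dt}), so the top-10 set already carries
essentially all class information and the other 356 dimensions
contribute only noise that degrades the SVM. Real EEG spreads class
information across most channels and bands through volume conduction
and broadband power shifts — exactly the physics the generator
deliberately omits. The package reports both accuracies honestly; a
rising curve should not be expected from, nor used to validate against,
this generator.

## Numerical choices and degenerate inputs

- Natural-spline boundary condition with two mirrored extrema per end;
  fewer than four spline knots falls back to linear interpolation, one
  knot to a constant.
- Log floors: 1e-30 for band powers and D_t, always flagged.
- MRMR ties → lowest feature index; aggregation ties → mean rank, then
  index.
- Constant features discretize to a single level and are flagged; their
  MI is exactly 0, so they are never selected before informative ones.
- EDF output quantizes to 16 bits over a per-channel symmetric integer
  range; round-trip error is below one quantization step (verified
  against mne's independent EDF reader). Sampling rates must be integer
  (1 s data records); the exact sample count and the trial annotations
  travel in a JSON sidecar.
- All randomness flows from explicit seeds through
  `numpy.random.SeedSequence`; fixed seeds give bit-identical recordings
  and byte-identical feature matrices.

## Known limitations

- Channel independence in the generator means spatial-filtering stages
  (ICA) face an easier problem than on real, volume-conducted EEG;
  passing the cleaning tests shows the criterion works, not that it
  matches a clinician's component selection.
- The chance-agreement band assumes clips are exchangeable units; with
  very few subjects the band is wide.
- MRMR rankings are computed on each subject's full feature matrix
  (selection is not nested inside the cross-validation folds), matching
  the study design being emulated; accuracies with selected features are
  therefore mildly optimistic.
- The EMD stop rule trades exact IMF-count conditions for bounded
  runtime; broadband IMF1s can miss the extrema/zero-crossing identity
  by a few counts near the boundaries (≤ 1 % of extrema in the suite).
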