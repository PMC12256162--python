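# Methods

This note documents the models and procedures implemented in `lgdnovelty`,
the choices made where the design was genuinely open, and what the
synthetic-data studies do and do not demonstrate.

## Paradigm model

A trial is a quintuple of 100-ms vowels separated by 50-ms gaps, so the
fifth vowel begins 600 ms after trial onset (`fifth_vowel_onset`). Local
deviance is defined per trial (fifth vowel ≠ base vowel); global deviance is
defined per sequence (the quintuple type that appears in ~20% of test
trials). A block holds four sequences; each of the four quintuple types
serves as the global standard of exactly one sequence, ordered by a uniform
random permutation per block. Each sequence opens with 10 habituation trials
of the GS type, followed by 80 GS + 20 GD test trials (variant A) or
72 + 18 (variant B, whose sequences are additionally preceded by a 15-s
silent gap standing in for the spoken instruction). Onset-to-onset intervals
are i.i.d. Normal(1500, 10) ms.

The pseudorandom ordering of test trials is not fully specified by the
protocol; we impose two conventional constraints — the first test trial is
always a GS and no two GD trials are adjacent — and sample uniformly over
all orderings satisfying them (via the bijection between non-adjacent
subsets and unconstrained combinations). These constraints are our
convention, chosen to keep deviants unpredictable; nothing downstream
depends on them beyond the exact 20%/80% composition.

## Synthetic recordings

The generator is plumbing for validation, not a biophysical model. Each
channel is the sum of:

* 1/f-power ("pink") noise, made by spectral shaping of white noise
  (exponent 1, flat below 1 Hz), scaled to 20 µV RMS by default;
* a 60-Hz sinusoid (5 µV) with random phase;
* a damped-sinusoid evoked kernel (12 µV, 6 Hz, 60-ms decay) at every vowel
  onset — minimal AEP-like morphology;
* a stationary high-gamma (70–150 Hz) component (5 µV RMS) on every
  channel, plus vowel-locked high-gamma bursts (100-ms Hann envelope, 3 µV)
  on envelope-following channels;
* optionally, a ~12-Hz narrowband component (sleep-spindle stand-in for the
  band-power sanity check) and Poisson-timed 20-ms artifacts with amplitude
  a configurable multiple (>5) of the channel SD;
* planted effects on designated channels: AEP kinds add a flat-topped
  (Tukey, 10% taper) deflection of the stated amplitude in µV on deviant
  trials; HG kinds multiply the high-gamma component's envelope by the
  stated gain over the effect window. Every effect is scaled by a per-state
  factor in [0, 1], the mechanism that makes effects state-dependent
  (defaults: awake 1.0, sedated 0.5, unresponsive 0).

Default planted latencies are 150 ms (LD) and 450 ms (GD) after the fifth
vowel, with 150-ms durations, mirroring the empirically longer latency of
global-novelty responses. The **detectable preset** (30 µV for AEP effects,
envelope gain 3 for HG effects) was fixed by an a-priori power calculation:
at within-block trial counts (200 vs 200 LD, 320 vs 80 GD) the expected
pointwise t is ≳10 for both signal types — in particular, the pink noise
contributes ~6.6 µV RMS inside 70–150 Hz, so a gain of 3 on the 5-µV
high-gamma component yields a ~6-dB in-band contrast against a ~1.5-dB
single-trial SD after smoothing.

What the generator does **not** emulate: spatially correlated noise across
channels, non-stationary arousal drift within a block, realistic AEP
morphology differences across regions, line-noise harmonic instability, or
behaviorally coupled (task-performance-dependent) GD effects. Passing the
recovery studies therefore shows the chain is correct and calibrated under
exchangeable noise with additive/multiplicative effects — not that it would
have identical operating characteristics on patient data.

## Preprocessing

Recordings are polyphase-resampled to 1000 Hz, then notch-filtered with
cascaded zero-phase IIR notches (Q = 35) at 60 Hz and all harmonics below
Nyquist. The notch cascade deliberately replaces more elaborate line-noise
denoising: it has an explicit, testable frequency response (≥20 dB at the
notches, <1 dB elsewhere). Artifact rejection follows the ±5 SD rule with
mean and SD computed over the **whole block per channel** (not per trial,
and not the kept subset — which makes the partition idempotent); a trial is
dropped for a channel if any sample of its [−100, 1400) ms epoch window
exceeds the threshold. Epoch windows are half-open `[start, end)` in ms;
sample index = ⌊t·rate/1000⌋, 0-based. Baseline correction subtracts the
mean over [−100, 0) ms before trial onset, exactly zeroing it. All filters
(including the 4th-order 30-Hz Butterworth smoother) run forward-backward,
so no stage introduces group delay into cluster timing; the AEP is smoothed
at the single-trial level before statistics, and the high-gamma envelope is
smoothed after extraction.

## High-gamma ERBP

The 70–150 Hz band is isolated with a linear-phase windowed-sinc (Hamming)
FIR of order 300; the even order gives an integer group delay (150 samples)
that is removed exactly. The Hilbert envelope is computed on **continuous**
data and epoched afterwards, avoiding analytic-signal edge artifacts inside
epochs. Power (envelope²) is expressed as 10·log₁₀ and normalized by
subtracting the mean log-power over each experimental sequence, i.e.
normalization to the sequence's geometric mean power, in dB. The subtractive
log-power form was chosen over dividing power by its arithmetic mean because
it makes the per-sequence zero-mean property exact and the output invariant
to any positive rescaling of the raw signal; the dividing form remains
available (`normalization="power"`). An isolated-zero floor of 1e-12 (power
units) guards the log; an all-zero sequence is rejected.

## Cluster-based permutation test

Per site and contrast, a pooled-variance two-sample Student t (df =
n₁+n₂−2) is computed at each time sample of the 0–800 ms post-5th-vowel
window. Pooled rather than Welch variance was chosen so that the
cluster-forming threshold is a single Student-T quantile at a single df:
the 99.5th percentile applied to |t| for the two-tailed AEP test, the 99th
percentile applied to t for the one-tailed high-gamma test (high-gamma
effects are defined as power increases; the model object orients the
one-tailed statistic as deviant − standard). Two-tailed clusters are split
by sign (standard practice), scored by Σt. The null distribution records,
for each of the random relabelings (10,000 by default; group sizes
preserved), the maximum |cluster sum| (two-tailed) or maximum positive sum
(one-tailed), with 0 when no cluster forms. Cluster p-values use the
add-one estimator p = (#{null ≥ |Σt|} + 1)/(N + 1), which cannot be zero;
ties are counted with a 1e-9 relative tolerance so permutations that
recompute the observed partition through the vectorized path still tie.
FDR correction is Benjamini–Hochberg over the family of **all cluster
p-values pooled across sites within one (effect, signal, state) analysis**;
a site exhibits an effect if at least one adjusted cluster p < 0.05.
Degenerate time samples (zero pooled variance) get t = 0 with a warning.

## Prevalence, odds ratios, time courses

Regional prevalence is 100 × (significant sites)/(sites) per ROI or ROI
group. Prevalence comparisons are two-sided Fisher exact tests; the
reported OR is the sample cross-product ratio ad/bc with the Woolf interval
exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)) — this pairing reproduces the
published whole-brain and state-comparison values exactly at printed
precision. With a zero cell the OR and CI are reported as undefined while
the exact p is still computed. State-resistance comparisons tabulate
LD/GD significant-site counts across two states (rows = effect, columns =
state). Effect time courses count, at each millisecond, the sites whose any
significant cluster covers that time.

The shipped count tables encode the published per-ROI distributions for
both cohorts. Two printed-source quirks are handled explicitly: the
dexmedetomidine table's site column sums to 861 while the stated cohort
total is 863 (the whole-brain Fisher denominators use the stated totals,
863 and 764, which also reproduce the printed CI bounds), and one quoted
prevalence (STS sedated, 31.5%) is inconsistent with the table's own counts
(10/31 = 32.3%); the package reports table-derived values. Habituation
trials are excluded from both contrast averages — they establish the global
rule rather than test it; the LD contrast pools both vowel identities and
both global statuses, the GD contrast pools local statuses.

## BIS arousal model

`BIS ~ PrePost * Assessment# + (1 | Participant)`, fitted by maximum
likelihood (statsmodels MixedLM). PrePost is coded 0/1, assessment order as
numeric 1–4, p-values are Wald tests; all three are conventions, as the
protocol fixes none of them. The Wald z reference is mildly anticonservative
at the design size (7 participants × 8 observations): simulation at the
study design puts the PrePost type-I rate near 6% at nominal 5%, which the
parameter-recovery study's pass margins account for.

## Validation studies and problem sizes

* **Null calibration**: 800 simulated sites (50 + 50 trials of 30-Hz
  low-passed white noise, 200 samples), 1,000 permutations each. The
  pre-FDR site flag rate sits within a couple of points of the nominal 5%
  (repeated runs land roughly between 3.5% and 6.5%, the spread expected
  from 800 Bernoulli sites plus the discreteness of 1,000-permutation
  p-values); the post-FDR rate on all-null data is ~0.
* **Recovery study**: one variant-A block, 12 planted channels (3 per
  effect kind at the detectable preset) + 96 null channels, full pipeline,
  1,000 permutations per test. Scores pre-FDR recovery of planted
  (channel, contrast) pairs and the false-positive rate over the 384 null
  tests; also derives the AEP effect-count time courses whose LD peak
  (~150 ms) precedes the GD peak (~450 ms) by construction.
* **Power curve**: flagged fraction at planted amplitudes 0, 0.4, 0.8 noise
  SDs, checked to be non-decreasing.

Study sizes were fixed in advance so the stochastic acceptance bounds sit
several standard errors away from their thresholds, and every study derives
its randomness from a single seed.

## Known limitations

* The demodulated-band-transform denoiser used in the original acquisition
  chain is replaced by the notch cascade; results on data with strongly
  non-stationary line noise will differ.
* Electrode localization, MNI projection and anatomical parcellation are
  out of scope; ROI labels are taken as given in the channel metadata.
* The per-site test assumes exchangeable trials under the null;
  slow within-block drift (e.g. progressive sedation inside one block)
  violates this and is not modeled.
* Fisher CIs are Woolf (asymptotic) by design; they are reported as
  undefined rather than approximated when a cell is zero.
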