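# Methods

## Recording model and conversation structure

The pipeline analyzes one participant interacting with a prerecorded
actress.  The analyzed conversation is modeled as six half-open,
non-overlapping segments on a common clock (seconds after the warm-up,
which is never analyzed): the actress's neutral/positive/negative excerpts
of 26/24/26 s, each followed by a 30-s participant answer window —
166 s in total.  Biomarker summaries are computed per segment and for the
whole-conversation aggregate, giving the "seven parts" used by the feature
builder.  The schedule is configurable via YAML; all default timings live
in `sitpipe.protocol`.

## Quality control

Frame-level: a frame is retained iff it was tracked successfully and its
confidence is ≥ 0.75.  Participant-level: included iff the retained
fraction is ≥ 0.90 **and** the mean confidence is ≥ 0.75.  Mean confidence
is computed over all frames (pre-filter) by default; whether the original
procedure averaged before or after filtering is ambiguous, so the choice
is a keyword argument (`confidence_over_all_frames`).

## Facial biomarkers

Occurrence = mean of the 0/1 presence channel; intensity = mean of the
0–5 intensity channel; both over the retained frames of a part.  Empty
parts yield NaN, never zero.  Part-vs-neutral contrasts are performed as
paired Wilcoxon tests at the statistics stage rather than as subtracted
features.

**Mimicry.** For action unit a, candidate reaction lags τ ∈ {0, 0.25, …,
3.0 s} (mimicry is reactive, so only the participant lagging the actress
is searched).  The participant's intensity series is shifted back by τ and
aligned to the actress clock by nearest timestamp with tolerance of half a
frame period.  The overlap is split into non-overlapping 10-s windows
anchored at its start; windows with < 10 aligned samples or zero variance
on either side are skipped.  Per-window Pearson correlations are averaged
on the Fisher-z scale (tanh of the mean of arctanh r) — this stabilizes
averaging of bounded correlations — and the reported score is the
aggregate at the τ maximizing it (ties break to the smallest τ, so an
exact copy reports lag 0).  Note the lag search makes the null
distribution of the *score* slightly positive by selection; the
no-coupling null property (mean ≈ 0) holds for the unsearched lag-0
statistic, which is what the corresponding test checks.

## Gaze kinematics

Per axis: mean angle; mean |angle − median(angle)| with the median taken
over the participant's whole analyzed conversation (robust to seating
height/position); speed as |Δθ|/Δt across consecutive retained frames;
acceleration as the analogous difference of the speed samples (placed at
pair midpoints).  Because frame filtering punches holes in the series,
differences are only taken across gaps ≤ 2 nominal frame periods; longer
gaps break the chain.  Units are rad/s and rad/s²; with small angles at
30 fps this yields speeds of order 0.6–1.0 rad/s for realistic gaze.

## Voice features

All audio is mono; WAV I/O uses `scipy.io.wavfile`.  Defaults: pitch
floor 75 Hz and ceiling 500 Hz (covers adult male and female speakers),
40-ms analysis frames at 10-ms hop, voicing threshold 0.45.

**Pitch.**  Per frame, the normalized autocorrelation of the mean-removed,
Hann-windowed signal is divided by the window's own autocorrelation
(Boersma's correction); candidate lags span [1/fmax, 1/fmin].  A small
octave cost (0.01 per octave toward the pitch floor) disambiguates pure
tones, whose correlation peaks at every multiple of the period.  Because
*any* periodic signal has equal peaks at period multiples, low
harmonics-to-noise ratios can flip individual frames to a subharmonic; a
second pass therefore re-scores all lags with a mild penalty
(0.15 per octave) away from the median f0 of confident frames (r ≥ 0.6).
Peak positions are refined by parabolic interpolation; a frame is voiced
iff its corrected peak r reaches the voicing threshold.

**Glottal cycles.**  Within each contiguous voiced stretch, cycle peaks
are located by searching the waveform maximum in consecutive windows of
one local period (predicted from the pitch track), with sub-sample
refinement by a least-squares parabola over five samples; truncated
windows at stretch edges are never searched.  Stretches shorter than three
cycles are dropped, and perturbation measures never difference across
stretch boundaries.  Periods T_i are inter-peak intervals; amplitudes A_i
are peak magnitudes.

**Perturbation measures** are the standard Praat family: jitter local,
local-absolute, rap, ppq5, ddp (= 3·rap by identity) on T_i; shimmer
local, local-dB, apq3, apq5, apq11 (requires ≥ 11 cycles), dda (= 3·apq3)
on A_i.  **HNR** per voiced frame is 10·log₁₀(r/(1−r)) with r the
harmonicity; values are clipped to [−20, 40] dB and aggregated as
mean/median/sd.  **MFCCs**: Hann magnitude spectrogram (25-ms frames,
10-ms hop) → 64 triangular mel filters spanning 0 to Nyquist → log with
floor 1e-10 → orthonormal DCT-II → coefficients 0–39, averaged over
frames.  These re-implement the standard definitions rather than wrapping
an external analysis tool, so absolute values are not bit-identical to any
particular implementation; correctness is established by closed-form
cases, invariances, and synthetic parameter recovery (below).

## Secondary features and classification

Each channel (17 AU intensity channels; 2 gaze angles) is summarized per
part by six order-invariant statistics: mean, sd (n−1), min, max, skewness
(g1) and excess kurtosis (g2).  The published dimension arithmetic
(17·7·6 = 714, 2·7·6 = 84) admits six statistics per channel although
seven are listed; we drop "time point of maximum", the only
order-dependent one, and count gender inside each block: 715 face, 85
gaze, 58 voice (40 MFCC + F0 mean/sd + 5 jitter + 6 shimmer + 3 HNR +
energy + gender), 856 combined after gender deduplication.  Missing
values (e.g. an empty segment) remain NaN until model fitting, where they
are imputed by the *training-fold* median.

Classification: random forest (default 1000 trees) under leave-one-out
cross-validation; inner stratified 3-fold CV selects max depth and min
samples per leaf from {1, 2, 4, 8, 16, 32, 64}² by mean AUC, ties broken
toward smaller depth then larger leaf.  Two design decisions:

* **Balanced bootstrap class weights.**  Leave-one-out makes the held-out
  subject's class the minority of every training fold, which biases the
  out-of-sample probability against that class and drags the null AUC
  below 0.5; `class_weight="balanced_subsample"` removes this artifact.
* **Inner selection metric** is AUC (threshold-free, appropriate for
  near-balanced groups).

AUC is the rank statistic U/(n₁n₂) with half credit for ties; threshold
metrics use prob ≥ 0.5 → ASD.  McNemar against the majority-vote baseline
reports the exact two-sided binomial p on discordant pairs (plus the
continuity-corrected χ² variant).  Spearman correlations use average
ranks, exact permutation p for n ≤ 8.

## Group statistics

Rank tests throughout (the motivating data are heavily skewed):
Mann-Whitney U with full-enumeration exact p for tie-free pooled n ≤ 12,
else the tie-corrected normal approximation; effect size r = |Z|/√N.
Wilcoxon signed-rank with sign-flip enumeration for n ≤ 12 (exact
conditional on the observed |differences|, hence valid under ties); the
reported statistic is the positive-rank sum W.  The group × gender ANOVA
uses type-II sums of squares (robust to mild imbalance) with generalized
η² = SS_effect/(SS_effect + SS_error), treating both factors as
manipulated.  Families of p-values (face/gaze/voice) are Holm-corrected.

## Synthetic cohorts

The generator emulates what the pipeline consumes, not raw video/speech:

* **AU channels** derive from latent Gaussian processes (white noise
  low-passed at 0.5 Hz, standardized).  Presence = latent above a
  per-segment threshold set to hit the segment's occurrence target in
  expectation; intensity = shifted-rectified latent scaled to the
  segment's mean-intensity target.  Segment weights raise joy AUs
  (AU6/AU12) in positive parts and disgust/frown AUs (AU4/AU9) in the
  negative part.
* **Mimicry**: for AU6/AU12/AU4/AU9 the participant latent is
  c·(actress latent, shifted by a 0.5-s reaction lag) + √(1−c²)·noise, so
  the coupling c is the expected latent correlation.
* **Gaze**: mean-reverting AR(1) per axis calibrated to a stationary sd
  and a mean absolute speed; per-subject means drawn from the
  between-subject spreads.
* **Voice**: per-cycle harmonic synthesis (six cosine-phase harmonics with
  1/k amplitudes — one dominant peak per cycle at the pulse time).
  Periods are T₀(1+ε), ε ~ N(0, σ_j) with σ_j = jitter·√π/2 so the
  expected local jitter equals the target; amplitudes analogously for
  shimmer; white noise is added at power P_h·10^(−HNR/10).
* **Heterogeneity**: each subject draws its own targets around the group
  calibration (logit-normal for occurrences, lognormal for intensities,
  normal for F0/HNR with the published between-subject SDs).  ASD
  subjects carry an effect multiplier g ~ N(1, 0.35) that scales their
  deviation from the neurotypical calibration; the synthetic severity
  score is linear in g plus noise, enabling the probability-severity
  correlation check without clinical scores.

Group calibration follows the published descriptives: AU12
whole-conversation occurrence 0.40 (NT) vs 0.09 (ASD), AU6 0.12 vs 0.02,
negative-part AU4 intensity 0.03 vs 0.08, mimicry coupling 0.19 vs 0.08,
sex-specific F0 (209.1/121.7 NT, 218.9/139.7 ASD) and HNR
(10.3/10.8 vs 6.9/8.5 dB — the table direction, NT > ASD), and near-null
gaze differences.  A `null` preset gives both groups the NT calibration.
Defaults: 40 subjects per group, half female, 30 fps, 16 kHz audio.  The
synthesized voice is 8 s per subject — long enough for stable F0/HNR/
perturbation estimates while keeping an 80-subject cohort simulatable in
seconds; frame tables span the full 166-s conversation.

**What the synthetic data does not contain:** camouflaging and
compensation, verbal content, speaking/pause structure, co-articulation
and vibrato, head pose and occlusion artifacts, age effects, or
measurement error beyond white tracking noise.  Group effects are cleaner
and larger relative to noise than clinical reality, so classifier
performance on the calibrated preset (AUC near 1 at 40+40) demonstrates
pipeline correctness and leakage-freedom, not clinical attainable
accuracy.

## Analysis scale

Cohort-level checks (null calibration, effect recovery) run at the study's
40+40 size.  Because a full 7×7 nested grid with 1000 trees across ~10⁴
leave-one-out fits is disproportionate for a synthetic-recovery analysis,
cohort-level cross-validation uses a fixed (depth 8, min-leaf 4) forest of
300 trees; the nested-selection machinery itself is exercised on smaller
matrices in the unit tests.  Replicate counts: 4–6 null seeds, 20
effect-recovery replicates, 2–3 calibrated classifier seeds in the test
suite (the acceptance script uses the upper counts).  Null-cohort LOO AUC
scatters noticeably more than the U-statistic standard deviation of 0.065
at n = 80 would suggest, because LOO training folds overlap almost
completely and the per-subject probabilities are strongly correlated; the
chance band used for calibration is [0.35, 0.65].

## Numerical choices and degenerate inputs

Empty frame selections yield NaN biomarkers, which the feature builder
carries and the model stage imputes.  Mimicry windows with zero variance
are skipped; per-window correlations are clipped to ±0.999999 before
Fisher-z.  Pitch frames with zero energy are unvoiced.  Constant series
give sd 0 and NaN skewness/kurtosis.  Chi-square uses no continuity
correction by default; McNemar's χ² variant uses it.  All simulation and
model randomness flows from explicit integer seeds (numpy `SeedSequence`
spawning per participant), and a fixed seed reproduces every artifact
bit-for-bit.
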