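# Methods

This note documents the models, the parameter choices that matter, and the
numerical conventions behind `pdscreen`, and states what the synthetic-data
generators do and do not emulate.

## Tremor analysis

**Detrending.** Accelerometer data carries large static offsets (gravity,
phone orientation) and step changes when the hand is repositioned. The
detrend filter subtracts the mean of each non-overlapping window per
channel (default 1 s = 100 samples at the nominal 100 Hz rate); the final
partial window is treated the same way. The operation is idempotent and
removes any piecewise-constant offset whose segments align with windows;
misaligned steps leave one transient window.

**Band decomposition.** The physiological bands of interest are ≈0–3 Hz
(voluntary movement / drift), 3–6 Hz (Parkinsonian rest tremor) and 6–12 Hz
(postural tremor). At 100 Hz a strictly dyadic filter bank cannot realize
these edges exactly; the package uses the closest dyadic approximation — a
4-level discrete wavelet transform whose level-4 approximation covers
0–3.125 Hz, level-4 detail 3.125–6.25 Hz and level-3 detail 6.25–12.5 Hz.
The >12.5 Hz details are kept as a `residual` band so the four
reconstructions sum to the input exactly (linearity of the inverse
transform; periodization boundary mode). The wavelet is Daubechies-8: the
filter bank's band selectivity grows with filter order, and db8 places ≈89%
of a band-centre (5 Hz) tone's energy in the rest band, versus ≈80% for
db4. Higher orders gain little and lengthen the filter support.

**Windowed features.** Eight categories per 20-sample window (25% overlap,
trailing window kept when ≥50% full), per axis, each summarized by mean and
variance across windows: 8 × 2 × 3 = 48 values. The category definitions
are this package's (the literature names the categories without formulas):
average amplitude = mean |x|; peak variation = SD of local-maxima heights;
consecutive peak change = mean |difference of successive peak heights|;
tremor occurrence = % of 5-sample sub-segments with RMS above an absolute
floor (0.05 m/s²); peak location variation = SD of inter-peak intervals;
zero-crossing rate = sign changes per window (exact zeros ignored); maximum
power and frequency at maximum power from a rectangular-window periodogram
(DC bin excluded; resolution fs/window = 5 Hz at defaults). Peaks are local
maxima above 10% of the window's max |value| (noise guard); ties resolve to
the earlier index via the scan order. A reference rank table for the 16
(category, statistic) slots ships with the module; the top-8 slots × 3 axes
give the compact 24-feature set used for classification.

**Quantitative severity.** The clinically styled summary is a pair
(maximum displacement amplitude in cm, occurrence as % of the recording).
The dominant frequency f̂ is the quadratically interpolated peak of the
axis-summed periodogram in 3–12 Hz; if no bin exceeds 20× the band's
median power the recording is declared tremor-free (0 cm, 0%) — the healthy
path, not an error. (The median, not the mean, is the reference because an
intermittent tremor's own spectral lobe dominates the band mean.) Each axis
is then band-passed ±1.5 Hz around f̂ (zero-phase Butterworth order 4),
per-axis Hilbert envelopes are combined in quadrature — recovering the
oscillation amplitude regardless of the tremor's spatial direction — and
the signal is reflect-padded before the Hilbert transform to suppress edge
spikes. Occurrence is the % of samples whose envelope exceeds
max(0.05 m/s², 0.15 × 99th-percentile envelope): the absolute floor rejects
sensor noise, the relative term rejects filter/Hilbert leakage around
strong bursts while keeping continuous tremor (which has no quiet baseline)
fully counted. Amplitude is the plateau level — the median of the upper
quartile of tremor-present envelope values — which is robust against the
~10% filter-transient overshoot at burst onsets; displacement follows from
the harmonic inversion d = a/(2πf̂)², reported in cm. How acceleration
amplitudes map to the clinical cm scale is not standardized; the harmonic
inversion is this package's choice.

**Grading.** Amplitude grades: no tremor → 0; <1 cm → 1; 1–3 cm → 2;
3–10 cm → 3; ≥10 cm → 4. Occurrence grades: none → 0; ≤25% → 1; ≤50% → 2;
≤75% → 3; >75% → 4. When the sub-grades disagree the severer one is
returned, making the rule monotone in both arguments. Occurrence refers to
the analyzed recording.

## Voice analysis

**Pre-processing.** Truncate (drop the first 1 s — utterance onset — and
the last 3 s — lung-pressure decay), band-pass 50 Hz–8 kHz (zero-phase
Butterworth order 4, −3 dB at the edges; the forward–backward pass doubles
the stopband attenuation, ≈22 dB for a 10 kHz tone relative to 1 kHz),
rational resample to 22.05 kHz, then peak-normalize to max |sample| = 1.
Normalization after resampling is this package's ordering choice; since
both operations are linear, only the final peak normalization is observable.

**Pitch tracking.** Frame-level (40 ms frames, 10 ms hop) normalized
cross-correlation r(τ) = Σx_t x_{t+τ} / √(E₀E_τ), searched over
τ ∈ [1/400, 1/60] s; a frame is voiced when the best r exceeds 0.45. A
subharmonic guard prefers the smallest-lag local maximum within 10% of the
global best — without it, about a third of frames of a jittery vowel lock
onto the octave below. Cycle-level sequences come from peak picking at
0.7× the median period spacing on a low-passed copy of the waveform whose
passband (14× F0, capped at 0.45 fs) covers the whole harmonic stack:
broadband noise above the harmonics only jitters peak positions without
carrying period information, so removing it cuts the jitter noise floor by
roughly 3×. Peaks are refined on a 4× sinc-upsampled copy (parabolic
refinement alone biases heights with the sub-sample offset). Cycles within
4 periods of the signal edges are dropped (filter edge transients), and
spacings outside 0.6–1.6× the median period are rejected as octave slips.

**Perturbation measures.** Standard perturbation-quotient forms on the
cycle period sequence T and amplitude sequence A: Jitter(%) = mean|ΔT| /
mean(T) × 100; Jitter(Abs) in seconds; RAP and PPQ the 3- and 5-point
quotients; DDP = mean of the second difference / mean(T) × 100 = 3·RAP
exactly; Shimmer, APQ3/5/11 analogously on A; Shimmer(dB) =
mean|20·log₁₀(A_{i+1}/A_i)|; DDA = 3·APQ3. All are invariant to global
amplitude scaling. One measurement caveat: the 50 Hz high-pass in
pre-processing physically transduces strong period jitter (≥2%) into
sub-percent amplitude modulation of the waveform itself, so a few tenths of
a percent of "shimmer" on a heavily jittered but amplitude-stable voice is
genuine signal content, not an estimator artefact.

**Harmonicity.** Per voiced frame, with r the normalized autocorrelation at
the pitch lag, HNR = mean of 10·log₁₀(r/(1−r)) (clipped to [−20, 60] dB)
and NHR = mean of (1−r)/r. For a periodic signal in additive noise,
r ≈ P_harm/(P_harm+P_noise), so the estimator recovers an additive-noise
HNR within a few tenths of a dB; cycle-to-cycle perturbation itself lowers
r, so jittery voices legitimately measure a lower HNR than their additive
noise alone would imply.

**Nonlinear measures.** These are under-determined in the feature-table
literature; the package's realizations are:

- **RPDE**: embedding dimension 4, delay at the first autocorrelation
  minimum, close returns at Chebyshev distance < 0.12 of the signal SD
  (unit-variance normalized), first-return periods between 0.5 and 3.5 mean
  pitch periods, entropy of the period histogram normalized by ln(number of
  admissible periods); computed on a centred 5000-sample excerpt.
- **DFA**: RMS fluctuation of the linearly detrended integrated signal over
  10 log-spaced box sizes (50–1000 samples, capped at n/4), slope α mapped
  through the logistic 1/(1+e^{−α}) to (0, 1); 30 000-sample excerpt.
- **D2**: Grassberger–Procaccia correlation dimension, embedding dimension
  10, Theiler window of one mean pitch period, slope of log C(r) over the
  2nd–20th distance percentiles, ~1200 embedded points.
- **spread1/spread2/PPE**: on the log-pitch scale q = ln(F0/F0_ref) with a
  healthy-speaker reference (male 120 Hz, female 190 Hz, unknown 150 Hz):
  spread1 = ln(mean absolute deviation of q) (more negative = steadier
  pitch, floored at ln 10⁻⁴), spread2 = SD of the AR(2)-whitened residual,
  PPE = discrete entropy of the 30-bin residual histogram normalized to
  [0, 1]. Exact numeric agreement with other toolchains (different pitch
  extractors, different conventions) is explicitly not claimed.

## Feature selection

Greedy mRMR in the MID (difference) form: first pick maximizes I(f; y),
subsequent picks maximize I(f; y) − mean_{s∈S} I(f; s). Mutual information
is estimated on equal-frequency quantile bins, min(10, ⌈√n⌉) per feature,
which makes the ranking invariant to row order and to strictly monotone
per-feature transforms. Ties (scores equal at 1e-12) break by higher
relevance, then canonical column order, so rankings are deterministic. The
MID-vs-MIQ variant choice and the discretization are this package's; the
ranking protocol (pooled, male-only, female-only strata) follows the
gender-stratified screening design, with unknown-gender rows participating
only in the pooled run.

## Modeling

Stratified k-fold cross-validation (default tenfold), features z-scored on
the training folds only (no leakage). Binary protocol: sensitivity =
TP/(TP+FN) on the PD class, specificity = TN/(TN+FP), pooled over folds.
The 5-level UPDRS protocol reports macro one-vs-rest sensitivity and
specificity — the multi-class definitions are not standardized, so the
macro convention is documented here. Hyperparameter search is an exhaustive
grid maximizing CV accuracy; ties go to the simpler model (smaller k, lower
polynomial degree). kNN supports correlation and Minkowski distances with
uniform / inverse / squared-inverse weights; SVM supports linear,
quadratic, cubic (polynomial, coef0 = 1) and RBF kernels; naive Bayes is
Gaussian or a per-feature 1-D kernel-density variant (box / Epanechnikov,
Scott-rule bandwidth with a 10⁻³ floor and a 10⁻¹² density floor). Grid
entries whose k exceeds the guaranteed training-fold size are skipped.

## Fusion

Per modality, 2-of-3 majority vote; the per-instance score is the number of
PD votes (0–3). Instance pairs are consumed in order until both modality
votes agree; the average score is total PD votes / (3 × instances consumed
× 2 modalities). On exhaustion without agreement, PD is declared when the
average strictly exceeds the threshold (default 0.6, the 2/3 majority ratio
rounded to a common threshold) and the decision is flagged `unresolved` —
the loop needs a termination rule, and the score threshold is the natural
one since the score is computed throughout anyway. A patient is non-PD only
when both modalities end negative. A predicted UPDRS grade, when per-instance
tremor quantitative summaries are attached to the profile, comes from the
grading rule on the agreeing instance; severity is never fused across
modalities. Synthetic patients are composed class-purely: per class, as
many patients as the smaller per-class row count, instances drawn with
replacement from that class's rows.

## Synthetic data: what it emulates, and what not

**Tremor generator.** A single 4–6 Hz sinusoidal carrier, amplitude set by
the displacement-to-acceleration relation a = (2πf)²d, projected on a
random spatial direction, gated by raised-cosine burst envelopes (0.25 s
ramps — sharp gating would splatter energy across bands) whose total span
sets the occurrence fraction; plus gravity on z, random mid-recording
orientation steps, sub-3 Hz drift (default 0.3 m/s²) and white sensor noise
(default SD 0.05 m/s²). Severity grades sample amplitude and occurrence
uniformly from the *interior* of each clinical grade range (a few-percent
guard at the boundaries; grade-4 amplitude capped at 15 cm): values
arbitrarily close to a grade boundary are not recoverable by any estimator
with finite frequency resolution and segment granularity, and the guarded
ranges represent the prototypical cases a grader is validated against.
Real Parkinsonian tremor has several harmonics, waxing-waning amplitude and
frequency drift; none of these are modelled, so closed-loop grade recovery
here demonstrates the estimator chain's correctness, not clinical-grade
accuracy.

**Vowel generator.** Harmonic source of 10 harmonics with 1/h roll-off;
cycle i has period T₀(1 + j·g_i) and amplitude 1 + s·h_i with g, h standard
normal clipped at ±3 SD (j, s the jitter/shimmer fractions). Additive noise
is band-limited to the 50 Hz–8 kHz speech band and scaled to the requested
HNR, so the target survives the pipeline's band-pass. Ground-truth period
and amplitude sequences are returned alongside. Not modelled: formant
structure, breath/aspiration spectra shaped like real turbulence,
micro-tremor of F0, onset/offset dynamics — so feature values agree with
real-voice tables in kind, not in calibrated magnitude.

**Feature tables.** Class-conditional unit-variance Gaussians with planted
per-gender informative subsets (default: jitter family for male rows,
shimmer family for female rows, 3 SD shifts; optionally scaled by
severity/4). This emulates the *structure* that makes gender-stratified
ranking worthwhile, not the covariance of real dysphonia measures (which
are strongly mutually correlated).

Because the generators are the test substrate, green tests show the chain
recovers what the generators planted under realistic noise — they do not
validate clinical performance on patient data.

## Problem sizes and numerical conventions

Default study conditions: 10 s tremor recordings at 100 Hz; 10 s vowels at
44.1 kHz (6 s and 132 300 samples after pre-processing); feature tables of
40–120 rows per class for model benchmarks; closed-loop severity recovery
checked over 50 seeds per grade (required ≥90% per grade; measured 98–100%).
Nonlinear voice measures run on capped excerpts (RPDE 5k, DFA 30k, D2 ~1.2k
embedded points) so a full 22-feature extraction takes a few seconds.
Floating-point conventions: reconstruction and idempotence tolerances 1e-9
absolute; variance uses the population convention (ddof 0); all indices are
0-based with t = i/fs.

## Known limitations

- The wavelet band edges are dyadic approximations (3.125/6.25/12.5 Hz) of
  the stated physiological bands; a tone at exactly 6 Hz splits its energy
  between the rest and postural bands.
- The quantitative severity estimator assumes a single dominant tremor
  frequency; multi-harmonic or bimodal tremors will under-read amplitude.
- Displacement conversion assumes steady-state harmonic motion; short
  bursts (<2 carrier periods) bias amplitude low.
- The voice pipeline expects sustained phonation; running speech, voice
  breaks and diplophonia are out of scope, and fewer than 30 detected
  cycles is treated as an error rather than degraded output.
- Nonlinear voice measures (RPDE/DFA/D2/spread/PPE) follow documented but
  package-specific conventions; compare trends, not absolute values, across
  toolchains.
- The 5-level protocol needs per-row UPDRS labels; the fusion stage
  attaches severity only from the tremor path.
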