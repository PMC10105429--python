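# Methods

`hhteeg` reimplements, as a tested library, a Hilbert–Huang-transform (HHT)
analysis of single-channel frontal EEG recorded during propofol general
anesthesia: empirical mode decomposition (EMD) of consecutive 8-s epochs,
per-mode instantaneous-frequency summaries (HHT_IF) tracked across the
induction, maintenance and emergence phases, matched-pairs trend testing,
and a Gaussian-process regression of the BIS depth-of-anesthesia index on
HHT_IF. Because the clinical recordings behind the original analysis are
not publicly deposited, a seeded synthetic cohort generator reproduces the
study conditions; everything downstream of the generator treats its output
exactly as it would treat monitor exports.

## Empirical mode decomposition

EMD sifts a signal x(t) into intrinsic mode functions (IMFs) c_k(t) from
the highest oscillation frequency downward, leaving a residual trend
r(t), with x = Σ c_k + r holding exactly. One sifting step subtracts the
mean m(t) of the upper and lower extrema envelopes from the running
candidate h: h ← h − m. An admissible IMF has (1) zero-crossing and
extrema counts differing by at most one, and (2) envelopes locally
symmetric about zero.

Choices the classical literature leaves open, as implemented here (all
configurable):

* **Envelopes.** Natural cubic splines through the maxima/minima, with the
  two extrema nearest each end mirror-reflected beyond the signal
  boundaries. Boundary handling is the main driver of end-of-epoch
  artefacts, which is one reason summaries trim the epoch edges (below).
* **Stopping rule.** A Cauchy-type criterion Σm²/Σh² < 0.2, accepted only
  once the candidate also meets the zero-crossing/extrema count criterion
  (a small correction alone does not make an IMF — without this guard a
  third of the modes returned on broadband input fail the defining count
  property), or counts stable and admissible for 3 consecutive sifts (an
  "S-number" of 3), whichever fires first; at most 50 sifts, after which
  the candidate is kept but flagged non-converged. Flags are carried
  through, never silently dropped.
* **Extrema.** Strict neighbour comparison; a flat plateau counts once at
  its midpoint index; endpoints are never extrema.
* **Symmetry tolerance.** RMS(envelope mean) ≤ 0.3 × RMS(series) for
  criterion (2). No numeric threshold is standard; under the stopping
  rule above a legitimately converged mode retains an envelope-mean RMS
  of roughly 5–20% of the series RMS (driving it lower means
  over-sifting), so the count criterion is the sharp admissibility
  detector and the symmetry bound catches gross asymmetry — an offset
  tone scores ≈ 1.
* **Budget.** At most six IMFs per epoch; extraction stops earlier when
  the remainder has fewer than two maxima or two minima. When fewer than
  six emerge, table exports pad with all-zero rows flagged empty so that
  downstream tables always have six IMF slots.

Completeness is enforced by construction (each remainder is input minus
extracted mode), so the reconstruction error is floating-point noise; the
suite asserts ≤ 1e-8 relative on every tested epoch.

## Instantaneous frequency and spectra

For each IMF the analytic signal Z = c + iH[c] is computed with the
frequency-domain Hilbert transform (`scipy.signal.hilbert`); the real part
equals the input exactly. Amplitude is |Z|; frequency is the
central-difference derivative of the unwrapped phase over 2π, in Hz.

Samples are masked out (never clamped) where the frequency is negative —
physically meaningless for a well-separated mode — or above Nyquist, where
the amplitude falls below 1e-3 × the mode's RMS (phase there is noise), or
within 0.5 s of an epoch edge (Hilbert end effects). The per-epoch scalar
HHT_IF is the amplitude-weighted mean of masked-in frequencies (an
unweighted median is available); it is reported missing when fewer than
25% of samples survive the mask, so near-empty modes never contribute
spurious numbers.

The Hilbert spectrogram accumulates a(t)² into 0.5 Hz × 1 s cells up to
Nyquist (64 Hz at the 128 Hz sampling rate); the marginal spectrum is its
exact time sum, and the suite checks energy bookkeeping against the
masked-in amplitudes exactly.

## Epoching, alignment and phases

Monitor exports carry EEG at 128 Hz and processed parameters (BIS, SEF95,
SR, EMGlow) every 3 s. Analysis epochs are non-overlapping half-open 8-s
windows [t, t+8) — the cadence at which the analysis refreshes — with a
trailing partial window dropped; concatenating epochs plus the dropped
tail reproduces the input exactly. Each epoch is assigned the median of
the parameter records whose timestamps fall inside it (the pairing of 3-s
records to 8-s epochs is not otherwise determined; the median is
order-invariant and robust to a missing record); epochs with no record get
missing values. The three clinical phases are 7-minute (420 s) windows
taken from a per-patient JSON config — how the original phase windows were
anchored is unknown, so they are explicit inputs here. A 420-s phase at
128 Hz yields 52 epochs.

No additional filtering is applied to the EEG: the emulated monitor
already preprocesses its export, and the pipeline analyses it as-is.

## Synthetic cohort generator

The generator emulates what the pipeline needs from the study setting —
the *spectral structure* of intraoperative frontal EEG and companion
monitor parameters — not the biophysics. Per patient it draws an alpha
peak in 8.5–11.5 Hz, a fast beta/low-gamma component in 25.5–28.5 Hz, a
low-beta component in 14–16 Hz, a slow-delta frequency in 0.8–1.8 Hz, and
a log-normal (σ = 0.15) amplitude scale. An arousal level u(t) ∈ [0, 1]
follows smooth monotone cosine ramps: 1 → 0 over the 420-s induction,
0 throughout maintenance, 0 → 1 over emergence. Samples are
u·awake + (1−u)·anesthetised + pink noise:

* **awake**: fast-beta tone (6.5 µV) + low-beta tone (8 µV) + weak
  broadband 31–45 Hz EMG-like noise (1.2 µV RMS) — desynchronised,
  low-amplitude, beta-dominated;
* **anesthetised**: alpha tone (18 µV) + slow-delta tone (11 µV) + a faint
  spindle-like tone at 1.7 × the alpha frequency (13 µV) — the propofol
  pattern of frontal alpha over slow-delta with a light fast residue;
* tones are narrow-band, with slow Gaussian frequency drift (0.2–0.5 Hz
  bandwidth) and waxing–waning amplitude modulation (5–10% depth), so EMD
  behaves as on real EEG rather than on pure sinusoids; background noise
  is pink (1/f), at 10% of the oscillation RMS.

The two-component beta mixture and the spindle residue exist because of
how EMD distributes broadband content: the decomposition behaves as a
near-dyadic filter bank, so a *single* awake beta tone cannot populate
both of the first two modes the way real awake EEG does, and without a
weak fast residue the maintained alpha oscillation would surface in IMF1
rather than IMF2. Component frequencies and amplitudes were calibrated
once against the reported phase endpoints (awake modes 1–2 at roughly
23/14 Hz here; maintained modes at roughly 14/10 Hz; see the package
tests) and then frozen. Two practical findings fixed the design: tones
separate cleanly only at frequency ratios ≳ 1.7 with comparable
amplitudes (a much weaker fast tone is swallowed by the slower mode), and
a pink-noise floor above ~10% of oscillation RMS contaminates the second
mode enough to drag its summary below the alpha band.

Companion records, every 3 s: BIS = 43 + 52·u plus N(0, 2²) jitter,
clipped to [0, 100] — an affine stand-in calibrated to the awake (95) and
maintained (43) medians, **not** a model of the proprietary index; EMGlow
= 27.5 + 17.4·u dB plus N(0, 1.5²); SEF95 is computed honestly as the 95%
spectral edge of the generated EEG in a sliding 8-s Welch window; SR ≡ 0
(burst suppression is not simulated). The cohort (default 30 patients ×
three 420-s phases) is a pure function of the master seed, and the writer
emits the same TSV formats the readers parse.

What the generator does **not** emulate — and hence what passing tests do
not establish about real recordings: artefacts (electrocautery, blinks,
movement), burst suppression, age-related amplitude decline, drug-mix
effects beyond a single arousal dimension, non-monotone transitions, and
any true coupling between BIS and the EEG waveform beyond their shared
dependence on u(t). Results on this cohort validate the machinery and the
qualitative phase pattern, not clinical performance.

A structural consequence of tone-based synthesis: 8-s epochs decompose
into about five meaningful modes; a sixth mode below ~0.3 Hz has too few
cycles to pass the 25% valid-sample threshold, so IMF6 summaries are
reported missing and its trend tests are undefined on the default cohort.
Real broadband EEG populates six modes; the trend machinery handles both.

## Trend statistics

For each variable (per-IMF HHT_IF, BIS, SEF95, EMGlow) and phase, the
value at each patient's first epoch is paired with the value at their last
epoch; patients missing either endpoint are excluded and counted. The
two-sided Wilcoxon matched-pairs signed-rank test uses an exact null — a
generating-function convolution over doubled midranks, equivalent to
enumerating all 2ⁿ sign assignments and valid under ties — for up to 25
non-zero differences, and the normal approximation with continuity and
tie corrections above. Zero differences are dropped before ranking
(Wilcoxon's convention; Pratt's alternative is not used). All-zero
differences make the test undefined, reported as such. Summaries are
median (Q1, Q3) with linear-interpolation (type-7) quartiles and the
conventional stars (* p<0.05, ** p<0.01, *** p<0.001). No
multiple-testing correction is applied — p-values are reported raw,
per variable, mirroring how such trend tables are conventionally
presented; readers comparing many rows should keep that in mind.

## Gaussian process regression

BIS is regressed on the IMF2 HHT_IF over the emergence phase, pooling the
first 50 valid epochs of each training patient (20 patients × 50 = 1000
points under the default cohort; the 20/10 patient split is a seeded
permutation). The kernel is the sum of Matern-3/2,
k(r) = v_m (1 + √3 r/ℓ_m) exp(−√3 r/ℓ_m), and an exponentiated-sin²
periodic kernel, k(r) = v_p exp(−2 sin²(π r/p)/ℓ_p²), plus white
observation noise. (Kernel *names* follow the GPy conventions of the
original analysis; GPy's "PeriodicExponential" may differ in detail from
the standard periodic form used here.) Inputs and targets are z-scored
internally; hyperparameters maximise the log marginal likelihood via
multi-start L-BFGS-B on log-parameters with analytic gradients (default 5
seeded restarts, best kept — the best objective never decreases as
restarts are added); a relative jitter of 1e-8 stabilises the Cholesky
factorisation. The 68% credible band is the posterior mean ± one
predictive standard deviation (including observation noise). Held-out
quality is RMSE and R² per test patient; R² is undefined (NaN) for a
constant-target patient. Pooling all training points into one GP — rather
than averaging per-patient posteriors — is the implemented reading of the
ambiguous original description; the per-patient alternative would need
only a loop over `fit`.

## Problem sizes and numerical checks

The test suite and the acceptance script regenerate everything they
measure. Sizes used: 200 mixed epochs (tones, chirps, noise, anesthesia
mixtures) for decomposition bookkeeping; tone/chirp oracles on single 8-s
epochs; 100 random instances (n ≤ 10) against brute-force sign
enumeration for the exact Wilcoxon null; 20 seeds × 1000 points (700/300
split) for the GP noise-floor recovery, where the single canonical
optimizer start is used because that likelihood surface is unimodal; and
the full default cohort (30 patients × 3 × 420 s, one fixed seed) for the
qualitative study replication. The pure-tone frequency oracle holds to
machine precision; the chirp is tracked to ≈ 0.02 Hz; EMD reconstruction
error is ~1e-15 relative.

## Known limitations

* EMD details (stopping rule, boundary treatment) differ across
  implementations, including the Java library behind the original
  analyzer; mode-level results can differ in detail even on identical
  input.
* The amplitude-weighted HHT_IF epoch summary is one reasonable
  aggregation; the original aggregation is not documented.
* The synthetic BIS is affine in arousal by construction, which makes the
  BIS–HHT_IF regression easier than on clinical data; held-out RMSE/R²
  on the synthetic cohort indicate machinery correctness, not expected
  clinical accuracy.
* Suppression ratio is carried through I/O but never analysed, matching
  the original scope; elderly-patient EEG (lower alpha power) is out of
  scope.
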