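# Methods

## Stimulus model

Two artificial languages of four tri-syllabic CV pseudo-words are built from
their printed word lists (L1: KUPOTE, DOGUKI, TAPIKO, DAGOPE; L2: TUGODE,
PAGODI, DUGAKE, KATIPU). Syllables last 350 ms, so a word spans 1050 ms.
L1's twelve syllables are pairwise distinct; the printed L2 list reuses GO
in two words, so its inventory has eleven labels and `build_language`
validates distinctness only where it actually holds (strict for L1, relaxed
for the shipped L2). One consequence worth knowing: in a melodic L2 stream
the bigram GO→DE/GO→DI is not deterministic, so the "within-word TP = 1.0"
property is an L1 property; L1 is the default language everywhere.

Learning streams concatenate the four words uniformly at random subject to
exact per-word token counts (default 50 each → 200 tokens, 3.5 min) and no
immediate repetition; dead ends are resolved by restarting the draw. Test
streams build a 66-per-word legal backbone the same way and then insert 22
tokens of each syllable-reversed illegal item at uniformly random positions,
re-drawing any insertion that would place an illegal item directly after its
source word or any token after an identical one. Both generators are
deterministic given a seed.

Pitch: the flat condition fixes every syllable at 216 Hz (the literal value,
not snapped to a tempered tone). The melodic condition assigns one tone per
syllable — the printed map for L1; for L2, where no map is printed, a
package convention of eleven distinct C-major tones chosen to give two
rising and two falling word contours, mirroring L1. Note names resolve in
equal temperament with A4 = 440 Hz. `interval_stats` contrasts the eight
within-word semitone steps with the boundary steps (observed bigrams or all
twelve ordered word pairs); for L1 the mean absolute within-word interval is
3.375 semitones versus ~7 semitones across boundaries.

## Forward EEG model

Each simulated newborn has latent traits drawn independently across
subjects:

| trait | distribution (μV) | source of the defaults |
|---|---|---|
| flat blocks (b1, b2) | N(0.35, 1.41), N(−0.11, 1.72) | printed group block means/SDs |
| melodic blocks (b1, b2) | N(−0.48, 1.65), N(0.88, 2.36) | printed group block means/SDs |
| TW1 (melodic MMR, 300–400 ms) | N(1.06, 1.50) | all-channel mean of the printed electrode table |
| TW2 (melodic MMR, 800–900 ms) | N(1.10, 1.08) | mean from the table; SD calibrated (below) |
| flat MMR | exactly 0 | no flat mismatch effect |

Amplitudes are defined on the **all-channel-mean scale**: the spatial
profile (fronto-central maximum ≈ 1.4 at Fz/Cz, ≈ 0.14 occipitally) is
normalised to mean 1 over the 16 scalp channels, so a 1 μV trait produces a
1 μV all-channel window mean, matching how the features are defined in the
analysis. Components are raised-cosine bumps spanning their window, scaled
so their mean over the window is exactly 1. The learning component's
amplitude follows a per-trial linear ramp parameterised so that the two
block *means* equal (b1, b2) — a ramp running from b1 to b2 would halve the
measured block contrast, and only block means are constrained by the data
the defaults come from. Mastoids carry noise only, so re-referencing is a
real operation.

Background noise is an equal-power mix of white and 1/f noise (Kellet
three-pole approximation), per-channel RMS ~N(15, 3) μV across subjects.
Artifacts are brief exponential-decay excursions of ±(120–300) μV on random
channel subsets at 0.5 events/min. Everything is seeded; a master seed fans
out per subject × condition × phase through `numpy.random.SeedSequence`.

Outcomes: MCDI = 47.575 + 6.263·L_melody − 22.929·TW2_melody + ε with
ε ~ N(0, 27.4); the BSID-III language score is a noisy affine transform of
MCDI. The noise SD and the TW2 trait SD are **calibrations**, chosen so the
two-predictor model's standardized betas (≈0.44, ≈−0.55) and its expected
sample R² at n = 13 (≈0.63) match the reference analysis; they are not
directly printed values. Under these population parameters the linear
predictor puts roughly a fifth of its mass below zero, so clamping scores at
zero would censor the outcome and attenuate the generative coefficients far
beyond their standard errors; by default the linear model is left intact
(occasional negative synthetic scores), with `truncate_mcdi=True` available
when plausible score ranges matter more than coefficient identifiability.

## ERP pipeline

Order: mastoid re-reference → band-pass → epoch → baseline → reject.

* **Filter**: Hamming-window FIR band-pass designed to ≥53 dB stopband
  attenuation and ≤0.0063 passband deviation (the Hamming window's inherent
  figures), transition widths following common M/EEG practice
  (min(max(f·0.25, 2 Hz), f)). Applied zero-phase as a single FFT
  convolution with the kernel's autocorrelation — identical to
  forward-backward filtering for a linear-phase FIR up to edge handling.
  Bands: 0.5–20 Hz (learning), 1–20 Hz (test), both configurable.
* **Epochs**: −50..1050 ms around word onsets. At 250 Hz this window is not
  sample-aligned; it is snapped to the 4 ms grid as −48..1052 ms, giving the
  276 samples the arithmetic implies. Epochs clipped by the recording edge
  are dropped and counted (simulated recordings carry 1 s padding, so none
  are in practice).
* **Baseline**: −50..0 ms (the full pre-stimulus span). **Rejection**: a
  trial is dropped if any channel sample exceeds ±120 μV, applied after
  filtering and baseline correction. **Blocks**: learning trials are
  labelled by token order, first half block 1 (100/100 at defaults, which
  coincides with the 1′45″ halves); an odd middle trial joins block 2.
  **Windows**: closed on both ends at sample resolution.

A known and deliberate property: the 1–20 Hz test-phase high-pass removes
the sub-1.5 Hz content of an isolated 100 ms mismatch bump, keeping ~75–85%
of its window-mean amplitude (the learning component is unaffected because
every token carries it, making the removed local mean a common offset that
baseline correction restores). Real ERP amplitudes pass the same filter;
tests check the exact forward-model identity on the unfiltered route and a
[0.70, 1.0]× band on the filtered one.

## Statistics

The repeated-measures ANOVA handles any number of within factors on a
complete balanced design; each effect is tested against its own
subject-by-effect interaction. Greenhouse–Geisser epsilon comes from the
covariance of orthonormal (Helmert) contrast scores, Kronecker-composed for
interactions, and is reported for every effect (it is exactly 1 for 1-df
effects); partial η² = SS_effect/(SS_effect + SS_error). The implementation
is validated against an explicit brute-force sum-of-squares oracle and
against pingouin for one- and two-factor designs (pingouin does not support
three).

One-sample t-tests report d = M/SD. The published per-electrode table's
Cohen's d column is ≈2×M/SD (an unknown variant formula) and is never used
as an expected value; two of its rows (melodic 300–400, T7/T8) have printed
SDs inconsistent with their own t and d and are excluded from the
t-identity test. Its FDR column is truncated, not rounded, to the printed
decimals; tests accept either convention. BH-FDR is the statsmodels
step-up; the per-electrode mismatch t-tests use the 10-electrode
fronto-central/temporal set with FDR over that family, while ANOVAs use all
16 channels. Fisher LSD post-hocs use the preceding ANOVA's error mean
square, unadjusted.

## Prediction and evaluation

Features are all-channel means: L_flat/L_melody (block 2 − block 1,
200–500 ms) and TW1/TW2 (illegal − legal, 300–400 / 800–900 ms, melodic).
Backward elimination starts from all four predictors and repeatedly drops
the largest p ≥ 0.10 (p_out configurable); all intermediate fits are
returned. Leave-two-subjects-out CV holds out every unordered pair once
(C(n,2) folds, n(n−1) predictions) with a fixed predictor subset — the
final-model features, as in the reference analysis; selecting features
before CV is a known optimism source and is documented rather than hidden.
Evaluation regresses true on predicted scores (R²) and computes MAE. The
permutation test shuffles the outcome vector and reruns the *entire* CV per
permutation (respecting the dependence among predicted scores), with the
+1-corrected empirical p. The per-fold training pseudo-inverses depend only
on the features, so all permutations reuse them; 5000 permutations at
n = 13 take well under a second.

Two statistical facts worth stating about recovery-style checks: (i) with
p_out = 0.10 each truly-null predictor survives elimination with
probability ~0.1, so "the final model is exactly the two generative
predictors" holds in only ~80% of simulated cohorts, by construction, at
any sample size; (ii) with the printed block SDs, the flat condition's
block-1 > block-2 population contrast of 0.46 μV gives a per-cohort sign
reproduction probability of ~0.86 at n = 28 even with noiseless
measurement. The test suite asserts aggregate (across-seed) patterns where
per-seed guarantees are mathematically unavailable.

## Problem sizes and defaults used in the checks

Simulated cohorts use the full default conditions: n = 28 newborns, 200
learning tokens and 352 test tokens per condition, 250 Hz, 18 channels. The
group-level pattern checks run 50 such cohorts; permutation-null
calibration uses 200 replicate 13-subject datasets at 500 permutations;
parameter recovery uses 100 cohorts of n = 200 (traits only, no EEG
simulation, since the recovery claim concerns the outcome linkage).

## Limitations

The generator does not attempt realistic neonatal sleep EEG: no sleep
stages or state transitions, no realistic artifact taxonomy, a stylised
1/f + white spectrum, and spatially independent channel noise (real EEG is
spatially correlated beyond the shared reference). Trait SDs of the
measured features are therefore slightly larger than the latent SDs.
Syllables are never rendered acoustically (an optional sine-tone WAV export
exists for demonstration only). Passing tests show the analysis chain is
correct and calibrated under this model, not that the underlying
developmental effects exist in real infants.
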