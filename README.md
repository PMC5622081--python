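# segspeech

Tools for studying **statistical word segmentation in sleeping neonates** and
its link to later language outcomes, built as a fully synthetic, end-to-end
testable pipeline:

1. **Stimuli** — artificial languages of four tri-syllabic CV pseudo-words
   (350 ms per syllable), concatenated into continuous streams in which the
   only reliable word-boundary cue is the transitional probability between
   adjacent syllables: TP = 1.0 inside a word, TP = 1/3 across boundaries.
   Streams come in a *flat* version (every syllable at 216 Hz) and a
   *melodically enriched* version (one fixed tone per syllable, so each word
   carries a unique 3-tone contour). Implicit *test* streams insert
   syllable-reversed "illegal" word-forms (25% of tokens) that never follow
   their source word.
2. **Simulated neonatal EEG** — a 16-channel 10/20 montage plus two mastoids
   at 250 Hz. Word-locked ERP components ride on 1/f + white background
   noise: a fronto-central learning component (200–500 ms) whose amplitude
   drifts from a block-1 to a block-2 level, and — for illegal word-forms in
   the melodic condition only — positive mismatch responses (MMR) in the
   300–400 ms and 800–900 ms windows. Each simulated newborn also receives
   an 18-month expressive-vocabulary score (MCDI) generated from a linear
   model on its EEG traits.
3. **ERP pipeline** — mastoid re-referencing, zero-phase Hamming-window FIR
   band-pass (0.5–20 Hz learning / 1–20 Hz test), −50..1050 ms word-onset
   epochs, baseline correction, ±120 μV artifact rejection, and window-mean
   amplitudes.
4. **Statistics** — repeated-measures ANOVA with Greenhouse–Geisser
   correction and partial η² (any number of within factors), one-sample and
   paired t-tests with Cohen's d, Benjamini–Hochberg FDR, Fisher LSD
   post-hocs.
5. **Prediction** — per-subject EEG features (L_flat, L_melody = block 2 −
   block 1 learning dynamics; TW1, TW2 = illegal − legal MMR amplitudes),
   Pearson correlations with FDR, backward multiple regression, and
   leave-two-subjects-out cross-validation with a full-rerun permutation
   test:

   predicted MCDI  =  b₀ + b₁·L_melody + b₂·TW2_melody,

   evaluated by the R² of the regression of true on predicted scores and the
   mean absolute error, each against its permutation null.

The package is aimed at researchers who want a transparent reference
implementation of this analysis chain — for power analysis, method checks,
or teaching — without access to infant EEG.

## Worked example

```python
import segspeech as s

# A melodic learning stream and its transition structure
lang   = s.stimgen.assign_pitches(s.stimgen.build_language(id="L1"), "melodic")
stream = s.stimgen.generate_learning_stream(lang, reps=50, seed=1)
tm     = s.stimgen.transition_matrix(stream)
print(len(stream.events), stream.total_duration_ms, tm.prob("KU", "PO"))
# 600 210000.0 1.0   -> 600 syllables over 3.5 min; within-word TP is 1.0

iv = s.stimgen.interval_stats(lang, stream)
print(round(iv.mean_abs_within, 3), round(iv.mean_abs_between, 3))
# 3.375 7.136   -> pitch steps are smaller inside words than across boundaries

# A small end-to-end run: simulate, preprocess, analyse, predict
cfg = s.PipelineConfig(n_subjects=6, n_outcome_subjects=6,
                       n_permutations=200, seed=11)
report = s.run_full(cfg, out_dir="run")
print(report["cv"])
# {'r_squared': ..., 'mae': ..., 'n_folds': 15, 'p_r2': ..., 'p_mae': ...}
```

`run/` then contains the tidy amplitude tables, the ANOVA and t-test result
tables, the per-subject feature table, the cross-validated predictions, and
a manifest with the seeds and file hashes. The same stages are exposed on
the command line:

```bash
segspeech stimgen --language L1 --condition melodic --phase test --seed 3 --out events.tsv
segspeech simulate --n 28 --seed 1 --out cohort/
segspeech preprocess --in cohort/ --phase learning --out learning.csv
segspeech run --n 13 --seed 1 --out run/
```

## Documentation

`docs/methods.md` describes the generative model, its calibration, the
numerical choices in the pipeline, and known limitations.
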