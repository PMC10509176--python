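# phonoscope

Interpretable speech and voice biomarkers for clinical group comparison.

Speech is a promising objective marker for psychiatric conditions such as
schizophrenia spectrum disorder (SSD) and major depressive disorder (MDD):
psychomotor slowing, alogia, and flat affect leave measurable traces in
timing, intonation, voice quality, and articulatory coordination.
`phonoscope` implements that analysis end to end for researchers working
with picture-description (or similar spontaneous-speech) recordings:

1. **Feature extraction** — 38 interpretable sample-level features:
   tempo/pause (speech rate, articulation rate, talking rate, pause
   duration mean/SD, pause rate, pauses per minute), prosody (f₀ and
   intensity SD/kurtosis/skewness, energy velocity), spectrum (MFCC means
   1–13), voice quality (smoothed cepstral peak prominence CPPs and
   low-to-high spectral ratio LHR, each with mean/SD/kurtosis/skewness),
   and articulation-coordination features (ACF1–3, eigenspectrum summaries
   of a channel-delay correlation matrix).
2. **Classification** — pairwise SVMs (linear, 2- and 3-degree polynomial
   kernels) under 5-fold cross-validation that never splits a
   participant's samples across folds, with the box constraint tuned per
   training split by expected-improvement Bayesian search, repeated over
   many independent fold seeds.
3. **Importance** — permutation feature importance
   (FI = accuracy − mean accuracy over 20 within-fold shuffles), averaged
   over folds and repetitions, with the top 25% of features selected per
   model.
4. **Statistics** — percent differences between patient groups and
   controls with assumption-routed tests (Shapiro-Wilk → Mann-Whitney U;
   Levene → Welch ANOVA; else one-way ANOVA), and two-tailed Pearson
   correlations with symptom scales (HAM-D, SANS, SAPS and subscales),
   Bonferroni-corrected per table.

Because clinical audio can rarely be redistributed, the package ships a
**synthetic cohort generator**: source-filter utterances (glottal pulse
train + shaped aspiration noise) whose pause schedule, pitch contour,
spectral tilt, harmonicity, and articulatory coupling are commanded
exactly — so every extractor, the classifier protocol, and the statistics
can be validated against known ground truth.  See `docs/methods.md` for
the full model description and its limits.

## Worked example

Run the whole pipeline on the default synthetic cohort (3 groups × 20
participants × 4 samples of 20 s each, 5 pipeline repetitions):

```bash
phonoscope run-all --simulate-default --out my_run --duration 20 --reps 5 --seed 1
```

or from Python:

```python
from phonoscope import RunConfig, run_all
bundle = run_all(RunConfig(out_dir="my_run", duration_s=20.0, reps=5, master_seed=1))
print(bundle["metrics"])
```

The metrics table printed for that seed:

```
 kernel_degree    pair  accuracy  precision  recall       f1
             1  HC-SSD   0.98625   1.000000  0.9725 0.985548
             2  HC-SSD   0.96750   0.995147  0.9400 0.963279
             3  HC-SSD   0.97500   0.995294  0.9550 0.972910
             1  HC-MDD   0.98625   0.995556  0.9775 0.985690
             2  HC-MDD   0.98500   0.993056  0.9775 0.984480
             3  HC-MDD   0.98625   0.990441  0.9825 0.985950
             1 SSD-MDD   0.70750   0.718562  0.7275 0.712509
             2 SSD-MDD   0.67125   0.660867  0.7600 0.695370
             3 SSD-MDD   0.66375   0.670251  0.7200 0.676283
```

Reading it: the generator plants strong HC-vs-patient differences (fewer
pauses per minute, lower talking rate, flatter pitch, simpler articulatory
coupling in the patient groups), so both HC models are nearly perfect; the
two patient groups share most effect directions by construction and differ
only subtly (mainly pitch variability and coupling strength), so SSD-vs-MDD
separates far more weakly.  These numbers characterize the synthetic
cohort, not any clinical population.

The run directory also contains `features.csv` (the 240 × 38 feature
table), `importance.csv` and `top_features.json` (permutation importances
and the top-25% sets whose union feeds the statistics), a group-comparison
table (feature, pair, percent difference, routed test, F/U statistic,
Bonferroni-adjusted p), a symptom-correlation table, and `run_log.json`
with the full configuration and its hash (which is also embedded in every
CSV header).

Individual stages are exposed both as library functions
(`extract_all`, `make_grouped_stratified_folds`, `repeat_pipeline`,
`importance_from_repetitions`, `compare_groups`, `correlate_symptoms`) and
as CLI subcommands (`simulate`, `extract`, `classify`, `run-all`).

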