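# Methods

`phonoscope` implements an interpretable speech-biomarker analysis for
clinical cohorts: a fixed set of 38 sample-level acoustic features, pairwise
SVM classification under participant-grouped cross-validation, post hoc
permutation feature importance, and assumption-routed descriptive statistics
with symptom-scale correlations.  Every stage is exercised on a synthetic
speech cohort whose acoustic structure is known exactly.  This note records
the models, the parameter choices that matter, and the limits of what the
synthetic test bed can show.

## Signal front end

Recordings are converted to mono float64 at a common analysis rate
(default 16 kHz; chosen so the 0–4 kHz low band of the spectral-balance
feature and the 8 kHz mel band of the MFCCs both fit with margin).
Amplitude is only peak-normalized when decoding overshoots [−1, 1]; no
loudness normalization is applied because every intensity-derived feature
is either referenced to the loudest frame or is a distribution-shape
statistic, both invariant to global gain.

Manual annotations of examiner speech or noise (tab-separated label
tracks, Audacity dialect) are excised by concatenating the kept regions.
Each splice point is logged, and a 50 ms guard band around it is excluded
from pause detection, so an excision can never manufacture or hide a pause.
A removal covering more than 75% of a recording raises a warning: such a
sample is considered unusable.

Two frame grids are used: 25 ms / 10 ms Hann frames for energy, spectrum,
and voice-activity decisions, and 40 ms / 10 ms frames for pitch and
cepstral analysis (40 ms fits two periods of the lowest tracked pitch,
60 Hz).  The grids are aligned by nearest frame center where a mask from
one is needed on the other.

## Voice activity, pauses, and tempo (7 features)

Frames are classified speech/silence by an adaptive threshold: the 35th
percentile of the frame-energy distribution minus 10 dB, with an absolute
−70 dBFS floor that rejects digital silence.  Because the threshold is a
percentile, the decision — and every tempo feature downstream — is
invariant to global gain.  Speech runs shorter than 60 ms are merged into
silence; silent runs of at least 250 ms *bounded by speech on both sides*
are pauses (250 ms is the conventional psycholinguistic minimum for a
silent pause; configurable).  Leading and trailing silence is neither
speech nor pause.

Syllable nuclei are intensity peaks within speech that exceed the median
speech intensity minus 2 dB, rise at least 2 dB above the surrounding
minima, coincide with a voiced frame, and are at least 100 ms apart.

The seven tempo/pause features: `speech_rate` (nuclei per second of total
duration), `articulation_rate` (nuclei per second of phonation time),
`talking_rate` (phonation time over total duration), pause-duration mean
and SD, `pause_rate` (pauses per second of phonation time), and `ppm`
(pauses per minute of total duration).  The two pause-frequency features
deliberately use different denominators so neither duplicates the other.
A degenerate sample (zero phonation) propagates missing values with
machine-readable reasons; it is never silently reported as 0.

## Prosody (7 features)

Pitch is estimated per frame from the normalized autocorrelation after
dividing out the Hann window's own autocorrelation (the taper otherwise
biases the peak down at long lags).  A frame is voiced when the corrected
peak in the 60–400 Hz lag band reaches 0.45 and the frame is energetic.
Because the window correction amplifies long lags, a comparable peak at
half the winning lag marks an octave-down error and is preferred; a
3-frame median filter smooths the track, and any residual estimate more
than a factor 1.5 from the global voiced median is folded back by octaves
(or dropped if no octave fits).  On synthetic constant-pitch material this
tracker holds the f0 SD near 0.1 Hz.

f0 statistics (SD, kurtosis, skewness) are computed in Hz over voiced
frames only.  Intensity is frame RMS in dB referenced to the loudest
frame; its statistics use speech frames only (silence would otherwise
dominate the kurtosis).  All SD/kurtosis/skewness features share one
helper returning population (n-denominator) moments with *non-excess*
kurtosis (normal → 3), matching the numeric conventions of the
MATLAB-style environments these features are usually reported from.
Constant input or fewer than 8 values gives missing statistics.
`energy_velocity` is the mean absolute first difference of the intensity
contour per second, taken only between frames adjacent in time — never
across a pause.

## Spectrum and voice quality (21 features)

* **MFCC means 1–13** — 26-band triangular mel filterbank to 8 kHz,
  orthonormal DCT-II, coefficient 0 excluded so all retained coefficients
  are gain-invariant; averaged over speech frames.
* **LHR** (low-to-high spectral ratio) — per speech frame,
  10·log10 of band energy below vs above 4 kHz (the conventional split for
  this dysphonia measure); frames with an empty high band clip at +60 dB
  and stay in the distribution.  Mean, SD, kurtosis, skewness.
* **CPPs** (smoothed cepstral peak prominence) — per 40 ms frame the real
  cepstrum of the dB power spectrum is taken; cepstra are moving-averaged
  over 10 frames and 10 quefrency bins; a least-squares line fitted over
  quefrencies [1 ms, 1/60 s] is the baseline, and CPPs is the height of
  the cepstral peak within [1/400 s, 1/60 s] above that line.  The
  cepstrum is expressed in dB of cepstral power (the convention of the
  smoothed-CPP literature and of standard tools), which puts modal voice
  around 15–25 dB and white noise near 0–2 dB.  Computed on voiced frames
  only.  Mean, SD, kurtosis, skewness.

## Articulation coordination (3 features)

The coordination features summarize the eigenvalue spectrum of a
channel-delay correlation matrix: C parallel articulatory time series are
stacked with D time-delayed copies of each (default C = 6 channels,
D = 15 delays of one 10 ms hop — a 150 ms span), and the (CD × CD)
correlation matrix is eigendecomposed.  With eigenvalues normalized to sum
1: `acf1` is the mass of the top ⌈CD/4⌉ eigenvalues, `acf2` the spectral
entropy normalized by ln(CD), `acf3` the bottom-quartile mass.  Tightly
coupled, low-dimensional articulation concentrates variance in few
eigenvalues (acf1 ↑, acf2 ↓); rich independent movement spreads it.

The canonical inputs to this construction are vocal-tract variables from a
trained speech-inversion network.  No such network is bundled here;
instead the default channels are the MFCC 1–6 trajectories over speech
frames, z-normalized — a proxy that preserves the delay-correlation
eigenspectrum construction and its coupling/complexity reading while being
computable from audio alone.  The channel source is pluggable, and results
from the proxy should be interpreted as coordination of the *spectral
envelope*, not of measured articulators.  Fewer than 5 s of speech leaves
the ACFs missing (the matrix is unstable below that).

## Classification protocol

Pairwise SVMs (HC–SSD, HC–MDD, SSD–MDD) with polynomial kernels of degree
1, 2, 3 (degree 1 is a plain linear kernel; degrees 2–3 use coef0 = 1).
Folds are built over *participants*: within each class, participants are
shuffled by the fold seed and dealt round-robin to the 5 folds, so all
four samples of a participant always share a fold and per-fold class
counts differ by at most one participant.  This grouping is load-bearing:
with within-participant correlation 0.9 the package's own leakage
demonstration shows row-level CV scoring above participant-grouped CV on
identical data.

The box constraint C is tuned per training split over log10 C ∈ [−3, 3]
by expected-improvement Bayesian search on a Gaussian-process surrogate
(5 space-filling starts, 30 evaluations total; a 13-point grid search is
the fallback), with a 3-fold participant-grouped inner CV inside the
training split as the objective.  Near-ties resolve to the smallest C.
The kernel scale is 1/(n_features · mean feature variance) of the training
data.  Standardization is `leakage_safe` by default (z-scoring fitted on
training folds only); a `paper_faithful` mode replicates the common
practice of z-scoring the whole table before splitting.  The null bias of
that practice is measurable here and is slightly *pessimistic* (permuted-
label accuracy ≈ 0.46 rather than 0.50) because pre-split centering forces
training and validation feature sums to cancel; both modes keep the null
bias under 0.05.

Metrics (accuracy, precision, recall, F1; positive class = the patient
group, or MDD for SSD–MDD) are computed per validation fold at the sample
level and averaged over folds; the entire pipeline, including fold
construction, is repeated (default 100 repetitions; the bundled scaled-down
run uses 5) with independent seeds and the metrics averaged again.

## Permutation importance

For each feature, the trained fold model is re-evaluated on its validation
fold with that feature's column shuffled (20 shuffles); the importance is
baseline accuracy minus mean permuted accuracy, averaged over folds and
repetitions.  Permutation happens at evaluation time only — the model is
never refitted — and a feature constant within a fold has importance
exactly 0.  Per-model importances are summed across the three pairwise
models for the cross-model aggregate ranking (a mean option exists).  The
top 25% is the ⌈0.25 · 38⌉ = 10 highest-ranked features per model, ties
broken by name; the union of the three top sets feeds the descriptive
statistics.

## Descriptive statistics

The unit of analysis is the participant: the four samples are averaged
before testing, avoiding pseudo-replication from repeated samples (a
`per_sample` switch reproduces the sample-level alternative).  For each
top feature and each patient-vs-HC pair: the percent difference
100·(mean_patient − mean_HC)/mean_HC, and a test routed by its
assumptions — Shapiro-Wilk per group at α = 0.05 (any failure →
Mann-Whitney U), else Levene (failure → Welch ANOVA, own implementation
cross-checked against an independent one), else one-way ANOVA (for two
groups, F = t²).  The route and assumption p-values are recorded with
every result.  Symptom correlations are two-tailed Pearson r between
participant-level features and HAM-D/SANS/SAPS scores (plus alogia, flat
affect, and formal-thought-disorder subscales) within each patient group.
Bonferroni correction is applied per output table (the group-comparison
table and the correlation table are separate families).

## Synthetic cohort

The generator is source-filter synthesis: a glottal pulse train follows a
commanded f0 contour (sinusoidal intonation; the commanded f0 SD is the
contour SD), aspiration noise is mixed at a commanded level, the spectrum
is shaped to a commanded tilt in dB/octave, a syllable-rate amplitude
modulation (~4 Hz, deep dips) creates countable nuclei, silences are
inserted at an exact pause schedule, and three frequency bands are
gain-modulated by a blend of independent band-limited carriers and one
shared slow pattern.  The blend weight (`articulation_complexity`) is the
coordination driver: at 1 the three bands move independently (rich
articulation), at 0 they follow one stereotyped pattern.  All modulation
weights are bounded at 2.5 SD so no carrier excursion can dominate the
waveform's peak normalization.

Default cohort: 3 groups × 20 participants × 4 samples.  Participant
parameters are drawn once per participant and perturbed ~6% per sample,
giving within-participant correlation.  Group effects are encoded as
multipliers on HC means and claim *directions only* — patients produce
fewer but longer pauses (PPM ↓, talking rate ↓), a flatter pitch contour
(f0 SD ↓, stronger in the SSD-like group), less variable harmonicity
(CPPs SD ↓), and simpler articulation (complexity multiplier ≈ 0.6 →
acf1 ↑, acf2 ↓).  Symptom scores are generated per participant from
group-specific means/SDs (clinically plausible magnitudes: e.g. SANS
highest in the SSD-like group), floored at 0, optionally with target
correlations to chosen features via r·z(feature) + √(1−r²)·noise.

Utterance duration defaults to 180 s but the bundled end-to-end runs use
20 s: at that length every feature family has ample support (≥ 15 s of
speech against the 5 s ACF minimum) while a full cohort extraction stays
in the minutes range on one core.

What the generator does *not* emulate: phones and words (so speech rate is
a modulation-rate proxy, not lexical), room acoustics and recorder
coloration, formant dynamics, creak/diplophonia, and any linguistic
content differences between groups.  Passing tests therefore demonstrate
that the pipeline recovers planted acoustic structure and is statistically
sound — not that the specific clinical effect sizes of real cohorts would
be reproduced.

## Numerical and degenerate-input conventions

FFT sizes are the next power of two above the frame length; cepstra use
the full symmetric spectrum.  LHR frames clip at ±60 dB rather than going
missing.  Eigenvalues are clipped at 0 after checking the matrix is PSD to
−1e-8.  Importance ranks and top sets break ties lexicographically by
feature name so repeated runs are stable.  Missing features propagate as
NaN with recorded reasons; rows with missing features are dropped (with
count logged) before model fitting.  All randomness flows from explicit
seeds through `numpy.random.Generator`/`SeedSequence`; repeated runs with
one master seed are bit-stable.

## Known limitations

* The articulation-coordination channels are spectral-envelope proxies,
  not inverted vocal-tract variables; absolute ACF values are not
  comparable to systems using a speech-inversion front end.
* The syllable-nucleus counter is tuned for modulation depths typical of
  speech and of the synthesizer; heavily compressed audio will undercount.
* The pitch tracker is an autocorrelation design adequate for the 60–400 Hz
  band; it is not a research-grade tracker for creaky or diplophonic voice.
* SSD-vs-MDD separation in the default synthetic cohort is markedly weaker
  than the HC contrasts by construction (the two patient groups share most
  effect directions and differ mainly in pitch variability and coupling
  strength).
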