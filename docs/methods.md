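# Methods

`apneakit` implements an epoch-level sleep-apnea detection and distinction
pipeline over a low-invasiveness polysomnography (PSG) channel set —
thoracic respiratory-inductance-plethysmography (RIP) volume, pulse-oximetry
SpO2, an audio (snore-intensity) registration, two electrooculograms (EOG),
one ECG and a body-position code, all at 100 Hz, 16-bit, band-limited below
30 Hz. Because clinical PSG archives are access-restricted, the package
ships a first-class synthetic-PSG generator whose planted physiology makes
every downstream stage testable end to end. This note documents the models,
the parameters that matter, and what the synthetic experiments do and do not
demonstrate.

## Synthetic recordings

**Event scheduling.** Respiratory events (hypopnea HYP; obstructive OSA,
central CSA and mixed MSA apneas) last 10–120 s, with durations drawn from a
log-normal with median 28 s and log-SD 0.41 (about 60% of events in the
typical 20–40 s band), truncated by resampling. Events recur in
class-homogeneous runs of 2–5 (the cyclic pattern of apneic sleep), with
15–25 s gaps inside a run; runs are separated by exponential quiet stretches
whose mean is set so the realized count concentrates around the nominal
events-per-hour rate. A minimum 15-s gap always separates consecutive
events. The default class mix gives half of all events to hypopnea and
splits the apneas 84.5/0.4/15.1% between OSA/CSA/MSA (the population shares
of the three apnea forms, normalized).

**Channel physiology.** Thoracic effort is a quasi-sinusoidal oscillation at
the subject's respiratory rate (0.15–0.35 Hz) with slow amplitude and
frequency wandering, a subject-level excursion scale (log-normal, σ=0.45 —
RIP amplitude varies severalfold with physique and belt placement) and
piecewise-constant belt-coupling segments. During CSA the envelope drops to
5% of baseline; during HYP to 50–70%; during OSA the envelope is preserved
with a crescendo (0.95→1.25) and breath-to-breath irregularity while the
effort rate slows by 40% (labored breaths against the closed airway); MSA is
a central first phase (40–60% of the event) followed by an obstructive one.
Every event ends with 12 s of recovery hyperpnea (gain 1.45 for apneas, 1.15
for hypopneas) and the slowed-breath phase deficit is repaid by fast
recovery breaths, so removing an event leaves the signal outside
[onset−5 s, end+60 s] untouched.

SpO2 sits at the subject baseline (94–99%) with ±0.5% slow noise. Each event
produces a desaturation of depth 3% + 4%·(1 − residual airflow) — 7% for
apneas, 4.2–5% for hypopneas (residual flow 0.5–0.7) — delayed by a
circulatory lag uniform in [10, 20] s, with an 8-s fall constant and a 15-s
exponential resaturation, tapered to zero 60 s after event end. Overlapping
desaturations inside a run add, emulating the progressive hypoxemia of
cyclic apnea. Values are clipped to [70, 100]%.

The audio channel is modeled as a *snore-intensity envelope* (a 100-Hz,
sub-30-Hz "audio registration" is physically a loudness trace, not raw
sound): non-negative respiration-gated bursts with a subject-level mic gain
and slow loudness drift, a small ambient floor, amplification around
obstructive events (scaled by the subject's snore propensity), silence
during central phases, and a 4-s resuscitative snort at airway reopening.
ECG is a QRS-template pulse train whose RR interval lengthens 15% during an
event and shortens 10% for 10 s at termination (halved for hypopneas). EOGs
are 1/f-like noise; each event termination adds a 10-s arousal burst with
both beta-band (13–30 Hz) and delta-band (eye-movement) components, weaker
after hypopneas. Body position is a piecewise-constant code (0 supine,
1 left, 2 right, 3 prone, 4 upright) with 0–4 changes per night.

**Scoring emulation.** Recorded annotations score event presence, onset and
duration faithfully, but confuse the apnea *subtype* (OSA/CSA/MSA) at a 15%
rate, reflecting the documented inter-scorer ambiguity of subtype assignment
(mixed events in particular). Channel physiology always follows the true
morphology; the pipeline — like any model trained on expert labels — sees
the scored classes. This is what bounds subtype-distinction performance well
below detection performance, as observed clinically.

**Front end.** A zero-phase order-4 Butterworth band-pass (0.05–30 Hz) is
applied to the AC-coupled channels (thoracic, audio, EOGs, ECG), a 30-Hz
low-pass to SpO2, then 16-bit midtread quantization over each channel's
physical range. One root seed per subject is expanded into independent
per-channel streams, and all event-locked draws are keyed by the event's
onset sample, so recordings are bit-reproducible and event responses are
local.

**What the generator does not emulate:** sleep-stage architecture beyond
sleep/wake flags, movement/electrode artifacts beyond annotated detachment
intervals (which are annotation-only; samples are not corrupted), CPAP
signals, leg movements, nasal airflow/pressure, and the subject-level
comorbidity structure of real cohorts. Passing results on synthetic cohorts
therefore demonstrate the correctness and calibration of the pipeline, not
clinical performance on real PSG.

## Epoching and labeling

Signals are cut into non-overlapping 30-s epochs anchored at recording
start (trailing partial windows dropped). Epochs flagged wake in the
hypnogram, or overlapping a sensor-detachment interval by ≥1 s, are
excluded. Each retained epoch takes the class of the scored event with the
largest temporal overlap, provided that overlap is at least 5 s (half the
minimum clinical event duration — this blocks labeling by a sliver of an
adjacent event); otherwise it is NORMAL. Exact ties go to the more severe
class (CSA > MSA > OSA > HYP).

## Feature bank

All features are computed from a single epoch; registries fix the two
named subsets:

* **Detection subset (32):** thoracic time statistics (mean, SD, median,
  IQR, peak count, min/mean/SD/sum of peak heights above the epoch median,
  mean inter-peak distance, rectified area), thoracic spectral statistics
  (mean/median/peak frequency and band power over the 0.05–1 Hz respiration
  band) and order-2 Renyi spectral entropy; SpO2 SD, range, min, 95th/5th
  percentiles, 12-s delta index, hypoxic burden TSA95 (fraction of the epoch
  below 95% saturation) and ApEn(2, 0.25·SD)/ApEn(2, 0.15·SD); audio mean,
  median, instantaneous-spectral-entropy (ISE) range and time outside
  mean±2SD; EOG delta power (both sides) and right-EOG beta power.
* **Distinction subset (44):** 16 ECG discrete-wavelet statistics (db4,
  5 levels, periodization: IQR of d3–d5, variance of d1–d3, SD and MAD of
  d1–d5) plus mean/median RR interval; 12 thoracic features (the time
  statistics above plus inter-peak-distance skewness, mean frequency and
  band power); 9 SpO2 features (M2, the second central moment, replacing the
  95th percentile); audio d3/d4 wavelet energies, ISE range and Renyi
  entropy; and the majority body-position code.

Numerical conventions worth noting: Welch spectra use 4-s Hann segments with
50% overlap (0.25-Hz bins); Renyi entropy is taken over the normalized Welch
PSD as a distribution over frequency bins (deterministic and bin-free, where
an amplitude histogram would need arbitrary binning); ApEn follows the
self-match-inclusive convention with Chebyshev distance and is computed on
the 1-Hz SpO2 series over a sliding context of the current plus three
previous epochs (120 samples — 30 samples alone under-determine ApEn with
m = 2); peak detection requires prominence ≥10% of the epoch range and 1-s
separation; beats are found by derivative-energy thresholding with a 250-ms
refractory period, and epochs with fewer than two beats get RR features
flagged and imputed with the training-split median; the delta index uses the
conventional 12-s windows; TSA95 is a time *fraction* (switchable to
seconds). SD uses the n−1 denominator throughout; skewness of a constant
series is defined as 0.

## Feature selection and class structure

Features are z-scored with training-split statistics (zero-variance columns
dropped with a warning), then PCA is performed by eigendecomposition of the
sample covariance; components are ordered by decreasing eigenvalue and
signed so the largest-magnitude loading is positive. Retention keeps, for
the smallest leading set of components reaching a cumulative-variance target
(default 0.9), the union of each component's top-k features by absolute
loading (default k = 10); both knobs are exposed, since published Pareto
charts do not pin them down. Retention is monotone in the variance target.

Class structure is summarized by the pairwise Mahalanobis distances between
class mean vectors under the pooled within-class covariance (the distance
structure a one-way MANOVA is built on; Wilks' Λ is reported alongside),
agglomerated with complete linkage — a stable choice for five points.
Ill-conditioned pooled covariances get a 1e-6·trace/p ridge, and globally
constant features are dropped before inversion. Pearson correlation matrices
flag zero-variance columns with zero off-diagonal entries.

## Case studies, balancing and evaluation

Three dichotomous tasks: (i) apnea (OSA/CSA/MSA) vs normal/hypopnea,
(ii) apnea vs normal with hypopnea epochs dropped entirely (the natural
reading of "apnea vs normal"), (iii) OSA/MSA vs CSA. Subjects are split
70/30 with no subject in both sides. Detection cases keep every apnea epoch
and randomly subsample negatives to the same count (roles flip, with a log
note, if negatives are rarer). The distinction case keeps all MSA epochs
(the rarest class) and subsamples OSA and CSA preserving their full-table
ratios to MSA, rescaled so the largest class is at most cap×MSA (cap
default 5 — the proportion clause admits several readings; this one is
switchable).

Five model families are compared: decision tree (max depth 1–30, min leaf
1–100 log-uniform), discriminant analysis (linear with shrinkage 0–1, or
quadratic with regularization 0–0.5), Gaussian naive Bayes (variance
smoothing 1e-12–1e-3; kernel-density naive Bayes is not available in
scikit-learn, so the family searches the Gaussian variant only), SVM
(kernel linear or RBF, C in 1e-2–1e3, gamma 1e-4–10; the kernel can be
pinned) and kNN (k 1–50; Euclidean, cityblock or cosine metric).
Hyperparameters are chosen by seeded random search (budget default 200
evaluations), each candidate scored by subject-grouped 5-fold CV accuracy
inside the training split — grouping prevents within-subject leakage — and
the winner is refit on all training rows.

Metrics are sensitivity, specificity, PPV, NPV and accuracy from the test
confusion matrix; zero-denominator ratios are flagged undefined (NaN), never
reported as 0. Evaluation repeats re-draw the balancing with a fresh rng
substream (default 20 repeats), so the reported mean ± SD reflects balancing
variability; on an exactly balanced test set ACC = (SENS+SPEC)/2 holds per
repeat by construction. The "best" family maximizes min(sensitivity,
specificity) among families whose mean accuracy is within one SD of the best
— an explicit reading of the accuracy-vs-balance tradeoff.

## Validation protocol and problem sizes

The validation suite checks, in increasing scope: registry fidelity (exact
feature counts by signal); equivalence of ApEn, delta index, DWT details and
Mahalanobis distances with brute-force reference implementations to 1e-9 on
50 random inputs; the metric formulas and the balanced-accuracy identity;
and end-to-end label recovery on a reference cohort of 40 subjects with 4-h
nights at 15 events/h and full effect size, where a linear-kernel SVM on the
32-feature registry must reach ≥0.90 accuracy, shuffled labels must fall to
chance (within three combined SDs of 0.5), and the five-class dendrogram's
first split must separate {NORMAL, HYP} from {OSA, CSA, MSA}. An
effect-size knob scaling every event-locked response is swept (1.0, 0.4, 0)
on smaller cohorts to confirm accuracy degrades monotonically to chance.
Search budgets and repeat counts in these protocols (budgets 2–6, repeats
2–3) are deliberately small: the SVM's accuracy on this cohort is flat in C
over a wide range, and the protocols are sized for routine desk runs. The
results-reproduction script uses a 24-subject, 3-h-night cohort for the same
reason.

## Known limitations

The synthetic cohort is easier than real PSG: no artifacts beyond annotated
detachments, no sleep-stage confounds, stationary subject physiology, and
a scorer model limited to subtype confusion. Accuracies on it — detection
and subtype distinction alike — exceed what the same pipeline attains on
clinical data. EEG features are out of scope. The subtype-confusion rate
(15%) and the balancing cap are package choices, exposed as parameters.
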