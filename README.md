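# apneakit

Epoch-level detection and distinction of sleep-apnea events from
multi-channel polysomnography (PSG), built for researchers in biomedical
signal processing and sleep medicine who want a tested, reproducible
pipeline from raw channels to classifier metrics — without access to a
restricted clinical archive.

Sleep apnea–hypopnea syndrome produces repetitive respiratory events of
10–120 s: obstructive apneas (OSA — effort continues against a collapsed
airway), central apneas (CSA — effort absent), mixed apneas (MSA — central
then obstructive) and hypopneas (HYP — partial reduction). Each event drives
a delayed, proportional drop in SpO2 and typically ends with recovery
hyperpnea, a resumption snort and a cortical arousal. `apneakit` turns a
night's recording into 30-s scored epochs, computes the 32-feature
(detection) and 44-feature (distinction) banks over a low-invasiveness
channel set (thoracic RIP belt, SpO2, audio, 2×EOG, ECG, body position),
and evaluates three dichotomous tasks with interpretable classifiers::

* **case i** — apnea (OSA/CSA/MSA) vs normal/hypopnea,
* **case ii** — apnea vs normal (hypopnea epochs dropped),
* **case iii** — OSA/MSA vs CSA.

Splits randomize on *subjects* (70/30), classes are balanced per the
case-specific rules, hyperparameters are tuned by seeded search with
subject-grouped 5-fold CV, and performance is reported as
SENS/SPEC/PPV/NPV/ACC, each mean ± SD over re-balanced repeats:

SENS = TP/(TP+FN), SPEC = TN/(TN+FP), PPV = TP/(TP+FP),
NPV = TN/(TN+FN), ACC = (TP+TN)/N.

Because clinical PSG archives are access-restricted, the package includes a
seeded synthetic-PSG generator (annotated events, hypnogram, detachment
intervals; EDF+ export) whose planted physiology — effort suppression,
lagged desaturations, snoring, RR-interval cycling, arousal bursts — makes
the whole pipeline testable end to end. PCA-based feature selection and the
MANOVA group-mean dendrogram (Mahalanobis distances, complete linkage) are
included for class-structure analysis. See `docs/methods.md` for models,
parameters and limitations.

## Worked example

```python
from apneakit import CaseStudy, build_feature_table, generate_cohort

mix = {"OSA": 0.45, "CSA": 0.15, "MSA": 0.15, "HYP": 0.25}
recs = generate_cohort(8, 1.0, event_rate_per_h=20, class_mix=mix, seed=3)
table = build_feature_table(recs, "b32")      # 8 subjects x 1-h nights

study = CaseStudy(table, "i", families=("svm", "knn"), seed=1)
print(study.fit(repeats=3, budget=6).summary())
```

prints:

```
                            Apnea case-study results
===============================================================================
Case:            i  (OSA/CSA/MSA vs NORMAL/HYP)
Feature registry: b32  (32 features)
Subjects:        6 train / 2 test (subject-wise split)
Repeats:         3
-------------------------------------------------------------------------------
family                 SENS         SPEC          PPV          NPV          ACC
-------------------------------------------------------------------------------
svm             0.942±0.033  0.968±0.011  0.967±0.012  0.944±0.032  0.955±0.022 *
knn             0.865±0.051  0.962±0.019  0.958±0.018  0.879±0.040  0.913±0.017
-------------------------------------------------------------------------------
* best accuracy/balance tradeoff
===============================================================================
```

Each row is one model family; entries are mean ± SD over re-balanced
evaluation repeats on held-out subjects, and `*` marks the family with the
best accuracy/balance tradeoff. A CLI covers the same flow
(`apneakit generate|extract|run-case --help`).

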