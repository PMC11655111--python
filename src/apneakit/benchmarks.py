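"""Reference evaluation protocols on synthetic cohorts.

These are the fixed study conditions used by the validation suite and the
results-reproduction script: a strong-effect cohort with all five epoch
classes represented, the linear-SVM detection protocol for case i, the
shuffled-label null calibration, the five-class group-mean dendrogram, and
the subtype-distinction protocol for case iii.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cases import subject_split
from .features import registry_names
from .selection import manova_dendrogram
from .study import CaseStudy, build_feature_table
from .synthetic import generate_cohort

#: event mix used for benchmark cohorts: obstructive-dominant but with all
#: five epoch classes populous enough to estimate class means
STRONG_MIX = {"OSA": 0.45, "CSA": 0.15, "MSA": 0.15, "HYP": 0.25}

META_COLS = ("subject_id", "epoch_index", "label")


def benchmark_table(
    n_subjects: int,
    hours: float,
    seed: int,
    registry_id: str = "b32",
    event_rate_per_h: float = 15.0,
    effect_size: float = 1.0,
) -> pd.DataFrame:
    """Generate a cohort and extract its epoch feature table."""
    recs = generate_cohort(
        n_subjects,
        hours,
        event_rate_per_h=event_rate_per_h,
        class_mix=STRONG_MIX,
        effect_size=effect_size,
        seed=seed,
    )
    return build_feature_table(recs, registry_id)


def subset_registry(table: pd.DataFrame, registry_id: str) -> pd.DataFrame:
    """Project a full-bank table onto one registry's columns."""
    return table[list(META_COLS) + registry_names(registry_id)]


def detection_protocol(
    table: pd.DataFrame,
    seed: int,
    repeats: int = 3,
    budget: int = 6,
    shuffle_labels: bool = False,
    families=("svm",),
    svm_kernel: str | None = "linear",
):
    """Case-i evaluation (apnea vs normal/hypopnea), linear-kernel SVM by
    default; returns the fitted CaseStudyResults."""
    study = CaseStudy(
        table, "i", registry_id="b32", families=families, seed=seed, svm_kernel=svm_kernel
    )
    return study.fit(repeats=repeats, budget=budget, shuffle_labels=shuffle_labels)


def distinction_protocol(
    table: pd.DataFrame, seed: int, repeats: int = 3, budget: int = 6, families=("svm",)
):
    """Case-iii evaluation (OSA/MSA vs CSA) on the 44-feature registry."""
    study = CaseStudy(table, "iii", registry_id="iii44", families=families, seed=seed)
    return study.fit(repeats=repeats, budget=budget)


def null_band(results) -> tuple[float, float]:
    """(|acc - 0.5|, 3 sigma band) for a shuffled-label run; the band
    combines the repeat SD with the binomial SE of the test-set size."""
    rep = results.report(results.best_family)
    n_test = rep.per_repeat[["tp", "fn", "tn", "fp"]].sum(axis=1).mean()
    acc = float(rep.mean["acc"])
    band = 3.0 * float(np.sqrt(0.25 / n_test + rep.std["acc"] ** 2))
    return abs(acc - 0.5), band


def dendrogram_first_split(table: pd.DataFrame):
    """Five-class group-mean dendrogram on labeled epochs; returns the
    ClassDendrogram (its first_split shows the top-level class grouping)."""
    labeled = table[table["label"].notna()]
    feats = [c for c in table.columns if c not in META_COLS]
    return manova_dendrogram(labeled[feats], labeled["label"])


def split_separates_apneas(dend) -> bool:
    groups = [set(g) for g in dend.first_split()]
    return {"NORMAL", "HYP"} in groups and {"OSA", "CSA", "MSA"} in groups
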