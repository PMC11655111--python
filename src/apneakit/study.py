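"""Top-level modelling interface: a CaseStudy fitted to a feature table.

Follows the model/results idiom: build a :class:`CaseStudy` from an epoch
feature table (or directly from recordings), call :meth:`CaseStudy.fit`,
and read estimates off the returned :class:`CaseStudyResults` — per-family
metric means and SDs, the selected best family, and a ``summary()`` table.

Each fit repeat re-draws the case's class balancing (a fresh rng substream)
so the reported SDs reflect balancing variability; the subject-wise 70/30
split is fixed per study.  A ``shuffle_labels`` switch permutes epoch labels
before everything else, giving the chance-level null used to calibrate the
pipeline against information leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import cases as _cases
from . import modeling as _modeling
from .features import extract_table, impute_with_train_median, registry_names
from .modeling import FAMILIES, MetricsReport, ModelSpec
from .preprocessing import epochs_from_recording
from .synthetic import Recording


def build_feature_table(
    recordings: Iterable[Recording], registry_id: str = "b32"
) -> pd.DataFrame:
    """Segment, exclude, label and featurize every recording into one table."""
    parts = []
    for rec in recordings:
        parts.append(extract_table(epochs_from_recording(rec), registry_id))
    if not parts:
        raise ValueError("no recordings supplied")
    return pd.concat(parts, ignore_index=True)


class CaseStudy:
    """One dichotomous classification case over an epoch feature table.

    Parameters
    ----------
    feature_table:
        Output of :func:`build_feature_table` (columns: subject_id,
        epoch_index, label, then the registry features).
    case_id:
        "i" (apnea vs normal/hypopnea), "ii" (apnea vs normal) or
        "iii" (OSA/MSA vs CSA).
    families:
        Model families to tune and compare (default: all five).
    fraction:
        Subject fraction assigned to training (default 0.7).
    cap:
        Distinction-balancing cap: largest class at most ``cap`` x MSA count.
    """

    def __init__(
        self,
        feature_table: pd.DataFrame,
        case_id: str = "i",
        registry_id: str | None = None,
        families: Sequence[str] = FAMILIES,
        fraction: float = 0.7,
        cap: float = 5.0,
        seed: int = 0,
        svm_kernel: str | None = None,
    ):
        self.config = _cases.case_config(case_id, registry_id, seed)
        self.table = feature_table
        self.families = tuple(families)
        self.fraction = fraction
        self.cap = cap
        self.seed = seed
        self.svm_kernel = svm_kernel
        self.feature_names = [
            c for c in feature_table.columns if c not in ("subject_id", "epoch_index", "label")
        ]
        self.split = _cases.subject_split(
            feature_table["subject_id"].tolist(), fraction, seed
        )

    @classmethod
    def from_recordings(
        cls, recordings: Iterable[Recording], case_id: str = "i", **kwargs
    ) -> "CaseStudy":
        registry_id = kwargs.pop("registry_id", None) or _cases.case_config(case_id).registry_id
        table = build_feature_table(recordings, registry_id)
        return cls(table, case_id, registry_id, **kwargs)

    # ------------------------------------------------------------------

    def _prepared_rows(self, shuffle_labels: bool) -> tuple[pd.DataFrame, pd.DataFrame]:
        table = self.table
        if shuffle_labels:
            rng = np.random.default_rng([self.seed, 918273])
            table = table.copy()
            table["label"] = rng.permutation(table["label"].to_numpy())
        rows = _cases.case_rows(table, self.config)
        train_mask = rows["subject_id"].isin(self.split.train_subjects).to_numpy()
        rows, _ = impute_with_train_median(rows, train_mask, self.feature_names)
        return rows.loc[train_mask], rows.loc[~train_mask]

    def fit(
        self,
        repeats: int = 20,
        budget: int = 200,
        shuffle_labels: bool = False,
    ) -> "CaseStudyResults":
        """Tune, train and evaluate every family over ``repeats`` re-balanced
        train/test draws."""
        trs, ts = self._prepared_rows(shuffle_labels)
        for part, name in ((trs, "training"), (ts, "test")):
            if part["y"].nunique() < 2:
                raise ValueError(f"{name} split does not contain both classes")
        reports: dict[str, MetricsReport] = {}
        tuned_params: dict[str, dict] = {}
        for family in self.families:
            recs = []
            for r in range(repeats):
                rng = np.random.default_rng([self.seed, 101, r])
                btr = _cases.balance_case(trs, self.config, rng, cap=self.cap)
                bts = _cases.balance_case(ts, self.config, rng, cap=self.cap)
                spec = ModelSpec(
                    family,
                    budget=budget,
                    seed=int((self.seed * 1009 + r) % 2**31),
                    kernel=self.svm_kernel if family == "svm" else None,
                )
                model = _modeling.tune_and_train(
                    spec,
                    btr[self.feature_names].to_numpy(float),
                    btr["y"].to_numpy(),
                    groups=btr["subject_id"].to_numpy(),
                )
                pred = model.estimator.predict(bts[self.feature_names].to_numpy(float))
                tp, fn, tn, fp = _modeling.confusion_counts(bts["y"].to_numpy(), pred)
                rec = _modeling.compute_metrics(tp, fn, tn, fp)
                rec.update({"tp": tp, "fn": fn, "tn": tn, "fp": fp})
                recs.append(rec)
                tuned_params[family] = model.params
            reports[family] = MetricsReport(family, pd.DataFrame(recs))
        return CaseStudyResults(self, reports, tuned_params, shuffled=shuffle_labels)


@dataclass
class CaseStudyResults:
    """Per-family evaluation metrics for one fitted case study."""

    study: CaseStudy
    reports: dict[str, MetricsReport]
    tuned_params: dict[str, dict]
    shuffled: bool = False

    @property
    def best_family(self) -> str:
        return _modeling.select_best_family(self.reports)

    @property
    def metrics(self) -> pd.DataFrame:
        """One row per family: mean and SD of each metric."""
        df = pd.DataFrame([r.as_row() for r in self.reports.values()])
        return df.set_index("family")

    def report(self, family: str | None = None) -> MetricsReport:
        return self.reports[family or self.best_family]

    def summary(self) -> str:
        cfg = self.study.config
        lines = [
            "Apnea case-study results".center(79),
            "=" * 79,
            f"Case:            {cfg.case_id}  "
            f"({'/'.join(cfg.positive_classes)} vs {'/'.join(cfg.negative_classes)})",
            f"Feature registry: {cfg.registry_id}  "
            f"({len(self.study.feature_names)} features)",
            f"Subjects:        {len(self.study.split.train_subjects)} train / "
            f"{len(self.study.split.test_subjects)} test (subject-wise split)",
            f"Repeats:         {len(next(iter(self.reports.values())).per_repeat)}"
            + ("   [labels shuffled: null calibration]" if self.shuffled else ""),
            "-" * 79,
            f"{'family':<14}" + "".join(f"{m.upper():>13}" for m in _modeling.METRIC_NAMES),
            "-" * 79,
        ]
        for family, rep in self.reports.items():
            cells = "".join(
                f"{rep.mean[m]:.3f}±{rep.std[m]:.3f}".rjust(13)
                for m in _modeling.METRIC_NAMES
            )
            marker = " *" if family == self.best_family else ""
            lines.append(f"{family:<14}{cells}{marker}")
        lines += ["-" * 79, "* best accuracy/balance tradeoff", "=" * 79]
        return "\n".join(lines)
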