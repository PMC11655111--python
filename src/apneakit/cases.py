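"""The three dichotomous case studies, subject-wise splitting and balancing.

* case i   — apnea (OSA, CSA, MSA) vs normal/hypopnea;
* case ii  — apnea vs normal, hypopnea epochs dropped;
* case iii — obstructive-onset apnea (OSA, MSA) vs central apnea (CSA),
  normal and hypopnea epochs dropped.

Splitting randomizes on *subjects* (70/30 by default) so no subject
contributes epochs to both sets.  Balancing follows the case-specific rules:
detection cases keep all apnea epochs and subsample negatives to the same
count; the distinction case keeps all MSA epochs (the rarest class) and
subsamples OSA and CSA preserving their proportions relative to MSA, capped
so the largest class is at most ``cap`` times the MSA count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocessing import LABELS

logger = logging.getLogger(__name__)

APNEA = ("OSA", "CSA", "MSA")


@dataclass(frozen=True)
class CaseConfig:
    case_id: str
    positive_classes: tuple[str, ...]
    negative_classes: tuple[str, ...]
    registry_id: str
    seed: int = 0


def case_config(case_id: str, registry_id: str | None = None, seed: int = 0) -> CaseConfig:
    """Canonical configuration of case i, ii or iii."""
    if case_id == "i":
        return CaseConfig("i", APNEA, ("NORMAL", "HYP"), registry_id or "b32", seed)
    if case_id == "ii":
        return CaseConfig("ii", APNEA, ("NORMAL",), registry_id or "b32", seed)
    if case_id == "iii":
        return CaseConfig("iii", ("OSA", "MSA"), ("CSA",), registry_id or "iii44", seed)
    raise ValueError(f"unknown case {case_id!r}")


@dataclass(frozen=True)
class SplitPlan:
    train_subjects: tuple[str, ...]
    test_subjects: tuple[str, ...]
    fraction: float = 0.7


def subject_split(
    subject_ids: Sequence[str], fraction: float = 0.7, seed: int = 0
) -> SplitPlan:
    """Disjoint subject-level train/test split: round(fraction * n) subjects
    go to training; deterministic under the seed."""
    subjects = sorted(set(subject_ids))
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects for a subject-wise split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(subjects))
    n_train = int(round(fraction * len(subjects)))
    n_train = min(max(n_train, 1), len(subjects) - 1)
    train = tuple(sorted(subjects[i] for i in perm[:n_train]))
    test = tuple(sorted(subjects[i] for i in perm[n_train:]))
    return SplitPlan(train, test, fraction)


def case_rows(table: pd.DataFrame, config: CaseConfig) -> pd.DataFrame:
    """Rows relevant to the case, with a binary ``y`` column (1 = positive).
    Labels outside the case's classes (e.g. HYP in case ii) are dropped."""
    keep = table["label"].isin(config.positive_classes + config.negative_classes)
    out = table.loc[keep].copy()
    out["y"] = out["label"].isin(config.positive_classes).astype(int)
    return out


def balance_detection(
    table: pd.DataFrame, config: CaseConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Keep every positive (apnea) epoch; subsample negatives without
    replacement to the same count.  If negatives are the rarer side, the
    roles flip (all negatives kept, positives subsampled), with a log note.
    """
    pos = table.index[table["y"] == 1].to_numpy()
    neg = table.index[table["y"] == 0].to_numpy()
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present before balancing")
    if len(neg) >= len(pos):
        keep_neg = rng.choice(neg, size=len(pos), replace=False)
        idx = np.concatenate([pos, keep_neg])
    else:
        logger.info(
            "fewer negatives (%d) than positives (%d): subsampling positives",
            len(neg), len(pos),
        )
        keep_pos = rng.choice(pos, size=len(neg), replace=False)
        idx = np.concatenate([keep_pos, neg])
    return table.loc[np.sort(idx)]


def balance_distinction(
    table: pd.DataFrame, rng: np.random.Generator, cap: float = 5.0
) -> pd.DataFrame:
    """Keep all MSA epochs; subsample OSA and CSA so their counts keep the
    full-table ratios to MSA, rescaled so the largest class is at most
    ``cap`` times the MSA count."""
    counts = table["label"].value_counts()
    for c in ("MSA", "OSA", "CSA"):
        if counts.get(c, 0) == 0:
            raise ValueError(f"class {c} absent; cannot balance the distinction case")
    n_msa = int(counts["MSA"])
    ratios = {c: counts[c] / n_msa for c in ("OSA", "CSA")}
    scale = min(1.0, cap / max(ratios.values())) if max(ratios.values()) > 0 else 1.0
    parts = [table.index[table["label"] == "MSA"].to_numpy()]
    for c in ("OSA", "CSA"):
        target = int(round(n_msa * ratios[c] * scale))
        target = min(max(target, 1), int(counts[c]))
        idx = table.index[table["label"] == c].to_numpy()
        parts.append(rng.choice(idx, size=target, replace=False))
    return table.loc[np.sort(np.concatenate(parts))]


def balance_case(
    table: pd.DataFrame, config: CaseConfig, rng: np.random.Generator, cap: float = 5.0
) -> pd.DataFrame:
    """Dispatch to the case's balancing rule (applied per split)."""
    if config.case_id in ("i", "ii"):
        return balance_detection(table, config, rng)
    return balance_distinction(table, rng, cap=cap)
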