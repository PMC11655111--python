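"""Segmentation of a recording into labeled, quality-filtered 30-s epochs.

The scoring grid follows the AASM convention: non-overlapping 30-second
windows anchored at recording start.  Epochs overlapping sensor detachments
or flagged as wake in the hypnogram are excluded; each retained epoch gets a
single class label (NORMAL, HYP, OSA, CSA, MSA) from the scored event with
the largest temporal overlap, subject to a 5-s minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic import FS, EventSpec, Recording

EPOCH_S = 30
EPOCH_SAMPLES = EPOCH_S * FS

LABELS = ("NORMAL", "HYP", "OSA", "CSA", "MSA")
#: tie-break severity, most severe first
SEVERITY_ORDER = ("CSA", "MSA", "OSA", "HYP")
MIN_LABEL_OVERLAP_S = 5.0
MIN_DETACH_OVERLAP_S = 1.0


@dataclass
class Epoch:
    """One 30-s scoring window of all channels."""

    subject_id: str
    index: int
    start_s: float
    channels: dict[str, np.ndarray]  # 3000 samples each
    label: str | None = None
    excluded: bool = False
    exclusion_reason: str = "none"

    @property
    def end_s(self) -> float:
        return self.start_s + EPOCH_S


def segment_epochs(recording: Recording) -> list[Epoch]:
    """Cut the recording into floor(n/3000) contiguous epochs; the trailing
    partial window is dropped."""
    lengths = {name: len(x) for name, x in recording.channels.items()}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"channels have mismatched lengths: {lengths}")
    n_epochs = recording.n_samples // EPOCH_SAMPLES
    epochs = []
    for k in range(n_epochs):
        sl = slice(k * EPOCH_SAMPLES, (k + 1) * EPOCH_SAMPLES)
        epochs.append(
            Epoch(
                subject_id=recording.subject_id,
                index=k,
                start_s=k * float(EPOCH_S),
                channels={name: x[sl] for name, x in recording.channels.items()},
            )
        )
    return epochs


def exclude_epochs(
    epochs: Sequence[Epoch],
    hypnogram: np.ndarray,
    detachment_intervals: Sequence[tuple[float, float]],
) -> list[Epoch]:
    """Mark wake epochs and epochs overlapping a detachment by >= 1 s.

    Wake takes precedence in the recorded reason when both apply.
    """
    out = []
    for ep in epochs:
        excluded, reason = False, "none"
        if ep.index < len(hypnogram) and hypnogram[ep.index]:
            excluded, reason = True, "wake"
        else:
            for a, b in detachment_intervals:
                if min(ep.end_s, b) - max(ep.start_s, a) >= MIN_DETACH_OVERLAP_S:
                    excluded, reason = True, "detachment"
                    break
        ep.excluded = excluded
        ep.exclusion_reason = reason
        if excluded:
            ep.label = None
        out.append(ep)
    return out


def label_epochs(epochs: Sequence[Epoch], events: Sequence[EventSpec]) -> list[Epoch]:
    """Assign each retained epoch the class of the maximally overlapping event.

    An event must overlap the window by at least 5 s (half the minimum
    clinical event duration) to claim it; otherwise the epoch is NORMAL.
    Exact-overlap ties go to the more severe class (CSA > MSA > OSA > HYP).
    """
    sev_rank = {c: i for i, c in enumerate(SEVERITY_ORDER)}
    for ep in epochs:
        if ep.excluded:
            ep.label = None
            continue
        best: tuple[float, int] | None = None  # (overlap, -severity_rank)
        best_class = None
        for ev in events:
            ov = min(ep.end_s, ev.end) - max(ep.start_s, ev.onset)
            if ov < MIN_LABEL_OVERLAP_S:
                continue
            key = (ov, -sev_rank[ev.event_class])
            if best is None or key > best:
                best, best_class = key, ev.event_class
        ep.label = best_class if best_class is not None else "NORMAL"
    return list(epochs)


def epochs_from_recording(recording: Recording) -> list[Epoch]:
    """Full segmentation pipeline: cut, exclude, label."""
    eps = segment_epochs(recording)
    eps = exclude_epochs(eps, recording.hypnogram, recording.detachment_intervals)
    return label_epochs(eps, recording.events)


def epoch_index_table(epochs: Sequence[Epoch]) -> pd.DataFrame:
    """Tabular epoch index (one row per epoch, excluded ones included)."""
    return pd.DataFrame(
        {
            "subject_id": [e.subject_id for e in epochs],
            "epoch_index": [e.index for e in epochs],
            "start_s": [e.start_s for e in epochs],
            "label": [e.label if e.label is not None else "" for e in epochs],
            "excluded": [e.excluded for e in epochs],
            "reason": [e.exclusion_reason for e in epochs],
        }
    )
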