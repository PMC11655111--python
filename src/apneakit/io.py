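"""Reading and writing recordings, annotations and feature tables.

Recordings are exchanged as EDF+ (one annotation channel carrying events,
wake epochs and detachments) plus a companion CSV annotation file.  The
EDF+ writer here is deliberately small — continuous EDF+C, 1-s data
records, 16-bit samples — and is round-trip-verified against mne's EDF
reader in the test suite.  Feature tables are written as CSV with a sidecar
JSON schema naming the registry and feature order (Parquet too when a
parquet engine is importable).
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic import CHANNEL_RANGES, FS, EventSpec, Recording

_EDF_UNITS = {
    "thoracic": "au",
    "spo2": "%",
    "audio": "au",
    "eog_l": "uV",
    "eog_r": "uV",
    "ecg": "mV",
    "position": "",
}


def _pad(s: str, n: int) -> bytes:
    b = s.encode("ascii", errors="replace")[:n]
    return b + b" " * (n - len(b))


def write_edf(recording: Recording, path: str | Path) -> Path:
    """Write a Recording as continuous EDF+ (EDF+C) with an annotation
    channel holding events, wake epochs and detachment intervals."""
    path = Path(path)
    rec_dur = 1.0  # s per data record
    spr = int(FS * rec_dur)  # samples per record per signal
    n_records = int(recording.n_samples // (FS * rec_dur))
    names = list(recording.channels)
    ns = len(names) + 1  # + EDF Annotations

    # ---- annotation TALs, bucketed into the record containing their onset
    def tal(onset: float, duration: float | None, text: str) -> bytes:
        s = f"+{onset:g}"
        if duration is not None:
            s += f"\x15{duration:g}"
        return s.encode("ascii") + b"\x14" + text.encode("ascii") + b"\x14\x00"

    buckets: dict[int, list[bytes]] = {}
    for ev in recording.events:
        buckets.setdefault(int(ev.onset // rec_dur), []).append(
            tal(ev.onset, ev.duration, ev.event_class)
        )
    for k, wake in enumerate(recording.hypnogram):
        if wake:
            buckets.setdefault(int(k * 30 // rec_dur), []).append(tal(k * 30.0, 30.0, "wake"))
    for a, b in recording.detachment_intervals:
        buckets.setdefault(int(a // rec_dur), []).append(tal(a, b - a, "detachment"))

    ann_bytes_per_rec = 2 * max(
        40, max((sum(len(t) for t in v) for v in buckets.values()), default=0) // 2 + 16
    )
    ann_spr = ann_bytes_per_rec // 2

    # ---- header
    now = _dt.datetime(2000, 1, 1, 0, 0, 0)
    header = b"".join(
        [
            _pad("0", 8),
            _pad(f"X X X {recording.subject_id}", 80),
            _pad(f"Startdate 01-JAN-2000 X X X", 80),
            _pad(now.strftime("%d.%m.%y"), 8),
            _pad(now.strftime("%H.%M.%S"), 8),
            _pad(str(256 * (ns + 1)), 8),
            _pad("EDF+C", 44),
            _pad(str(n_records), 8),
            _pad(f"{rec_dur:g}", 8),
            _pad(str(ns), 4),
        ]
    )
    labels = [f"{n}"[:16] for n in names] + ["EDF Annotations"]
    phys_lo = [CHANNEL_RANGES[n][0] for n in names] + [-1.0]
    phys_hi = [CHANNEL_RANGES[n][1] for n in names] + [1.0]
    sig_hdr = b"".join(
        [
            b"".join(_pad(l, 16) for l in labels),
            b"".join(_pad("", 80) for _ in range(ns)),
            b"".join(_pad(_EDF_UNITS.get(n, ""), 8) for n in names) + _pad("", 8),
            b"".join(_pad(f"{v:g}", 8) for v in phys_lo),
            b"".join(_pad(f"{v:g}", 8) for v in phys_hi),
            b"".join(_pad("-32768", 8) for _ in range(ns)),
            b"".join(_pad("32767", 8) for _ in range(ns)),
            b"".join(_pad("BP 0.05-30 Hz" if n not in ("spo2", "position") else "", 80) for n in names)
            + _pad("", 80),
            b"".join(_pad(str(spr), 8) for _ in range(ns - 1)) + _pad(str(ann_spr), 8),
            b"".join(_pad("", 32) for _ in range(ns)),
        ]
    )

    # ---- digital signals (exact on the generator's 16-bit grid)
    digital = {}
    for n_ in names:
        lo, hi = CHANNEL_RANGES[n_]
        scale = (hi - lo) / (2**16 - 1)
        d = np.round((recording.channels[n_] - lo) / scale).astype(np.int64) - 32768
        digital[n_] = np.clip(d, -32768, 32767).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_hdr)
        for r in range(n_records):
            sl = slice(r * spr, (r + 1) * spr)
            for n_ in names:
                fh.write(digital[n_][sl].tobytes())
            ann = tal(r * rec_dur, None, "")  # timekeeping TAL
            ann += b"".join(buckets.get(r, []))
            ann = ann[:ann_bytes_per_rec]
            fh.write(ann + b"\x00" * (ann_bytes_per_rec - len(ann)))
    return path


def write_annotations_csv(recording: Recording, path: str | Path) -> Path:
    """Companion CSV annotation file: one row per scored event."""
    path = Path(path)
    pd.DataFrame(
        {
            "subject_id": [recording.subject_id] * len(recording.events),
            "class": [ev.event_class for ev in recording.events],
            "onset_s": [ev.onset for ev in recording.events],
            "duration_s": [ev.duration for ev in recording.events],
        }
    ).to_csv(path, index=False)
    return path


def read_annotations_csv(path: str | Path) -> list[EventSpec]:
    df = pd.read_csv(path)
    return [
        EventSpec(str(row["class"]), float(row["onset_s"]), float(row["duration_s"]))
        for _, row in df.iterrows()
    ]


def write_feature_table(
    table: pd.DataFrame, path: str | Path, registry_id: str
) -> Path:
    """Write a feature table as CSV plus a sidecar JSON schema; a Parquet
    copy is written alongside when a parquet engine is available."""
    path = Path(path)
    table.to_csv(path, index=False)
    feature_order = [
        c for c in table.columns if c not in ("subject_id", "epoch_index", "label")
    ]
    schema = {"registry_id": registry_id, "feature_order": feature_order}
    path.with_suffix(".schema.json").write_text(json.dumps(schema, indent=1))
    try:
        table.to_parquet(path.with_suffix(".parquet"))
    except (ImportError, ValueError):
        pass
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
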