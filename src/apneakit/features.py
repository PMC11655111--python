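"""Per-epoch feature bank for apnea detection and distinction.

Implements the named per-epoch features over the low-invasiveness channel
set, organized as registries so the 32-feature detection subset and the
44-feature distinction subset are constructible by name:

* time-domain statistics and peak morphology of the thoracic effort signal;
* Welch-spectrum statistics (mean/median/peak frequency, band power) and
  order-2 Renyi spectral entropy;
* SpO2 oximetry statistics, the 12-s delta index, hypoxic burden (TSA95,
  fraction of the epoch below 95% saturation) and approximate entropy
  ApEn(m=2, r = 0.15 or 0.25 of SD) on the 1-Hz saturation series;
* instantaneous spectral entropy (ISE) of the audio channel;
* EOG delta- and beta-rhythm band powers;
* ECG discrete-wavelet detail statistics (db4, 5 levels) and RR-interval
  statistics from a derivative-energy beat detector;
* the body-position code.

All features are computed from a single 30-s epoch at 100 Hz, except ApEn,
which by design uses a sliding context of the current plus three previous
epochs of the 1-Hz SpO2 series (30 samples alone under-determine ApEn(m=2)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps
from scipy import stats as spstats

from .preprocessing import Epoch
from .synthetic import FS

RESPIRATION_BAND = (0.05, 1.0)  # Hz, thoracic spectral band
DELTA_BAND = (0.5, 4.0)
BETA_BAND = (13.0, 30.0)
WELCH_SEGMENT_S = 4.0
DWT_WAVELET = "db4"
DWT_MODE = "periodization"
DWT_LEVELS = 5


# ---------------------------------------------------------------------------
# elementary operations


def time_stats(x: np.ndarray) -> dict[str, float]:
    """Sample statistics of a series; AUC is the trapezoidal integral of |x|
    over the epoch in signal-units * s."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    sd = x.std(ddof=1) if x.size > 1 else 0.0
    skew = float(spstats.skew(x)) if sd > 0 else 0.0
    return {
        "mean": float(x.mean()),
        "std": float(sd),
        "median": float(np.median(x)),
        "iqr": float(np.percentile(x, 75) - np.percentile(x, 25)),
        "skewness": skew,
        "auc": float(np.trapezoid(np.abs(x), dx=1.0 / FS)),
    }


def peak_stats(x: np.ndarray, fs: float = FS) -> dict[str, float]:
    """Peak morphology: local maxima with prominence >= 10% of the epoch
    range and >= 1 s separation.  Peak height (PH) is measured from the
    epoch median; inter-peak distances (IPD) are in seconds."""
    x = np.asarray(x, dtype=float)
    rng_ = float(x.max() - x.min()) if x.size else 0.0
    if rng_ == 0.0:
        peaks = np.array([], dtype=int)
    else:
        peaks, _ = sps.find_peaks(x, prominence=0.1 * rng_, distance=int(fs))
    med = float(np.median(x)) if x.size else 0.0
    ph = x[peaks] - med
    out = {
        "n_peaks": float(len(peaks)),
        "min_ph": float(ph.min()) if len(peaks) else 0.0,
        "mean_ph": float(ph.mean()) if len(peaks) else 0.0,
        "std_ph": float(ph.std(ddof=1)) if len(peaks) > 1 else 0.0,
        "sum_ph": float(ph.sum()) if len(peaks) else 0.0,
    }
    if len(peaks) >= 2:
        ipd = np.diff(peaks) / fs
        out["mean_ipd"] = float(ipd.mean())
        sd = ipd.std(ddof=1) if len(ipd) > 1 else 0.0
        out["skew_ipd"] = float(spstats.skew(ipd)) if sd > 0 else 0.0
        out["ipd_flagged"] = 0.0
    else:
        out.update({"mean_ipd": 0.0, "skew_ipd": 0.0, "ipd_flagged": 1.0})
    return out


def welch_psd(x: np.ndarray, fs: float = FS) -> tuple[np.ndarray, np.ndarray]:
    """Welch periodogram: 4-s Hann segments, 50% overlap, density scaling."""
    nperseg = min(int(WELCH_SEGMENT_S * fs), len(x))
    return sps.welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2)


def spectral_stats(
    x: np.ndarray,
    fs: float = FS,
    band: tuple[float, float] = (0.0, 50.0),
    psd: tuple[np.ndarray, np.ndarray] | None = None,
) -> dict[str, float]:
    """Spectral summary over ``band``: PSD-weighted mean frequency, the
    frequency splitting band power in half, the argmax frequency, and the
    integrated band power (signal-units^2)."""
    f, p = welch_psd(x, fs) if psd is None else psd
    m = (f >= band[0]) & (f <= band[1])
    f, p = f[m], p[m]
    if len(f) == 0 or p.sum() <= 0:
        return {"mean_freq": 0.0, "median_freq": 0.0, "peak_freq": 0.0, "band_power": 0.0}
    df = f[1] - f[0] if len(f) > 1 else 1.0
    power = float(np.sum(p) * df)
    cum = np.cumsum(p)
    median_freq = float(f[np.searchsorted(cum, cum[-1] / 2.0)])
    return {
        "mean_freq": float(np.sum(f * p) / np.sum(p)),
        "median_freq": median_freq,
        "peak_freq": float(f[int(np.argmax(p))]),
        "band_power": power,
    }


def band_power(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    return spectral_stats(x, fs, band)["band_power"]


def renyi_entropy(
    x: np.ndarray,
    order: int = 2,
    fs: float = FS,
    psd: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """Order-2 Renyi entropy -log sum(p_i^2) of the normalized Welch PSD
    treated as a distribution over frequency bins (natural log)."""
    if order != 2:
        raise NotImplementedError("only order 2 is used")
    _, p = welch_psd(x, fs) if psd is None else psd
    total = p.sum()
    if total <= 0:
        return 0.0
    q = p / total
    return float(-np.log(np.sum(q**2)))


def approximate_entropy(x: np.ndarray, m: int = 2, r_frac: float = 0.25) -> float:
    """ApEn(m, r) with self-matches included (Pincus convention),
    r = r_frac * SD(x), Chebyshev distance."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    sd = x.std()
    if sd == 0.0 or n < m + 2:
        return 0.0
    r = r_frac * sd

    def phi(mm: int) -> float:
        nwin = n - mm + 1
        # embedding matrix, Chebyshev distances, self-matches included
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)
        d = np.max(np.abs(emb[:, None, :] - emb[None, :, :]), axis=2)
        c = (d <= r).sum(axis=1) / nwin
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def spo2_features(x: np.ndarray) -> dict[str, float]:
    """Oximetry statistics in % saturation.

    delta_index: mean absolute difference between consecutive 12-s window
    means; tsa95: fraction of the epoch spent below 95% saturation;
    m2: second central moment.
    """
    x = np.asarray(x, dtype=float)
    win = int(12 * FS)
    n_win = len(x) // win
    if n_win >= 2:
        means = x[: n_win * win].reshape(n_win, win).mean(axis=1)
        delta_index = float(np.mean(np.abs(np.diff(means))))
    else:
        delta_index = 0.0
    return {
        "std": float(x.std(ddof=1)) if len(x) > 1 else 0.0,
        "range": float(x.max() - x.min()),
        "min": float(x.min()),
        "p95": float(np.percentile(x, 95)),
        "p5": float(np.percentile(x, 5)),
        "m2": float(np.mean((x - x.mean()) ** 2)),
        "delta_index": delta_index,
        "tsa95": float(np.mean(x < 95.0)),
    }


def instantaneous_spectral_entropy(x: np.ndarray, fs: float = FS) -> np.ndarray:
    """Shannon entropy of each 1-s spectrogram column's normalized PSD
    (natural log); silent columns get entropy 0 by convention."""
    nperseg = int(fs)
    f, t, S = sps.spectrogram(x, fs=fs, window="hann", nperseg=nperseg, noverlap=0)
    totals = S.sum(axis=0)
    ise = np.zeros(S.shape[1])
    ok = totals > 0
    P = S[:, ok] / totals[ok]
    with np.errstate(divide="ignore", invalid="ignore"):
        ise[ok] = -np.sum(np.where(P > 0, P * np.log(P), 0.0), axis=0)
    return ise


def ise_features(audio: np.ndarray, fs: float = FS) -> dict[str, float]:
    """ISE range over the epoch and the fraction of 1-s columns with ISE
    outside mean +/- 2*SD of the epoch's own ISE series."""
    ise = instantaneous_spectral_entropy(audio, fs)
    if len(ise) == 0:
        return {"ise_range": 0.0, "time_outside": 0.0}
    mu, sd = ise.mean(), ise.std()
    outside = np.abs(ise - mu) > 2 * sd if sd > 0 else np.zeros(len(ise), dtype=bool)
    return {"ise_range": float(ise.max() - ise.min()), "time_outside": float(outside.mean())}


def eog_rhythm_power(eog_l: np.ndarray, eog_r: np.ndarray, fs: float = FS) -> dict[str, float]:
    """Delta-rhythm power of both EOGs and beta-rhythm power of the right EOG."""
    return {
        "delta_l": band_power(eog_l, fs, DELTA_BAND),
        "delta_r": band_power(eog_r, fs, DELTA_BAND),
        "beta_r": band_power(eog_r, fs, BETA_BAND),
    }


def dwt_details(x: np.ndarray) -> list[np.ndarray]:
    """Detail coefficients d1..d5 of the 5-level db4 decomposition
    (periodization boundary)."""
    coeffs = pywt.wavedec(np.asarray(x, dtype=float), DWT_WAVELET, mode=DWT_MODE, level=DWT_LEVELS)
    # wavedec returns [a5, d5, d4, d3, d2, d1]
    return [coeffs[-1], coeffs[-2], coeffs[-3], coeffs[-4], coeffs[-5]]


def ecg_dwt_features(ecg: np.ndarray, fs: float = FS) -> dict[str, float]:
    """16 ECG wavelet statistics: IQR of d3-d5, variance of d1-d3, SD and
    MAD (mean absolute deviation from the median) of d1-d5."""
    d = dwt_details(ecg)  # d[0] = d1 ... d[4] = d5
    out: dict[str, float] = {}
    for lvl in (3, 4, 5):
        c = d[lvl - 1]
        out[f"dwt_iqr_d{lvl}"] = float(np.percentile(c, 75) - np.percentile(c, 25))
    for lvl in (1, 2, 3):
        out[f"dwt_var_d{lvl}"] = float(np.var(d[lvl - 1], ddof=1))
    for lvl in range(1, 6):
        c = d[lvl - 1]
        out[f"dwt_std_d{lvl}"] = float(np.std(c, ddof=1))
        out[f"dwt_mad_d{lvl}"] = float(np.mean(np.abs(c - np.median(c))))
    return out


def audio_dwt_energy(audio: np.ndarray) -> dict[str, float]:
    """Energy (sum of squared coefficients) in the 3rd and 4th detail levels."""
    d = dwt_details(audio)
    return {
        "dwt_energy_d3": float(np.sum(d[2] ** 2)),
        "dwt_energy_d4": float(np.sum(d[3] ** 2)),
    }


def detect_beats(ecg: np.ndarray, fs: float = FS) -> np.ndarray:
    """QRS sample indices by derivative-energy thresholding with a 250-ms
    refractory period."""
    energy = np.gradient(np.asarray(ecg, dtype=float)) ** 2
    kernel = np.ones(int(0.1 * fs)) / (0.1 * fs)
    smooth = np.convolve(energy, kernel, mode="same")
    if smooth.max() <= 0:
        return np.array([], dtype=int)
    peaks, _ = sps.find_peaks(
        smooth, height=0.2 * smooth.max(), distance=int(0.25 * fs)
    )
    return peaks


def rr_features(ecg: np.ndarray, fs: float = FS) -> dict[str, float]:
    """Mean and median RR interval (s); flagged NaN when < 2 beats are found
    (imputed downstream with the training-split median)."""
    beats = detect_beats(ecg, fs)
    if len(beats) < 2:
        return {"mean_rr": float("nan"), "median_rr": float("nan")}
    rr = np.diff(beats) / fs
    return {"mean_rr": float(rr.mean()), "median_rr": float(np.median(rr))}


def position_code(position: np.ndarray) -> float:
    """Majority (modal) integer position code of the epoch."""
    codes = np.round(np.asarray(position, dtype=float)).astype(int)
    vals, counts = np.unique(codes, return_counts=True)
    return float(vals[int(np.argmax(counts))])


# ---------------------------------------------------------------------------
# registries


@dataclass(frozen=True)
class FeatureDef:
    name: str
    signal: str
    category: str  # time | frequency | complexity | hypoxic_burden | rr | position


def _defs(signal: str, category: str, names: Sequence[str]) -> list[FeatureDef]:
    return [FeatureDef(n, signal, category) for n in names]


_THOR_TIME_32 = _defs(
    "thoracic",
    "time",
    [
        "thor_mean", "thor_std", "thor_median", "thor_iqr",
        "thor_n_peaks", "thor_min_ph", "thor_mean_ph", "thor_std_ph",
        "thor_sum_ph", "thor_mean_ipd", "thor_auc",
    ],
)
_THOR_FREQ_32 = _defs(
    "thoracic", "frequency",
    ["thor_mean_freq", "thor_median_freq", "thor_peak_freq", "thor_band_power"],
)
_SPO2_9_DET = _defs(
    "spo2", "time",
    ["spo2_std", "spo2_range", "spo2_min", "spo2_p95", "spo2_p5", "spo2_delta_index"],
) + _defs("spo2", "hypoxic_burden", ["spo2_tsa95"]) + _defs(
    "spo2", "complexity", ["spo2_apen_025", "spo2_apen_015"]
)

#: Detection subset: 32 features (thoracic 16, SpO2 9, audio 4, EOG 3).
DETECTION_32 = (
    _THOR_TIME_32
    + _THOR_FREQ_32
    + _defs("thoracic", "complexity", ["thor_renyi"])
    + _SPO2_9_DET
    + _defs("audio", "time", ["audio_mean", "audio_median"])
    + _defs("audio", "frequency", ["audio_ise_range", "audio_ise_time_outside"])
    + _defs("eog", "frequency", ["eog_delta_l", "eog_delta_r", "eog_beta_r"])
)

_ECG_18 = _defs(
    "ecg", "frequency",
    [f"ecg_dwt_iqr_d{l}" for l in (3, 4, 5)]
    + [f"ecg_dwt_var_d{l}" for l in (1, 2, 3)]
    + [f"ecg_dwt_std_d{l}" for l in range(1, 6)]
    + [f"ecg_dwt_mad_d{l}" for l in range(1, 6)],
) + _defs("ecg", "rr", ["ecg_mean_rr", "ecg_median_rr"])

_SPO2_9_DIS = _defs(
    "spo2", "time",
    ["spo2_std", "spo2_range", "spo2_min", "spo2_m2", "spo2_p5", "spo2_delta_index"],
) + _defs("spo2", "hypoxic_burden", ["spo2_tsa95"]) + _defs(
    "spo2", "complexity", ["spo2_apen_025", "spo2_apen_015"]
)

#: Distinction subset: 44 features (ECG 18, thoracic 12, SpO2 9, audio 4,
#: position 1).
DISTINCTION_44 = (
    _ECG_18
    + _defs(
        "thoracic", "time",
        [
            "thor_std", "thor_iqr", "thor_n_peaks", "thor_min_ph", "thor_mean_ph",
            "thor_std_ph", "thor_sum_ph", "thor_mean_ipd", "thor_skew_ipd", "thor_auc",
        ],
    )
    + _defs("thoracic", "frequency", ["thor_mean_freq", "thor_band_power"])
    + _SPO2_9_DIS
    + _defs("audio", "frequency", ["audio_dwt_energy_d3", "audio_dwt_energy_d4"])
    + _defs("audio", "complexity", ["audio_ise_range", "audio_renyi"])
    + _defs("position", "position", ["position_code"])
)


def _full_bank() -> list[FeatureDef]:
    seen: dict[str, FeatureDef] = {}
    for fd in DETECTION_32 + DISTINCTION_44 + _defs(
        "thoracic", "time", ["thor_skewness"]
    ) + _defs("audio", "time", ["audio_std"]):
        seen.setdefault(fd.name, fd)
    return list(seen.values())


FULL_BANK = _full_bank()

REGISTRIES: Mapping[str, list[FeatureDef]] = {
    "b32": DETECTION_32,
    "iii44": DISTINCTION_44,
    "full": FULL_BANK,
}


def registry(registry_id: str) -> list[FeatureDef]:
    try:
        return REGISTRIES[registry_id]
    except KeyError:
        raise KeyError(f"unknown registry {registry_id!r}; choose from {sorted(REGISTRIES)}")


def registry_names(registry_id: str) -> list[str]:
    return [fd.name for fd in registry(registry_id)]


# ---------------------------------------------------------------------------
# extraction


def _spo2_1hz(x: np.ndarray) -> np.ndarray:
    """Second-by-second means: the 1-Hz saturation series of an epoch."""
    n = len(x) // FS
    return x[: n * FS].reshape(n, FS).mean(axis=1)


class _EpochFeatureComputer:
    """Computes any registry feature for one epoch, sharing intermediates
    (Welch PSDs, peak sets, DWT coefficients) across features of a signal."""

    def __init__(self, epoch: Epoch, spo2_context: np.ndarray | None):
        self.ch = epoch.channels
        self._cache: dict[str, object] = {}
        self.spo2_context = spo2_context

    def _channel(self, name: str, feature: str) -> np.ndarray:
        if name not in self.ch:
            raise KeyError(f"feature {feature!r} needs missing channel {name!r}")
        return self.ch[name]

    def _cached(self, key: str, fn: Callable):
        if key not in self._cache:
            self._cache[key] = fn()
        return self._cache[key]

    def value(self, fd: FeatureDef) -> float:
        name = fd.name
        if name.startswith("thor_"):
            x = self._channel("thoracic", name)
            stat = name[len("thor_"):]
            if stat in ("mean", "std", "median", "iqr", "skewness", "auc"):
                return self._cached("thor_time", lambda: time_stats(x))[stat]
            if stat in ("n_peaks", "min_ph", "mean_ph", "std_ph", "sum_ph", "mean_ipd", "skew_ipd"):
                return self._cached("thor_peaks", lambda: peak_stats(x))[stat]
            if stat in ("mean_freq", "median_freq", "peak_freq", "band_power"):
                psd = self._cached("thor_psd", lambda: welch_psd(x))
                return self._cached(
                    "thor_spec", lambda: spectral_stats(x, band=RESPIRATION_BAND, psd=psd)
                )[stat]
            if stat == "renyi":
                psd = self._cached("thor_psd", lambda: welch_psd(x))
                return renyi_entropy(x, psd=psd)
        if name.startswith("spo2_"):
            x = self._channel("spo2", name)
            stat = name[len("spo2_"):]
            if stat.startswith("apen_"):
                ctx = self.spo2_context if self.spo2_context is not None else _spo2_1hz(x)
                r_frac = 0.25 if stat == "apen_025" else 0.15
                key = f"apen_{r_frac}"
                return self._cached(key, lambda: approximate_entropy(ctx, 2, r_frac))
            return self._cached("spo2_stats", lambda: spo2_features(x))[stat]
        if name.startswith("audio_"):
            x = self._channel("audio", name)
            stat = name[len("audio_"):]
            if stat in ("mean", "median", "std"):
                return self._cached("audio_time", lambda: time_stats(x))[stat]
            if stat in ("ise_range", "ise_time_outside"):
                key = "ise_range" if stat == "ise_range" else "time_outside"
                return self._cached("audio_ise", lambda: ise_features(x))[key]
            if stat in ("dwt_energy_d3", "dwt_energy_d4"):
                return self._cached("audio_dwt", lambda: audio_dwt_energy(x))[stat]
            if stat == "renyi":
                return self._cached("audio_renyi", lambda: renyi_entropy(x))
        if name.startswith("eog_"):
            el = self._channel("eog_l", name)
            er = self._channel("eog_r", name)
            return self._cached("eog", lambda: eog_rhythm_power(el, er))[name[len("eog_"):]]
        if name.startswith("ecg_"):
            x = self._channel("ecg", name)
            stat = name[len("ecg_"):]
            if stat.startswith("dwt_"):
                return self._cached("ecg_dwt", lambda: ecg_dwt_features(x))[stat]
            return self._cached("ecg_rr", lambda: rr_features(x))[stat]
        if name == "position_code":
            return position_code(self._channel("position", name))
        raise KeyError(f"no computation rule for feature {name!r}")


def extract_features(
    epoch: Epoch,
    registry_id: str = "b32",
    spo2_context: np.ndarray | None = None,
) -> dict[str, float]:
    """Feature vector for one epoch, ordered as the registry.

    ``spo2_context`` is the 1-Hz SpO2 series of the current plus up to three
    previous epochs (used by ApEn); when omitted the epoch's own 30 1-Hz
    samples are used.
    """
    if epoch.excluded:
        raise ValueError("cannot extract features from an excluded epoch")
    comp = _EpochFeatureComputer(epoch, spo2_context)
    return {fd.name: comp.value(fd) for fd in registry(registry_id)}


APEN_CONTEXT_EPOCHS = 4  # current + 3 previous


def extract_table(
    epochs: Sequence[Epoch],
    registry_id: str = "b32",
) -> pd.DataFrame:
    """Feature table for a subject's (or cohort's) epochs.

    Excluded epochs are dropped.  The ApEn context buffer is keyed by
    subject and fed by *all* epochs in recording order, so context crosses
    excluded epochs but never subjects.
    """
    names = registry_names(registry_id)
    rows, meta = [], []
    buffers: dict[str, list[np.ndarray]] = {}
    for ep in epochs:
        buf = buffers.setdefault(ep.subject_id, [])
        if "spo2" in ep.channels:
            buf.append(_spo2_1hz(ep.channels["spo2"]))
            del buf[:-APEN_CONTEXT_EPOCHS]
        if ep.excluded:
            continue
        ctx = np.concatenate(buf) if buf else None
        rows.append(extract_features(ep, registry_id, spo2_context=ctx))
        meta.append((ep.subject_id, ep.index, ep.label))
    df = pd.DataFrame(rows, columns=names)
    df.insert(0, "subject_id", [m[0] for m in meta])
    df.insert(1, "epoch_index", [m[1] for m in meta])
    df.insert(2, "label", [m[2] for m in meta])
    return df


def impute_with_train_median(
    table: pd.DataFrame, train_mask: np.ndarray, feature_names: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replace non-finite feature values with the training-split median of
    that feature; returns (imputed table, boolean imputation mask)."""
    out = table.copy()
    mask = pd.DataFrame(False, index=table.index, columns=list(feature_names))
    for name in feature_names:
        col = out[name].to_numpy(dtype=float)
        bad = ~np.isfinite(col)
        if not bad.any():
            continue
        med = np.nanmedian(np.where(np.isfinite(col), col, np.nan)[train_mask])
        if not np.isfinite(med):
            med = 0.0
        col[bad] = med
        out[name] = col
        mask.loc[bad, name] = True
    return out, mask
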