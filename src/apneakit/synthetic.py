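"""Synthetic annotated polysomnography (PSG) generator.

Produces seeded multi-channel overnight recordings that emulate a type-I PSG
montage restricted to low-invasiveness channels: thoracic RIP-belt volume,
SpO2, audio, two EOGs, ECG and body position, all sampled at 100 Hz,
band-limited below 30 Hz and quantized on a 16-bit grid.  Apneic events
(hypopnea HYP, obstructive OSA, central CSA, mixed MSA) of 10-120 s are
planted with the physiology that distinguishes them:

* thoracic effort — absent during CSA, preserved but irregular during OSA,
  partially reduced during HYP, central-then-obstructive during MSA;
* SpO2 — a delayed desaturation proportional to the airflow reduction,
  with exponential resaturation;
* audio — respiration-gated snoring, loud around obstructive events,
  silent during central ones;
* ECG — RR intervals lengthen during an event and shorten at termination
  (cyclic variation of heart rate);
* EOG — a brief beta-band arousal burst after each event ends.

Every stochastic element is driven by independent, seed-derived streams:
per-event draws are keyed by the event's onset sample so that removing one
event leaves the rest of the night bit-identical (event locality), and each
channel has its own stream so adding a channel never perturbs another.

An ``effect_size`` knob in [0, 1] scales every event-locked physiological
response; at 0 events are annotated but physiologically invisible, which
gives a null cohort for pipeline calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

FS = 100  # Hz, fixed acquisition rate
EVENT_CLASSES = ("HYP", "OSA", "CSA", "MSA")
APNEA_CLASSES = ("OSA", "CSA", "MSA")
CHANNEL_NAMES = ("thoracic", "spo2", "audio", "eog_l", "eog_r", "ecg", "position")

#: body position integer codes
POSITION_CODES = {0: "supine", 1: "left", 2: "right", 3: "prone", 4: "upright"}

# Apnea-type shares among apneic events (CSA, OSA, MSA ~ 0.4%, 84%, 15%,
# normalized); half of all scored respiratory events are hypopneas.
_APNEA_SHARES = np.array([0.004, 0.84, 0.15]) / 0.994
DEFAULT_CLASS_MIX: Mapping[str, float] = {
    "HYP": 0.5,
    "CSA": 0.5 * _APNEA_SHARES[0],
    "OSA": 0.5 * _APNEA_SHARES[1],
    "MSA": 0.5 * _APNEA_SHARES[2],
}

# Event-duration model: truncated log-normal, median 28 s; sigma puts ~60%
# of the mass in the clinically typical 20-40 s range, truncated to 10-120 s.
_DUR_MEDIAN = 28.0
_DUR_SIGMA = 0.41
_MIN_GAP = 15.0  # s, enforced between consecutive events

# physical ranges used for 16-bit midtread quantization, per channel
CHANNEL_RANGES: Mapping[str, tuple[float, float]] = {
    "thoracic": (-6.0, 6.0),
    "spo2": (0.0, 100.0),
    "audio": (-6.0, 6.0),
    "eog_l": (-300.0, 300.0),
    "eog_r": (-300.0, 300.0),
    "ecg": (-4.0, 4.0),
    "position": (0.0, 4.0),
}


@dataclass(frozen=True)
class EventSpec:
    """One scored respiratory event."""

    event_class: str
    onset: float  # s from recording start
    duration: float  # s

    def __post_init__(self) -> None:
        if self.event_class not in EVENT_CLASSES:
            raise ValueError(f"unknown event class {self.event_class!r}")
        if not 10.0 <= self.duration <= 120.0:
            raise ValueError(
                f"event duration {self.duration:.1f} s outside the clinical 10-120 s range"
            )
        if self.onset < 0:
            raise ValueError("event onset must be non-negative")

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject physiological baseline and the root seed of their night."""

    subject_id: str
    baseline_spo2: float = 96.5  # %
    resp_rate: float = 0.25  # Hz
    heart_rate: float = 65.0  # bpm
    snore_propensity: float = 0.5  # 0..1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 94.0 <= self.baseline_spo2 <= 99.0:
            raise ValueError("baseline_spo2 must lie in [94, 99] %")
        if not 0.15 <= self.resp_rate <= 0.35:
            raise ValueError("resp_rate must lie in [0.15, 0.35] Hz")
        if not 50.0 <= self.heart_rate <= 90.0:
            raise ValueError("heart_rate must lie in [50, 90] bpm")
        if not 0.0 <= self.snore_propensity <= 1.0:
            raise ValueError("snore_propensity must lie in [0, 1]")


@dataclass
class Recording:
    """One subject's annotated multi-channel night at 100 Hz."""

    subject_id: str
    channels: dict[str, np.ndarray]
    events: list[EventSpec]
    hypnogram: np.ndarray  # bool per 30-s epoch, True = wake
    detachment_intervals: list[tuple[float, float]]
    fs: int = FS

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def validate(self) -> None:
        n = self.n_samples
        for name, x in self.channels.items():
            if len(x) != n:
                raise ValueError(f"channel {name} has length {len(x)} != {n}")
        if len(self.hypnogram) != n // (30 * self.fs):
            raise ValueError("hypnogram not aligned to the 30-s epoch grid")


# ---------------------------------------------------------------------------
# rng plumbing

# fixed stream indices so adding a channel never perturbs another
_STREAMS = {
    "schedule": 0,
    "thoracic": 1,
    "spo2": 2,
    "audio": 3,
    "eog_l": 4,
    "eog_r": 5,
    "ecg": 6,
    "position": 7,
    "hypnogram": 8,
    "detach": 9,
    "scoring": 10,
}


def channel_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent per-channel stream derived from one root seed."""
    return np.random.default_rng([int(seed), _STREAMS[stream]])


def _event_rng(seed: int, stream: str, event: EventSpec) -> np.random.Generator:
    # keyed by the onset sample: removing another event cannot shift draws
    return np.random.default_rng([int(seed), _STREAMS[stream], int(round(event.onset * FS))])


def _slow_noise(rng: np.random.Generator, n: int, cutoff_hz: float, fs: int = FS) -> np.ndarray:
    """Unit-variance low-pass Gaussian noise (smooth modulation source)."""
    w = rng.standard_normal(n)
    sos = sps.butter(2, cutoff_hz, btype="low", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, w)
    sd = y.std()
    return y / sd if sd > 0 else y


def _cos_ramp(n: int) -> np.ndarray:
    """Half-cosine ramp from 0 to 1 over n samples."""
    return 0.5 * (1.0 - np.cos(np.linspace(0.0, np.pi, n)))


# ---------------------------------------------------------------------------
# event scheduling


def schedule_events(
    duration_s: float,
    event_rate_per_h: float,
    class_mix: Mapping[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> list[EventSpec]:
    """Place non-overlapping apneic events along the night.

    Events recur in class-homogeneous runs of 2-4 (the cyclic pattern of
    apneic sleep), with 15-25 s gaps inside a run; runs are separated by
    exponential quiet stretches whose mean compensates for run span so the
    realized count concentrates around
    ``event_rate_per_h * duration_s / 3600``.  Durations follow the
    truncated log-normal model (median 28 s); each run's class is drawn
    from ``class_mix``.
    """
    if event_rate_per_h < 0:
        raise ValueError("event_rate_per_h must be non-negative")
    mix = dict(DEFAULT_CLASS_MIX if class_mix is None else class_mix)
    probs = np.array([mix.get(c, 0.0) for c in EVENT_CLASSES], dtype=float)
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-6:
        raise ValueError("class_mix entries must be non-negative and sum to 1")
    probs = probs / probs.sum()
    if event_rate_per_h == 0:
        return []
    rng = np.random.default_rng() if rng is None else rng

    def draw_duration() -> float:
        dur = float(rng.lognormal(math.log(_DUR_MEDIAN), _DUR_SIGMA))
        while not 10.0 <= dur <= 120.0:
            dur = float(rng.lognormal(math.log(_DUR_MEDIAN), _DUR_SIGMA))
        return dur

    mean_dur = _DUR_MEDIAN * math.exp(_DUR_SIGMA**2 / 2)
    mean_run = 3.5  # events per run
    run_span = mean_run * mean_dur + (mean_run - 1) * 20.0
    quiet_mean = max(mean_run * 3600.0 / event_rate_per_h - run_span, 30.0)

    events: list[EventSpec] = []
    t = rng.exponential(quiet_mean / 2.0)  # first run can start early
    while t < duration_s:
        cls = EVENT_CLASSES[int(rng.choice(len(EVENT_CLASSES), p=probs))]
        run_size = int(2 + rng.integers(0, 4))
        for k in range(run_size):
            dur = draw_duration()
            if t + dur > duration_s:
                t = duration_s
                break
            events.append(EventSpec(cls, round(t, 2), round(dur, 2)))
            t = t + dur + rng.uniform(_MIN_GAP, 25.0)
        t += rng.exponential(quiet_mean)
    return events


# ---------------------------------------------------------------------------
# channel synthesis


def _obstructive_effort(erng: np.random.Generator, n: int, e: float, fs: int) -> np.ndarray:
    """Obstructed-effort envelope: preserved amplitude with the textbook
    crescendo (increasing effort against the closed airway) plus
    breath-to-breath irregularity.  Effect-size scaling toward the neutral
    envelope happens in the caller."""
    if n <= 0:
        return np.zeros(0)
    crescendo = np.linspace(0.95, 1.25, n)
    irr = _slow_noise(erng, n, cutoff_hz=0.5, fs=fs)
    return np.clip(crescendo + 0.4 * irr, 0.15, None)


def _event_gain_profile(
    n: int,
    events: Sequence[EventSpec],
    seed: int,
    effect_size: float,
    fs: int = FS,
) -> np.ndarray:
    """Multiplicative thoracic-effort gain with per-class event envelopes.

    Transition ramps (1.5 s) sit just outside the scored interval so the
    in-event envelope is flat at the class target.
    """
    gain = np.ones(n)
    ramp_n = int(1.5 * fs)
    e = float(effect_size)
    for ev in events:
        erng = _event_rng(seed, "thoracic", ev)
        i0, i1 = int(ev.onset * fs), int(ev.end * fs)
        if ev.event_class == "CSA":
            seg = np.full(i1 - i0, 0.05)
        elif ev.event_class == "HYP":
            # mild events: effort kept in the upper half of the 30-70% range
            seg = np.full(i1 - i0, erng.uniform(0.5, 0.7))
        elif ev.event_class == "OSA":
            seg = _obstructive_effort(erng, i1 - i0, e, fs)
        else:  # MSA: central phase then obstructive phase
            split = int((i1 - i0) * erng.uniform(0.4, 0.6))
            seg = np.concatenate(
                [np.full(split, 0.05), _obstructive_effort(erng, i1 - i0 - split, e, fs)]
            )
        seg = 1.0 - e * (1.0 - seg)  # effect-size interpolation toward no change
        a, b = max(i0 - ramp_n, 0), min(i1 + ramp_n, n)
        out = np.ones(b - a)
        out[i0 - a : i1 - a] = seg
        ra = i0 - a
        if ra > 0:  # ramp down to the event's entry gain
            out[:ra] = 1.0 + (seg[0] - 1.0) * _cos_ramp(ra)
        rb = b - i1
        if rb > 0:
            out[i1 - a :] = seg[-1] + (1.0 - seg[-1]) * _cos_ramp(rb)
        gain[a:b] *= out
        # recovery hyperpnea: exaggerated resumption breaths after the event
        h = 1.15 if ev.event_class == "HYP" else 1.45
        h = 1.0 + e * (h - 1.0)
        j1 = min(i1 + int(12 * fs), n)
        if j1 > i1:
            tt = np.arange(j1 - i1) / fs
            pulse = (h - 1.0) * np.sin(np.clip(tt / 2.0, 0, 1) * np.pi / 2) * np.exp(-tt / 6.0)
            gain[i1:j1] *= 1.0 + pulse
    return gain


def synth_thoracic(
    events: Sequence[EventSpec],
    profile: SubjectProfile,
    duration_s: float,
    rng: np.random.Generator | None = None,
    effect_size: float = 1.0,
) -> np.ndarray:
    """Thoracic RIP-belt effort: quasi-sinusoidal breathing with event gating."""
    rng = channel_rng(profile.seed, "thoracic") if rng is None else rng
    n = int(round(duration_s * FS))
    e = float(effect_size)
    # instantaneous breathing rate: slow wobble, plus slowed labored efforts
    # against the obstructed airway (OSA and the obstructive phase of MSA)
    rate = profile.resp_rate * (
        1.0 + 0.05 * _slow_noise(rng, n, cutoff_hz=0.02)
    )
    for ev in events:
        if ev.event_class not in ("OSA", "MSA"):
            continue
        i0, i1 = int(ev.onset * FS), min(int(ev.end * FS), n)
        if ev.event_class == "MSA":
            erng = _event_rng(profile.seed, "thoracic", ev)
            i0 = i0 + int((i1 - i0) * erng.uniform(0.4, 0.6))
        deficit = 0.4 * e * float(np.sum(rate[i0:i1])) / FS  # cycles lost
        rate[i0:i1] *= 1.0 - 0.4 * e
        # repay the phase deficit with fast recovery breaths so the
        # baseline breathing phase is untouched beyond the recovery window
        j1 = min(i1 + 12 * FS, n)
        if j1 > i1 and deficit > 0:
            w = np.sin(np.linspace(0.0, np.pi, j1 - i1)) ** 2
            rate[i1:j1] += deficit * FS * w / max(w.sum(), 1.0)
    phase = 2 * np.pi * np.cumsum(rate) / FS
    # subject-level excursion scale: RIP amplitude varies severalfold across
    # physiques and belt placements
    subject_gain = float(np.exp(0.45 * rng.standard_normal()))
    # belt-coupling gain: piecewise-constant segments emulating belt shifts
    # and position-dependent RIP sensitivity
    belt = np.ones(n)
    n_seg = int(rng.integers(2, 6))
    bounds = np.sort(rng.uniform(0.0, duration_s, n_seg - 1))
    seg_gains = rng.uniform(0.8, 1.25, n_seg)
    belt[:] = seg_gains[0]
    for g, start in zip(seg_gains[1:], bounds):
        belt[int(start * FS):] = g
    amp = subject_gain * belt * (1.0 + 0.2 * _slow_noise(rng, n, cutoff_hz=0.02)) * (
        1.0 + 0.1 * _slow_noise(rng, n, cutoff_hz=0.3)
    )
    gain = _event_gain_profile(n, events, profile.seed, effect_size)
    return amp * gain * np.sin(phase)


def synth_spo2(
    events: Sequence[EventSpec],
    profile: SubjectProfile,
    duration_s: float,
    rng: np.random.Generator | None = None,
    effect_size: float = 1.0,
) -> np.ndarray:
    """SpO2 with event-locked, delayed, proportional desaturations.

    Desaturation depth is ``3% + 4% * (1 - residual airflow)``, lagged
    10-20 s behind event onset, with exponential resaturation (tau = 15 s)
    tapered to zero by 60 s after the event ends (event locality).
    """
    rng = channel_rng(profile.seed, "spo2") if rng is None else rng
    n = int(round(duration_s * FS))
    base = profile.baseline_spo2 + np.clip(0.17 * _slow_noise(rng, n, 0.01), -0.5, 0.5)
    x = base.copy()
    e = float(effect_size)
    for ev in events:
        erng = _event_rng(profile.seed, "spo2", ev)
        lag = erng.uniform(10.0, 20.0)
        residual = erng.uniform(0.5, 0.7) if ev.event_class == "HYP" else 0.0
        depth = e * (3.0 + 4.0 * (1.0 - residual))
        i0 = int((ev.onset + lag) * FS)
        i1 = int((ev.end + lag) * FS)
        i_end = min(int((ev.end + 60.0) * FS), n)
        if i0 >= n:
            continue
        i1 = min(i1, n)
        tt = np.arange(i0, i1) / FS - (ev.onset + lag)
        drop = np.zeros(i_end - i0)
        drop[: i1 - i0] = -depth * (1.0 - np.exp(-tt / 8.0))
        if i_end > i1:
            d1 = drop[i1 - i0 - 1] if i1 > i0 else 0.0
            tt2 = np.arange(i1, i_end) / FS - i1 / FS
            drop[i1 - i0 :] = d1 * np.exp(-tt2 / 15.0)
        # cosine taper to exactly zero over the last 10 s of the window
        tap0 = min(int((ev.end + 50.0) * FS), n)
        if i_end > tap0 > i0:
            m = i_end - tap0
            drop[tap0 - i0 :] *= 0.5 * (1.0 + np.cos(np.linspace(0, np.pi, m)))
        x[i0:i_end] += drop
    return np.clip(x, 70.0, 100.0)


def _qrs_template(fs: int = FS) -> np.ndarray:
    # stylized QRS: biphasic Gaussian derivative, ~120 ms support
    tt = np.linspace(-0.06, 0.06, int(0.12 * fs))
    return -tt / 0.02 * np.exp(0.5 - (tt / 0.02) ** 2 / 2)


def synth_ancillary(
    events: Sequence[EventSpec],
    profile: SubjectProfile,
    duration_s: float,
    rng: np.random.Generator | None = None,
    effect_size: float = 1.0,
) -> dict[str, np.ndarray]:
    """Audio, both EOGs, ECG and body position for one night."""
    n = int(round(duration_s * FS))
    t = np.arange(n) / FS
    e = float(effect_size)
    if rng is None:
        rngs = {c: channel_rng(profile.seed, c) for c in ("audio", "eog_l", "eog_r", "ecg", "position")}
    else:
        spawned = rng.spawn(5)
        rngs = dict(zip(("audio", "eog_l", "eog_r", "ecg", "position"), spawned))

    # --- audio: snore-intensity trace (the 100-Hz, <30-Hz "audio
    # registration" is a loudness envelope, not raw sound): non-negative
    # respiration-gated bursts, amplified around obstructive events and
    # silent during central ones
    gate = np.maximum(np.sin(2 * np.pi * profile.resp_rate * t), 0.0) ** 2
    # subject-level mic gain plus slow loudness drift (coupling, position)
    mic_gain = float(np.exp(0.6 * rngs["audio"].standard_normal()))
    loud = 0.2 * mic_gain * np.exp(0.5 * _slow_noise(rngs["audio"], n, cutoff_hz=0.01))
    ev_mod = np.ones(n)
    for ev in events:
        i0, i1 = int(ev.onset * FS), min(int(ev.end * FS), n)
        if ev.event_class in ("OSA",):
            ev_mod[i0:i1] *= 1.0 + 4.0 * profile.snore_propensity * e
        elif ev.event_class == "CSA":
            ev_mod[i0:i1] *= 1.0 - 0.95 * e
        elif ev.event_class == "MSA":
            erng = _event_rng(profile.seed, "audio", ev)
            split = i0 + int((i1 - i0) * erng.uniform(0.4, 0.6))
            ev_mod[i0:split] *= 1.0 - 0.95 * e
            ev_mod[split:i1] *= 1.0 + 4.0 * profile.snore_propensity * e
        else:  # HYP: mildly louder (partial obstruction)
            ev_mod[i0:i1] *= 1.0 + 0.5 * profile.snore_propensity * e
        # resuscitative snort at airway reopening (all apneas, mild for HYP)
        snort = 1.5 if ev.event_class == "HYP" else 4.0
        j1 = min(i1 + 4 * FS, n)
        ev_mod[i1:j1] *= 1.0 + e * snort
    # small ambient/cardiogenic floor: the mic is never truly silent
    audio = loud * (0.05 + ev_mod * gate) * np.abs(rngs["audio"].standard_normal(n))

    # --- EOGs: 1/f-like background + post-event beta arousal burst
    def one_over_f(rng_: np.random.Generator) -> np.ndarray:
        w = rng_.standard_normal(n)
        spec = np.fft.rfft(w)
        f = np.fft.rfftfreq(n, 1.0 / FS)
        spec /= np.sqrt(f + 0.1)
        y = np.fft.irfft(spec, n)
        return 40.0 * y / y.std()

    sos_beta = sps.butter(4, (13.0, 30.0), btype="band", fs=FS, output="sos")
    sos_delta = sps.butter(4, (0.5, 4.0), btype="band", fs=FS, output="sos")
    eogs = {}
    for name in ("eog_l", "eog_r"):
        y = one_over_f(rngs[name])
        for ev in events:
            erng = _event_rng(profile.seed, name, ev)
            j0 = int(ev.end * FS)
            j1 = min(j0 + 10 * FS, n)
            if j1 <= j0:
                continue
            burst = sps.sosfiltfilt(sos_beta, erng.standard_normal(j1 - j0))
            sd = burst.std()
            if sd > 0:
                # hypopneas arouse less consistently than apneas
                sev = 0.4 if ev.event_class == "HYP" else 1.0
                win = np.sin(np.linspace(0, np.pi, j1 - j0)) ** 2
                y[j0:j1] += 1.1 * sev * e * 40.0 * (burst / sd) * win
                # arousal eye movements: large slow (delta-band) deflections
                slow = sps.sosfiltfilt(sos_delta, erng.standard_normal(j1 - j0))
                y[j0:j1] += 2.0 * sev * e * 40.0 * (slow / max(slow.std(), 1e-12)) * win
        eogs[name] = y

    # --- ECG: template pulse train, RR lengthens in-event, shortens post-event
    rr_base = 60.0 / profile.heart_rate
    mult = np.ones(n)
    ramp_n = int(2.0 * FS)
    for ev in events:
        sev = 0.5 if ev.event_class == "HYP" else 1.0  # weaker cyclic response
        i0, i1 = int(ev.onset * FS), min(int(ev.end * FS), n)
        j1 = min(i1 + 10 * FS, n)
        mult[i0:i1] = 1.0 + 0.15 * sev * e
        mult[i1:j1] = 1.0 - 0.10 * sev * e
        a = max(i0 - ramp_n, 0)
        if i0 > a:
            mult[a:i0] = 1.0 + 0.15 * sev * e * _cos_ramp(i0 - a)
        b = min(j1 + ramp_n, n)
        if b > j1:
            mult[j1:b] = (1.0 - 0.10 * sev * e) + 0.10 * sev * e * _cos_ramp(b - j1)
    ecg = 0.03 * rngs["ecg"].standard_normal(n)
    tmpl = _qrs_template()
    tb = rngs["ecg"].uniform(0.0, rr_base)
    half = len(tmpl) // 2
    while tb < duration_s:
        k = int(tb * FS)
        a, b = k - half, k - half + len(tmpl)
        ta, tbnd = max(a, 0), min(b, n)
        if tbnd > ta:
            ecg[ta:tbnd] += tmpl[ta - a : tbnd - a]
        rr_k = rr_base * mult[min(k, n - 1)] * (1.0 + 0.02 * rngs["ecg"].standard_normal())
        tb += max(rr_k, 0.3)

    # --- body position: piecewise-constant code, 0-4 changes per night
    prng = rngs["position"]
    n_changes = int(prng.integers(0, 5))
    change_at = np.sort(prng.uniform(0, duration_s, n_changes))
    codes = [int(prng.integers(0, 5))]
    for _ in range(n_changes):
        nxt = int(prng.integers(0, 4))
        codes.append(nxt if nxt < codes[-1] else nxt + 1)  # always an actual change
    position = np.full(n, float(codes[0]))
    for c, start in zip(codes[1:], change_at):
        position[int(start * FS) :] = float(c)

    return {"audio": audio, "eog_l": eogs["eog_l"], "eog_r": eogs["eog_r"], "ecg": ecg, "position": position}


# ---------------------------------------------------------------------------
# assembly


def quantize16(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Midtread 16-bit quantization over the physical range [lo, hi]:
    65536 levels anchored at ``lo``, step (hi - lo) / 65535."""
    step = (hi - lo) / (2**16 - 1)
    k = np.clip(np.round((x - lo) / step), 0, 2**16 - 1)
    return lo + k * step


_SOS_BAND = sps.butter(4, (0.05, 30.0), btype="band", fs=FS, output="sos")
_SOS_LOW = sps.butter(4, 30.0, btype="low", fs=FS, output="sos")


def generate_recording(
    profile: SubjectProfile,
    duration_h: float,
    event_rate_per_h: float = 15.0,
    class_mix: Mapping[str, float] | None = None,
    wake_fraction: float = 0.15,
    detach_rate_per_h: float = 0.25,
    effect_size: float = 1.0,
    subtype_confusion: float = 0.15,
) -> Recording:
    """Generate one subject's full annotated recording.

    Channel physiology follows each event's true morphology; the *recorded*
    annotations emulate expert scoring, which confuses apnea subtypes
    (OSA/CSA/MSA) at rate ``subtype_confusion`` — the well-documented
    inter-scorer ambiguity of subtype assignment.  Event presence, onset and
    duration are scored faithfully.

    The analog front end is emulated last: a zero-phase band-pass
    (0.05-30 Hz) on the AC-coupled channels (thoracic, audio, EOGs, ECG),
    a 30-Hz low-pass on SpO2 (its DC level is the measurement), then
    16-bit midtread quantization over each channel's physical range.
    """
    if not 0.5 <= duration_h <= 12.0:
        raise ValueError("duration_h must lie in [0.5, 12]")
    if not 0.0 <= wake_fraction <= 0.5:
        raise ValueError("wake_fraction must lie in [0, 0.5]")
    duration_s = duration_h * 3600.0
    n = int(round(duration_s * FS))

    events = schedule_events(
        duration_s, event_rate_per_h, class_mix, channel_rng(profile.seed, "schedule")
    )
    channels = {
        "thoracic": synth_thoracic(events, profile, duration_s, effect_size=effect_size),
        "spo2": synth_spo2(events, profile, duration_s, effect_size=effect_size),
    }
    channels.update(synth_ancillary(events, profile, duration_s, effect_size=effect_size))

    # scored annotations: apnea subtype confused at the stated rate
    scored: list[EventSpec] = []
    for ev in events:
        cls = ev.event_class
        if cls in APNEA_CLASSES and subtype_confusion > 0:
            srng = _event_rng(profile.seed, "scoring", ev)
            if srng.random() < subtype_confusion:
                others = [c for c in APNEA_CLASSES if c != cls]
                cls = others[int(srng.integers(0, len(others)))]
        scored.append(replace(ev, event_class=cls))
    events = scored

    for name in ("thoracic", "audio", "eog_l", "eog_r", "ecg"):
        channels[name] = sps.sosfiltfilt(_SOS_BAND, channels[name])
    channels["spo2"] = np.clip(sps.sosfiltfilt(_SOS_LOW, channels["spo2"]), 70.0, 100.0)
    for name, x in channels.items():
        lo, hi = CHANNEL_RANGES[name]
        channels[name] = quantize16(x, lo, hi)

    n_epochs = n // (30 * FS)
    hyp_rng = channel_rng(profile.seed, "hypnogram")
    hypnogram = np.zeros(n_epochs, dtype=bool)
    event_free = [
        k
        for k in range(n_epochs)
        if not any(ev.onset < (k + 1) * 30.0 and ev.end > k * 30.0 for ev in events)
    ]
    n_wake = min(int(round(wake_fraction * n_epochs)), len(event_free))
    if n_wake:
        wake_idx = hyp_rng.choice(len(event_free), size=n_wake, replace=False)
        hypnogram[np.array(event_free)[wake_idx]] = True

    drng = channel_rng(profile.seed, "detach")
    detachments: list[tuple[float, float]] = []
    for _ in range(int(drng.poisson(detach_rate_per_h * duration_h))):
        start = float(drng.uniform(0.0, duration_s))
        length = float(drng.uniform(5.0, 60.0))
        detachments.append((start, min(start + length, duration_s)))
    detachments.sort()

    rec = Recording(profile.subject_id, channels, events, hypnogram, detachments)
    rec.validate()
    return rec


def cohort_profiles(n_subjects: int, seed: int) -> list[SubjectProfile]:
    """Draw a cohort of subject profiles with physiology spanning the stated ranges."""
    rng = np.random.default_rng([int(seed), 424243])
    profiles = []
    for i in range(n_subjects):
        profiles.append(
            SubjectProfile(
                subject_id=f"S{i:03d}",
                baseline_spo2=float(rng.uniform(94.5, 98.5)),
                resp_rate=float(rng.uniform(0.18, 0.32)),
                heart_rate=float(rng.uniform(52.0, 88.0)),
                snore_propensity=float(rng.uniform(0.2, 1.0)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return profiles


def generate_cohort(
    n_subjects: int,
    duration_h: float,
    event_rate_per_h: float = 15.0,
    class_mix: Mapping[str, float] | None = None,
    wake_fraction: float = 0.15,
    effect_size: float = 1.0,
    seed: int = 0,
):
    """Yield one Recording per subject (lazily — a night is ~10 MB/channel-hour)."""
    for prof in cohort_profiles(n_subjects, seed):
        yield generate_recording(
            prof,
            duration_h,
            event_rate_per_h=event_rate_per_h,
            class_mix=class_mix,
            wake_fraction=wake_fraction,
            effect_size=effect_size,
        )
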