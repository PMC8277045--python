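"""Synthetic abdominal-accelerometer sessions with known ground truth.

The generator emulates the phenomenology the downstream pipeline relies on:

* Z-axis-dominant transient bursts for fetal kicks (exponentially damped
  oscillation, carrier 5-20 Hz, ~0.3-0.7 s);
* maternal-laugh artifacts that look like kicks in the time domain
  (amplitude-modulated oscillation trains, 4-6 Hz envelope, 1.5-4 s);
* a 0.2-0.4 Hz respiratory sinusoid plus slow piecewise-constant baseline
  shifts from maternal posture changes;
* white sensor noise; X/Y axes as attenuated copies of Z with independent
  noise (only the Z-dominance ordering is physical);
* annotation button presses lagging each true event by a few seconds.

Everything is driven by a single integer seed so corpora are reproducible
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .session_io import RawSession, SessionMeta

__all__ = [
    "EventTruth",
    "SynthConfig",
    "SynthCorpus",
    "synth_event_waveform",
    "synth_session",
    "synth_dataset",
]

EVENT_KINDS = ("kick", "laugh")

KICK_DURATION_S = (0.3, 0.7)
KICK_CARRIER_HZ = (5.0, 20.0)
KICK_DECAY_S = 0.1
LAUGH_DURATION_S = (1.5, 4.0)
LAUGH_ENVELOPE_HZ = (4.0, 6.0)
LAUGH_CARRIER_HZ = (8.0, 14.0)
XY_ATTENUATION = 0.2


class GenerationError(RuntimeError):
    """Raised when events cannot be placed without collisions."""


@dataclass(frozen=True)
class EventTruth:
    """Ground-truth record for one generated event."""

    kind: str  # "kick" | "laugh"
    onset_idx: int
    duration_s: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"kind must be one of {EVENT_KINDS}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition parameters of the synthetic session generator.

    Amplitudes are in AMU, the device's uncalibrated linear unit; the noise
    floor ``noise_sigma`` sets the scale against which events are judged.
    Defaults give a moderate-SNR session: kicks ~12x the noise floor with a
    clearly visible respiratory sinusoid and occasional baseline jumps.
    """

    fs: float = 280.0
    duration_s: float = 600.0
    kick_rate: float = 3.0          # events / min
    laugh_rate: float = 1.0         # events / min
    kick_amp: float = 12.0          # AMU, peak
    laugh_amp: float = 10.0         # AMU, peak
    resp_freq: float = 0.3          # Hz, in the 0.2-0.4 breathing band
    resp_amp: float = 5.0           # AMU
    drift_step_amp: float = 8.0     # AMU, sd of baseline levels
    drift_rate: float = 2.0         # level changes / min
    noise_sigma: float = 1.0        # AMU
    btn_lag_range_s: tuple[float, float] = (0.5, 5.0)
    seed: int = 0
    count_mode: Literal["poisson", "expected"] = "poisson"

    def __post_init__(self) -> None:
        if min(self.kick_rate, self.laugh_rate, self.kick_amp, self.laugh_amp,
               self.resp_amp, self.drift_step_amp, self.noise_sigma) < 0:
            raise ValueError("rates, amplitudes and sigmas must be >= 0")
        lo, hi = self.btn_lag_range_s
        if lo > hi:
            raise ValueError("btn_lag_range_s must satisfy lo <= hi")
        if not (0 < self.resp_freq < self.fs / 2):
            raise ValueError("resp_freq must lie in (0, fs/2)")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration_s must be positive")


def synth_event_waveform(
    kind: str,
    duration_s: float,
    amplitude: float,
    fs: float = 280.0,
    seed: int = 0,
) -> np.ndarray:
    """Generate one event waveform, normalized so peak |value| == amplitude.

    ``kick``  — exponentially damped oscillation: carrier drawn uniformly
    from 5-20 Hz, amplitude decay time constant 0.1 s.  ``laugh`` — an
    amplitude-modulated oscillation train: raised-cosine envelope at 4-6 Hz
    over a carrier at 8-14 Hz, mimicking the repetitive abdominal motion of
    laughter.
    """
    if kind not in EVENT_KINDS:
        raise ValueError(f"unknown event kind {kind!r}")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(seed)
    n = max(int(round(duration_s * fs)), 1)
    t = np.arange(n) / fs
    if kind == "kick":
        f = rng.uniform(*KICK_CARRIER_HZ)
        phase = rng.uniform(0, 2 * np.pi)
        w = np.sin(2 * np.pi * f * t + phase) * np.exp(-t / KICK_DECAY_S)
    else:
        f_env = rng.uniform(*LAUGH_ENVELOPE_HZ)
        f_car = rng.uniform(*LAUGH_CARRIER_HZ)
        phase = rng.uniform(0, 2 * np.pi)
        envelope = 0.5 * (1.0 - np.cos(2 * np.pi * f_env * t))
        # taper the train so it starts and ends near zero
        taper = np.sqrt(np.clip(np.sin(np.pi * np.arange(n) / max(n - 1, 1)), 0.0, None))
        w = envelope * taper * np.sin(2 * np.pi * f_car * t + phase)
    peak = np.max(np.abs(w))
    if peak > 0:
        w = w * (amplitude / peak)
    else:  # degenerate (should not happen for n >= 2)
        w = np.zeros(n)
    return w


def _draw_count(rng: np.random.Generator, rate_per_min: float,
                duration_s: float, mode: str) -> int:
    expected = rate_per_min * duration_s / 60.0
    if mode == "poisson":
        return int(rng.poisson(expected))
    # "expected": deterministic floor plus seeded probabilistic rounding,
    # keeping corpus-level class mixes tight at small n
    base = int(np.floor(expected))
    return base + int(rng.random() < (expected - base))


def _place_events(
    rng: np.random.Generator,
    n_samples: int,
    fs: float,
    specs: list[tuple[str, float, float]],
    margin_s: float = 1.0,
) -> list[tuple[str, int, float, float]]:
    """Place events without overlap; 100 attempts per event, else error.

    Each event keeps a ``margin_s`` guard on both sides so peak-centred
    200-sample windows from different events never overlap.
    """
    margin = int(margin_s * fs)
    placed: list[tuple[int, int]] = []  # (start, end) including margins
    out = []
    for kind, dur_s, amp in specs:
        dur = int(round(dur_s * fs))
        ok = False
        for _ in range(100):
            onset = int(rng.integers(margin, n_samples - dur - margin))
            lo, hi = onset - margin, onset + dur + margin
            if all(hi <= s or lo >= e for s, e in placed):
                placed.append((lo, hi))
                out.append((kind, onset, dur_s, amp))
                ok = True
                break
        if not ok:
            raise GenerationError(
                f"could not place {kind} event after 100 attempts "
                f"(session too crowded: {len(placed)} events placed)"
            )
    return out


def synth_session(config: SynthConfig) -> tuple[RawSession, list[EventTruth]]:
    """Generate one session and its ground-truth event list.

    The Z axis is noise + respiration sinusoid + piecewise-constant baseline
    + superposed kick/laugh waveforms; X and Y are 0.2x attenuated copies of
    the clean Z content with independent noise.  Button 1 is pressed once
    per kick and button 2 once per laugh, each lagging the event onset by a
    uniform draw from ``btn_lag_range_s``.  Fully seed-deterministic.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs

    # background: respiration + baseline drift
    resp = config.resp_amp * np.sin(2 * np.pi * config.resp_freq * t)
    drift = np.zeros(n)
    if config.drift_step_amp > 0 and config.drift_rate > 0:
        n_steps = _draw_count(rng, config.drift_rate, config.duration_s, "poisson")
        change_pts = np.sort(rng.integers(0, n, size=n_steps))
        levels = rng.normal(0.0, config.drift_step_amp, size=n_steps + 1)
        bounds = np.concatenate(([0], change_pts, [n]))
        for k in range(n_steps + 1):
            drift[bounds[k] : bounds[k + 1]] = levels[k]

    n_kicks = _draw_count(rng, config.kick_rate, config.duration_s, config.count_mode)
    n_laughs = _draw_count(rng, config.laugh_rate, config.duration_s, config.count_mode)
    specs = [
        ("kick", rng.uniform(*KICK_DURATION_S), config.kick_amp)
        for _ in range(n_kicks)
    ] + [
        ("laugh", rng.uniform(*LAUGH_DURATION_S), config.laugh_amp)
        for _ in range(n_laughs)
    ]
    placed = _place_events(rng, n, fs, specs)

    events_z = np.zeros(n)
    truth: list[EventTruth] = []
    btn1, btn2 = [], []
    lag_lo, lag_hi = config.btn_lag_range_s
    for kind, onset, dur_s, amp in placed:
        w = synth_event_waveform(
            kind, dur_s, amp, fs=fs, seed=int(rng.integers(0, 2**31))
        )
        events_z[onset : onset + w.size] += w
        truth.append(EventTruth(kind, onset, dur_s, amp))
        lag = rng.uniform(lag_lo, lag_hi)
        press = min(onset + int(round(lag * fs)), n - 1)
        (btn1 if kind == "kick" else btn2).append(press)

    clean_z = resp + drift + events_z
    az = clean_z + rng.normal(0.0, config.noise_sigma, size=n)
    ax = XY_ATTENUATION * clean_z + rng.normal(0.0, config.noise_sigma, size=n)
    ay = XY_ATTENUATION * clean_z + rng.normal(0.0, config.noise_sigma, size=n)

    truth.sort(key=lambda e: e.onset_idx)
    meta = SessionMeta(subject_id=f"SYN{config.seed % 10**6:06d}")
    session = RawSession(
        meta=meta,
        fs=fs,
        ax=ax,
        ay=ay,
        az=az,
        btn1_idx=np.unique(np.asarray(sorted(btn1), dtype=np.int64)),
        btn2_idx=np.unique(np.asarray(sorted(btn2), dtype=np.int64)),
    )
    return session, truth


@dataclass
class SynthCorpus:
    """A labeled corpus: sessions with truth, subject table, class plan."""

    sessions: list[RawSession]
    truths: list[list[EventTruth]]
    subject_ids: list[str]
    gestational_ages: dict[str, float]
    n_respiratory_per_session: list[int]
    seed: int

    def manifest(self) -> list[dict]:
        rows = []
        for sess, truth in zip(self.sessions, self.truths):
            for ev in truth:
                rows.append(
                    {
                        "subject_id": sess.meta.subject_id,
                        "kind": ev.kind,
                        "onset_idx": ev.onset_idx,
                        "duration_s": ev.duration_s,
                        "amplitude": ev.amplitude,
                    }
                )
        return rows


def _apportion(total: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of `total` into len(weights) parts."""
    quota = total * weights / weights.sum()
    base = np.floor(quota).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:rem]] += 1
    return base


def synth_dataset(
    n_subjects: int,
    sessions_per_subject: int,
    class_mix: Sequence[float],
    base_config: SynthConfig,
    seed: int = 0,
) -> SynthCorpus:
    """Generate a multi-subject corpus with a prescribed class mix.

    ``class_mix`` gives the desired kick : laugh : respiratory proportions
    (e.g. the clinical tabulation 1022:276:1563).  Event counts follow the
    mix by largest-remainder apportionment across sessions, so realized
    corpus proportions stay within rounding of the target; respiratory
    realizations are quiet-background windows cut later by the segmenter,
    and their planned per-session count is carried in the corpus.  Each
    subject receives a multiplicative log-normal jitter on amplitudes
    (sd 0.2) and rates (sd 0.05) so between-subject variation exists and
    global-vs-local training contrasts are meaningful; with ``n_subjects=1``
    no jitter is applied.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    mix = np.asarray(class_mix, dtype=float)
    if mix.shape != (3,) or mix.sum() <= 0 or np.any(mix < 0):
        raise ValueError("class_mix must be 3 non-negative ratios, not all zero")
    rng = np.random.default_rng(seed)

    n_sessions = n_subjects * sessions_per_subject
    # total events implied by the base kick rate; mix sets the composition
    mean_events = base_config.kick_rate * base_config.duration_s / 60.0
    total_kicks = max(int(round(mean_events * n_sessions)), n_sessions)
    totals = _apportion(
        int(round(total_kicks * mix.sum() / mix[0])) if mix[0] > 0 else total_kicks,
        mix,
    )
    kicks_per = _apportion(int(totals[0]), np.ones(n_sessions))
    laughs_per = _apportion(int(totals[1]), np.ones(n_sessions))
    resp_per = _apportion(int(totals[2]), np.ones(n_sessions))

    sessions, truths, subject_ids = [], [], []
    ages: dict[str, float] = {}
    s = 0
    for i in range(n_subjects):
        sid = f"S{i + 1:02d}"
        subject_ids.append(sid)
        ages[sid] = float(rng.integers(27, 42))
        if n_subjects > 1:
            amp_jit = float(np.exp(rng.normal(0.0, 0.2)))
            rate_jit = float(np.exp(rng.normal(0.0, 0.05)))
        else:
            amp_jit = rate_jit = 1.0
        for _ in range(sessions_per_subject):
            per_min = 60.0 / base_config.duration_s
            cfg = replace(
                base_config,
                kick_amp=base_config.kick_amp * amp_jit,
                laugh_amp=base_config.laugh_amp * amp_jit,
                # exact per-session counts via rates of rate*duration/60 == count
                kick_rate=kicks_per[s] * per_min * rate_jit,
                laugh_rate=laughs_per[s] * per_min * rate_jit,
                count_mode="expected",
                seed=int(rng.integers(0, 2**31)),
            )
            sess, truth = synth_session(cfg)
            sess.meta.subject_id = sid
            sess.meta.gestational_age = ages[sid]
            sessions.append(sess)
            truths.append(truth)
            s += 1
    return SynthCorpus(
        sessions=sessions,
        truths=truths,
        subject_ids=subject_ids,
        gestational_ages=ages,
        n_respiratory_per_session=[int(r) for r in resp_per],
        seed=seed,
    )
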