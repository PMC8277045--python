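"""Reading, validating and writing device session recordings.

A session is one continuous tri-axial accelerometer recording from the
abdominal belt sensor (280 samples/s, amplitudes in the device's
uncalibrated AMU scale) together with the two annotation button channels:
button 1 is pressed by the mother when she feels a fetal movement, button 2
when she makes a movement herself (laugh).

On-disk format (plain columnar text, inspectable and diff-able)::

    #fs=280
    #subject_id=S01
    #gestational_age=33
    i,ax,ay,az,btn1,btn2
    0,0.1200,-0.0300,1.5000,0,0
    1,...

Button presses are stored per-sample as 0/1 columns; in memory they are
exposed as rising-edge sample indices (a held button spanning k samples is
one event at its first sample). Sample indices are 0-based everywhere.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SessionMeta",
    "RawSession",
    "SessionFormatError",
    "SessionIntegrityError",
    "read_session",
    "write_session",
    "session_summary",
]

GESTATION_WEEKS_MIN = 26
GESTATION_WEEKS_MAX = 42
DEFAULT_FS = 280.0

_FETAL_GENDERS = ("male", "female", "unstated")


class SessionFormatError(ValueError):
    """The file does not follow the session-log format."""


class SessionIntegrityError(ValueError):
    """The file parses but violates a session invariant."""


@dataclass
class SessionMeta:
    """Subject/session metadata recorded at the start of a clinical session."""

    subject_id: str
    maternal_age: float | None = None
    gestational_age: float | None = None
    fetal_gender: str = "unstated"
    session_date: str | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise ValueError("subject_id must be non-empty")
        if self.fetal_gender not in _FETAL_GENDERS:
            raise ValueError(f"fetal_gender must be one of {_FETAL_GENDERS}")
        if self.gestational_age is not None and not (
            GESTATION_WEEKS_MIN <= self.gestational_age <= GESTATION_WEEKS_MAX
        ):
            raise ValueError(
                f"gestational_age {self.gestational_age} outside "
                f"[{GESTATION_WEEKS_MIN}, {GESTATION_WEEKS_MAX}] weeks"
            )


@dataclass
class RawSession:
    """One belt recording: tri-axial AMU samples plus button-press indices."""

    meta: SessionMeta
    fs: float
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    btn1_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    btn2_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self) -> None:
        self.ax = np.asarray(self.ax, dtype=np.float64)
        self.ay = np.asarray(self.ay, dtype=np.float64)
        self.az = np.asarray(self.az, dtype=np.float64)
        self.btn1_idx = np.asarray(self.btn1_idx, dtype=np.int64)
        self.btn2_idx = np.asarray(self.btn2_idx, dtype=np.int64)
        n = self.ax.size
        if not (self.ay.size == n == self.az.size):
            raise SessionIntegrityError("axis arrays must have equal length")
        if n < 1:
            raise SessionIntegrityError("session must contain at least one sample")
        if self.fs <= 0:
            raise SessionIntegrityError("sampling rate must be positive")
        for name, idx in (("btn1_idx", self.btn1_idx), ("btn2_idx", self.btn2_idx)):
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise SessionIntegrityError(f"{name} outside [0, n_samples)")
            if idx.size > 1 and not np.all(np.diff(idx) > 0):
                raise SessionIntegrityError(f"{name} must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.ax.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RawSession):
            return NotImplemented
        return (
            self.meta == other.meta
            and self.fs == other.fs
            and np.array_equal(self.ax, other.ax)
            and np.array_equal(self.ay, other.ay)
            and np.array_equal(self.az, other.az)
            and np.array_equal(self.btn1_idx, other.btn1_idx)
            and np.array_equal(self.btn2_idx, other.btn2_idx)
        )


_META_KEYS = {
    "subject_id": str,
    "maternal_age": float,
    "gestational_age": float,
    "fetal_gender": str,
    "session_date": str,
    "notes": str,
}
_COLUMNS = "i,ax,ay,az,btn1,btn2"


def _rising_edges(col: np.ndarray) -> np.ndarray:
    """Indices where a 0/1 channel switches from 0 to 1."""
    col = np.asarray(col, dtype=np.int64)
    prev = np.concatenate(([0], col[:-1]))
    return np.flatnonzero((col == 1) & (prev == 0)).astype(np.int64)


def read_session(path, strict: bool = True) -> RawSession:
    """Parse a session-log file into a :class:`RawSession`.

    Parameters
    ----------
    path : str or Path
        Session-log file (UTF-8 columnar text, see module docstring).
    strict : bool
        If True a non-monotone sample-index column is an integrity error;
        if False the rows are re-sorted by index with a warning.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    lines = text.splitlines()
    header: dict[str, str] = {}
    i = 0
    while i < len(lines) and lines[i].startswith("#"):
        line = lines[i][1:]
        if "=" not in line:
            raise SessionFormatError(f"malformed header line: {lines[i]!r}")
        key, _, val = line.partition("=")
        header[key.strip()] = val.strip()
        i += 1
    if i >= len(lines) or lines[i].strip() != _COLUMNS:
        raise SessionFormatError(
            f"expected column header {_COLUMNS!r}, got "
            f"{lines[i].strip()!r}" if i < len(lines) else "missing column header"
        )
    if "fs" not in header:
        raise SessionFormatError("header missing required key 'fs'")
    if "subject_id" not in header:
        raise SessionFormatError("header missing required key 'subject_id'")

    body = "\n".join(lines[i + 1 :])
    try:
        data = np.loadtxt(
            io.StringIO(body), delimiter=",", ndmin=2, dtype=np.float64
        )
    except ValueError as exc:
        raise SessionFormatError(f"malformed data section: {exc}") from exc
    if data.shape[1] != 6:
        raise SessionFormatError(
            f"expected 6 columns (i,ax,ay,az,btn1,btn2), got {data.shape[1]}"
        )

    idx = data[:, 0]
    if not np.all(np.diff(idx) > 0):
        if strict:
            raise SessionIntegrityError("sample index column is not monotone")
        warnings.warn("non-monotone sample index; rows re-sorted", stacklevel=2)
        data = data[np.argsort(idx, kind="stable")]

    meta_kwargs = {}
    for key, conv in _META_KEYS.items():
        if key in header and header[key] != "":
            meta_kwargs[key] = conv(header[key])
    meta = SessionMeta(**meta_kwargs)
    return RawSession(
        meta=meta,
        fs=float(header["fs"]),
        ax=data[:, 1],
        ay=data[:, 2],
        az=data[:, 3],
        btn1_idx=_rising_edges(data[:, 4]),
        btn2_idx=_rising_edges(data[:, 5]),
    )


def write_session(session: RawSession, path) -> str:
    """Write a session-log file readable by :func:`read_session`.

    Returns the path written. Acceleration is stored with the shortest
    decimal representation that round-trips the float64 value exactly, so
    read(write(s)) == s holds field-for-field; buttons as 0/1 point events.
    """
    n = session.n_samples
    btn1 = np.zeros(n, dtype=np.int64)
    btn1[session.btn1_idx] = 1
    btn2 = np.zeros(n, dtype=np.int64)
    btn2[session.btn2_idx] = 1
    m = session.meta
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#fs={session.fs:g}\n")
        fh.write(f"#subject_id={m.subject_id}\n")
        if m.maternal_age is not None:
            fh.write(f"#maternal_age={m.maternal_age:g}\n")
        if m.gestational_age is not None:
            fh.write(f"#gestational_age={m.gestational_age:g}\n")
        fh.write(f"#fetal_gender={m.fetal_gender}\n")
        if m.session_date is not None:
            fh.write(f"#session_date={m.session_date}\n")
        if m.notes:
            fh.write(f"#notes={m.notes}\n")
        fh.write(_COLUMNS + "\n")
        ax, ay, az = session.ax.tolist(), session.ay.tolist(), session.az.tolist()
        for k in range(n):
            fh.write(f"{k},{ax[k]!r},{ay[k]!r},{az[k]!r},{btn1[k]},{btn2[k]}\n")
    return str(path)


def session_summary(session: RawSession) -> dict:
    """Duration, sample count, per-button counts and per-axis amplitude range."""
    return {
        "subject_id": session.meta.subject_id,
        "n_samples": session.n_samples,
        "duration_s": session.duration_s,
        "btn1_count": int(session.btn1_idx.size),
        "btn2_count": int(session.btn2_idx.size),
        "range_ax": (float(session.ax.min()), float(session.ax.max())),
        "range_ay": (float(session.ay.min()), float(session.ay.max())),
        "range_az": (float(session.az.min()), float(session.az.max())),
    }
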