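"""Domain containers and delimited-text I/O.

Everything on disk is plain comma-separated text with a single header line.
Time is in seconds from task onset (0-based); skin conductance in microsiemens;
inter-beat intervals in milliseconds. Floats round-trip to 12 significant
digits, integers bit-exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError

log = logging.getLogger("physiosync.io")

_FLOAT_FMT = "%.12g"

#: tolerance on timestamp uniformity, seconds
TIME_TOL = 1e-6

CHANNELS = ("SC", "HR")
TESTS = ("analytical", "historical")
PHASES = ("pre", "post")
N_ITEMS = 10


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class PhysioRecording:
    """One participant's uniformly sampled signal for a single channel."""

    participant_id: str
    channel: str
    rate_hz: float
    samples: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise FormatError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")
        if not self.rate_hz > 0:
            raise FormatError(f"rate_hz must be positive, got {self.rate_hz}")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise FormatError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise FormatError("samples contain non-finite values")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.rate_hz


@dataclass
class RatingStream:
    """Real-time pleasure reports: ordered, non-overlapping press episodes.

    Each episode is ``(onset_s, offset_s, level)`` with level 1-5
    (1 = unpleasant ... 4 = high pleasure, 5 = extreme pleasure).
    """

    participant_id: str
    episodes: list[tuple[float, float, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_off = -np.inf
        for i, (on, off, lvl) in enumerate(self.episodes):
            if not on < off:
                raise FormatError(f"episode {i}: onset {on} not before offset {off}")
            if lvl not in (1, 2, 3, 4, 5):
                raise FormatError(f"episode {i}: level {lvl} outside 1..5")
            if on < prev_off - TIME_TOL:
                raise FormatError(f"episode {i}: overlaps previous episode (onset {on} < {prev_off})")
            prev_off = off
        self.episodes = [(float(a), float(b), int(l)) for a, b, l in self.episodes]


@dataclass
class KnowledgeVector:
    """Binary response pattern on one 10-item knowledge test."""

    participant_id: str
    test: str
    phase: str
    answers: np.ndarray

    def __post_init__(self) -> None:
        if self.test not in TESTS:
            raise FormatError(f"test must be one of {TESTS}, got {self.test!r}")
        if self.phase not in PHASES:
            raise FormatError(f"phase must be one of {PHASES}, got {self.phase!r}")
        self.answers = np.asarray(self.answers, dtype=int)
        if self.answers.shape != (N_ITEMS,):
            raise FormatError(
                f"knowledge vector for {self.participant_id!r} has "
                f"{self.answers.size} items, expected {N_ITEMS}"
            )
        if not np.isin(self.answers, (0, 1)).all():
            raise FormatError("knowledge answers must be 0 or 1")


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

def write_recording(rec: PhysioRecording, path: str | Path) -> None:
    arr = np.column_stack([rec.times(), rec.samples])
    np.savetxt(path, arr, delimiter=",", header="time_s,value", comments="", fmt=_FLOAT_FMT)


def _read_numeric_csv(path: str | Path, expected_cols: Sequence[str] | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: cannot parse ({exc})") from exc
    if expected_cols is not None and list(df.columns) != list(expected_cols):
        raise FormatError(f"{path}: expected columns {list(expected_cols)}, got {list(df.columns)}")
    return df


def _as_float_column(df: pd.DataFrame, col: str, path: Path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce").to_numpy()
    bad = np.flatnonzero(~np.isfinite(vals))
    if bad.size:
        # +2: header line plus 1-based numbering
        raise FormatError(f"{path}: non-numeric value in column {col!r} at line {bad[0] + 2}")
    return vals.astype(float)


def read_recording(
    path: str | Path, channel: str, rate_hz: float | None = None
) -> PhysioRecording:
    """Read a recording from ``time_s,value`` or single ``value`` column text.

    Non-uniform timestamps are rejected (tolerance ``TIME_TOL`` seconds) with
    the first offending line named.
    """
    path = Path(path)
    df = _read_numeric_csv(path)
    cols = list(df.columns)
    if cols == ["time_s", "value"]:
        t = _as_float_column(df, "time_s", path)
        v = _as_float_column(df, "value", path)
        if t.size < 2:
            rate = float(rate_hz) if rate_hz else 1.0
            return PhysioRecording(path.stem, channel, rate, v, t0=float(t[0]) if t.size else 0.0)
        dt = np.diff(t)
        step = dt[0]
        bad = np.flatnonzero(np.abs(dt - step) > TIME_TOL)
        if bad.size:
            raise FormatError(
                f"{path}: non-uniform sampling at line {bad[0] + 3} "
                f"(step {dt[bad[0]]:.9g} vs {step:.9g})"
            )
        if step <= 0:
            raise FormatError(f"{path}: non-increasing timestamps at line 3")
        return PhysioRecording(path.stem, channel, 1.0 / step, v, t0=float(t[0]))
    if cols == ["value"]:
        if rate_hz is None:
            raise FormatError(f"{path}: single-column file requires an explicit rate_hz")
        v = _as_float_column(df, "value", path)
        return PhysioRecording(path.stem, channel, float(rate_hz), v)
    raise FormatError(f"{path}: expected columns ['time_s','value'] or ['value'], got {cols}")


# ---------------------------------------------------------------------------
# inter-beat intervals
# ---------------------------------------------------------------------------

def write_ibi(intervals_ms: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(intervals_ms, float), delimiter=",",
               header="ibi_ms", comments="", fmt=_FLOAT_FMT)


def read_ibi(path: str | Path) -> np.ndarray:
    """Read an IBI series: one ``ibi_ms`` per line, or ``beat_time_s`` per line
    (successive differences are returned, in ms). Auto-detected by header."""
    path = Path(path)
    df = _read_numeric_csv(path)
    cols = list(df.columns)
    if cols == ["ibi_ms"]:
        ivals = _as_float_column(df, "ibi_ms", path)
    elif cols == ["beat_time_s"]:
        t = _as_float_column(df, "beat_time_s", path)
        if t.size < 2:
            raise FormatError(f"{path}: need at least two beat times")
        ivals = np.diff(t) * 1000.0
    else:
        raise FormatError(f"{path}: expected header 'ibi_ms' or 'beat_time_s', got {cols}")
    bad = np.flatnonzero(ivals <= 0)
    if bad.size:
        raise FormatError(f"{path}: non-positive interval at line {bad[0] + 2}")
    return ivals


# ---------------------------------------------------------------------------
# ratings
# ---------------------------------------------------------------------------

def write_ratings(stream: RatingStream, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("participant_id,onset_s,offset_s,level\n")
        for on, off, lvl in stream.episodes:
            fh.write(f"{stream.participant_id},{on:.12g},{off:.12g},{lvl}\n")


def read_ratings(path: str | Path) -> RatingStream:
    path = Path(path)
    df = _read_numeric_csv(path, ["participant_id", "onset_s", "offset_s", "level"])
    on = _as_float_column(df, "onset_s", path)
    off = _as_float_column(df, "offset_s", path)
    lvl = _as_float_column(df, "level", path).astype(int)
    pid = str(df["participant_id"].iloc[0]) if len(df) else path.stem
    episodes = list(zip(on, off, lvl))
    try:
        return RatingStream(pid, episodes)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# knowledge tables
# ---------------------------------------------------------------------------

_KNOWLEDGE_COLS = ["participant_id", "test", "phase"] + [f"q{i}" for i in range(1, N_ITEMS + 1)]


def write_knowledge(vectors: Iterable[KnowledgeVector], path: str | Path) -> None:
    rows = [
        {"participant_id": v.participant_id, "test": v.test, "phase": v.phase,
         **{f"q{i + 1}": int(a) for i, a in enumerate(v.answers)}}
        for v in vectors
    ]
    pd.DataFrame(rows, columns=_KNOWLEDGE_COLS).to_csv(path, index=False)


def read_knowledge(path: str | Path) -> list[KnowledgeVector]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in ("participant_id", "test", "phase") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    qcols = [c for c in df.columns if c.startswith("q")]
    if len(qcols) != N_ITEMS:
        raise FormatError(f"{path}: expected {N_ITEMS} item columns, found {len(qcols)}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(KnowledgeVector(str(row["participant_id"]), str(row["test"]),
                                       str(row["phase"]), row[qcols].to_numpy()))
        except FormatError as exc:
            raise FormatError(f"{path}: line {i + 2}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def write_manifest(data: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
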