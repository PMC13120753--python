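"""Data model and on-disk layout for interview sessions.

A corpus is a directory with one sub-directory per session containing
``transcript.csv`` plus zero or more per-frame feature tables named
``<channel>.csv`` (channels: mfcc, egemaps, gaze, pose, au), and a top-level
``manifest.csv`` listing ``session_id,split,phq8``. All tables are RFC-4180
CSV with a header row; times are seconds; intervals are half-open
``[start, stop)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("depfuse.session_model")

PHQ_CUTOFF = 10
PHQ_MIN, PHQ_MAX = 0, 24

AUDIO_CHANNELS = ("mfcc", "egemaps")
VISUAL_CHANNELS = ("gaze", "pose", "au")
CHANNELS = AUDIO_CHANNELS + VISUAL_CHANNELS

SPEAKERS = ("participant", "agent")
SPLITS = ("train", "dev", "test")
LABEL_SOURCES = ("measured", "threshold_approximated", "synthetic")

DEPRESSED, CONTROL = "depressed", "control"


class SchemaError(ValueError):
    """A table is missing a required column or has an unparsable cell."""


class EmptySessionError(ValueError):
    """A session directory holds neither a transcript nor any channel."""


class LeakageError(ValueError):
    """A dev/test session reached a train-only procedure."""


class LabelError(ValueError):
    """PHQ-8 / binary labels violate the cutoff contract."""


@dataclass
class Utterance:
    speaker: str
    start_time: float
    stop_time: float
    text: str

    def __post_init__(self):
        if self.speaker not in SPEAKERS:
            log.warning("unknown speaker %r mapped to 'agent'", self.speaker)
            self.speaker = "agent"
        if self.start_time < 0:
            raise ValueError(f"negative start_time {self.start_time}")
        if self.stop_time < self.start_time:
            raise ValueError(
                f"stop_time {self.stop_time} < start_time {self.start_time}"
            )
        if not self.text.strip():
            raise ValueError("utterance text empty after stripping")


@dataclass
class Transcript:
    utterances: list[Utterance] = field(default_factory=list)

    def __post_init__(self):
        starts = [u.start_time for u in self.utterances]
        if any(b < a for a, b in zip(starts, starts[1:])):
            log.warning("transcript start_times not sorted; sorting")
            self.utterances = sorted(self.utterances, key=lambda u: u.start_time)

    def __len__(self):
        return len(self.utterances)

    def participant_utterances(self) -> list[Utterance]:
        return [u for u in self.utterances if u.speaker == "participant"]


@dataclass
class FrameSeries:
    """Per-frame features for one channel: strictly increasing times, n x d values."""

    channel: str
    times: np.ndarray
    values: np.ndarray
    feature_names: list[str]

    def __post_init__(self):
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or len(self.times) != self.values.shape[0]:
            raise ValueError("times and values lengths disagree")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length != value columns")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError(f"times not strictly increasing in {self.channel}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in {self.channel}")

    @property
    def n(self) -> int:
        return len(self.times)

    @property
    def d(self) -> int:
        return self.values.shape[1]


@dataclass
class Labels:
    phq8: int | None = None
    binary: str | None = None
    label_source: str = "measured"

    def __post_init__(self):
        if self.label_source not in LABEL_SOURCES:
            raise ValueError(f"unknown label_source {self.label_source!r}")
        if self.phq8 is not None:
            self.phq8 = int(self.phq8)
            if not PHQ_MIN <= self.phq8 <= PHQ_MAX:
                raise LabelError(f"phq8 {self.phq8} outside [{PHQ_MIN},{PHQ_MAX}]")
            implied = DEPRESSED if self.phq8 >= PHQ_CUTOFF else CONTROL
            if self.binary is None:
                self.binary = implied
            elif self.binary != implied:
                raise LabelError(
                    f"binary {self.binary!r} inconsistent with phq8={self.phq8} "
                    f"under cutoff >= {PHQ_CUTOFF}"
                )
        if self.binary is not None and self.binary not in (DEPRESSED, CONTROL):
            raise LabelError(f"unknown binary label {self.binary!r}")


@dataclass
class Session:
    session_id: str
    split: str
    transcript: Transcript = field(default_factory=Transcript)
    channels: dict[str, FrameSeries] = field(default_factory=dict)
    labels: Labels = field(default_factory=Labels)
    provenance: dict | None = None  # e.g. {"source_id", "generator", "seed"}

    def __post_init__(self):
        if self.split not in SPLITS:
            raise ValueError(f"unknown split {self.split!r}")
        if len(self.transcript) == 0 and not self.channels:
            raise EmptySessionError(f"session {self.session_id}: no transcript, no channels")


# ---------------------------------------------------------------------------
# readers / writers

_TRANSCRIPT_COLS = ("start_time", "stop_time", "speaker", "text")


def read_transcript(path: str | Path) -> Transcript:
    """Read a transcript CSV; rows with empty text are dropped and counted."""
    df = pd.read_csv(path, dtype={"speaker": str, "text": str}, keep_default_na=False)
    for col in _TRANSCRIPT_COLS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    for col in ("start_time", "stop_time"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        if parsed.isna().any():
            row = int(parsed.isna().idxmax())
            raise SchemaError(f"{path}: non-numeric {col} at row {row}")
        df[col] = parsed
    empty = df["text"].str.strip() == ""
    if empty.any():
        log.info("%s: dropped %d empty-text rows", path, int(empty.sum()))
        df = df[~empty]
    utts = [
        Utterance(r.speaker, float(r.start_time), float(r.stop_time), r.text)
        for r in df.itertuples()
    ]
    return Transcript(utts)


def write_transcript(transcript: Transcript, path: str | Path) -> None:
    pd.DataFrame(
        {
            "start_time": [u.start_time for u in transcript.utterances],
            "stop_time": [u.stop_time for u in transcript.utterances],
            "speaker": [u.speaker for u in transcript.utterances],
            "text": [u.text for u in transcript.utterances],
        }
    ).to_csv(path, index=False)


def read_frame_table(path: str | Path, channel: str) -> FrameSeries:
    """Read a frame table (first column timestamp); non-finite rows dropped."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: need a timestamp column plus >=1 feature column")
    arr = df.to_numpy(dtype=float)
    times, values = arr[:, 0], arr[:, 1:]
    finite = np.isfinite(values).all(axis=1) & np.isfinite(times)
    n_drop = int((~finite).sum())
    if n_drop:
        log.info("%s: dropped %d non-finite rows", path, n_drop)
        times, values = times[finite], values[finite]
    if len(times) == 0:
        raise SchemaError(f"{path}: zero usable rows")
    dup = np.flatnonzero(np.diff(np.sort(times)) == 0)
    if dup.size:
        raise SchemaError(
            f"{path}: duplicate timestamp {np.sort(times)[dup[0]]:.6f}"
        )
    order = np.argsort(times)
    return FrameSeries(channel, times[order], values[order], list(df.columns[1:]))


def write_frame_table(series: FrameSeries, path: str | Path) -> None:
    df = pd.DataFrame(series.values, columns=series.feature_names)
    df.insert(0, "timestamp", series.times)
    df.to_csv(path, index=False, float_format="%.9g")


def load_session(directory: str | Path, session_id: str, split: str,
                 labels: Labels | None = None) -> Session:
    """Load one session directory; absent channel files are simply missing."""
    directory = Path(directory)
    tpath = directory / "transcript.csv"
    transcript = read_transcript(tpath) if tpath.exists() else Transcript()
    channels = {}
    for ch in CHANNELS:
        cpath = directory / f"{ch}.csv"
        if cpath.exists():
            channels[ch] = read_frame_table(cpath, ch)
    return Session(session_id, split, transcript, channels, labels or Labels())


def save_session(session: Session, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if len(session.transcript):
        write_transcript(session.transcript, directory / "transcript.csv")
    for ch, series in session.channels.items():
        write_frame_table(series, directory / f"{ch}.csv")


def save_corpus(sessions: list[Session], root: str | Path) -> None:
    """Write sessions plus ``manifest.csv`` (session_id, split, phq8, ...)."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in sessions:
        save_session(s, root / s.session_id)
        rows.append(
            {
                "session_id": s.session_id,
                "split": s.split,
                "phq8": "" if s.labels.phq8 is None else s.labels.phq8,
                "binary": s.labels.binary or "",
                "label_source": s.labels.label_source,
                "source_id": (s.provenance or {}).get("source_id", ""),
            }
        )
    pd.DataFrame(rows).to_csv(root / "manifest.csv", index=False)


def load_corpus(root: str | Path) -> list[Session]:
    root = Path(root)
    manifest = pd.read_csv(root / "manifest.csv", keep_default_na=False)
    sessions = []
    for r in manifest.itertuples():
        phq8 = None if r.phq8 == "" else int(r.phq8)
        source = getattr(r, "label_source", "measured") or "measured"
        labels = Labels(phq8=phq8, label_source=source)
        s = load_session(root / r.session_id, r.session_id, r.split, labels)
        src = getattr(r, "source_id", "")
        if src:
            s.provenance = {"source_id": src}
        sessions.append(s)
    return sessions
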