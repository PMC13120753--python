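"""Training-data augmentation: social-post conversion and paraphrase synthesis.

Two procedures expand the training split only:

* ``post_to_session`` turns a binary-labelled social-media post into an
  interview-style session: sentences become participant utterances on
  consecutive 3-second slots, and the PHQ-8 label is threshold-approximated
  (depressed -> 10, control -> 0).
* ``paraphrase_session`` rewrites a training session's participant
  utterances through a pluggable paraphraser, rescales utterance timing in
  proportion to the new token counts and resamples the original acoustic/
  visual frames (with replacement, per window) onto the new timeline.

Both raise a leakage error for dev/test inputs, and every synthetic session
carries provenance so an augmented corpus can be audited.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .feature_encoding import DEFAULT_WINDOW_LENGTH, tokenize
from .session_model import (
    CONTROL,
    DEPRESSED,
    FrameSeries,
    Labels,
    LeakageError,
    Session,
    Transcript,
    Utterance,
)
from .synthetic_data import NEGATIVE_LEXICON

log = logging.getLogger("depfuse.augmentation")

#: threshold-approximated PHQ-8 labels for binary-only corpora
THRESHOLD_LABEL_MAP = {DEPRESSED: 10, CONTROL: 0}

#: affect-bearing words a paraphrase must never rewrite
SENTIMENT_KEYWORDS = frozenset(NEGATIVE_LEXICON) | {
    "happy", "hopeful", "calm", "cheerful", "content",
}


@dataclass
class SocialPost:
    post_id: str
    text: str
    binary_label: str

    def __post_init__(self):
        if not self.text.strip():
            raise ValueError("post text must be non-empty")
        if self.binary_label not in THRESHOLD_LABEL_MAP:
            raise ValueError(f"unknown label {self.binary_label!r}")


def read_posts(path: str | Path) -> list[SocialPost]:
    """CSV with columns post_id, label, text."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [SocialPost(r.post_id, r.text, r.label) for r in df.itertuples()]


# ---------------------------------------------------------------------------
# sentence segmentation

_ABBREVIATIONS = {"mr", "mrs", "ms", "dr", "prof", "st", "vs", "etc", "eg", "ie",
                  "e.g", "i.e", "no"}
_BOUNDARY = re.compile(r"(?<=[.!?])\s+")


def segment_post(post: SocialPost) -> list[str]:
    """Split a post into response-style utterances at sentence boundaries.

    Rule-based: terminal punctuation followed by whitespace ends a sentence
    unless the preceding token is a known abbreviation. Joining the segments
    with single spaces conserves the token stream; a post with no boundary
    is one utterance.
    """
    text = " ".join(post.text.split())
    pieces, buf = [], ""
    for chunk in _BOUNDARY.split(text):
        buf = f"{buf} {chunk}".strip() if buf else chunk
        last = buf.rstrip(".!?").rsplit(" ", 1)[-1].lower().rstrip(".")
        if last in _ABBREVIATIONS:
            continue  # boundary was after an abbreviation; keep accumulating
        pieces.append(buf)
        buf = ""
    if buf:
        pieces.append(buf)
    return pieces or [text]


def post_to_session(post: SocialPost,
                    window_length: float = DEFAULT_WINDOW_LENGTH) -> Session:
    """Interview-style training session from a social post.

    Utterances sit on consecutive fixed windows; the session carries no
    acoustic/visual series, so every nonverbal presence mask is set
    downstream. Labels follow the threshold map (depressed -> PHQ-8 10,
    control -> 0) with ``label_source='threshold_approximated'``.
    """
    texts = segment_post(post)
    utterances = [
        Utterance("participant", i * window_length, (i + 1) * window_length, t)
        for i, t in enumerate(texts)
    ]
    phq8 = THRESHOLD_LABEL_MAP[post.binary_label]
    return Session(
        session_id=f"post-{post.post_id}",
        split="train",
        transcript=Transcript(utterances),
        channels={},
        labels=Labels(phq8=phq8, label_source="threshold_approximated"),
        provenance={"source_id": post.post_id, "generator": "post_to_session"},
    )


# ---------------------------------------------------------------------------
# paraphrase-based multimodal synthesis

class MockParaphraser:
    """Deterministic offline paraphraser: synonym table + clause reordering.

    Words in :data:`SENTIMENT_KEYWORDS` are never substituted, so the
    affective content that carries the label survives the rewrite.
    """

    _SYNONYMS = {
        "really": "truly", "week": "stretch", "work": "my job",
        "people": "others", "usually": "typically", "feel": "sense",
        "feeling": "sensing", "recently": "of late", "lately": "these days",
        "most": "nearly all", "say": "state", "talking": "speaking",
        "mornings": "early hours", "evenings": "late hours", "home": "my place",
        "seems": "appears", "everything": "it all", "mood": "state of mind",
    }

    def __init__(self, seed: int = 0):
        self.seed = seed
        self.name = f"mock-paraphraser-{seed}"

    def paraphrase(self, text: str) -> str:
        words = text.split()
        out = []
        for w in words:
            key = w.lower().strip(".,!?")
            if key in SENTIMENT_KEYWORDS:
                out.append(w)
            else:
                out.append(self._SYNONYMS.get(key, w))
        # deterministic clause swap keyed on content + seed
        joined = " ".join(out)
        if "," in joined:
            head, tail = joined.split(",", 1)
            if (len(joined) + self.seed) % 2 == 0:
                joined = f"{tail.strip()}, {head.strip()}"
        return joined


def mock_paraphraser(seed: int = 0) -> MockParaphraser:
    return MockParaphraser(seed)


def paraphrase_session(original: Session, paraphraser, seed: int = 0,
                       resample: str = "within-window",
                       window_length: float = DEFAULT_WINDOW_LENGTH) -> Session:
    """Synthetic multimodal session from a training session.

    Participant texts are replaced by the paraphraser; utterance durations
    are rescaled in proportion to the paraphrase token counts; each channel
    is rebuilt by resampling the original frames with replacement (within
    the corresponding window, or from the whole session with
    ``resample='whole-session'``) onto the new timeline. Labels are copied
    verbatim; dev/test input is a leakage error.
    """
    if original.split != "train":
        raise LeakageError(
            f"paraphrase augmentation refused for split={original.split!r} "
            f"session {original.session_id}"
        )
    if resample not in ("within-window", "whole-session"):
        raise ValueError(f"unknown resample strategy {resample!r}")
    rng = np.random.default_rng(seed)

    new_utts: list[Utterance] = []
    t = 0.0
    scale_total_old = 0.0
    for u in original.transcript.utterances:
        dur = u.stop_time - u.start_time
        if u.speaker == "participant":
            new_text = paraphraser.paraphrase(u.text)
            if not new_text.strip():
                log.warning("paraphraser returned empty text for %s; session skipped",
                            original.session_id)
                raise ValueError("paraphraser produced empty output")
            n_old = max(len(tokenize(u.text)), 1)
            n_new = max(len(tokenize(new_text)), 1)
            dur = dur * n_new / n_old
            text = new_text
        else:
            text = u.text
        new_utts.append(Utterance(u.speaker, t, t + dur, text))
        t += dur
        scale_total_old = max(scale_total_old, u.stop_time)

    new_duration = t
    channels: dict[str, FrameSeries] = {}
    for ch, series in original.channels.items():
        if series.n < 2:
            continue
        old_duration = series.times[-1]
        rate = series.n / max(old_duration, 1e-9)
        new_times = np.arange(0.0, new_duration, 1.0 / rate)
        values = np.empty((len(new_times), series.d))
        if resample == "whole-session":
            idx = rng.integers(0, series.n, len(new_times))
            values = series.values[idx]
        else:
            time_scale = old_duration / max(new_duration, 1e-9)
            for w0 in range(int(new_times[-1] // window_length) + 1 if len(new_times) else 0):
                sel = (new_times >= w0 * window_length) & (
                    new_times < (w0 + 1) * window_length
                )
                if not sel.any():
                    continue
                src_start = w0 * window_length * time_scale
                src_stop = (w0 + 1) * window_length * time_scale
                i0 = int(np.searchsorted(series.times, src_start, side="left"))
                i1 = int(np.searchsorted(series.times, src_stop, side="left"))
                if i1 <= i0:  # empty source window: fall back to whole session
                    i0, i1 = 0, series.n
                idx = rng.integers(i0, i1, int(sel.sum()))
                values[sel] = series.values[idx]
        channels[ch] = FrameSeries(ch, new_times, values, list(series.feature_names))

    return Session(
        session_id=f"{original.session_id}-syn{seed}",
        split="train",
        transcript=Transcript(new_utts),
        channels=channels,
        labels=Labels(phq8=original.labels.phq8,
                      binary=original.labels.binary,
                      label_source="synthetic"),
        provenance={"source_id": original.session_id,
                    "generator": paraphraser.name, "seed": seed},
    )


def audit_corpus(sessions: list[Session]) -> list[str]:
    """Leakage audit: source ids of synthetic sessions must all be train ids.

    Returns the offending session ids (empty list = clean corpus).
    """
    split_of = {s.session_id: s.split for s in sessions}
    offenders = []
    for s in sessions:
        src = (s.provenance or {}).get("source_id")
        if src is None:
            continue
        if split_of.get(src, "train") != "train":
            offenders.append(s.session_id)
    return offenders
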