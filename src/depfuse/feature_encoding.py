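"""Temporal windowing, bag-of-words codebooks and text embedding.

Variable-length acoustic/visual frame sequences become fixed-size
distributional vectors per 3-second window: frames are assigned to the
nearest centroid of a channel-specific codebook learned by k-means on the
training split, and each window is represented by its L1-normalised
assignment histogram (bag-of-audio-words / bag-of-visual-words). Transcript
text is embedded per window at word and sentence level through a pluggable
encoder; a deterministic hash encoder is provided so the whole pipeline runs
without pretrained weights.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .session_model import CHANNELS, LeakageError, Session

log = logging.getLogger("depfuse.feature_encoding")

DEFAULT_WINDOW_LENGTH = 3.0  # seconds; the global alignment clock
DEFAULT_CODEBOOK_K = 100
DEFAULT_MAX_TOKENS = 32

_TOKEN_RE = re.compile(r"[a-z']+")


def tokenize(text: str) -> list[str]:
    return _TOKEN_RE.findall(text.lower())


# ---------------------------------------------------------------------------
# windowing

@dataclass
class Window:
    start: float
    stop: float
    #: channel -> (first_frame_index, one_past_last_frame_index)
    frame_ranges: dict[str, tuple[int, int]]
    utterance_indices: list[int]


def align_windows(session: Session,
                  window_length: float = DEFAULT_WINDOW_LENGTH,
                  include_agent: bool = False) -> list[Window]:
    """Tile the session timeline into half-open fixed-length windows.

    Windows cover ``[0, T)`` where T bounds the last timestamp seen in any
    channel or utterance; the final partial window is kept. An utterance
    belongs to the window containing its start time.
    """
    if window_length <= 0:
        raise ValueError("window_length must be positive")
    last = -np.inf
    for series in session.channels.values():
        if series.n:
            last = max(last, series.times[-1])
    utts = [
        (i, u) for i, u in enumerate(session.transcript.utterances)
        if include_agent or u.speaker == "participant"
    ]
    for _, u in utts:
        last = max(last, u.start_time)
    if not np.isfinite(last):
        return []
    n_windows = int(last // window_length) + 1

    windows = []
    for w in range(n_windows):
        start, stop = w * window_length, (w + 1) * window_length
        final = w == n_windows - 1
        ranges = {}
        for ch, series in session.channels.items():
            i0 = int(np.searchsorted(series.times, start, side="left"))
            # the final window absorbs any frame pushed onto its stop
            # boundary by floating-point accumulation
            i1 = series.n if final else int(
                np.searchsorted(series.times, stop, side="left")
            )
            ranges[ch] = (i0, i1)
        idx = [i for i, u in utts
               if start <= u.start_time and (final or u.start_time < stop)]
        windows.append(Window(start, stop, ranges, idx))
    return windows


# ---------------------------------------------------------------------------
# codebooks

@dataclass
class Codebook:
    channel: str
    k: int
    centroids: np.ndarray  # k x d
    trained_on: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.k < 1 or self.centroids.shape[0] != self.k:
            raise ValueError("centroid count must equal k >= 1")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be finite")

    @property
    def d(self) -> int:
        return self.centroids.shape[1]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "channel": self.channel, "k": self.k,
            "centroids": self.centroids.tolist(),
            "trained_on": self.trained_on,
        }))

    @classmethod
    def load(cls, path: str | Path) -> "Codebook":
        obj = json.loads(Path(path).read_text())
        return cls(obj["channel"], obj["k"], np.array(obj["centroids"]),
                   obj["trained_on"])


def learn_codebook(sessions: list[Session], channel: str, k: int = DEFAULT_CODEBOOK_K,
                   seed: int = 0, max_frames: int = 20000) -> Codebook:
    """k-means codebook on frames pooled over training-split sessions.

    Rejects any non-train session outright (leakage guard). Pooled frames
    are subsampled to ``max_frames`` (seeded) before clustering; k-means
    uses k-means++ initialisation, 300 max iterations, tolerance 1e-4.
    """
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}")
    bad = [s.session_id for s in sessions if s.split != "train"]
    if bad:
        raise LeakageError(
            f"codebook for {channel!r} offered non-train sessions: {bad[:5]}"
        )
    pools, trained_on = [], []
    for s in sessions:
        series = s.channels.get(channel)
        if series is not None and series.n:
            pools.append(series.values)
            trained_on.append(s.session_id)
    pooled = np.concatenate(pools, axis=0) if pools else np.empty((0, 0))
    if pooled.shape[0] < k:
        raise ValueError(
            f"channel {channel!r}: {pooled.shape[0]} pooled frames < k={k}"
        )
    if pooled.shape[0] > max_frames:
        idx = np.random.default_rng(seed).choice(
            pooled.shape[0], size=max_frames, replace=False
        )
        pooled = pooled[idx]
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, max_iter=300,
                tol=1e-4, random_state=seed)
    km.fit(pooled)
    return Codebook(channel, k, km.cluster_centers_, trained_on)


def quantize(frames: np.ndarray, codebook: Codebook,
             raw_counts: bool = False) -> np.ndarray:
    """Nearest-centroid histogram of a frame block (ties -> lowest index)."""
    frames = np.asarray(frames, dtype=float)
    if frames.size == 0:
        return np.zeros(codebook.k)
    if frames.ndim != 2 or frames.shape[1] != codebook.d:
        raise ValueError(
            f"frame dim {frames.shape[-1]} != codebook dim {codebook.d}"
        )
    assign = np.argmin(cdist(frames, codebook.centroids), axis=1)
    counts = np.bincount(assign, minlength=codebook.k).astype(float)
    return counts if raw_counts else counts / counts.sum()


# ---------------------------------------------------------------------------
# text encoders

class HashTextEncoder:
    """Deterministic token-hash embeddings; a stand-in for pretrained encoders.

    Each token's vector is drawn from a generator seeded by a stable hash of
    (token, seed), so identical tokens always map to identical vectors and
    different seeds give different embeddings. The sentence vector is the
    mean of the word vectors (projected if d_s != d_w).
    """

    def __init__(self, d_w: int = 32, d_s: int = 32, seed: int = 0):
        if d_w < 1 or d_s < 1:
            raise ValueError("embedding dims must be >= 1")
        self.d_w, self.d_s, self.seed = d_w, d_s, seed
        self.name = f"hash-{d_w}x{d_s}-{seed}"
        if d_s != d_w:
            rng = np.random.default_rng(seed + 1)
            self._proj = rng.normal(0, 1 / np.sqrt(d_w), (d_w, d_s))
        else:
            self._proj = None
        self._cache: dict[str, np.ndarray] = {}

    def _token_vector(self, token: str) -> np.ndarray:
        vec = self._cache.get(token)
        if vec is None:
            digest = hashlib.blake2b(
                f"{self.seed}:{token}".encode(), digest_size=8
            ).digest()
            rng = np.random.default_rng(int.from_bytes(digest, "big") % (2**63))
            vec = rng.standard_normal(self.d_w)
            self._cache[token] = vec
        return vec

    def embed_words(self, text: str) -> np.ndarray:
        tokens = tokenize(text)
        if not tokens:
            return np.zeros((0, self.d_w))
        return np.stack([self._token_vector(t) for t in tokens])

    def embed_sentence(self, text: str) -> np.ndarray:
        words = self.embed_words(text)
        if words.shape[0] == 0:
            return np.zeros(self.d_s)
        mean = words.mean(axis=0)
        return mean if self._proj is None else mean @ self._proj


def hash_text_encoder(d_w: int = 32, d_s: int = 32, seed: int = 0) -> HashTextEncoder:
    return HashTextEncoder(d_w, d_s, seed)


# ---------------------------------------------------------------------------
# session encoding

@dataclass
class WindowSequence:
    """Aligned per-window multimodal features for one session."""

    session_id: str
    window_length: float
    n_windows: int
    histograms: dict[str, np.ndarray]  # channel -> (n_windows, k)
    hist_mask: dict[str, np.ndarray]  # channel -> (n_windows,) bool
    word_emb: np.ndarray  # (n_windows, max_tokens, d_w)
    word_mask: np.ndarray  # (n_windows, max_tokens) bool
    sent_emb: np.ndarray  # (n_windows, d_s)
    sent_mask: np.ndarray  # (n_windows,) bool
    normalized: bool = True  # False when histograms hold raw counts

    def __post_init__(self):
        if not self.normalized:
            return
        for ch, h in self.histograms.items():
            nonempty = self.hist_mask[ch]
            sums = h[nonempty].sum(axis=1) if nonempty.any() else np.array([])
            if sums.size and np.any(np.abs(sums - 1.0) > 1e-9):
                raise ValueError(f"histograms for {ch} not normalised")


def encode_session(session: Session, codebooks: dict[str, Codebook],
                   text_encoder, window_length: float = DEFAULT_WINDOW_LENGTH,
                   max_tokens: int = DEFAULT_MAX_TOKENS,
                   include_agent: bool = False,
                   raw_counts: bool = False,
                   per_session: bool = False) -> WindowSequence:
    """Encode one session into per-window histograms and text embeddings.

    ``per_session=True`` collapses the whole session into a single window
    (one histogram per channel over all frames), the per-sequence variant
    of the bag-of-words representation.
    """
    missing = [ch for ch in session.channels if ch not in codebooks]
    if missing:
        raise ValueError(f"no codebook for present channels {missing}")
    if per_session:
        window_length = 1e12  # one window spanning the whole session
    windows = align_windows(session, window_length, include_agent=include_agent)
    n = len(windows)

    d_w, d_s = text_encoder.d_w, text_encoder.d_s
    histograms = {ch: np.zeros((n, cb.k)) for ch, cb in codebooks.items()}
    hist_mask = {ch: np.zeros(n, dtype=bool) for ch in codebooks}
    word_emb = np.zeros((n, max_tokens, d_w))
    word_mask = np.zeros((n, max_tokens), dtype=bool)
    sent_emb = np.zeros((n, d_s))
    sent_mask = np.zeros(n, dtype=bool)

    utterances = session.transcript.utterances
    for w, window in enumerate(windows):
        for ch, cb in codebooks.items():
            series = session.channels.get(ch)
            if series is None:
                continue
            i0, i1 = window.frame_ranges[ch]
            if i1 > i0:
                try:
                    histograms[ch][w] = quantize(
                        series.values[i0:i1], cb, raw_counts=raw_counts
                    )
                except ValueError as exc:
                    raise ValueError(f"window {w}: {exc}") from exc
                hist_mask[ch][w] = True
        texts = [utterances[i].text for i in window.utterance_indices]
        if texts:
            joined = " ".join(texts)
            sent_emb[w] = text_encoder.embed_sentence(joined)
            sent_mask[w] = True
            words = text_encoder.embed_words(joined)[:max_tokens]
            word_emb[w, : words.shape[0]] = words
            word_mask[w, : words.shape[0]] = True

    return WindowSequence(session.session_id, window_length, n, histograms,
                          hist_mask, word_emb, word_mask, sent_emb, sent_mask,
                          normalized=not raw_counts)
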