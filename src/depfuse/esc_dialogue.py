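"""Emotion-aware dialogue layer: ESC stage selection and response generation.

The emotional-support-conversation (ESC) framework divides support into
three ordered stages — exploration (open up the topic), comfort (validate
and empathise), action (suggest concrete steps) — each with its own
strategy repertoire. Stage selection runs the backend classifier k times on
the last 10 conversational sentences at temperature 0.7 and takes the
plurality vote (self-consistency); ties break toward the earliest stage,
the safest default early in a support conversation. Response generation is
called once at temperature 0. Backends are pluggable; the deterministic
keyword-rule mock ships with the package so everything runs offline.
"""

from __future__ import annotations

import logging
from collections import Counter
from enum import IntEnum

import numpy as np

from .session_model import Transcript

log = logging.getLogger("depfuse.esc_dialogue")


class ESCStage(IntEnum):
    exploration = 0
    comfort = 1
    action = 2


STRATEGY_TABLE: dict[ESCStage, list[str]] = {
    ESCStage.exploration: [
        "questioning", "paraphrasing", "emotional reflection", "self-disclosure",
    ],
    ESCStage.comfort: [
        "emotional validation", "shared experiences", "supportive affirmations",
    ],
    ESCStage.action: [
        "suggestions", "practical information", "continued encouragement",
    ],
}

DEFAULT_CONTEXT_SENTENCES = 10
DEFAULT_VOTES = 5  # odd, to reduce ties
STAGE_TEMPERATURE = 0.7
GENERATION_TEMPERATURE = 0.0


class BackendError(RuntimeError):
    """The dialogue backend failed on every attempt."""


def extract_context(transcript: Transcript,
                    n: int = DEFAULT_CONTEXT_SENTENCES) -> list[str]:
    """Last ``n`` utterance texts, both speakers, in order."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [u.text for u in transcript.utterances[-n:]]


def select_stage(context: list[str], backend, k: int = DEFAULT_VOTES,
                 temperature: float = STAGE_TEMPERATURE,
                 seed: int = 0) -> tuple[ESCStage, Counter]:
    """Self-consistency stage selection: plurality over k classifications.

    Partial backend failures are logged and the vote runs over the
    successes; all-k failure raises :class:`BackendError`. Ties break by
    stage order (exploration < comfort < action).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    votes: Counter = Counter()
    failures = 0
    for i in range(k):
        try:
            stage = backend.classify_stage(context, temperature=temperature,
                                           seed=seed + i)
            votes[ESCStage(stage)] += 1
        except Exception as exc:  # backend contract: any failure is per-call
            failures += 1
            log.warning("stage vote %d/%d failed: %s", i + 1, k, exc)
    if not votes:
        raise BackendError(f"all {k} stage classifications failed")
    if failures:
        log.info("stage vote over %d/%d successful calls", k - failures, k)
    top = max(votes.values())
    winner = min(stage for stage, c in votes.items() if c == top)
    return winner, votes


def respond(context: list[str], backend,
            strategy_table: dict[ESCStage, list[str]] | None = None,
            k: int = DEFAULT_VOTES, seed: int = 0) -> tuple[ESCStage, str, str]:
    """Stage-conditioned empathetic response.

    The stage comes from :func:`select_stage`; the strategy is a seeded
    deterministic pick from the stage's repertoire; generation runs at
    temperature 0. An empty generation is retried once.
    """
    if not context:
        raise ValueError("context must be non-empty")
    table = strategy_table or STRATEGY_TABLE
    stage, _ = select_stage(context, backend, k=k, seed=seed)
    options = table[stage]
    pick = np.random.default_rng(
        (seed * 1_000_003 + sum(map(len, context))) % (2**31)
    ).integers(len(options))
    strategy = options[int(pick)]
    for attempt in range(2):
        text = backend.generate(stage, strategy, context,
                                temperature=GENERATION_TEMPERATURE)
        if text and text.strip():
            return stage, strategy, text
        log.warning("empty generation (attempt %d)", attempt + 1)
    raise BackendError("backend produced empty responses twice")


# ---------------------------------------------------------------------------
# mock backend

DEFAULT_RULE_TABLE: dict[ESCStage, tuple[str, ...]] = {
    ESCStage.comfort: ("lonely", "sad", "hopeless", "crying", "miserable",
                       "worthless", "empty"),
    ESCStage.action: ("what should", "how can", "help me", "advice",
                      "plan", "fix"),
}


class MockDialogueBackend:
    """Keyword-rule stage classifier with seeded temperature-scaled noise.

    The rule stage is the first stage whose keyword list matches the
    context (comfort and action rules; anything unmatched defaults to
    exploration). Classification flips to a uniformly random stage with
    probability ``noise_rate * temperature`` — so temperature 0 is the pure
    rule. Generation is a deterministic template fill.
    """

    def __init__(self, rule_table: dict[ESCStage, tuple[str, ...]] | None = None,
                 noise_rate: float = 0.4, seed: int = 0):
        if not 0.0 <= noise_rate <= 1.0:
            raise ValueError("noise_rate must be in [0,1]")
        self.rule_table = rule_table or DEFAULT_RULE_TABLE
        self.noise_rate = noise_rate
        self.seed = seed
        self.name = f"mock-esc-{seed}"

    def rule_stage(self, context: list[str]) -> ESCStage:
        blob = " ".join(context).lower()
        for stage in (ESCStage.comfort, ESCStage.action):
            if any(kw in blob for kw in self.rule_table.get(stage, ())):
                return stage
        return ESCStage.exploration

    def classify_stage(self, context: list[str], temperature: float = 0.0,
                       seed: int = 0) -> ESCStage:
        stage = self.rule_stage(context)
        p_flip = self.noise_rate * temperature
        if p_flip > 0.0:
            rng = np.random.default_rng(
                (self.seed * 2_654_435_761 + seed) % (2**31)
            )
            if rng.random() < p_flip:
                stage = ESCStage(int(rng.integers(3)))
        return stage

    def generate(self, stage: ESCStage, strategy: str, context: list[str],
                 temperature: float = 0.0) -> str:
        last = context[-1] if context else ""
        return (f"[{ESCStage(stage).name}/{strategy}] I hear you when you say "
                f"\"{last}\" — let's stay with that together.")


def mock_backend(rule_table: dict[ESCStage, tuple[str, ...]] | None = None,
                 noise_rate: float = 0.4, seed: int = 0) -> MockDialogueBackend:
    return MockDialogueBackend(rule_table, noise_rate, seed)
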