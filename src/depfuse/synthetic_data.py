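"""Synthetic interview cohorts with controllable depression effects.

Generates sessions in the on-disk layout of :mod:`depfuse.session_model`:
a transcript of templated utterances and Gaussian per-frame feature series
for the five channels (mfcc, egemaps, gaze, pose, au). Depression shows up
the way the screening literature describes it: depressed speakers draw more
from a negative-affect lexicon (graded with PHQ-8 severity), show reduced
acoustic variability, and reduced facial action-unit intensity. Effect sizes
are dials so tests can span "no effect" to "cleanly separable".

Group-conditional PHQ-8 scores follow the clinical benchmark statistics:
nondepressed mean 3.36 (SD 3.04), depressed mean 15.50 (SD 3.76), truncated
so every label is consistent with the >=10 cutoff (real cohorts are messier;
this is a deliberate fidelity limit of the generator).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .session_model import (
    CONTROL,
    DEPRESSED,
    PHQ_CUTOFF,
    FrameSeries,
    Labels,
    Session,
    Transcript,
    Utterance,
    save_corpus,
)

log = logging.getLogger("depfuse.synthetic_data")

#: words signalling negative affect; sampling weight grows with PHQ-8
NEGATIVE_LEXICON = (
    "tired exhausted hopeless empty sad lonely worthless numb anxious "
    "drained miserable restless guilty overwhelmed heavy dark tearful"
).split()

#: neutral / positive everyday vocabulary
NEUTRAL_LEXICON = (
    "fine good okay busy calm cheerful relaxed productive social content "
    "steady hopeful energetic curious settled bright motivated"
).split()

_TEMPLATES = (
    "I have been feeling {w} and {w2} most days, kind of {w3}",
    "Lately everything seems {w} to me, {w2} and {w3}",
    "My week at work felt {w}, mostly {w2} and {w3}",
    "Sleeping has been {w} and {w2} recently, I wake up {w3}",
    "Talking to people makes me feel {w}, even {w2} or {w3}",
    "Mornings are the most {w} part, I start out {w2} and {w3}",
    "I would say my mood is {w} overall, somewhere between {w2} and {w3}",
    "Evenings at home have felt {w} and {w2}, often {w3}",
)

_AGENT_PROMPTS = (
    "How have you been feeling lately?",
    "Can you tell me more about that?",
    "What has your sleep been like?",
    "How are things at work or school?",
    "Who do you usually spend time with?",
    "What do you do to relax?",
)

DEFAULT_CHANNEL_DIMS = {"mfcc": 39, "egemaps": 23, "gaze": 8, "pose": 6, "au": 17}
AUDIO_FRAME_RATE = 100.0  # Hz, typical acoustic LLD extractor rate
VISUAL_FRAME_RATE = 30.0  # Hz, typical video frame rate


@dataclass
class GeneratorConfig:
    n_sessions: int = 100
    prevalence: float = 8 / 22  # depressed fraction observed in field data
    phq_mean_control: float = 3.36
    phq_sd_control: float = 3.04
    phq_mean_depressed: float = 15.50
    phq_sd_depressed: float = 3.76
    n_utterances: int = 12  # participant utterances per session (>= 10)
    channel_dims: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_DIMS)
    )
    text_lexical_shift: float = 1.0  # 0 = no lexical depression signal
    audio_variability_shift: float = 0.8  # log-sigma reduction, depressed
    au_activity_shift: float = 0.8  # AU mean-intensity reduction, depressed
    #: SD of the per-session speaker effect (shared scalar per channel):
    #: log-sigma offset for acoustic channels, mean offset for visual ones.
    #: Individual variability unrelated to depression is what makes the
    #: nonverbal modalities auxiliary rather than decisive.
    speaker_variability: float = 0.3
    split_fracs: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must be in [0,1]")
        if min(self.phq_sd_control, self.phq_sd_depressed) <= 0:
            raise ValueError("PHQ SDs must be positive")
        if any(d < 1 for d in self.channel_dims.values()):
            raise ValueError("channel dims must be >= 1")
        if abs(sum(self.split_fracs) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def separable_config(n_sessions: int = 100, seed: int = 0,
                     split_fracs: tuple[float, float, float] = (0.8, 0.2, 0.0)
                     ) -> GeneratorConfig:
    """Canonical strongly separable cohort: large effects in every modality.

    The reference condition for end-to-end learnability experiments.
    """
    return GeneratorConfig(
        n_sessions=n_sessions, seed=seed, split_fracs=split_fracs,
        text_lexical_shift=1.5, audio_variability_shift=1.5,
        au_activity_shift=1.5,
    )


def text_dominant_config(n_sessions: int = 60, seed: int = 0,
                         split_fracs: tuple[float, float, float] = (0.7, 0.3, 0.0)
                         ) -> GeneratorConfig:
    """Canonical text-dominant cohort for modality-ablation experiments.

    A large lexical effect with barely informative nonverbal shifts, the
    configuration under which knocking out text should hurt most.
    """
    return GeneratorConfig(
        n_sessions=n_sessions, seed=seed, split_fracs=split_fracs,
        text_lexical_shift=1.5, audio_variability_shift=0.15,
        au_activity_shift=0.15,
    )


def sample_phq(group: str, config: GeneratorConfig, rng: np.random.Generator) -> int:
    """Draw a PHQ-8 score for a group; truncated so labels respect the cutoff."""
    if group == DEPRESSED:
        raw = rng.normal(config.phq_mean_depressed, config.phq_sd_depressed)
        return int(np.clip(np.round(raw), PHQ_CUTOFF, 24))
    if group == CONTROL:
        raw = rng.normal(config.phq_mean_control, config.phq_sd_control)
        return int(np.clip(np.round(raw), 0, PHQ_CUTOFF - 1))
    raise ValueError(f"unknown group {group!r}")


def _negative_word_prob(phq8: int, shift: float) -> float:
    """Probability an affect slot is filled from the negative lexicon."""
    return float(np.clip(0.15 + shift * 0.8 * (phq8 / 24.0), 0.0, 0.95))


def _make_transcript(phq8: int, config: GeneratorConfig,
                     rng: np.random.Generator) -> Transcript:
    p_neg = _negative_word_prob(phq8, config.text_lexical_shift)

    def affect_word() -> str:
        lex = NEGATIVE_LEXICON if rng.random() < p_neg else NEUTRAL_LEXICON
        return lex[rng.integers(len(lex))]

    utterances = []
    t = 0.0
    for _ in range(config.n_utterances):
        prompt = _AGENT_PROMPTS[rng.integers(len(_AGENT_PROMPTS))]
        utterances.append(Utterance("agent", t, t + 2.0, prompt))
        template = _TEMPLATES[rng.integers(len(_TEMPLATES))]
        text = template.format(w=affect_word(), w2=affect_word(), w3=affect_word())
        utterances.append(Utterance("participant", t + 2.0, t + 5.5, text))
        t += 6.0
    return Transcript(utterances)


def _feature_offsets(channel: str, d: int) -> np.ndarray:
    """Fixed per-feature baseline means, identical across sessions."""
    rng = np.random.default_rng(zlib.crc32(channel.encode()) % (2**31))
    return rng.normal(0.0, 1.0, d)


def generate_session(group: str, phq8: int, config: GeneratorConfig,
                     rng: np.random.Generator,
                     session_id: str = "synthetic", split: str = "train") -> Session:
    """One synthetic session; all session-model invariants hold by construction."""
    transcript = _make_transcript(phq8, config, rng)
    duration = 6.0 * config.n_utterances
    depressed = group == DEPRESSED

    channels: dict[str, FrameSeries] = {}
    for ch, d in config.channel_dims.items():
        rate = AUDIO_FRAME_RATE if ch in ("mfcc", "egemaps") else VISUAL_FRAME_RATE
        times = np.arange(0.0, duration, 1.0 / rate)
        base = _feature_offsets(ch, d)
        speaker = rng.normal(0.0, config.speaker_variability)  # per channel
        sigma = 1.0
        mean_shift = 0.0
        if ch in ("mfcc", "egemaps"):
            log_sigma = speaker
            if depressed:
                log_sigma -= config.audio_variability_shift
            sigma = float(np.exp(log_sigma))
        elif ch == "au":
            base = base + 1.0  # AU intensities sit above zero at baseline
            mean_shift = speaker
            if depressed:
                mean_shift -= config.au_activity_shift
        else:  # gaze / pose: speaker idiosyncrasy, no depression effect
            mean_shift = speaker
        values = rng.normal(base + mean_shift, sigma, (len(times), d))
        names = [f"{ch}_{j}" for j in range(d)]
        channels[ch] = FrameSeries(ch, times, values, names)

    labels = Labels(phq8=phq8, label_source="synthetic")
    return Session(session_id, split, transcript, channels, labels,
                   provenance={"generator": "synthetic_data", "phq8": phq8})


def _assign_splits(n: int, fracs: tuple[float, float, float],
                   rng: np.random.Generator) -> list[str]:
    n_train = int(round(n * fracs[0]))
    n_dev = int(round(n * fracs[1]))
    n_train = min(n_train, n)
    n_dev = min(n_dev, n - n_train)
    splits = ["train"] * n_train + ["dev"] * n_dev + ["test"] * (n - n_train - n_dev)
    order = rng.permutation(n)
    return [splits[i] for i in np.argsort(order)]


def generate_cohort(config: GeneratorConfig,
                    out_dir: str | Path | None = None
                    ) -> tuple[list[Session], pd.DataFrame]:
    """Generate ``n_sessions`` sessions plus a cohort manifest.

    The manifest records id, split, group, phq8 and the per-session
    generator seed. When ``out_dir`` is given the cohort is serialized in
    the session-model layout with the manifest at ``manifest.csv``.
    """
    if config.n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    rng = np.random.default_rng(config.seed)
    groups = [
        DEPRESSED if rng.random() < config.prevalence else CONTROL
        for _ in range(config.n_sessions)
    ]
    session_seeds = rng.integers(0, 2**31 - 1, config.n_sessions)
    splits = _assign_splits(config.n_sessions, config.split_fracs, rng)

    sessions, rows = [], []
    for i, (group, split, seed) in enumerate(zip(groups, splits, session_seeds)):
        srng = np.random.default_rng(int(seed))
        phq8 = sample_phq(group, config, srng)
        sid = f"S{i:04d}"
        s = generate_session(group, phq8, config, srng, session_id=sid, split=split)
        sessions.append(s)
        rows.append(
            {"session_id": sid, "split": split, "group": group,
             "phq8": phq8, "seed": int(seed)}
        )
    manifest = pd.DataFrame(rows)

    if out_dir is not None:
        out_dir = Path(out_dir)
        save_corpus(sessions, out_dir)
        base = pd.read_csv(out_dir / "manifest.csv", keep_default_na=False)
        merged = base.merge(manifest[["session_id", "group", "seed"]], on="session_id")
        merged.to_csv(out_dir / "manifest.csv", index=False)
        log.info("wrote %d sessions to %s", len(sessions), out_dir)
    return sessions, manifest
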