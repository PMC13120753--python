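"""Attention-based multimodal fusion with dual classification/regression heads.

Four per-window streams (sentence embeddings, word embeddings, audio
bag-of-words, visual bag-of-words) are z-scored with training-split
statistics, linearly projected into a shared d_model space, contextualised
by per-stream self-attention, aligned by text-to-nonverbal cross-attention,
masked-mean-pooled over windows and fed through a shared trunk into two
heads: a sigmoid head for the probability of clinical depression and a
linear head for the continuous PHQ-8 score.

Both heads apply a fixed output gain equal to the PHQ-8 range (24): the
heads produce unit-scale outputs which the gain maps to score/logit scale,
keeping weight magnitudes comparable across the network under the very
small Adam learning rate used for training. The regression head's bias is
initialised at mid-scale (0.5, i.e. a PHQ-8 of 12) and its final weights at
zero, so an untrained model predicts the centre of the scale and p = 0.5.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._autodiff import Tensor, softmax
from .feature_encoding import WindowSequence
from .session_model import AUDIO_CHANNELS, VISUAL_CHANNELS

log = logging.getLogger("depfuse.fusion_model")

STREAMS = ("sentence", "word", "audio", "visual")
NONVERBAL_STREAMS = ("audio", "visual")

PHQ_SCALE = 24.0


class BudgetError(ValueError):
    """Trainable parameter count exceeds the configured budget."""


class UninformativeInputError(ValueError):
    """Every stream of a session is fully masked."""


@dataclass
class FusionConfig:
    d_model: int = 64
    n_heads: int = 4
    n_self_layers: int = 1
    dropout: float = 0.1
    head_hidden: int = 32
    output_gain: float = PHQ_SCALE
    parameter_budget: int = 1_000_000
    seed: int = 0
    #: raw input width of each stream (k per BoW channel summed; d_w; d_s)
    stream_dims: dict[str, int] = field(
        default_factory=lambda: {"sentence": 32, "word": 32,
                                 "audio": 200, "visual": 300}
    )

    def __post_init__(self):
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0,1)")
        if set(self.stream_dims) != set(STREAMS):
            raise ValueError(f"stream_dims must cover exactly {STREAMS}")


@dataclass
class Prediction:
    p_depression: float
    phq8_raw: float

    @property
    def phq8_estimate(self) -> float:
        return float(np.clip(self.phq8_raw, 0.0, PHQ_SCALE))


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan = sum(shape)
    return rng.normal(0.0, np.sqrt(2.0 / fan), shape)


def _attn_block(rng, d: int) -> dict[str, np.ndarray]:
    return {
        f"W{x}": _glorot(rng, (d, d)) for x in "qkvo"
    } | {f"b{x}": np.zeros(d) for x in "qkvo"}


def init_parameters(config: FusionConfig) -> dict[str, Tensor]:
    """Seeded Glorot initialisation; head output layers start at zero."""
    rng = np.random.default_rng(config.seed)
    d, h = config.d_model, config.head_hidden
    arrays: dict[str, np.ndarray] = {}
    for stream in STREAMS:
        arrays[f"proj_{stream}_W"] = _glorot(rng, (config.stream_dims[stream], d))
        arrays[f"proj_{stream}_b"] = np.zeros(d)
        for layer in range(config.n_self_layers):
            for k, v in _attn_block(rng, d).items():
                arrays[f"self_{stream}_{layer}_{k}"] = v
    for stream in NONVERBAL_STREAMS:
        for k, v in _attn_block(rng, d).items():
            arrays[f"cross_{stream}_{k}"] = v
    arrays["trunk_W"] = _glorot(rng, (d, d))
    arrays["trunk_b"] = np.zeros(d)
    for head in ("cls", "reg"):
        arrays[f"{head}_W1"] = _glorot(rng, (d, h))
        arrays[f"{head}_b1"] = np.zeros(h)
        arrays[f"{head}_w2"] = np.zeros((h, 1))
        arrays[f"{head}_b2"] = np.zeros(1)
    arrays["reg_b2"] = np.full(1, 0.5)  # mid-scale initial severity
    return {k: Tensor(v, requires_grad=True) for k, v in arrays.items()}


def count_parameters(config: FusionConfig) -> int:
    """Exact trainable-scalar count; raises past the configured budget.

    Closed form: sum over streams of (dim+1)*d for projections, plus
    4*(d^2+d) per attention block (one per stream per self layer, one per
    nonverbal stream for cross-attention), plus (d+1)*d for the trunk and
    2*((d+1)*h + h + 1) for the heads.
    """
    params = init_parameters(config)
    n = sum(int(np.prod(p.shape)) for p in params.values())
    if n > config.parameter_budget:
        raise BudgetError(
            f"{n} trainable scalars exceed budget {config.parameter_budget}"
        )
    return n


# ---------------------------------------------------------------------------
# stream assembly (numpy level)

def assemble_streams(seq: WindowSequence
                     ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Raw per-window stream matrices and presence masks from an encoding.

    The modality-knockout evaluation mode that replaces whole streams with
    noise lives in :func:`depfuse.evaluation.ablation_run`.
    """
    n = seq.n_windows
    token_counts = seq.word_mask.sum(axis=1)
    word_mean = np.divide(
        (seq.word_emb * seq.word_mask[:, :, None]).sum(axis=1),
        np.maximum(token_counts, 1)[:, None],
    )
    streams = {
        "sentence": (seq.sent_emb.copy(), seq.sent_mask.copy()),
        "word": (word_mean, token_counts > 0),
    }
    for name, group in (("audio", AUDIO_CHANNELS), ("visual", VISUAL_CHANNELS)):
        parts, masks = [], []
        for ch in group:
            if ch in seq.histograms:
                parts.append(seq.histograms[ch])
                masks.append(seq.hist_mask[ch])
        if parts:
            streams[name] = (
                np.concatenate(parts, axis=1),
                np.logical_or.reduce(masks),
            )
        else:
            streams[name] = (np.zeros((n, 0)), np.zeros(n, dtype=bool))
    return streams


def fit_scaler(stream_sets: list[dict[str, tuple[np.ndarray, np.ndarray]]]
               ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-stream per-feature mean/SD over unmasked windows of the train split."""
    scaler = {}
    for stream in STREAMS:
        rows = [X[m] for s in stream_sets for X, m in (s[stream],) if m.any()]
        if rows:
            pooled = np.concatenate(rows, axis=0)
            scaler[stream] = (pooled.mean(axis=0), pooled.std(axis=0) + 1e-8)
        else:
            scaler[stream] = (None, None)
    return scaler


# ---------------------------------------------------------------------------
# the network

@dataclass
class FusedInput:
    """Projected per-window stream embeddings plus masks (shared d_model)."""

    embeddings: dict[str, Tensor]  # stream -> (n_windows, d_model)
    masks: dict[str, np.ndarray]  # stream -> (n_windows,) bool
    n_windows: int


class FusionModel:
    """The dual-head attention fusion network."""

    def __init__(self, config: FusionConfig,
                 params: dict[str, Tensor] | None = None,
                 scaler: dict | None = None):
        self.config = config
        self.params = params if params is not None else init_parameters(config)
        self.scaler = scaler or {}
        self.training = False
        self._rng = np.random.default_rng(config.seed)

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        arrays = {k: t.data for k, t in self.params.items()}
        for stream, (mu, sd) in self.scaler.items():
            if mu is not None:
                arrays[f"scaler_{stream}_mu"] = mu
                arrays[f"scaler_{stream}_sd"] = sd
        np.savez(path, __config__=json.dumps(asdict(self.config)), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "FusionModel":
        with np.load(path, allow_pickle=False) as data:
            cfg_dict = json.loads(str(data["__config__"]))
            cfg_dict["stream_dims"] = dict(cfg_dict["stream_dims"])
            config = FusionConfig(**cfg_dict)
            params, scaler = {}, {}
            for key in data.files:
                if key == "__config__":
                    continue
                if key.startswith("scaler_"):
                    stream, kind = key[len("scaler_"):].rsplit("_", 1)
                    scaler.setdefault(stream, [None, None])
                    scaler[stream][0 if kind == "mu" else 1] = data[key]
                else:
                    params[key] = Tensor(data[key], requires_grad=True)
        expected = set(init_parameters(config))
        if set(params) != expected:
            raise ValueError("checkpoint parameters do not match its config")
        model = cls(config, params, {k: tuple(v) for k, v in scaler.items()})
        return model

    def train_mode(self, on: bool = True) -> None:
        self.training = on

    def reset_rng(self, seed: int) -> None:
        """Re-seed the dropout noise stream (training determinism)."""
        self._rng = np.random.default_rng(seed)

    # -- layers ------------------------------------------------------------
    def _linear(self, x: Tensor, name: str) -> Tensor:
        return x @ self.params[f"{name}_W"] + self.params[f"{name}_b"]

    def _dropout(self, x: Tensor) -> Tensor:
        if self.training and self.config.dropout > 0:
            return x.dropout(self.config.dropout, self._rng)
        return x

    def _attention(self, prefix: str, queries: Tensor, keys: Tensor,
                   q_mask: np.ndarray, k_mask: np.ndarray,
                   return_attn: bool = False):
        """Scaled dot-product multi-head attention with masking.

        Masked positions are excluded as keys and return zero as queries;
        with no valid key the output is all-zero.
        """
        p = self.params
        nh = self.config.n_heads
        d = self.config.d_model
        dh = d // nh
        n_q, n_k = queries.shape[0], keys.shape[0]
        if not k_mask.any() or not q_mask.any():
            out = Tensor(np.zeros((n_q, d)))
            return (out, np.zeros((nh, n_q, n_k))) if return_attn else out

        def heads(x: Tensor, n: int) -> Tensor:
            return x.reshape(n, nh, dh).swapaxes(0, 1)  # (nh, n, dh)

        Q = heads(queries @ p[f"{prefix}_Wq"] + p[f"{prefix}_bq"], n_q)
        K = heads(keys @ p[f"{prefix}_Wk"] + p[f"{prefix}_bk"], n_k)
        V = heads(keys @ p[f"{prefix}_Wv"] + p[f"{prefix}_bv"], n_k)
        scores = (Q @ K.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))
        key_mask = np.broadcast_to(k_mask[None, None, :], (nh, n_q, n_k))
        attn = softmax(scores, mask=key_mask)
        ctx = (attn @ V).swapaxes(0, 1).reshape(n_q, d)
        out = ctx @ p[f"{prefix}_Wo"] + p[f"{prefix}_bo"]
        out = out * Tensor(q_mask[:, None].astype(float))
        out = self._dropout(out)
        return (out, attn.data) if return_attn else out

    def project_streams(self, streams: dict[str, tuple[np.ndarray, np.ndarray]]
                        ) -> FusedInput:
        """z-score (train statistics), project to d_model, zero masked windows."""
        embeddings, masks = {}, {}
        n = next(iter(streams.values()))[0].shape[0]
        for stream in STREAMS:
            X, mask = streams[stream]
            dim = self.config.stream_dims[stream]
            if X.shape[1] != dim:
                raise ValueError(
                    f"stream {stream!r}: input dim {X.shape[1]} != configured {dim}"
                )
            mu_sd = self.scaler.get(stream)
            if mu_sd and mu_sd[0] is not None:
                X = (X - mu_sd[0]) / mu_sd[1]
            X = X * mask[:, None]  # masked windows carry zero embeddings
            emb = self._linear(Tensor(X), f"proj_{stream}")
            emb = emb * Tensor(mask[:, None].astype(float))
            embeddings[stream] = emb
            masks[stream] = mask.copy()
        return FusedInput(embeddings, masks, n)


    def forward(self, fused: FusedInput) -> Tensor:
        """Full pipeline to the two raw head outputs, shape (2,).

        Returns a Tensor [classification_logit, raw_phq8] so the training
        loop can differentiate through it; use :meth:`predict` for a
        :class:`Prediction`.
        """
        cfg = self.config
        if not any(m.any() for m in fused.masks.values()):
            raise UninformativeInputError("all streams fully masked")

        contextual: dict[str, Tensor] = {}
        for stream in STREAMS:
            x, mask = fused.embeddings[stream], fused.masks[stream]
            for layer in range(cfg.n_self_layers):
                x = self._attention(f"self_{stream}_{layer}", x, x, mask, mask)
            contextual[stream] = x

        # per-window text representation: masked average of the two text streams
        sm = fused.masks["sentence"].astype(float)[:, None]
        wm = fused.masks["word"].astype(float)[:, None]
        denom = np.maximum(sm + wm, 1.0)
        text = (contextual["sentence"] * Tensor(sm)
                + contextual["word"] * Tensor(wm)) * Tensor(1.0 / denom)
        text_mask = fused.masks["sentence"] | fused.masks["word"]

        components: list[tuple[Tensor, np.ndarray]] = [
            (text, text_mask),
            (contextual["audio"], fused.masks["audio"]),
            (contextual["visual"], fused.masks["visual"]),
        ]
        for stream in NONVERBAL_STREAMS:
            ca = self._attention(
                f"cross_{stream}", text, contextual[stream],
                text_mask, fused.masks[stream],
            )
            valid = text_mask & fused.masks[stream].any()
            components.append((ca, valid))

        comp_masks = np.stack([m.astype(float) for _, m in components])  # (c, n)
        window_valid = comp_masks.sum(axis=0)  # per-window component count
        pooled_num = None
        for (tensor, _), m in zip(components, comp_masks):
            term = tensor * Tensor(m[:, None])
            pooled_num = term if pooled_num is None else pooled_num + term
        per_window = pooled_num * Tensor(
            1.0 / np.maximum(window_valid, 1.0)[:, None]
        )
        pool_mask = window_valid > 0
        weights = pool_mask.astype(float) / max(pool_mask.sum(), 1)
        pooled = (per_window * Tensor(weights[:, None])).sum(axis=0)  # (d,)

        h = self._dropout(self._linear(pooled.reshape(1, -1), "trunk").relu())
        p = self.params
        outs = []
        for head in ("cls", "reg"):
            a = (h @ p[f"{head}_W1"] + p[f"{head}_b1"]).relu()
            z = (a @ p[f"{head}_w2"] + p[f"{head}_b2"]) * cfg.output_gain
            outs.append(z.reshape(1))
        from ._autodiff import concat

        return concat(outs, axis=0)  # [logit, raw_phq8]

    def predict(self, streams_or_seq) -> Prediction:
        """Deterministic eval-mode prediction for one encoded session."""
        was_training = self.training
        self.training = False
        try:
            if isinstance(streams_or_seq, WindowSequence):
                streams = assemble_streams(streams_or_seq)
            else:
                streams = streams_or_seq
            out = self.forward(self.project_streams(streams)).data
        finally:
            self.training = was_training
        from scipy.special import expit

        return Prediction(float(expit(out[0])), float(out[1]))


def describe(config: FusionConfig) -> str:
    """Human-readable per-layer shape listing plus the parameter count."""
    params = init_parameters(config)
    lines = [f"{k:28s} {str(p.shape):>14s} {int(np.prod(p.shape)):>8d}"
             for k, p in params.items()]
    total = count_parameters(config)
    lines.append(f"{'total trainable scalars':28s} {'':>14s} {total:>8d}")
    return "\n".join(lines)
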