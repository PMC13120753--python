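"""Multitask training: Adam on binary cross-entropy + squared error.

The objective per session is L = alpha * L_cls + beta * L_reg with
L_cls = BCE(p, y) on the depression probability and L_reg = (s_hat - y)^2 on
the raw (unclipped) PHQ-8 estimate; batches average over sessions. Training
uses Adam (lr 1e-5, weight decay 1e-4, batch size 8 by default), seeded
shuffling, and early stopping on dev macro-F1 with patience; the weights of
the best dev epoch are returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor
from .evaluation import macro_f1, prf1
from .feature_encoding import (
    DEFAULT_CODEBOOK_K,
    DEFAULT_MAX_TOKENS,
    DEFAULT_WINDOW_LENGTH,
    Codebook,
    HashTextEncoder,
    encode_session,
    hash_text_encoder,
    learn_codebook,
)
from .fusion_model import (
    FusionConfig,
    FusionModel,
    Prediction,
    assemble_streams,
    fit_scaler,
)
from .session_model import DEPRESSED, Session

log = logging.getLogger("depfuse.training")


@dataclass
class TrainConfig:
    alpha: float = 1.0
    beta: float = 1.0
    learning_rate: float = 1e-5
    weight_decay: float = 1e-4
    batch_size: int = 8
    max_epochs: int = 100
    patience: int = 10  # epochs without dev macro-F1 improvement
    seed: int = 0
    bce_epsilon: float = 1e-7

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.learning_rate <= 0 and self.learning_rate != 0.0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainHistory:
    epoch: list[int] = field(default_factory=list)
    loss: list[float] = field(default_factory=list)
    loss_cls: list[float] = field(default_factory=list)
    loss_reg: list[float] = field(default_factory=list)
    dev_macro_f1: list[float] = field(default_factory=list)
    dev_mae: list[float] = field(default_factory=list)


def multitask_loss(p: float, y_cls: int, s_hat: float, y_reg: float,
                   alpha: float = 1.0, beta: float = 1.0,
                   eps: float = 1e-7) -> tuple[float, float, float]:
    """Closed-form multitask loss for one item (probability clipped before log)."""
    p = float(np.clip(p, eps, 1.0 - eps))
    l_cls = -(y_cls * np.log(p) + (1 - y_cls) * np.log(1.0 - p))
    l_reg = (s_hat - y_reg) ** 2
    return alpha * l_cls + beta * l_reg, l_cls, l_reg


class Adam:
    """Classic Adam with L2 weight decay added to the gradient."""

    def __init__(self, params: dict[str, Tensor], lr: float, weight_decay: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = (p.grad if p.grad is not None else 0.0) + self.wd * p.data
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# encoding helpers

def fit_encoders(train_sessions: list[Session], k: int = DEFAULT_CODEBOOK_K,
                 seed: int = 0, d_w: int = 32, d_s: int = 32
                 ) -> tuple[dict[str, Codebook], HashTextEncoder]:
    """Learn one codebook per channel present in the training split."""
    channels = sorted({ch for s in train_sessions for ch in s.channels})
    codebooks = {
        ch: learn_codebook(train_sessions, ch, k=k, seed=seed) for ch in channels
    }
    return codebooks, hash_text_encoder(d_w, d_s, seed)


def encode_corpus(sessions: list[Session], codebooks: dict[str, Codebook],
                  encoder, window_length: float = DEFAULT_WINDOW_LENGTH,
                  max_tokens: int = DEFAULT_MAX_TOKENS):
    """Encode sessions and pre-assemble their raw stream matrices."""
    out = []
    for s in sessions:
        seq = encode_session(s, codebooks, encoder, window_length=window_length,
                             max_tokens=max_tokens)
        out.append((s, assemble_streams(seq)))
    return out


def stream_dims_from(codebooks: dict[str, Codebook], encoder) -> dict[str, int]:
    from .session_model import AUDIO_CHANNELS, VISUAL_CHANNELS

    return {
        "sentence": encoder.d_s,
        "word": encoder.d_w,
        "audio": sum(codebooks[c].k for c in AUDIO_CHANNELS if c in codebooks),
        "visual": sum(codebooks[c].k for c in VISUAL_CHANNELS if c in codebooks),
    }


# ---------------------------------------------------------------------------
# the training loop

def _targets(session: Session) -> tuple[int, float]:
    if session.labels.phq8 is None or session.labels.binary is None:
        raise ValueError(f"session {session.session_id} lacks training labels")
    return int(session.labels.binary == DEPRESSED), float(session.labels.phq8)


def _session_loss(model: FusionModel, streams, y_cls: int, y_reg: float,
                  cfg: TrainConfig) -> tuple[Tensor, float, float]:
    out = model.forward(model.project_streams(streams))
    # out is a length-2 tensor [classification logit, raw PHQ-8 estimate]
    logit = (out * Tensor(np.array([1.0, 0.0]))).sum()
    s_hat = (out * Tensor(np.array([0.0, 1.0]))).sum()
    p = logit.sigmoid().clip(cfg.bce_epsilon, 1.0 - cfg.bce_epsilon)
    if y_cls == 1:
        l_cls = -p.log()
    else:
        l_cls = -(1.0 - p).log()
    l_reg = (s_hat - y_reg) ** 2.0
    loss = l_cls * cfg.alpha + l_reg * cfg.beta
    return loss, float(l_cls.data), float(l_reg.data)


def _dev_metrics(model: FusionModel, dev) -> tuple[float, float]:
    y_true, y_pred, abs_err = [], [], []
    for session, streams in dev:
        y_cls, y_reg = _targets(session)
        pred = model.predict(streams)
        y_true.append(y_cls)
        y_pred.append(int(pred.p_depression >= 0.5))
        abs_err.append(abs(pred.phq8_estimate - y_reg))
    f1_pos = prf1(y_true, y_pred, positive=1)[2]
    f1_neg = prf1(y_true, y_pred, positive=0)[2]
    return macro_f1(f1_pos, f1_neg), float(np.mean(abs_err))


def _init_output_biases(model: FusionModel, train_data) -> None:
    """Start fresh heads at the train base rate / mean label.

    Standard output-layer initialisation for imbalanced multitask heads: the
    classification bias is set to the base-rate log-odds and the regression
    bias to the mean training label (both divided by the output gain), so no
    optimisation budget is spent on re-centering. Applied only when the
    head output weights are still at their zero initialisation.
    """
    p = model.params
    gain = model.config.output_gain
    targets = [_targets(s) for s, _ in train_data]
    if not np.any(p["cls_w2"].data):
        base = float(np.clip(np.mean([t[0] for t in targets]), 0.02, 0.98))
        p["cls_b2"].data[:] = np.log(base / (1.0 - base)) / gain
    if not np.any(p["reg_w2"].data):
        p["reg_b2"].data[:] = np.mean([t[1] for t in targets]) / gain


def train(model: FusionModel, train_data, dev_data,
          config: TrainConfig | None = None) -> tuple[FusionModel, TrainHistory]:
    """Fit the model on encoded (session, streams) pairs.

    ``train_data``/``dev_data`` come from :func:`encode_corpus`. The stream
    scaler is fitted here, on the training split only. Returns the model
    holding the best-dev weights and the per-epoch history.
    """
    config = config or TrainConfig()
    if not train_data:
        raise ValueError("empty training set")
    bad = [s.session_id for s, _ in train_data if s.split != "train"]
    if bad:
        from .session_model import LeakageError

        raise LeakageError(f"non-train sessions in training data: {bad[:5]}")

    model.scaler = fit_scaler([streams for _, streams in train_data])
    _init_output_biases(model, train_data)
    model.reset_rng(config.seed)
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.params, config.learning_rate, config.weight_decay)
    history = TrainHistory()

    # model selection: dev macro-F1, ties broken by lower dev MAE so the
    # regression head keeps training once classification saturates
    best_key, best_epoch = (-np.inf, -np.inf), -1
    best_params = {k: p.data.copy() for k, p in model.params.items()}

    for epoch in range(config.max_epochs):
        model.train_mode(True)
        order = rng.permutation(len(train_data))
        ep_l, ep_lc, ep_lr = [], [], []
        for b0 in range(0, len(order), config.batch_size):
            batch = [train_data[i] for i in order[b0:b0 + config.batch_size]]
            optimizer.zero_grad()
            total = None
            for session, streams in batch:
                y_cls, y_reg = _targets(session)
                loss, lc, lr_ = _session_loss(model, streams, y_cls, y_reg, config)
                ep_lc.append(lc)
                ep_lr.append(lr_)
                ep_l.append(config.alpha * lc + config.beta * lr_)
                total = loss if total is None else total + loss
            total = total * (1.0 / len(batch))
            if not np.isfinite(total.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {b0 // config.batch_size}"
                )
            total.backward()
            optimizer.step()
        model.train_mode(False)
        dev_f1, dev_mae = _dev_metrics(model, dev_data) if dev_data else (np.nan, np.nan)

        history.epoch.append(epoch)
        history.loss.append(float(np.mean(ep_l)))
        history.loss_cls.append(float(np.mean(ep_lc)))
        history.loss_reg.append(float(np.mean(ep_lr)))
        history.dev_macro_f1.append(dev_f1)
        history.dev_mae.append(dev_mae)
        log.info("epoch %d L=%.4f Lcls=%.4f Lreg=%.4f devF1=%.4f devMAE=%.4f",
                 epoch, history.loss[-1], history.loss_cls[-1],
                 history.loss_reg[-1], dev_f1, dev_mae)

        if dev_data:
            key = (dev_f1, -dev_mae)
            if key > best_key:
                best_key, best_epoch = key, epoch
                best_params = {k: p.data.copy() for k, p in model.params.items()}
            elif epoch - best_epoch >= config.patience:
                log.info("early stop at epoch %d (best dev macro-F1 %.4f @ %d)",
                         epoch, best_key[0], best_epoch)
                break

    if dev_data:
        for k, p in model.params.items():
            p.data = best_params[k]
    return model, history


def predict_batch(model: FusionModel, sessions: list[Session],
                  codebooks: dict[str, Codebook], encoder,
                  window_length: float = DEFAULT_WINDOW_LENGTH) -> list[Prediction]:
    """Order-preserving eval-mode predictions for raw sessions."""
    dims = stream_dims_from(codebooks, encoder)
    if dims != model.config.stream_dims:
        raise ValueError(
            f"encoder/codebook dims {dims} do not match checkpoint "
            f"{model.config.stream_dims}"
        )
    preds = []
    for s in sessions:
        seq = encode_session(s, codebooks, encoder, window_length=window_length)
        preds.append(model.predict(seq))
    return preds
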