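"""Metrics and the modality-ablation runner.

Regression: RMSE, MAE and Lin's concordance correlation coefficient (CCC,
population 1/n moments by default — the affective-computing convention).
Classification: per-class precision/recall/F1 with the depression class or
the control class as positive, macro F1 as their unweighted mean, accuracy,
and an exact two-sided binomial test. Ablations re-evaluate a trained model
with chosen streams replaced by seeded unit-variance noise at the input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import binomtest
from sklearn.metrics import accuracy_score, precision_recall_fscore_support

from .session_model import CONTROL, DEPRESSED, PHQ_CUTOFF

log = logging.getLogger("depfuse.evaluation")


# ---------------------------------------------------------------------------
# regression metrics

def _paired(y, yhat):
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise ValueError("empty input")
    return y, yhat


def rmse(y, yhat) -> float:
    y, yhat = _paired(y, yhat)
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


def mae(y, yhat) -> float:
    y, yhat = _paired(y, yhat)
    return float(np.mean(np.abs(yhat - y)))


def ccc(y, yhat, sample_moments: bool = False) -> float:
    """Lin's concordance correlation coefficient.

    2*cov / (var_y + var_yhat + (mean_y - mean_yhat)^2) with population
    (1/n) moments unless ``sample_moments``. Two equal constant vectors
    give 1; any other zero-variance pair gives 0.
    """
    y, yhat = _paired(y, yhat)
    if y.size < 2:
        raise ValueError("ccc needs length >= 2")
    ddof = 1 if sample_moments else 0
    vy, vyh = y.var(ddof=ddof), yhat.var(ddof=ddof)
    dm = y.mean() - yhat.mean()
    if vy == 0.0 and vyh == 0.0:
        return 1.0 if dm == 0.0 else 0.0
    if vy == 0.0 or vyh == 0.0:
        return 0.0
    n = y.size
    cov = ((y - y.mean()) * (yhat - yhat.mean())).sum() / (n - ddof)
    return float(2.0 * cov / (vy + vyh + dm * dm))


# ---------------------------------------------------------------------------
# classification metrics

def binarize_phq(phq8: float) -> str:
    """PHQ-8 >= 10 -> depressed, else control."""
    if not np.isfinite(phq8):
        raise ValueError("phq8 must be finite")
    return DEPRESSED if phq8 >= PHQ_CUTOFF else CONTROL


def prf1(y_true, y_pred, positive) -> tuple[float, float, float]:
    """Precision, recall, F1 with ``positive`` as the positive class.

    Zero denominators yield 0 by convention (logged).
    """
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred) or not y_true:
        raise ValueError("equal nonzero lengths required")
    labels = set(y_true) | set(y_pred)
    if positive not in labels:
        # a class never observed nor predicted: all three are 0 by convention
        log.info("positive class %r absent from data; returning zeros", positive)
        return 0.0, 0.0, 0.0
    p, r, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=[positive], average=None, zero_division=0
    )
    if p[0] == 0.0 or r[0] == 0.0:
        log.info("zero denominator in P/R/F1 for positive=%r", positive)
    return float(p[0]), float(r[0]), float(f1[0])


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of a printed (precision, recall) pair; 0 if both are 0."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must be in [0,1]")
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def macro_f1(f1_pos: float, f1_neg: float) -> float:
    """Unweighted mean of the two per-class F1 scores."""
    if not (0.0 <= f1_pos <= 1.0 and 0.0 <= f1_neg <= 1.0):
        raise ValueError("per-class F1 values must be in [0,1]")
    return (f1_pos + f1_neg) / 2.0


def binomial_test(successes: int, n: int, p0: float) -> float:
    """Exact two-sided binomial tail probability."""
    if n == 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    return float(binomtest(successes, n, p0).pvalue)


# ---------------------------------------------------------------------------
# reports

@dataclass
class EvalReport:
    rmse: float
    mae: float
    ccc: float
    precision_depressed: float
    recall_depressed: float
    f1_depressed: float
    precision_control: float
    recall_control: float
    f1_control: float
    macro_f1: float
    accuracy: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate_predictions(y_phq, y_binary, predictions) -> EvalReport:
    """Score a list of :class:`~depfuse.fusion_model.Prediction` objects."""
    yhat_score = [p.phq8_estimate for p in predictions]
    yhat_cls = [DEPRESSED if p.p_depression >= 0.5 else CONTROL
                for p in predictions]
    y_binary = list(y_binary)
    pd_, rd, fd = prf1(y_binary, yhat_cls, positive=DEPRESSED)
    pc, rc, fc = prf1(y_binary, yhat_cls, positive=CONTROL)
    return EvalReport(
        rmse=rmse(y_phq, yhat_score),
        mae=mae(y_phq, yhat_score),
        ccc=ccc(y_phq, yhat_score),
        precision_depressed=pd_, recall_depressed=rd, f1_depressed=fd,
        precision_control=pc, recall_control=rc, f1_control=fc,
        macro_f1=macro_f1(fd, fc),
        accuracy=float(accuracy_score(y_binary, yhat_cls)),
        n=len(y_binary),
    )


def evaluate_model(model, data) -> EvalReport:
    """Plain evaluation of encoded (session, streams) pairs."""
    y_phq = [float(s.labels.phq8) for s, _ in data]
    y_bin = [s.labels.binary for s, _ in data]
    preds = [model.predict(streams) for _, streams in data]
    return evaluate_predictions(y_phq, y_bin, preds)


def ablation_run(model, data, knockout: tuple[str, ...], seed: int = 0) -> EvalReport:
    """Evaluate with ``knockout`` streams replaced by seeded N(0,1) noise.

    The replacement happens at the model input; architecture and weights are
    untouched, so any score drop is attributable to the missing modality.
    """
    from .feature_encoding import WindowSequence  # noqa: F401 (doc reference)
    from .fusion_model import assemble_streams

    rng = np.random.default_rng(seed)
    y_phq = [float(s.labels.phq8) for s, _ in data]
    y_bin = [s.labels.binary for s, _ in data]
    preds = []
    for _, streams in data:
        if knockout:
            noisy = dict(streams)
            for stream in knockout:
                if stream not in noisy:
                    raise ValueError(f"unknown stream {stream!r}")
                X, _ = noisy[stream]
                eps = rng.standard_normal(X.shape)
                # unit variance in the space the network consumes: undo the
                # z-scoring so normalised inputs are exactly N(0,1)
                mu_sd = model.scaler.get(stream) if model.scaler else None
                if mu_sd and mu_sd[0] is not None:
                    eps = mu_sd[0] + mu_sd[1] * eps
                noisy[stream] = (eps, np.ones(X.shape[0], dtype=bool))
            preds.append(model.predict(noisy))
        else:
            preds.append(model.predict(streams))
    return evaluate_predictions(y_phq, y_bin, preds)
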