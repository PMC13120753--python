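# depfuse

Lightweight multimodal depression screening from conversational interview
data: acoustic and facial frame features are quantized into bag-of-words
histograms, fused with text embeddings through self- and cross-attention,
and decoded by a dual-head network that jointly predicts binary depression
status and a continuous PHQ-8 severity score. The package also ships the
surrounding apparatus a screening study needs: training-data augmentation
with strict train-split leakage guards, an evaluation suite
(RMSE/MAE/CCC, per-class F1), an emotion-aware dialogue layer built on the
emotional-support-conversation (ESC) stage framework with self-consistency
voting, and a synthetic cohort generator so everything runs end to end
without access-restricted clinical corpora.

It is aimed at affective-computing researchers who want a small, fully
inspectable reference pipeline: the network has ~145K parameters, trains in
seconds on a laptop CPU, and every numerical component is tested against an
independent brute-force oracle.

## The model

Each interview session is tiled into fixed 3-second windows. Per window:

* **Audio** (MFCC, eGeMAPS low-level descriptors) and **visual** (gaze,
  head pose, facial action units) frames are assigned to the nearest
  centroid of a channel-specific codebook (k-means, learned on the training
  split only) and summarized as L1-normalized histograms — the
  bag-of-audio-words / bag-of-visual-words representation.
* **Text** is embedded at word and sentence level through a pluggable
  encoder (a deterministic hash encoder is included; transformer encoders
  can be plugged in).

The four streams (sentence, word, audio-BoW, visual-BoW) are z-scored with
training statistics, projected into a shared `d_model` space, passed
through per-stream self-attention, aligned by text-to-nonverbal
cross-attention, masked-mean-pooled over windows, and decoded by two heads:

* classification: `p = sigmoid(g * f_cls(h))`, the probability of clinical
  depression (PHQ-8 ≥ 10);
* regression: `s = g * f_reg(h)`, the continuous PHQ-8 estimate
  (reported clipped to [0, 24]),

with a fixed output gain `g = 24` (the PHQ-8 range). Training minimizes
the multitask objective

```
L = α·BCE(p, y) + β·(s − y_PHQ)²,   α = β = 1,
```

with Adam (lr 1e-5, weight decay 1e-4, batch size 8, dropout 0.1) and
early stopping on dev macro-F1. The network and its gradients are
implemented on a small tape-based reverse-mode autodiff engine in numpy
(`depfuse._autodiff`), so there is no deep-learning framework dependency.

## Worked example

```
depfuse --seed 7 simulate --n 50 --out cohort
depfuse --config config.yaml --seed 7 train --corpus cohort --out model.npz
depfuse --config config.yaml --seed 7 evaluate --ckpt model.npz \
        --corpus cohort --split test
```

with `config.yaml` shrinking the run for demonstration
(`codebook_k: 32`, `learning_rate: 0.001`, `max_epochs: 25`). Training
logs one JSON record per epoch, ending with

```
{"epoch": 17, "L": 0.8897, "L_cls": 0.0014, "L_reg": 0.8883,
 "dev_macro_f1": 1.0, "dev_mae": 3.6410}
```

and evaluation on the held-out test split prints

```
{
  "rmse": 2.8081, "mae": 2.2856, "ccc": 0.8368,
  "f1_depressed": 1.0, "f1_control": 1.0,
  "macro_f1": 1.0, "accuracy": 1.0, "n": 7
}
```

i.e. on this synthetic 50-session cohort the model recovers binary status
perfectly and predicts PHQ-8 within ~2.3 points on average, with a
concordance correlation of 0.84 against the true scores. The dialogue
layer runs on the same corpus:

```
depfuse --seed 7 chat --transcript cohort/S0001/transcript.csv
{"stage": "comfort", "strategy": "shared experiences",
 "response": "[comfort/shared experiences] I hear you when you say ..."}
```

## Layout

```
src/depfuse/
  session_model.py    session/transcript/frame-series data model and CSV I/O
  synthetic_data.py   cohort generator with controllable depression effects
  feature_encoding.py windowing, codebooks, quantization, text encoders
  fusion_model.py     the attention fusion network and dual heads
  training.py         multitask loss, Adam, early stopping
  evaluation.py       RMSE/MAE/CCC, per-class F1, binomial test, ablations
  augmentation.py     social-post conversion, paraphrase synthesis, audits
  esc_dialogue.py     ESC stages, self-consistency voting, mock backend
  cli.py              simulate | augment | train | evaluate | predict | chat | describe
```

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
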