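# Methods

This note records the modelling choices behind depfuse: what is computed,
which defaults matter, what the synthetic cohorts do and do not emulate,
and where the design was genuinely open.

## Data model

A session is a time-aligned bundle of a transcript (utterances with
speaker, start/stop seconds, text) and up to five per-frame feature
channels: `mfcc` (39), `egemaps` (23) at 100 Hz, and `gaze` (8), `pose`
(6), `au` (17) at 30 Hz. All intervals are half-open `[start, stop)`.
Labels are integer PHQ-8 scores (0–24); the binary label is derived from
the standard clinical cutoff (≥ 10 → depressed) and this implication is
enforced at construction for every label source. Rows with non-finite
feature values are dropped at load time (not imputed) — the downstream
histogram encoding makes imputation pointless. Speakers outside
{participant, agent} are coerced to `agent` with a warning; by default only
participant utterances feed detection (the respondent is the modelled
subject; an `include_agent` switch exposes the alternative).

## Windowing and bag-of-words encoding

The session timeline is tiled into fixed windows of `window_length = 3.0` s
— the alignment interval used throughout, also by the augmentation
pipelines — with the final partial window kept. An utterance belongs to
the window containing its start time. For each acoustic/visual channel a
codebook of `k = 100` centroids (per-channel k-means: k-means++ init,
300 max iterations, tol 1e-4, seeded, frames subsampled to 20 000 for
tractability) is learned **on the training split only**; offering any
dev/test session raises a leakage error rather than a warning. Each
window is then the L1-normalized histogram of nearest-centroid assignments
(ties to the lowest index; empty windows yield a zero vector plus a mask
bit). Histograms are computed per window so the attention stage sees a
sequence; a `per_session` mode collapses the whole session into one
histogram for the per-sequence variant of the representation.

Text is embedded per window at word level (tokens truncated/padded to 32
per window) and sentence level (the window's concatenated participant
text). The bundled `HashTextEncoder` (d_w = d_s = 32) maps each token to a
vector drawn from a generator seeded by a stable hash of (token, seed):
fully deterministic, vocabulary-free, and obviously semantics-free — it
carries distributional signal (which words occur) but no meaning, which is
exactly what a controlled test fixture needs. Real sentence/word
transformer encoders can be substituted through the same two-method
interface.

## Fusion network

Four streams per window — sentence embedding, mean word embedding,
concatenated audio histograms (200 dims), concatenated visual histograms
(300 dims) — are z-scored per feature with training-split statistics,
linearly projected to `d_model = 64`, and contextualized by one layer of
per-stream multi-head self-attention (4 heads). A per-window text
representation (masked average of the two text streams) queries each
nonverbal stream through cross-attention. The per-window fused vector is
the masked mean of five components (text, self-attended audio, self-attended
visual, and the two cross-attention outputs); masked windows are excluded
as attention keys, return zero as queries, and are skipped by the final
mean-pool over windows. A linear-ReLU trunk and two linear-ReLU-linear
heads (hidden 32) produce the classification logit and the raw severity.

Three numerical choices matter and are deliberate:

* **Output gain.** Both heads multiply their scalar output by a fixed gain
  of 24 (the PHQ-8 range): the heads work on a unit scale and the gain
  maps them to logit/score scale. With the very small default learning
  rate (1e-5) the total per-weight movement over a full training run is
  bounded by roughly `steps x lr` ≈ 0.01, and without the gain neither head
  could traverse the output range at all.
* **Head initialization.** Final head layers start at zero, so an
  untrained model predicts p = 0.5 and a raw score of 0. When training
  starts on fresh heads, the output biases are set from the training
  labels (base-rate log-odds; mean label) — the standard imbalanced-head
  initialization — so that no movement budget is spent re-centering.
* **Masking contract.** The forward pass is exactly invariant to values
  stored at masked windows (fuzz-tested), which is what makes missing
  modalities and the zero-padded augmentation sessions well-defined.

Default size: 144 578 trainable scalars (`depfuse describe` prints the
per-layer breakdown), well under the 1 000 000 budget enforced by
`count_parameters`. Dropout (0.1) is active only in training mode; eval
mode is deterministic.

The network runs on a minimal tape-based reverse-mode autodiff engine
written for this package (float64, numpy). Its gradients are verified
against central finite differences in the test suite, and the attention
blocks and full forward pass against independent brute-force numpy
implementations.

## Training

The per-session objective is `L = α·L_cls + β·L_reg` with
`L_cls = BCE(p, y)` (probabilities clipped to [1e-7, 1−1e-7] before the
log) and `L_reg = (s_raw − y_PHQ)²` on the unclipped severity; batches
average over sessions. Defaults follow the screening literature: Adam,
learning rate 1e-5, weight decay 1e-4 (added to the gradient), batch size
8, dropout 0.1, α = β = 1, at most 100 epochs. The loss magnitudes are
intentionally left unbalanced (L_reg is typically an order of magnitude
above L_cls early in training); α and β are exposed for rebalancing
experiments.

Early stopping uses patience 10 on dev macro-F1 with ties broken by lower
dev MAE. The tie-break exists because on separable cohorts classification
saturates within a few epochs, and patience on macro-F1 alone would halt
training long before the regression head has moved; epochs that improve
severity estimation without hurting classification count as improvement.
The best-dev weights are restored at the end.

## Augmentation

Two procedures expand the training split:

* **Social-post conversion**: rule-based sentence segmentation (terminal
  punctuation with an abbreviation guard; token stream conserved), one
  sentence per 3-second slot, PHQ-8 threshold-approximated as
  depressed → 10, control → 0. These sessions carry no nonverbal frames;
  under the masking contract an absent channel and a zero-padded channel
  are equivalent, and absence is what keeps every presence mask honest.
* **Paraphrase synthesis**: participant utterances rewritten by a
  pluggable paraphraser (the bundled mock does deterministic synonym
  substitution and clause reordering while never touching a fixed
  sentiment-keyword set), durations rescaled in proportion to new token
  counts, and nonverbal frames resampled with replacement from the
  corresponding original window (or whole session) onto the new timeline.
  Labels are copied verbatim.

Both refuse dev/test input with a leakage error, every synthetic session
carries provenance (source id, generator, seed), and `audit_corpus`
verifies that no synthetic session in a corpus has a dev/test source. The
synthetic-to-real mixing ratio is a config knob with no claimed optimum.

## Evaluation

RMSE, MAE, Lin's concordance correlation coefficient (population 1/n
moments by default, the affective-computing convention; the sample-moment
variant sits behind a flag), per-class precision/recall/F1 (zero
denominators → 0, logged), macro F1 as the unweighted per-class mean,
accuracy, and an exact two-sided binomial test. A paired-accuracy t test
is deliberately out of the metric core (dependent proportions with unclear
pairing units); McNemar-style contingency counting can be built from the
per-session predictions if needed.

Modality ablations re-evaluate a trained model with chosen streams
replaced by seeded Gaussian noise that is unit-variance **in the
normalized space the network consumes** (drawn as `mu + sd·eps` in raw
units). Raw-unit noise would be grossly out of distribution for
small-variance histogram bins and would destroy predictions regardless of
which modality was removed, defeating the purpose of the protocol.

## Synthetic cohorts

The generator emulates the E-DAIC-style layout with controllable
depression effects:

* PHQ-8 scores are normal draws per group — nondepressed mean 3.36
  (SD 3.04), depressed 15.50 (SD 3.76), the clinical benchmark statistics
  — rounded and truncated to [0, 9] / [10, 24] so labels are never
  cutoff-inconsistent. Real cohorts are messier at the boundary; this is
  a documented fidelity limit.
* Depressed prevalence defaults to 8/22 ≈ 0.364 (field-study proportion);
  splits are 70/15/15 by session.
* Text: templated participant utterances (≥ 10 per session) with three
  affect-word slots each, drawn from a negative-affect lexicon with
  probability `0.15 + text_lexical_shift · 0.8 · PHQ/24` — a graded
  severity signal.
* Audio: per-channel log-sigma shift of `−audio_variability_shift` for the
  depressed group (reduced acoustic variability).
* Facial AUs: mean-intensity shift of `−au_activity_shift` for the
  depressed group (reduced expressiveness). Gaze/pose carry no depression
  effect.
* **Speaker variability**: every session draws one scalar per channel
  (SD 0.3) offsetting log-sigma (acoustic) or the mean (visual).
  Without it, group shifts in nonverbal channels are estimable to
  arbitrary precision from thousands of frames and nonverbal cues dominate
  text — the opposite of what interview studies consistently find. The
  speaker effect is what makes audio and video auxiliary signals here,
  as they are in real data.

Two named presets freeze the study conditions used by the heavier tests
and the acceptance script: `separable_config` (all effects 1.5; the
end-to-end learnability condition) and `text_dominant_config` (lexical
1.5, nonverbal 0.15; the ablation condition). Default problem sizes —
100 sessions (80/20) for learnability, 60 sessions (70/30) × 5 seeds for
ablations — keep a full suite run in the low minutes on one CPU while
leaving ~15–20 sessions per dev split for stable metric estimates.

What the generator does **not** emulate: real lexical semantics (the hash
encoder sees token identity only), inter-channel correlation, temporal
dynamics within a session, annotator noise, or cutoff-inconsistent labels.
Passing tests therefore demonstrate that the pipeline recovers the kinds
of statistical structure it is built for — lexical distribution shifts,
variance shifts, mean shifts — not clinical validity on real interviews.

The learnability experiment uses the literature training setup verbatim
(Adam 1e-5, weight decay 1e-4, batch 8, dropout 0.1, ≤ 100 epochs). The
ablation experiments instead train at lr 1e-3 for up to 60 epochs: at
1e-5 the bounded weight movement can exploit coarse variance cues but
cannot align the text-embedding direction within 100 epochs, leaving
nothing meaningful to ablate; at 1e-3 all modalities are learned and the
knockout comparison is informative.

## ESC dialogue layer

Three ordered stages (exploration < comfort < action), each with its
strategy repertoire. Stage selection runs the backend classifier
`k = 5` times (odd, to reduce ties) at temperature 0.7 on the last 10
conversational sentences — both speakers' turns — and takes the plurality,
breaking ties toward the earliest stage (the safest default early in a
support conversation). Generation is called once at temperature 0. The
bundled mock backend classifies by keyword rules with flip-to-uniform
noise scaled by `noise_rate × temperature` (so temperature 0 is exactly
the rule) and generates by template fill; with noise 0.4 and k = 5 the
plurality vote recovers the rule stage with probability ≈ 0.98/0.97/0.95
for exploration/comfort/action-rule contexts (exact enumeration), and
recovery is monotone in k. Prompt templates for real LLM backends are
ordinary editable strings, not code.

## Known limitations

* The hash text encoder is distributional, not semantic; results with it
  say nothing about transformer-embedding behaviour.
* Histogram (BoW) encodings discard within-window temporal order.
* The regression head is trained on raw PHQ-8 scale; calibration beyond
  the mean-label bias initialization is left to the user.
* Sequence lengths beyond a few hundred windows are out of scope (the
  autodiff engine favours clarity over speed).
* Synthetic-cohort results quantify pipeline correctness, not clinical
  performance; the benchmark interview corpora this layout mirrors are
  access-restricted and no claim is made about them.
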