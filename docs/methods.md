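# Methods

## Problem and model

The package models early cognitive decline (healthy control, HC, vs. an
impaired state — MCI in autobiographical-memory interviews, AD in
picture-description corpora) from *longitudinal* spontaneous speech.  Each
subject is interviewed at up to `V = 3` visits and narrates one or more free
stories per visit; each story contributes audio, a timestamped ASR
transcript, and a topic string.  The prediction target is the cognitive label
of the **last** visit, from a visit triplet of the subject's stories.

The pipeline has four stages:

1. **Feature extraction.**
   *Acoustic*: the waveform is averaged to mono, resampled to 16 kHz and
   normalised to zero mean / unit (population) variance; cut into 15 s clips
   with 5 s overlap; each clip is mapped to `[seq_len, F]` frame features by a
   pluggable extractor (`F = 1024` with a pretrained self-supervised speech
   encoder; a deterministic sinusoid-projection extractor ships for desk
   scale); frames are averaged within each clip and the clip vectors averaged
   (unweighted) into one story-level vector.
   *Linguistic*: inter-segment silences are classified short (< 0.5 s),
   medium (0.5–2 s, boundaries inclusive) or long (> 2 s); together with mean
   length of utterance (words per ASR segment) and counts of five coarse POS
   classes (noun/verb/adjective/pronoun/other) they form a 9-dim numeric
   vector.  The *enriched transcript* prepends a topic sentence
   ("I'm going to share a story of {topic}.") and inserts bracketed pause
   marker tokens (`[PAUSE_S/M/L]`) at the gaps; per-token context ids mark
   the topic span (0) vs. story content (1).

2. **Encoders and fusion.**  The acoustic vector passes through three 1-D
   conv blocks (16/32/64 filters, kernel 3, stride 1, batch norm, ReLU,
   max-pool 2 — an exact `⌊⌊⌊F/2⌋/2⌋/2⌋` temporal reduction) and an affine
   projection to a 128-dim latent.  The enriched transcript is tokenised
   (stable CRC32 hashing tokeniser at desk scale), each token embedding is
   summed with a learned 2-row context embedding, a bidirectional transformer
   encodes the sequence, and the first-token vector is concatenated with an
   affine encoding of the z-scored 9-vector (statistics fit on the training
   fold only) and projected to 128 dims.  The two modality embeddings are
   summed and refined by one multi-head self-attention layer (the sum treated
   as a 1-token sequence) into the story embedding `e`.

3. **Aging-trajectory module.**  For consecutive visits, cross-attention with
   the current visit as query and the previous visit as key/value (plus a
   residual to the current visit) yields enhanced embeddings; the module is
   strictly causal — later visits are never inputs, which the test suite
   asserts at the gradient level.  A direction encoder
   `f_D(e_k − e_{k−1})` (two affine layers with ReLU, 128 → 64 → 32) yields
   32-dim aging-direction vectors.  The classifier applies batch norm and one
   affine layer to `[ē₁‖ē₂‖ē₃‖d₁‖d₂]` (448 dims at default widths) and
   outputs a single sigmoid logit.  Both visit pairs share the
   cross-attention and `f_D` parameters.

4. **Losses.**  `L = L_class + α·L_E + δ·L_G + γ·L_S` with defaults
   α = 0.01, δ = 0.001, γ = 0.001.  `L_class` is binary cross-entropy on the
   triplet logit.  `L_E` is a supervised contrastive loss (SupCon, τ = 0.07)
   over story embeddings labelled by visit status; as formulated it sums from
   the second visit, so visit-1 embeddings are excluded by default
   (`include_visit1` widens it).  `L_G` is SupCon over direction vectors
   labelled by the transition code (HC→HC = 0, HC→impaired = 1,
   impaired→impaired = 2); impaired→HC transitions exist in real cohorts but
   are outside the trained taxonomy and are excluded rather than given a
   fourth class.  `L_S` sums `1 − cos(d̄, d)` between each direction and its
   subject/visit-pair mean; the default reduction divides by the number of
   terms for batch-size independence, with an exact-sum mode retained for
   worked-example checks.  All cosines carry 1e-8 epsilon guards.  Each
   vectorised loss is tested against an independent naive-loop oracle at
   1e-6.

## Training protocol

Folds are split **by subject** (10-fold by default, stratified by last-visit
label where class counts allow) and a leakage assertion runs inside the
training loop, not only at split time.  Each epoch re-pairs stories: one
triplet per last-visit story, with visit-1/2 partners drawn uniformly within
the subject (seeded per (seed, epoch, subject)), so the model sees many
sampled transitions.  The majority class of training triplets is
down-sampled to the minority count each epoch; validation data are never
down-sampled.  Optimisation is Adam; batch size 8; early stopping monitors
the validation total loss with patience 10.

**Checkpoint policy.**  The model evaluated is the one at stopping time.
Restoring the best-validation-loss checkpoint and then scoring the same ~20
validation subjects measurably inflated validation AUROC on null cohorts
(selection on the evaluation set); `restore_best=True` remains available but
is off by default.

Evaluation is subject-level: soft voting averages a subject's triplet
probabilities (one triplet per last-visit story, deterministic evaluation
pairing), impaired iff the mean exceeds 0.5 (ties to HC).  Metrics: accuracy,
F1, precision, sensitivity, specificity, and rank-based AUROC; with a
single-class truth vector AUROC is reported as NaN with a warning rather
than failing the whole report.  Metrics are reported per fold, fold-averaged,
and pooled over all validation subjects; the pooled subject-level AUROC is
the headline number in the recovery experiments.

## Synthetic cohorts

`ltam.synthetic.generate_dataset` draws label paths from a two-state chain
whose defaults reproduce observed cohort proportions (transition counts
50/10/8/40 over 108 consecutive-visit pairs; initial impaired fraction
26/54).  Story features at visit `k` are
`b + Δ·Σ_{j≤k} g_{c_j} + s₀·u·1[impaired] + ε`, with a per-subject base
`b ~ N(0, base_sd²·I)`, fixed orthonormal drift axes `g_HC`, `g_MCI`, a
static-offset axis `u`, per-visit drift magnitude `Δ`, and isotropic noise
`ε ~ N(0, σ²·I)`.  For subjects whose label changes, each visit step drifts
along the axis of the label *at that visit*, so the latest step direction
carries the current status.  Transcripts are rendered from word-pool
templates with group-dependent statistics (impaired: medium/long pause
probabilities ×1.5, mean utterance length ×0.8), so the linguistic extractor
recovers the intended pause counts and MLU by construction; toy audio is a
deterministic sinusoid mix snapped to whole cycles (zero mean).

What the generator does **not** emulate: real acoustics or language (no
speech content, no ASR errors), irregular visit intervals, covariate shift
between cohorts, or annotator noise.  Passing the recovery experiments shows
that the architecture and losses can read trajectory-coded signal under the
model's own assumptions — not that the same separation holds on clinical
recordings.

## Recovery experiments (desk-scale profile)

Problem sizes were chosen so the full suite runs in minutes on one CPU:
60 subjects, 16-dim features, 16-dim latents, 8-dim directions, 3-fold
subject-wise CV, Adam at lr 1e-2 (the published lr of 1e-5 matches
fine-tuning of large pretrained backbones; tiny randomly initialised
encoders need the usual 1e-2 scale), max 60 epochs with patience 10.

* **Directional recovery** (`drift = 1.5`, `static_sep = 0`, `noise_sd =
  0.3`, `base_sd = 8`): the signal lives only in the step direction.  The
  full longitudinal model reaches pooled subject-level AUROC ≥ 0.95; a
  logistic regression on last-visit story features stays near chance (the
  accumulated drift offset, ~`2√2·Δ ≈ 4.2`, is buried in the base sd of 8);
  the direction-ablated configuration (classifier over raw concatenated
  embeddings) underperforms the full model — consistently across seeds by a
  sign test.  A linear head *could* in principle form embedding differences
  itself, so ablated performance is above chance but well below the model
  given explicit direction embeddings and alignment losses.
* **Null control** (`drift = static_sep = 0`): pooled AUROC 0.5 within
  sampling noise (per-cohort sd ≈ 0.07 at 60 subjects).
* **Static sanity** (`static_sep` large, `drift = 0`): both cross-sectional
  and longitudinal modes succeed — the trajectory machinery does not destroy
  static signal (covered in the estimator tests at the unit level).

## Numerical choices and conventions

* All tensors are float64; the in-repo reverse-mode autograd engine is
  verified against central finite differences (rtol 1e-5).
* Max-pool gradients route to the argmax (ties split evenly); batch norm uses
  biased batch variance with eps 1e-5 and momentum 0.1 running statistics.
* Attention over a single fused token is degenerate by construction; the
  value/output projections still apply, and identity-initialised projections
  make the layer an exact identity — used to realise ablations and tests.
* Pause boundaries 0.5 s and 2.0 s map to MEDIUM (the short/long definitions
  are strict); negative ASR-overlap gaps clip to zero (counted short).
* A trailing audio clip shorter than 1 s beyond the last full clip's end is
  dropped (no padding, which would bias clip means); audio shorter than one
  clip is kept whole.
* Visit indices are 1-based; labels serialise as strings in manifests and
  integers (HC = 0, impaired = 1) internally; all times in seconds.
* Manifest writing is canonical (fixed column order, sorted rows), so
  write→read→write is byte-identical.

## Known limitations

* The desk-scale backbones (hashing tokeniser + tiny transformer, sinusoid
  frame projections, linear feature encoder) share interfaces and dimensions
  with pretrained checkpoints but none of their linguistic or acoustic
  knowledge; results on synthetic cohorts do not transfer to real speech.
* Subjects with fewer than `V` visits are reported as violations rather than
  imputed; variable visit counts and irregular intervals are out of scope
  (visits are ordinal).
* SupCon behaviour floors at `log(n_pos)` for clustered batches; identical
  same-label vectors give exactly zero loss only for a single positive.
* Probability calibration, hyperparameter search and multi-device training
  are out of scope.
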