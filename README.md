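# ltam

Longitudinal trajectory-aligned multimodal modelling of cognitive decline
from spontaneous-speech interviews.

## The problem

Early mild cognitive impairment (MCI) shows up in speech before it is obvious
clinically: more and longer pauses, shorter utterances, shifted syntax, and —
crucially — *change over time*.  This package implements a longitudinal
dual-modal classifier for interview cohorts in which each subject narrates
free-form stories at up to three visits.  Instead of classifying a single
visit, the model consumes a visit triplet and predicts the last visit's
label (HC vs. impaired), explicitly encoding how the subject's latent
representation moves between visits.

It is intended for researchers working on speech-based cognitive biomarkers
who need the complete method — feature extraction, encoders, trajectory
module, alignment losses, evaluation protocol — runnable and testable at
desk scale without access to clinical recordings.

## The model

Per story, an acoustic vector (clip-segmented audio, frame features from a
pluggable speech encoder, two-stage average pooling) and a linguistic input
(topic-prefixed, pause-annotated transcript with context ids, plus a 9-dim
vector: mean length of utterance, short/medium/long pause counts, five POS
counts) are encoded and fused by self-attention into a story embedding
*e*ᵢ,ₖ.  The aging-trajectory module then:

* enhances each visit's embedding by cross-attention onto the previous visit
  only (query = current, key/value = previous; strictly causal),
* encodes aging directions **d** = f_D(*e*ₖ − *e*ₖ₋₁), f_D: 128 → 64 → 32,
* classifies the concatenation [ē₁‖ē₂‖ē₃‖d₁‖d₂] with batch norm + affine.

Training minimises

```
L = L_class + α·L_E + δ·L_G + γ·L_S        (α=0.01, δ=0.001, γ=0.001)
```

where L_class is binary cross-entropy on the triplet logit, L_E a supervised
contrastive (SupCon) loss over story embeddings labelled by visit status,
L_G SupCon over directions labelled by the label *transition*
(HC→HC / HC→impaired / impaired→impaired), and L_S a cosine loss pulling each
subject's directions toward their per-subject mean.  Evaluation is
subject-wise k-fold with majority down-sampling and subject-level soft
voting.  See `docs/methods.md` for the full account.

A synthetic cohort generator (`ltam.synthetic`) produces complete
longitudinal datasets with configurable drift/static/noise structure, label
transitions matching observed cohort proportions, and template transcripts
whose pause and utterance statistics are group-dependent by construction —
so every stage is testable with no data download.

## Worked example

Train on a synthetic cohort in which the class signal lives *only* in the
visit-to-visit drift direction (no static separation; per-subject baseline
variance eight times the noise scale):

```python
from ltam import SynthConfig, generate_dataset, TrainConfig, train

cfg = SynthConfig(n_subjects=60, drift=1.5, static_sep=0.0,
                  base_sd=8.0, feature_dim=16, seed=0)
ds, truth = generate_dataset(cfg)
print(f"{len(ds.stories)} stories from {len(ds.subjects())} subjects")

result = train(ds, TrainConfig(n_folds=3, latent_dim=16, direction_dim=8,
                               fd_hidden=16, max_epochs=60), seed=0)
for k, v in result.pooled_report.as_dict().items():
    print(f"{k:12s} {v:.3f}")
```

prints

```
377 stories from 60 subjects
accuracy     0.900
f1           0.900
precision    0.931
sensitivity  0.871
specificity  0.931
auroc        0.982
```

The pooled subject-level AUROC of 0.98 comes entirely from trajectory
information: a logistic regression on last-visit story features sits near
chance on the same cohort (`ltam.experiments.static_last_visit_auroc`), and
setting `drift=0, static_sep=0` drives the model itself to chance.

The same workflows are scriptable from the shell:

```bash
ltam simulate --out cohort/ --n-subjects 20 --seed 3
ltam extract  --manifest cohort/manifest.csv --out features/
ltam train    --manifest cohort/manifest.csv --out runs/ --n-folds 3
ltam viz-trajectories --manifest cohort/manifest.csv --out fig.png
```

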