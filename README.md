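# altriage

Active-learning triage of biomedical abstracts for high-recall literature
screening, built around the retrieval problem of clinical drug-safety
drug–drug interaction (DDI) evidence: a tiny positive class scattered
through millions of unreviewed abstracts, a manually labeled set of
near-miss negatives that does not resemble the general population, and a
screening requirement of missing almost nothing.

## Who it is for

Curation teams and text-mining researchers who need to train a
document-retrieval classifier when manual labeling is the bottleneck.
The package implements and compares four pool-based active-learning (AL)
workflows and ships a synthetic corpus generator so every mechanism can
be exercised and tested without any proprietary corpus.

## The method

Documents are represented as raw stemmed-term counts (lowercase, strip
punctuation, drop digit-only tokens, Porter stemming). Terms whose count
standard deviation across documents is ≤ 0.03 are discarded as
uninformative; the rest form the feature space.

Let ML₁ be a classifier trained on positives vs *random negatives* (a
uniform draw of unreviewed abstracts, presumed negative because the
positive class is rare), and ML₂ a classifier trained on positives vs
*manually labeled negatives*. Each AL round:

1. fit the model(s) on the current training sets;
2. score the unlabeled pool; acquire a seeded random subset of documents
   with positive-class probability in the uncertainty band [0.4, 0.6],
   plus every random-pool document scoring > 0.7 (candidate mislabeled
   positives);
3. send the acquired documents to the labeling oracle;
4. route the newly labeled documents back. The four workflow variants
   differ here: `traditional` (single model, labels go to training only),
   `traditional_plus_random` (adds the random-negative stratum and
   high-confidence mining), `dual_model` (both ML₁ and ML₂), and
   `dual_model_val_update` (dual models, and each labeled batch is
   re-split 0.4 / 0.3 / 0.3 between ML₁'s training set, ML₂'s training
   set, and the validation set, so the validation distribution tracks
   the evolving sample population).

Evaluation is by confusion-matrix recall R = TP/(TP+FN), precision
P = TP/(TP+FP), F1 = 2PR/(P+R), and the headline screening figure
**precision at recall 0.99** (P@R=0.99): sweep all score thresholds,
keep those whose recall reaches 0.99, report the precision of the most
conservative one. Both classifier families are linear — logistic
regression and a Platt-calibrated linear SVM.

## Worked example

`examples/03_run_active_learning.py` runs the validation-updating dual
workflow for two rounds on a synthetic corpus (600 positives, 400
labeled negatives, 2,000-document random pool):

```
 round model  TP  FP  TN  FN  recall  precision    f1  p_at_r
     1   ml1 148  67 425  53   0.736      0.688 0.712   0.473
     1   ml2 162 182 310  39   0.806      0.471 0.594   0.310
     2   ml1 137  61 431  64   0.682      0.692 0.687   0.463
     2   ml2 155  66 426  46   0.771      0.701 0.735   0.373

round-1 acquisitions: 310 (1 labeled positive)
```

Both rounds are evaluated on the *updated* validation set. Round 1's
ML₂ — trained only against manually labeled negatives — mistakes a large
slice of the unreviewed background for positives (182 false positives,
P@R=0.99 of 0.31). After one acquisition round its training and
validation sets contain oracle-labeled background documents and its
precision at the same recall target rises to 0.37 (and 0.47 → 0.70 at
the 0.5 threshold). The other examples demonstrate corpus simulation,
SD feature selection, the fixed-recall sweep, and the principal-component
diagnostic that motivates using two classifiers.

A command-line interface wraps the same pipeline:

```
altriage simulate --seed 7 --out corpus.tsv --truth truth.tsv
altriage preprocess --in corpus.tsv --out features.tsv
altriage run --corpus corpus.tsv --truth truth.tsv --variant dual_model_val_update --out rundir/
altriage report --rundir rundir/
```

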