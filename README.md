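# lexcnn — lexicon-weighted attention CNN for mental-health triage

`lexcnn` classifies social-media posts into the four escalating risk
categories used by moderator triage queues — **green** (no concern),
**amber** (possible concern), **red** (serious, needs a moderator), and
**crisis** (strong self-harm tendency).  It is aimed at researchers in
clinical NLP who want a fully inspectable, dependency-light implementation of
lexicon-guided attention for risk classification, together with a synthetic
corpus generator that makes every stage testable without access to restricted
clinical data.

## The method

The model couples an LIWC-style word-class lexicon with a Kim-style
convolutional text classifier:

1. **Word-class frequencies.**  For each semantic word class *l* and category
   *c*, compute TF(*l*, *c*): the fraction of tokens in category-*c* posts
   that match class *l* (wildcard patterns like `friend*` included).
2. **Discriminability.**  Max-normalize each row,
   TF′(*l*, *c*) = TF(*l*, *c*) / max₍c₎ TF(*l*, *c*), and score each class by
   the spread of the normalized row across the four categories:
   δ\_l = √( Σ\_c (TF′(*l*, *c*) − μ\_l)² ),  μ\_l = mean₍c₎ TF′(*l*, *c*).
   A class used very unevenly across categories (large δ) separates them well;
   the top-*k* classes by δ are retained.
3. **Attention weights.**  Every token *i* gets a weight
   a\_i = exp(δ\_best) / Σ\_{l ∈ selected} exp(δ\_l) + 1, where δ\_best is the
   largest δ among the selected classes the token belongs to; tokens matching
   no selected class get a\_i = 1.  Thus a\_i ∈ [1, 2).
4. **Classifier.**  The post's word-vector matrix X (corpus-trained skip-gram
   vectors) is scaled row-wise, M = diag(a)·X, then passed through sigmoid
   convolutions over windows h ∈ {2, 3, 5, 7}, max-over-time pooling, and a
   dense softmax over the four categories.  Training minimizes cross-entropy
   plus an L2 penalty on kernels and dense weights with mini-batch Adam; the
   checkpoint at the validation-accuracy peak is kept.

Per-post linguistic feature vectors LGF(*l*, *p*) — the fraction of the
post's tokens in each selected class — are exported for external analyses.

Baselines mirror the usual comparison set: the same CNN with unit attention
weights and Gaussian (`cnn_random`) or skip-gram (`cnn_word2vec`) embeddings,
and an averaged-embedding softmax (`fasttext_avg`).  Forcing every a_i to 1
reproduces the traditional CNN *bit for bit* — the attention layer is the
only difference, which makes the ablation exact.

Evaluation follows triage-shared-task conventions: 4-way accuracy and
macro-F1 (`all_acc`, `all_f1`), macro-F1 over the at-risk classes
(`non_green_f1`), and two binary collapses — *flagged* ({amber, red, crisis}
vs green) and *urgent* ({red, crisis} vs {green, amber}) — each with
positive-class F1 and binary accuracy.

## Worked example

`examples/02_rank_word_classes.py` generates the default planted-signal
corpus (8 synthetic word classes, 1,600 posts; class 1 emitted at rates
0.08 / 0.05 / 0.02 / 0.005 in crisis / red / amber / green posts) and runs
the weighting pipeline:

```
class  delta    selected
class_01  0.7103  *
class_02  0.1879  *
class_07  0.1795  *
class_06  0.1450
...
weight of planted-class word 'c01w00x': 1.4585
weight of an out-of-lexicon word: 1.0000
```

The planted class tops the δ ranking by a wide margin (0.71 vs ≤ 0.19 noise
for the uniform classes); its words receive attention weight ≈ 1.46 while
all other tokens keep the neutral weight 1.  `examples/03_train_and_evaluate.py`
then trains a reduced model on 600 posts and prints the held-out report —
e.g. `all_acc 0.9083`, `urgent_f1 0.9492` — showing the pipeline recovers the
planted structure end to end.  A thin CLI mirrors the pipeline
(`lexcnn simulate | weights | train | evaluate`).

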