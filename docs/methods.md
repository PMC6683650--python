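# Methods

This note documents the models implemented in `projcoder`, the choices
made where the design was genuinely open, the synthetic study conditions,
and what the tests do and do not establish.

## Skip-gram trainer

`embedding.train_skipgram` implements skip-gram with the negative-sampling
objective

    L = −log σ(u_c · v_o) − Σᵢ log σ(−u_c · v_{nᵢ}),

where `u` rows come from the input (embedding) table and `v` rows from the
output (context) table, and noise words are drawn from the unigram
distribution raised to 0.75. Full-scale defaults: dimension 50, window 12,
minimum word frequency 20, 5 negatives, learning rate 0.1, momentum 0.9.
An NCE-proper variant (adding the log-partition correction `− log(k·Pₙ(w))`
to every score) is available via `SkipGramConfig(loss="nce")`; the
negative-sampling form is the default because it is what standard word2vec
implementations optimize.

Implementation choices:

* Mini-batch SGD (default batch 256) with classical momentum and a linear
  learning-rate decay to ~0 over the run; gradients are averaged within a
  batch. Input table initialized uniform in ±0.5/D, output table at zero
  (the word2vec convention).
* Context windows are positional: an out-of-vocabulary token occupies its
  position and does not shrink the ±window span of its neighbours.
* Subsampling of frequent words is off; there is no hierarchical softmax.
* One integer seed drives initialization, pair shuffling and noise draws;
  single-threaded runs are bit-reproducible.

The returned `EmbeddingTable` carries the input vectors and, as an extra
attribute, the context table from the same run (`context_vectors`). The
word2vec text format stores only the input table, so the attribute is
absent after a save/load round trip.

## Projection adaptation

`embedding.train_projection` freezes both base tables and learns one D×D
matrix `P`, initialized at the identity. Skip-gram pairs from the internal
corpus (tokens missing from the base vocabulary are skipped) drive the
same negative-sampling loss, computed on projected vectors: the center
path uses `(input row)·P`, the context and noise paths use
`(context row)·P`. Only `P` receives gradients; `materialize` applies `P`
to every input row, yielding a table over exactly the base vocabulary.
Trainable parameters: D² (2500 at D = 50).

Routing the two skip-gram paths through the two *separate* frozen tables
matters. If both paths share the input table, every negative draw directly
penalizes the inner product between two input embeddings, and frequent
internal words — precisely the words the adaptation is supposed to pull
together — repel each other; the planted-synonym study then fails. With
the standard two-table routing the repulsion acts across tables, as in
ordinary word2vec, and the adaptation behaves as intended. When a base
table has no context table (e.g. loaded from text format), the trainer
falls back to using the input table for both paths, with the caveat above.

Noise words for projection training are drawn from the *internal* corpus
unigram distribution (^0.75), restricted to words the internal corpus
actually uses.

## Concatenation baseline

`concat_embeddings` stacks two tables over their vocabulary intersection
(dimension Da+Db, 100 for two 50-dimensional tables). It is the natural
baseline for the projection model and demonstrates its limitation:
concatenation cannot represent words outside the intersection.

## Intrinsic evaluation

`semeval.score_dataset` correlates model cosine similarities with human
relatedness judgments (Pearson r, per the convention of published
term-pair benchmarks). Multi-word terms embed as the arithmetic mean of
their word vectors. Out-of-vocabulary words are replaced per word by the
vocabulary token with minimal Levenshtein distance (computed by edlib),
ties broken lexicographically — deterministic and idempotent. The seven
published benchmark datasets are not redistributable here; the loader
accepts their common 3-column format, and tests use synthetic look-alike
fixtures.

## Hierarchical CNN coder

Per chapter (ICD-10-CM level-1 category), the classifier is:

    token grid (D×n, one per embedding channel)
      → convolutions of widths 1..5, Kᵢ filters each, spanning full depth
      → global max over window positions, per filter
      → concatenation of all channels' pooled features
      → affine output layer, one logistic unit per three-character code

Code probabilities then max-pool up the hierarchy: two-character group =
max over member codes, chapter = max over groups (`hierarchical_pool`).
The 21 chapter ranges ship as a package data file; the external-causes
chapter V00-Y99 is parsed but flagged excluded, and excluded codes are
dropped from training.

Design choices the architecture description leaves open:

* **No activation between convolution and max-pool.** Max-pooling already
  supplies the nonlinearity; adding ReLU would only clip the feature floor.
* **No convolution bias.** A bias adds a constant candidate to every max
  pool. With zero-padded inputs that constant path trains into an
  "absence of evidence" detector, which badly distorts the single-word
  score diagnostic (see below); without it, an all-zero input yields
  exactly the logistic of the output-layer bias.
* **Masked pooling.** The global max runs only over windows containing at
  least one real token, so batch padding never contributes features and
  logits are independent of padding length. Notes are truncated at
  `max_len` (default 512) and batch-padded to the longest note present.
* **Per-chapter classifiers are independently parameterized** (the
  chapter classifier is the named unit of the design); filters are not
  shared across chapters.
* **Unknown tokens embed as the zero vector**, keeping channels aligned
  across embedding tables with different vocabularies.
* **Parameter parity across channel counts.** An m-channel model uses
  Kᵢ/m filters per channel; the convolution stage then has exactly the
  same parameter count as the one-channel model (the output layer's size
  difference is unavoidable). `conv_parameter_count` asserts this.

Optimizer: SGD with Nesterov momentum 0.9 (no dampening), initial learning
rate 0.05, batch 32, weight decay 1e-4. Rare-code handling is
inverse-frequency weighting of the per-code binary cross-entropy
(weights ∝ 1/frequency, normalized to mean 1); a duplication-based
oversampler is available behind `oversample_duplicate`. The learning rate
drops by a factor of 10 when the validation loss fails to improve by more
than 1e-4 over an epoch, at most three times, after which training stops
(also bounded by `max_epochs`).

## Hybrid sampling

A training note is pasted (positive first, no separator) with a uniformly
drawn partner sharing none of its codes. The default labeling is the
*union* of both notes' codes — both texts genuinely appear in the pasted
sample; `hybrid_labels="positive"` keeps only the positive note's codes,
in which case the pasted foreign text acts as label noise that soft-limits
weight growth. `hybrid_prob` controls the fraction of training samples
hybridized (default 0.5).

The `word_score` diagnostic feeds a single token through the trained model
and reports the last fully connected output before the logistic transform;
a score above 0 means that word alone implies a probability above 50%.
Hybrid sampling is expected to raise the share of vocabulary with positive
scores: the model shifts from "absence/presence of foreign terms" toward
positive evidence only.

## Synthetic data

`synth` generates three kinds of fixtures, all fully determined by their
seed and accompanied by a manifest sufficient to verify the planted
structure:

* **Topic corpora** — each document drawn from one topic's private
  vocabulary mixed with shared background words; used for skip-gram sanity
  (within-topic cosines must exceed between-topic).
* **Synonym-pair corpus pairs** — external corpus in which the planted
  pair never share a document (each word has its own context group, plus
  shared filler vocabulary), internal corpus in which every context
  sentence appears once with each planted word; a control pair is equally
  separated externally and absent internally.
* **Keyword-driven notes** — each note samples 1–3 codes (never violating
  the anti-pair list, which by default forbids all cancer-chapter ×
  pregnancy-chapter combinations), emits at least one keyword per assigned
  code, and fills with keywords plus background noise. Keyword lists are
  pairwise disjoint so recovery has a ceiling of 1. `noise_rate` defaults
  to 0 (deterministic, noiseless mapping). `ward_bias` draws background
  words preferentially from a pool homed at the note's chapter, emulating
  ward-specific phrasing — the realistic source of spuriously negative
  vocabulary.

## Study conditions and problem sizes

Chosen once, desk-scale, so the whole suite runs in minutes on one CPU:

* Skip-gram fixtures: dimension 16, window 5, min_count 1, 20 epochs at
  batch 64. Twenty epochs are needed because with the word2vec zero-output
  initialization a small corpus needs that long to leave the near-isotropic
  initial state and develop co-occurrence geometry; the paper-scale
  defaults (50/12/20) apply to full corpora.
* Projection study: 10 seeds; projection trained 5 epochs; success means
  the planted pair's cosine gain is positive and exceeds the control
  pair's.
* Coder recovery: 2000 training notes, 500 validation notes, 20 codes over
  5 chapters, noiseless keywords; one 32-dimensional random embedding
  channel; filter counts (48, 36, 18, 12, 6) — the full-scale counts
  divided by 50; max 12 epochs.
* Hybrid-sampling study: 500 notes, 6 codes in the two anti-correlated
  chapters, noise_rate 0.4 with ward_bias 0.8 over 60 background words;
  filter counts (64, 48, 24, 16, 8); 4 epochs; the hybrid arm pastes every
  training sample (`hybrid_prob=1.0`) with union labels. Four epochs is
  the deliberate operating point: both arms already classify the notes
  well there, while at full convergence on a perfectly separable toy task
  both arms drive their decision margins so large that the word-level
  contrast between them is dominated by margin growth rather than by what
  the words mean. Real discharge data is never separable in this way,
  which is why the full-scale method can train to plateau.

## What the synthetic results do and do not show

Passing tests establish that the implementations do what the designs
claim under controlled conditions: the projection moves planted synonyms
together without touching the vocabulary or a control pair; the CNN
recovers a planted keyword→code mapping essentially perfectly; hybrid
sampling measurably shifts the model toward positive-term evidence. They
do not establish clinical-scale performance: real discharge notes have
vastly larger vocabularies, misspellings, non-keyword syntax, correlated
codes and annotation noise, none of which the generators model. The
benchmark correlations and F-measures of full-scale corpora are outside
what synthetic fixtures can reproduce.

## Numerical details

* Probabilities are clipped to [1e-12, 1−1e-12] inside cross-entropy.
* Degenerate precision/recall ratios (zero denominator) are reported as 0
  with a `degenerate` flag; macro averages include them unless the caller
  filters.
* The "90% most used codes" reporting rule ranks codes by occurrence
  (ties lexicographic) and keeps the smallest prefix covering 90% of
  occurrences; a top-fraction-of-types mode exists as an alternative
  reading.
* Vocabulary ids are assigned by descending frequency, ties lexicographic,
  making builds platform-independent.
* All stochastic routines take explicit integer seeds; nothing reads
  global random state.
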