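# Methods

## Problem setting

The pipeline characterises vaccine-mistrust discourse in a large stream of
short, noisy social-media messages. Its stages mirror how such studies are
actually run: broaden a single seed keyword into the *semantic field* of the
topic using word embeddings, restrict the corpus to messages touching that
field, clean and spell-correct the text, remove bot authors, classify
sentiment into positive / negative / neutral with an imbalance-aware
protocol, and summarise the predictions over time and vocabulary.

Because real tweet collections are not redistributable, the package is
developed and validated against a synthetic corpus generator with planted
ground truth. This document describes each model, its parameters and
defaults, the numerical choices, and what the synthetic validation does and
does not establish.

## Synthetic corpus generator

Each organic tweet is a bag of tokens rendered as space-separated text:

* **Background vocabulary** — 2 000 unique pseudo-words (4–9 lowercase
  letters), sampled with Zipf weights (exponent 1.1, a realistic long-tail
  for token frequencies and a meaningful ranking signal for the
  spell-correction builder). Each tweet draws 4–9 background tokens.
* **Planted semantic field** — 24 French topic words (the seed *vaccin*
  plus treatments, manufacturers and conspiracy vocabulary). 9 % of tweets
  are field tweets (mirroring the ~9 % topical share such filters retain);
  a field tweet carries 2–3 field words with probability 0.8, otherwise 1,
  giving the tight within-tweet co-occurrence the expansion stage must
  detect.
* **Sentiment signal** — class labels drawn i.i.d. from priors
  (0.519, 0.269, 0.212) for neutral/negative/positive, the shares of a
  reference hand-annotation campaign. 90 % of tweets receive 1–2 marker
  words from their class's 8-word marker list; the signal is lexical by
  design, so the classifier has a recoverable but imperfect ceiling.
* **Misspelling noise** — each token of length ≥ 4 is independently
  perturbed with probability 0.1 by exactly one character edit
  (substitution, deletion, insertion or adjacent transposition), with a
  full substitution log in the ground truth.
* **Bot** — one author posts 2 343 copies of 3 fixed templates, each with a
  different random @-mention, inside a single 6-hour window.
* **Decorations** — URLs (15 %), @-mentions (15 %), a hashtag mark on one
  token (10 %); timestamps uniform over Feb 1 – Aug 31 2020.

The generator does **not** emulate grammar, morphology beyond shared
character n-grams, conversational structure, topic drift, or annotator
noise. Passing the recovery tests therefore shows the pipeline's machinery
is correct and well-calibrated on corpora with these statistics — not that
the same thresholds transfer unchanged to a real French tweet stream.

## Embedding trainer

`train_embeddings` is a subword-aware skip-gram with negative sampling
implemented on numpy, single-threaded and fully deterministic given its
seed:

* vocabulary = words with frequency ≥ `min_count`, ordered by (frequency
  desc, word); negative targets from the unigram distribution ^ 0.75;
  dynamic window (radius drawn uniformly in 1..`window` per position);
  frequent-word subsampling with the usual `(sqrt(z/t)+1)·t/z` keep rule at
  `t = 1e-3`; linearly decaying learning rate.
* optional character n-grams (`min_n`..`max_n`, boundary-marked, FNV-1a
  hashed into `bucket` rows); a word's input representation is the mean of
  its word vector and n-gram vectors, so misspelled or unseen forms can be
  composed from n-grams alone.
* updates are applied per mini-batch with the gradient **averaged over
  duplicate rows** within the batch: with Zipf-heavy text a head word can
  occur hundreds of times per batch, and summing those stale-gradient
  contributions diverges. Averaging bounds each row's step and keeps the
  vectorised trainer stable at word2vec-like learning rates.
* after training, the composed vectors are **mean-centred**: small-corpus
  SGNS vectors share a large common direction (all cosines ≈ 1) that
  swamps contrasts; removing the common component restores them. Cosine
  similarity on the centred vectors is the similarity used everywhere.

Defaults in `EmbeddingSettings` (dim 300, n-grams 3–5) reflect a full-scale
corpus. The bundled pipeline runs a scaled-down configuration chosen for
desk-scale corpora: dim 100, window 5, 25 epochs, lr 0.05, 5 negatives,
`min_count` 15, and **no subwords**. Two of these deserve justification:

* `min_count` 15 — words below ~15 occurrences get essentially untrained
  vectors which, after centring, cluster with each other; keeping them
  would let single-linkage expansion chain through that cluster. The floor
  admits all planted field words (≈ 40 occurrences each) while excluding
  the untrained tail. Expansion candidates are exactly the trainer's
  vocabulary; no separate frequency floor is applied.
* no subwords — at a few thousand sentences the n-gram vectors stay close
  to initialisation, so composing each word with ~20 noisy n-gram rows
  dilutes word identity faster than morphology helps. Subword support is
  retained (and tested) for out-of-vocabulary composition and for larger
  corpora.

## Embedding-fit criterion (DCG)

For curated word pairs expected to be near neighbours, the score sums
`g(r) = 1/log2(1+r)` over both directions of each pair, where `r` is the
neighbour rank (ties broken lexicographically) and ranks beyond cutoff
K = 100 earn 0. Pairs with out-of-vocabulary words are skipped (coverage is
reported) or raise, per configuration. Hyperparameter tuning trains one
model per grid candidate and returns the maximiser, ties to the earlier
grid entry, with a full audit table.

## Semantic-field expansion

Single-linkage growth from the seed: each round absorbs every vocabulary
word whose cosine similarity to ≥ 1 current member is ≥ θ; the fixed point
equals the seed's connected component in the θ-similarity graph (verified
against an independent BFS oracle). Centroid linkage is available as an
option. θ is user-defined; the pipeline default θ = 0.85 was chosen on the
default synthetic conditions as the level at which the planted field is
recovered with both precision and recall ≥ 0.8 across seeds (observed
0.96–1.0 / 0.92–1.0). Lowering θ can only grow the field (tested
property). Discovery order is deterministic: within a round, by descending
similarity then lexicographically.

PCA projection of field vectors (deterministic full-SVD, mean-centred) is
provided for visual inspection only.

## Preprocessing

Cleaning removes URLs first, then @-mentions; strips `#` but keeps the tag
word (hashtags carry topic signal); maps all remaining non-word characters
to spaces; lowercases; drops stopwords (an input word list — none is
hard-coded) and tokens shorter than 2. Tokens are NFC-normalised but
accents are kept (French minimal pairs). Cleaning is idempotent.

Spelling correction ranks out-of-lexicon tokens by corpus frequency (ties
lexicographic), takes the top 3 000, and maps each to the
Damerau-Levenshtein-nearest lexicon word if the distance is ≤ 2 (ties:
more corpus-frequent correction, then lexicographic). Candidate lookup
uses a deletion-neighbourhood index so only plausible lexicon words are
compared exactly. The map is emitted as editable two-column TSV so a
curated dictionary can grow beyond the automatic entries. Corrections are
exact-token, single-pass (never re-corrected). On default synthetic
conditions the map restores ≈ 98–100 % of planted single-edit
misspellings; the residual losses are misspellings that collide with
another lexicon word or fall past the top-n cut.

Keyword filtering is exact-token (the field lists morphological variants
as separate keywords) and case-insensitive through cleaning; it is monotone
in the keyword set. Bot filtering flags an author iff posts ≥ 100 and
mention-stripped distinct texts ≤ 3, removing all posts of flagged authors.

## Sentiment protocol

* **Split** — per-class test counts are `count × fraction` rounded by
  largest remainder so the total equals `round(N × fraction)`; default test
  fraction 0.2; selection within class is a seeded shuffle.
* **TF-IDF** — `tf · (ln((1+N)/(1+df)) + 1)`, rows L2-normalised, unseen
  terms ignored (cross-checked against scikit-learn).
* **MNB** — Lidstone smoothing α = 1 on the real-valued TF-IDF features
  (fractional counts); priors are class document shares; prediction ties
  resolve majority-class first (neutral, negative, positive) for
  determinism. Cross-checked against a brute-force Bayes enumeration and
  scikit-learn.
* **Baseline** — the neutral-only constant predictor; its accuracy on any
  set is the modal-class share (0.52 on the reference label counts).
* **Encoder stage** — a contract only: a pretrained encoder with a 3-logit
  linear head satisfying the same predict interface. Without a deep
  learning runtime the stage warns and is skipped; the pipeline completes
  via MNB. Reproducing a fine-tuned transformer's reported accuracy would
  require the original hand-labelled data and weights, which are not
  distributable.

## Evaluation

Confusion matrices use the fixed class order (positive, negative, neutral).
The report emits per-class precision/recall/F1, macro (unweighted mean),
micro (pooled TP/FP/FN — provably equal to accuracy for single-label
multiclass, and property-tested), weighted averages, and accuracy.
Zero-division yields 0 with a warning (needed for the degenerate neutral-only
baseline). Both micro and weighted rows are emitted because published tables
do not always follow the standard micro definition; this implementation
keeps the standard one.

## Pipeline

Stage order: generate/ingest → bot filter → clean → correct → embed
(optional DCG tuning) → expand → keyword filter → split/train/predict →
evaluate → trends. One global seed fans out per stage as
`seed XOR crc32(stage_name) mod 2^31`. Every artifact is line-oriented
text; the manifest records per-stage parameters, record counts and wall
times and references every file written. Reruns with identical config are
byte-identical except for the manifest's timings.

## Known limitations

* The generator's bag-of-tokens texts cannot probe word-order effects;
  bigram tables on synthetic data reflect shuffled bags.
* The embedding trainer is designed for desk-scale corpora (10⁴–10⁵ short
  sentences); it is not an optimised replacement for production embedding
  libraries at 10⁸-token scale.
* Correction quality depends on lexicon coverage: with an incomplete
  lexicon, valid unseen words are candidate "misspellings" and can be
  falsely mapped to a near lexicon word.
* θ = 0.85 and `min_count` = 15 are calibrated to the default synthetic
  conditions; new corpora need their own calibration (the DCG audit table
  and the expansion's discovery order are the intended tools for that).
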