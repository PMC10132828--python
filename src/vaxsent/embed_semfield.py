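"""Word embeddings, embedding-fit scoring, and semantic-field expansion.

This module carries the lexical half of the study: learn dense word vectors
from the (cleaned) tweet stream, score candidate hyperparameter settings
with a discounted-cumulative-gain (DCG) criterion over curated word pairs
that are known to be close in meaning, then grow a *semantic field* from a
seed word ("vaccin") by iteratively absorbing every vocabulary word whose
cosine similarity to a current member reaches a user-defined threshold.
The resulting keyword set drives corpus filtering downstream; a 2-D PCA
projection of the field supports visual inspection.

The trainer is a subword-aware skip-gram with negative sampling, written on
numpy: each word is represented by its own vector plus hashed character
n-gram vectors (boundary-marked, lengths ``min_n..max_n``), and the input
representation is their mean — so rare and misspelled forms still receive
usable vectors.  Training is single-threaded and fully determined by the
settings seed.

DCG convention: for a word pair (a, b), gain ``g(r) = 1 / log2(1 + r)`` is
accrued for the rank of b among a's nearest neighbours *and* for the rank
of a among b's (a symmetric two-direction sum), with ranks beyond the
cutoff K contributing 0.  Higher totals mean the embedding space places
known-related pairs closer, i.e. fits the corpus better.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "EmbeddingSettings",
    "EmbeddingTable",
    "DcgConfig",
    "SemanticField",
    "TrainingError",
    "train_embeddings",
    "cosine_similarity",
    "neighbor_rank",
    "dcg_score",
    "tune_hyperparams",
    "expand_semantic_field",
    "pca_project",
]


class TrainingError(RuntimeError):
    """Raised when an embedding model cannot be trained on the given corpus."""


@dataclass(frozen=True)
class EmbeddingSettings:
    """Hyperparameters of one skip-gram training run.

    ``dim`` defaults to 300, the dimensionality used for the full-scale
    corpus; tests and the bundled pipeline use smaller values.  ``min_n`` /
    ``max_n`` bound the character n-grams (0/0 disables subwords);
    ``bucket`` is the hashed n-gram table size.
    """

    dim: int = 300
    window: int = 5
    epochs: int = 5
    learning_rate: float = 0.05
    negative: int = 5
    min_count: int = 5
    min_n: int = 3
    max_n: int = 5
    bucket: int = 1 << 15
    batch_size: int = 512
    #: frequent-word subsampling threshold (0 disables)
    subsample: float = 1e-3
    seed: int = 0

    def validate(self) -> None:
        if self.dim < 1 or self.window < 1 or self.epochs < 1:
            raise ValueError("dim, window and epochs must be >= 1")
        if self.negative < 1 or self.min_count < 1:
            raise ValueError("negative and min_count must be >= 1")
        if (self.min_n == 0) != (self.max_n == 0):
            raise ValueError("min_n and max_n must both be 0 or both be > 0")
        if self.min_n > self.max_n:
            raise ValueError("min_n must not exceed max_n")


def _fnv1a(data: bytes) -> int:
    h = 0x811C9DC5
    for byte in data:
        h = ((h ^ byte) * 0x01000193) & 0xFFFFFFFF
    return h


def _subword_ngrams(word: str, min_n: int, max_n: int) -> list[str]:
    if min_n == 0:
        return []
    padded = f"<{word}>"
    grams = []
    for n in range(min_n, max_n + 1):
        for i in range(len(padded) - n + 1):
            g = padded[i : i + n]
            if g != padded:
                grams.append(g)
    return grams


class EmbeddingTable:
    """Word -> dense vector map with cosine similarity.

    ``vectors[i]`` is the composed representation of ``words[i]`` (word
    vector averaged with its subword vectors).  When the table retains its
    subword block, :meth:`vector` can also compose vectors for
    out-of-vocabulary words from their character n-grams alone.
    """

    def __init__(
        self,
        words: Sequence[str],
        vectors: np.ndarray,
        metadata: dict | None = None,
        subword_block: np.ndarray | None = None,
        subword_params: tuple[int, int, int] | None = None,
        subword_offset: np.ndarray | None = None,
    ):
        if any(not w for w in words):
            raise ValueError("vocabulary entries must be non-empty")
        vectors = np.asarray(vectors, dtype=np.float32)
        if vectors.ndim != 2 or vectors.shape[0] != len(words):
            raise ValueError("vectors must be a (len(words), d) matrix")
        self.words: list[str] = list(words)
        self.vectors = vectors
        self.index: dict[str, int] = {w: i for i, w in enumerate(self.words)}
        if len(self.index) != len(self.words):
            raise ValueError("duplicate vocabulary entries")
        self.metadata = dict(metadata or {})
        self._subword_block = subword_block  # (bucket, d) hashed n-gram rows
        self._subword_params = subword_params  # (min_n, max_n, bucket)
        self._subword_offset = subword_offset  # centering offset for OOV vectors
        self._unit: np.ndarray | None = None

    @property
    def dim(self) -> int:
        return int(self.vectors.shape[1])

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self.index

    def vector(self, word: str) -> np.ndarray:
        """Vector for *word*; out-of-vocabulary words are composed from their
        hashed character n-grams when the subword block is available."""
        i = self.index.get(word)
        if i is not None:
            return self.vectors[i]
        if self._subword_block is not None and self._subword_params is not None:
            min_n, max_n, bucket = self._subword_params
            grams = _subword_ngrams(word, min_n, max_n)
            if grams:
                rows = [_fnv1a(g.encode("utf-8")) % bucket for g in grams]
                vec = self._subword_block[rows].mean(axis=0)
                if self._subword_offset is not None:
                    vec = vec - self._subword_offset
                return vec
        raise KeyError(f"word not in vocabulary: {word!r}")

    def unit_vectors(self) -> np.ndarray:
        """Row-normalised vectors (cached); zero rows left as zeros."""
        if self._unit is None:
            norms = np.linalg.norm(self.vectors, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            self._unit = self.vectors / norms
        return self._unit

    def similarity(self, a: str, b: str) -> float:
        return cosine_similarity(self.vector(a), self.vector(b))

    def save_word2vec(self, path: str | Path) -> None:
        """Plain-text format: header ``vocab_size dim``, then one word and
        its components per line."""
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write(f"{len(self.words)} {self.dim}\n")
            for w, vec in zip(self.words, self.vectors):
                fh.write(w + " " + " ".join(f"{x:.6f}" for x in vec) + "\n")

    @classmethod
    def load_word2vec(cls, path: str | Path) -> "EmbeddingTable":
        with Path(path).open("r", encoding="utf-8") as fh:
            header = fh.readline().split()
            n, d = int(header[0]), int(header[1])
            words, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                words.append(parts[0])
                rows.append([float(x) for x in parts[1 : d + 1]])
        if len(words) != n:
            raise ValueError(f"{path}: header promises {n} rows, found {len(words)}")
        return cls(words, np.asarray(rows, dtype=np.float32))


# ---------------------------------------------------------------------------
# training


def _build_vocab(
    corpus_tokens: Iterable[Sequence[str]], min_count: int
) -> tuple[list[str], dict[str, int], np.ndarray, list[np.ndarray]]:
    freq: dict[str, int] = {}
    sentences = []
    for sent in corpus_tokens:
        sentences.append(sent)
        for tok in sent:
            if tok:
                freq[tok] = freq.get(tok, 0) + 1
    words = sorted((w for w, c in freq.items() if c >= min_count), key=lambda w: (-freq[w], w))
    index = {w: i for i, w in enumerate(words)}
    counts = np.array([freq[w] for w in words], dtype=np.float64)
    encoded = []
    for sent in sentences:
        ids = np.array([index[t] for t in sent if t in index], dtype=np.int32)
        if len(ids) >= 2:
            encoded.append(ids)
    return words, index, counts, encoded


def _generate_pairs(
    encoded: list[np.ndarray],
    window: int,
    keep_prob: np.ndarray | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """(center, context) id pairs with a dynamic window drawn per center.

    With *keep_prob* given, tokens are first thinned by frequent-word
    subsampling (the classic ``(sqrt(z/t)+1)·t/z`` keep rule), which both
    de-emphasises Zipf-head words and keeps any one word from dominating a
    training batch.
    """
    centers: list[int] = []
    contexts: list[int] = []
    for ids in encoded:
        if keep_prob is not None:
            ids = ids[rng.random(len(ids)) < keep_prob[ids]]
        L = len(ids)
        if L < 2:
            continue
        spans = rng.integers(1, window + 1, size=L)
        for i in range(L):
            b = int(spans[i])
            lo, hi = max(0, i - b), min(L, i + b + 1)
            for j in range(lo, hi):
                if j != i:
                    centers.append(int(ids[i]))
                    contexts.append(int(ids[j]))
    if not centers:
        return np.empty((0, 2), dtype=np.int32)
    return np.stack(
        [np.array(centers, dtype=np.int32), np.array(contexts, dtype=np.int32)], axis=1
    )


def train_embeddings(
    corpus_tokens: Iterable[Sequence[str]],
    settings: EmbeddingSettings = EmbeddingSettings(),
) -> EmbeddingTable:
    """Train a subword-aware skip-gram model with negative sampling.

    Every word with corpus frequency >= ``settings.min_count`` receives a
    vector.  Negative targets are drawn from the unigram distribution raised
    to the 3/4 power.  The run is deterministic for a fixed settings seed.

    Raises :class:`TrainingError` if the corpus is empty or too small to
    yield a single (center, context) pair.
    """
    settings.validate()
    words, index, counts, encoded = _build_vocab(corpus_tokens, settings.min_count)
    if not words or not encoded:
        raise TrainingError(
            "corpus too small: no word reaches min_count within a usable sentence"
        )
    V, d = len(words), settings.dim
    rng = np.random.default_rng(settings.seed)

    use_subwords = settings.min_n > 0
    bucket = settings.bucket if use_subwords else 0
    # input rows: [0, V) word vectors, [V, V+bucket) hashed n-gram vectors
    w_in = ((rng.random((V + bucket, d)) - 0.5) / d).astype(np.float32)
    w_out = np.zeros((V, d), dtype=np.float32)

    if use_subwords:
        row_lists = []
        for i, w in enumerate(words):
            grams = _subword_ngrams(w, settings.min_n, settings.max_n)
            row_lists.append(
                [i] + [V + _fnv1a(g.encode("utf-8")) % bucket for g in grams]
            )
    else:
        row_lists = [[i] for i in range(V)]
    max_s = max(len(r) for r in row_lists)
    sub_rows = np.zeros((V, max_s), dtype=np.int64)
    sub_mask = np.zeros((V, max_s), dtype=np.float32)
    for i, r in enumerate(row_lists):
        sub_rows[i, : len(r)] = r
        sub_mask[i, : len(r)] = 1.0
    sub_counts = sub_mask.sum(axis=1)

    noise = counts**0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    keep_prob = None
    if settings.subsample > 0:
        z = counts / counts.sum()
        t = settings.subsample
        keep_prob = np.minimum(1.0, (np.sqrt(z / t) + 1.0) * t / z)

    epoch_pairs = [
        _generate_pairs(encoded, settings.window, keep_prob, rng)
        for _ in range(settings.epochs)
    ]
    total_pairs = sum(len(p) for p in epoch_pairs)
    if total_pairs == 0:
        raise TrainingError("corpus smaller than one context window")

    from scipy.special import expit

    lr0, K, B = settings.learning_rate, settings.negative, settings.batch_size
    done = 0
    for pairs in epoch_pairs:
        order = rng.permutation(len(pairs))
        pairs = pairs[order]
        for s in range(0, len(pairs), B):
            batch = pairs[s : s + B]
            nb = len(batch)
            lr = lr0 * max(1e-4, 1.0 - done / total_pairs)
            done += nb

            c, o = batch[:, 0], batch[:, 1]
            rows = sub_rows[c]  # (nb, S)
            mask = sub_mask[c]
            h = (w_in[rows] * mask[..., None]).sum(axis=1) / sub_counts[c][:, None]

            negs = np.searchsorted(noise_cdf, rng.random((nb, K))).astype(np.int64)
            targets = np.concatenate([o[:, None], negs], axis=1)  # (nb, K+1)
            labels = np.zeros((nb, K + 1), dtype=np.float32)
            labels[:, 0] = 1.0

            t_vecs = w_out[targets]  # (nb, K+1, d)
            scores = np.einsum("bd,bkd->bk", h, t_vecs)
            g = (labels - expit(scores)) * lr  # (nb, K+1)

            # average (not sum) the gradient over duplicate rows within the
            # batch, so Zipf-head words take bounded steps per update
            flat_t = targets.ravel()
            t_dup = np.bincount(flat_t, minlength=V)[flat_t].astype(np.float32)
            grad_h = np.einsum("bk,bkd->bd", g, t_vecs)
            np.add.at(
                w_out,
                flat_t,
                (g[..., None] * h[:, None, :]).reshape(-1, d) / t_dup[:, None],
            )
            flat_r = rows.ravel()
            flat_m = mask.ravel()
            r_dup = np.bincount(
                flat_r, weights=flat_m, minlength=V + bucket
            )[flat_r].astype(np.float32)
            r_dup[r_dup == 0] = 1.0
            contrib = (grad_h / sub_counts[c][:, None])[:, None, :] * mask[..., None]
            np.add.at(w_in, flat_r, contrib.reshape(-1, d) / r_dup[:, None])

    composed = (
        (w_in[sub_rows] * sub_mask[..., None]).sum(axis=1) / sub_counts[:, None]
    ).astype(np.float32)
    # remove the common component: SGNS vectors share a large mean direction
    # that swamps cosine contrasts; centering restores them
    mean_vec = composed.mean(axis=0)
    composed -= mean_vec

    meta = {
        "dim": d,
        "window": settings.window,
        "epochs": settings.epochs,
        "learning_rate": settings.learning_rate,
        "negative": settings.negative,
        "min_count": settings.min_count,
        "min_n": settings.min_n,
        "max_n": settings.max_n,
        "seed": settings.seed,
        "n_sentences": len(encoded),
        "n_pairs": int(total_pairs),
    }
    return EmbeddingTable(
        words,
        composed,
        metadata=meta,
        subword_block=w_in[V:] if use_subwords else None,
        subword_params=(settings.min_n, settings.max_n, bucket) if use_subwords else None,
        subword_offset=mean_vec if use_subwords else None,
    )


# ---------------------------------------------------------------------------
# similarity, ranks, DCG


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two nonzero vectors, in [-1, 1]."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def neighbor_rank(table: EmbeddingTable, a: str, b: str) -> int:
    """Rank (1-based) of *b* in the descending-similarity ordering of the
    vocabulary relative to *a*, excluding *a* itself; similarity ties are
    broken by lexicographic word order."""
    for w in (a, b):
        if w not in table:
            raise KeyError(f"word not in vocabulary: {w!r}")
    if a == b:
        raise ValueError("neighbor_rank requires two distinct words")
    U = table.unit_vectors()
    ia = table.index[a]
    sims = U @ U[ia]
    target = (-float(sims[table.index[b]]), b)
    rank = 1
    for j, w in enumerate(table.words):
        if j == ia:
            continue
        if (-float(sims[j]), w) < target:
            rank += 1
    return rank


@dataclass
class DcgConfig:
    """Word pairs plus rank cutoff K for the embedding-fit criterion."""

    pairs: Sequence[tuple[str, str]]
    rank_cutoff: int = 100
    missing_word_policy: str = "skip"  # or "error"

    def validate(self) -> None:
        if self.rank_cutoff < 1:
            raise ValueError("rank_cutoff must be >= 1")
        if self.missing_word_policy not in ("skip", "error"):
            raise ValueError("missing_word_policy must be 'skip' or 'error'")
        if not self.pairs:
            raise ValueError("pair list must be non-empty")


def _gain(rank: int, cutoff: int) -> float:
    return 1.0 / math.log2(1.0 + rank) if rank <= cutoff else 0.0


def dcg_score(table: EmbeddingTable, config: DcgConfig) -> tuple[float, float]:
    """Two-direction DCG over the pair list.

    Returns ``(score, coverage)`` where coverage is the fraction of pairs
    with both words in vocabulary.  With policy ``skip``, pairs containing a
    missing word contribute nothing; with ``error`` they raise.
    """
    config.validate()
    score = 0.0
    usable = 0
    for a, b in config.pairs:
        if a not in table or b not in table:
            if config.missing_word_policy == "error":
                missing = a if a not in table else b
                raise KeyError(f"word not in vocabulary: {missing!r}")
            continue
        usable += 1
        score += _gain(neighbor_rank(table, a, b), config.rank_cutoff)
        score += _gain(neighbor_rank(table, b, a), config.rank_cutoff)
    if usable == 0:
        raise ValueError("no usable word pairs (all contain missing words)")
    return score, usable / len(config.pairs)


def tune_hyperparams(
    corpus_tokens: Sequence[Sequence[str]],
    grid: Sequence[EmbeddingSettings],
    config: DcgConfig,
) -> tuple[EmbeddingSettings, list[dict]]:
    """Train one model per grid candidate and return the DCG-maximising
    settings (ties broken by grid order) plus the full audit table."""
    if not grid:
        raise ValueError("hyperparameter grid must be non-empty")
    rows: list[dict] = []
    best_i, best_score = None, -np.inf
    for i, settings in enumerate(grid):
        row: dict = {"settings": settings}
        try:
            table = train_embeddings(corpus_tokens, settings)
            score, coverage = dcg_score(table, config)
            row.update(score=score, coverage=coverage, error=None)
            if score > best_score:
                best_i, best_score = i, score
        except Exception as exc:  # recorded per candidate, not fatal
            row.update(score=None, coverage=None, error=str(exc))
        rows.append(row)
    if best_i is None:
        raise TrainingError("every grid candidate failed to train or score")
    return grid[best_i], rows


# ---------------------------------------------------------------------------
# semantic-field expansion


@dataclass
class SemanticField:
    """Seed word, similarity threshold, members in discovery order."""

    seed: str
    threshold: float
    members: list[str] = field(default_factory=list)
    iterations: int = 0
    converged: bool = True

    def __contains__(self, word: str) -> bool:
        return word in self.members

    def __len__(self) -> int:
        return len(self.members)


def expand_semantic_field(
    table: EmbeddingTable,
    seed: str,
    theta: float,
    max_iter: int = 100,
    linkage: str = "single",
) -> SemanticField:
    """Grow the seed's semantic field to a fixed point.

    With single linkage (default), each round absorbs every vocabulary word
    whose cosine similarity to at least one current member is >= ``theta``;
    the fixed point is the connected component containing the seed in the
    graph joining word pairs with similarity >= theta.  With centroid
    linkage, membership is tested against the mean vector of the current
    members instead.  Stops after ``max_iter`` rounds without convergence
    and flags the result.
    """
    if seed not in table:
        raise KeyError(f"seed word not in vocabulary: {seed!r}")
    if not -1.0 <= theta <= 1.0:
        raise ValueError("theta must be in [-1, 1]")
    if linkage not in ("single", "centroid"):
        raise ValueError("linkage must be 'single' or 'centroid'")

    U = table.unit_vectors()
    n = len(table)
    member = np.zeros(n, dtype=bool)
    seed_i = table.index[seed]
    member[seed_i] = True
    members = [seed]
    frontier = [seed_i]
    iterations = 0
    converged = True

    for _ in range(max_iter):
        if linkage == "single":
            sims = U[frontier] @ U.T  # (|frontier|, n)
            best = sims.max(axis=0)
        else:
            centroid = table.vectors[member].mean(axis=0)
            norm = np.linalg.norm(centroid)
            if norm == 0:
                break
            best = U @ (centroid / norm)
        new = np.flatnonzero((best >= theta) & ~member)
        if new.size == 0:
            break
        iterations += 1
        order = sorted(new, key=lambda j: (-float(best[j]), table.words[j]))
        for j in order:
            member[j] = True
            members.append(table.words[j])
        frontier = list(order)
    else:
        # loop exhausted max_iter with growth still possible
        converged = False

    return SemanticField(
        seed=seed,
        threshold=theta,
        members=members,
        iterations=iterations,
        converged=converged,
    )


def pca_project(
    table: EmbeddingTable, words: Sequence[str], k: int = 2
) -> dict[str, np.ndarray]:
    """Mean-centred projection of the words' vectors onto the top-k principal
    axes (deterministic full SVD; component variances non-increasing)."""
    if len(words) < k + 1:
        raise ValueError(f"need at least {k + 1} words for a {k}-D projection")
    missing = [w for w in words if w not in table]
    if missing:
        raise KeyError(f"words not in vocabulary: {missing[:5]!r}")
    from sklearn.decomposition import PCA

    X = np.stack([table.vectors[table.index[w]] for w in words]).astype(np.float64)
    proj = PCA(n_components=k, svd_solver="full").fit_transform(X)
    return {w: proj[i] for i, w in enumerate(words)}


def default_settings_grid() -> list[EmbeddingSettings]:
    """A small, auditable grid around the default training settings."""
    base = EmbeddingSettings(dim=100, epochs=5, window=5)
    return [
        base,
        replace(base, window=3),
        replace(base, learning_rate=0.025),
    ]
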