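"""Three-class sentiment classification with an imbalance-aware protocol.

The labelled data are heavily skewed towards the neutral class
(≈ 52/27/21 neutral/negative/positive), so the module provides:

* :func:`stratified_split` — a train/test partition that preserves each
  class's share via largest-remainder rounding;
* :func:`majority_baseline` — the neutral-only constant predictor whose
  accuracy equals the modal-class share (the floor any model must beat);
* TF-IDF + multinomial naive Bayes, implemented from the formulas:
  ``tfidf(d,t) = tf(d,t) · (ln((1+N)/(1+df(t))) + 1)`` with L2-normalised
  rows, and MNB with Lidstone smoothing
  ``P(t|c) = (Σ_{d∈c} x_dt + α) / (Σ_t Σ_{d∈c} x_dt + α|V|)``, consuming
  the real-valued TF-IDF weights as fractional counts;
* a pluggable encoder-classifier contract for a transformer stage: the
  stage is optional and the pipeline completes without it.

Prediction ties are broken majority-class first (neutral, then negative,
then positive) for determinism.
"""

from __future__ import annotations

import importlib.util
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "LabeledSet",
    "TfidfModel",
    "MnbModel",
    "MajorityClassifier",
    "EncoderClassifierSpec",
    "CLASS_PREFERENCE",
    "stratified_split",
    "fit_tfidf",
    "tfidf_transform",
    "fit_mnb",
    "mnb_predict",
    "majority_baseline",
    "train_encoder_classifier",
]

#: tie-break preference: majority class first
CLASS_PREFERENCE = ("neutral", "negative", "positive")


def _ordered_classes(labels: Sequence[str]) -> list[str]:
    present = set(labels)
    if present <= set(CLASS_PREFERENCE):
        return [c for c in CLASS_PREFERENCE if c in present]
    return sorted(present)


@dataclass
class LabeledSet:
    """(tokenized document, label) pairs."""

    docs: list[list[str]]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.docs) != len(self.labels):
            raise ValueError("docs and labels must have equal length")

    def __len__(self) -> int:
        return len(self.docs)

    @property
    def class_counts(self) -> dict[str, int]:
        return dict(Counter(self.labels))


def stratified_split(
    data: LabeledSet, test_fraction: float, seed: int
) -> tuple[LabeledSet, LabeledSet]:
    """Disjoint, exhaustive train/test split preserving class shares.

    Per-class test counts are ``class_count × test_fraction`` rounded by the
    largest-remainder method so the total equals
    ``round(N × test_fraction)``.  Deterministic given the seed.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    counts = data.class_counts
    small = [c for c, n in counts.items() if n < 2]
    if small:
        raise ValueError(f"every class needs >= 2 members; too small: {small}")

    classes = _ordered_classes(data.labels)
    total_test = round(len(data) * test_fraction)
    raw = {c: counts[c] * test_fraction for c in classes}
    take = {c: int(np.floor(raw[c])) for c in classes}
    leftover = total_test - sum(take.values())
    # assign remaining slots by largest fractional remainder (ties: class order)
    by_remainder = sorted(
        classes, key=lambda c: (-(raw[c] - take[c]), classes.index(c))
    )
    for c in by_remainder[: max(0, leftover)]:
        take[c] += 1

    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    by_class: dict[str, list[int]] = {c: [] for c in classes}
    for i, lab in enumerate(data.labels):
        by_class[lab].append(i)
    for c in classes:
        idx = np.array(by_class[c])
        rng.shuffle(idx)
        test_idx.extend(int(i) for i in idx[: take[c]])
    test_set = set(test_idx)
    train_i = [i for i in range(len(data)) if i not in test_set]
    test_i = sorted(test_set)
    return (
        LabeledSet([data.docs[i] for i in train_i], [data.labels[i] for i in train_i]),
        LabeledSet([data.docs[i] for i in test_i], [data.labels[i] for i in test_i]),
    )


# ---------------------------------------------------------------------------
# TF-IDF


@dataclass
class TfidfModel:
    vocabulary: dict[str, int]
    idf: np.ndarray
    n_docs: int = 0


def fit_tfidf(train_docs: Sequence[Sequence[str]]) -> TfidfModel:
    """Fit IDF weights: ``idf(t) = ln((1+N)/(1+df(t))) + 1``."""
    if not train_docs:
        raise ValueError("training set must be non-empty")
    df: Counter[str] = Counter()
    for doc in train_docs:
        df.update(set(doc))
    if not df:
        raise ValueError("all training documents are empty")
    vocab = {t: i for i, t in enumerate(sorted(df))}
    n = len(train_docs)
    idf = np.empty(len(vocab))
    for t, i in vocab.items():
        idf[i] = np.log((1.0 + n) / (1.0 + df[t])) + 1.0
    return TfidfModel(vocabulary=vocab, idf=idf, n_docs=n)


def tfidf_transform(model: TfidfModel, docs: Sequence[Sequence[str]]) -> sp.csr_matrix:
    """Weight matrix (docs × terms), rows L2-normalised; unseen terms are
    ignored and a document of only unseen terms yields a zero row."""
    rows, cols, vals = [], [], []
    for i, doc in enumerate(docs):
        tf: Counter[int] = Counter(
            model.vocabulary[t] for t in doc if t in model.vocabulary
        )
        for j, c in tf.items():
            rows.append(i)
            cols.append(j)
            vals.append(c * model.idf[j])
    X = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(docs), len(model.vocabulary))
    )
    norms = np.sqrt(np.asarray(X.multiply(X).sum(axis=1)).ravel())
    norms[norms == 0] = 1.0
    return sp.diags(1.0 / norms) @ X


# ---------------------------------------------------------------------------
# multinomial naive Bayes


@dataclass
class MnbModel:
    classes: list[str]
    class_log_prior: np.ndarray
    feature_log_prob: np.ndarray  # (C, V)
    alpha: float = 1.0


def fit_mnb(
    X: sp.spmatrix | np.ndarray, y: Sequence[str], alpha: float = 1.0
) -> MnbModel:
    """Fit MNB with Lidstone smoothing on nonnegative (possibly fractional)
    feature totals."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    X = sp.csr_matrix(X)
    if X.shape[0] != len(y):
        raise ValueError("X rows must align with y")
    if X.nnz and X.min() < 0:
        raise ValueError("feature matrix must be nonnegative")
    classes = _ordered_classes(y)
    y_arr = np.asarray(y)
    n, v = X.shape
    priors = np.empty(len(classes))
    cond = np.empty((len(classes), v))
    for ci, c in enumerate(classes):
        mask = y_arr == c
        if not mask.any():
            raise ValueError(f"class absent from y: {c!r}")
        priors[ci] = mask.sum() / n
        totals = np.asarray(X[mask].sum(axis=0)).ravel()
        cond[ci] = (totals + alpha) / (totals.sum() + alpha * v)
    return MnbModel(
        classes=classes,
        class_log_prior=np.log(priors),
        feature_log_prob=np.log(cond),
        alpha=alpha,
    )


def mnb_predict(
    model: MnbModel, X: sp.spmatrix | np.ndarray
) -> tuple[list[str], np.ndarray]:
    """Labels and class-probability rows (columns follow ``model.classes``).

    The label is the most probable class; exact ties go to the earlier class
    in ``model.classes`` (majority class first).
    """
    X = sp.csr_matrix(X)
    if X.shape[1] != model.feature_log_prob.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: X has {X.shape[1]}, "
            f"model expects {model.feature_log_prob.shape[1]}"
        )
    joint = X @ model.feature_log_prob.T + model.class_log_prior
    joint = np.asarray(joint)
    m = joint.max(axis=1, keepdims=True)
    probs = np.exp(joint - m)
    probs /= probs.sum(axis=1, keepdims=True)
    labels = [model.classes[int(i)] for i in np.argmax(joint, axis=1)]
    return labels, probs


# ---------------------------------------------------------------------------
# baselines and the optional encoder stage


@dataclass
class MajorityClassifier:
    """Constant predictor of the modal training class; its accuracy on any
    evaluation set is that set's modal-class share."""

    modal_class: str
    classes: list[str]
    priors: np.ndarray

    def predict(self, docs: Sequence) -> tuple[list[str], np.ndarray]:
        n = len(docs)
        return [self.modal_class] * n, np.tile(self.priors, (n, 1))


def majority_baseline(train: LabeledSet) -> MajorityClassifier:
    if not len(train):
        raise ValueError("training set must be non-empty")
    classes = _ordered_classes(train.labels)
    counts = train.class_counts
    modal = max(classes, key=lambda c: (counts[c], -classes.index(c)))
    priors = np.array([counts[c] / len(train) for c in classes])
    return MajorityClassifier(modal_class=modal, classes=classes, priors=priors)


@dataclass
class EncoderClassifierSpec:
    """Contract for a pretrained-encoder + linear-head classifier (3 logits).

    The stage needs a locally available encoder and a deep-learning runtime;
    when either is missing the stage is skipped with a warning and the
    pipeline falls back to the MNB baseline.
    """

    encoder_id: str = "camembert-base"
    head: str = "linear-3"
    epochs: int = 3
    learning_rate: float = 2e-5
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.head != "linear-3":
            raise ValueError("classification head must map to exactly 3 logits")


class EncoderUnavailableWarning(UserWarning):
    pass


def train_encoder_classifier(spec: EncoderClassifierSpec, train: LabeledSet):
    """Train the optional transformer stage if a runtime is available.

    Returns a classifier satisfying the same predict contract as
    :func:`mnb_predict`, or ``None`` (with a warning) when the encoder
    runtime is unavailable — callers must treat ``None`` as "stage
    skipped", never as a pipeline failure.
    """
    for mod in ("torch", "transformers"):
        if importlib.util.find_spec(mod) is None:
            warnings.warn(
                f"encoder stage skipped: {mod!r} is not installed",
                EncoderUnavailableWarning,
                stacklevel=2,
            )
            return None
    raise NotImplementedError(
        "encoder fine-tuning requires project-specific weights and schedule; "
        "plug in a classifier object satisfying the mnb_predict contract"
    )
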