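"""Temporal and lexical summaries of predicted sentiment.

:func:`daily_counts` buckets labelled tweets by UTC calendar date and emits
a complete date span (days with no tweets appear with zero counts), one
column per sentiment class.  :func:`top_ngrams` tabulates the most frequent
words and bigrams per class; bigrams are formed from adjacent tokens within
a single tweet only — they never cross tweet boundaries.  The neutral class
is computed like the others; rendering typically focuses on positive and
negative, which carry the interpretable signal.
"""

from __future__ import annotations

import warnings
from collections import Counter
from typing import Sequence

import pandas as pd

from .corpus_io import Corpus
from .evalmetrics import DEFAULT_CLASSES

__all__ = ["daily_counts", "top_ngrams", "ngram_table_tsv"]


def daily_counts(
    corpus: Corpus,
    labels: dict[str, str],
    classes: Sequence[str] = DEFAULT_CLASSES,
) -> pd.DataFrame:
    """Per-date class counts over the corpus's full date span.

    Tweets without a label are excluded with a warning reporting how many.
    Returns a DataFrame indexed by date with one integer column per class;
    each row sums to the number of labelled tweets that day.
    """
    rows = []
    unlabeled = 0
    for rec in corpus:
        lab = labels.get(rec.id)
        if lab is None:
            unlabeled += 1
            continue
        if lab not in classes:
            raise ValueError(f"unknown label: {lab!r}")
        rows.append((rec.created_at.date(), lab))
    if unlabeled:
        warnings.warn(f"excluded {unlabeled} tweet(s) without a label", stacklevel=2)
    if not rows:
        return pd.DataFrame(columns=list(classes), dtype="int64")
    df = pd.DataFrame(rows, columns=["date", "label"])
    table = (
        df.pivot_table(index="date", columns="label", aggfunc="size", fill_value=0)
        .reindex(columns=list(classes), fill_value=0)
    )
    span = pd.date_range(table.index.min(), table.index.max(), freq="D").date
    table = table.reindex(span, fill_value=0)
    table.index.name = "date"
    table.columns.name = None
    return table.astype("int64")


def top_ngrams(
    tokens_by_class: dict[str, list[list[str]]],
    n: int = 1,
    k: int = 30,
) -> dict[str, list[tuple[str, int]]]:
    """Top-k n-grams (n in {1, 2}) per class by frequency, ties broken
    lexicographically.  Bigrams join adjacent tokens with a space."""
    if n not in (1, 2):
        raise ValueError("n must be 1 or 2")
    out: dict[str, list[tuple[str, int]]] = {}
    for cls, docs in tokens_by_class.items():
        counts: Counter[str] = Counter()
        for toks in docs:
            if n == 1:
                counts.update(toks)
            else:
                counts.update(
                    f"{a} {b}" for a, b in zip(toks, toks[1:])
                )
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        out[cls] = ranked[:k]
    return out


def ngram_table_tsv(table: list[tuple[str, int]]) -> str:
    return "".join(f"{g}\t{c}\n" for g, c in table)


def plot_daily_counts(
    series: pd.DataFrame,
    path: str,
    classes: Sequence[str] = ("positive", "negative"),
) -> None:
    """Render the daily series to an image (requires matplotlib; the neutral
    class is omitted by default as it carries little interpretable signal)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    for cls in classes:
        ax.plot(series.index, series[cls], label=cls, lw=0.9)
    ax.set_xlabel("date")
    ax.set_ylabel("tweets per day")
    ax.legend()
    fig.autofmt_xdate()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
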