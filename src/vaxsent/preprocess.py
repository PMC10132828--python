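"""Noise-aware preprocessing for short social-media text.

Four stages, each exposed separately so the pipeline can audit record
counts in and out:

* :func:`clean_text` — remove URLs then @-mentions, strip ``#`` while
  keeping the tag word (hashtags carry topic signal), drop punctuation and
  special characters, lowercase, tokenize on whitespace, drop stopwords and
  very short tokens.  Tokens are Unicode-normalised (NFC) but accents are
  *kept*: French has minimal pairs that differ only in diacritics.
* :func:`build_correction_map` / :func:`apply_corrections` — rank
  out-of-lexicon tokens by corpus frequency, map each of the top-n to its
  nearest lexicon word under Damerau-Levenshtein distance (cutoff 2), and
  substitute exact tokens in a single pass.  The map is emitted as editable
  TSV so a curated dictionary can grow beyond the automatic entries.
* :func:`filter_by_keywords` — keep tweets whose cleaned token set meets
  the semantic-field keyword list (exact-token matching: the field lists
  morphological variants as separate keywords).
* :func:`detect_and_remove_bots` — flag authors with many posts but only a
  handful of distinct texts once @-mentions are stripped, and drop all
  their posts.
"""

from __future__ import annotations

import re
import unicodedata
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .corpus_io import Corpus

__all__ = [
    "CleanConfig",
    "CorrectionMap",
    "BotFilterConfig",
    "damerau_levenshtein",
    "clean_text",
    "build_correction_map",
    "apply_corrections",
    "filter_by_keywords",
    "detect_and_remove_bots",
]

_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_MENTION_RE = re.compile(r"@\w+")
# anything that is not a word character becomes a space; underscores too
_NONWORD_RE = re.compile(r"[\W_]+", re.UNICODE)


@dataclass
class CleanConfig:
    stopword_list: frozenset[str] = frozenset()
    strip_urls: bool = True
    strip_mentions: bool = True
    strip_hashmarks: bool = True
    min_token_length: int = 2

    def __post_init__(self) -> None:
        self.stopword_list = frozenset(w.lower() for w in self.stopword_list)


def clean_text(text: str, config: CleanConfig = CleanConfig()) -> list[str]:
    """Clean one message into a token list.  Idempotent: cleaning a cleaned
    and re-joined text returns the same tokens."""
    if not text or not text.strip():
        return []
    s = unicodedata.normalize("NFC", text)
    if config.strip_urls:
        s = _URL_RE.sub(" ", s)
    if config.strip_mentions:
        s = _MENTION_RE.sub(" ", s)
    if config.strip_hashmarks:
        s = s.replace("#", " ")  # drop the mark, keep the tag word
    else:
        s = re.sub(r"#\w+", " ", s)  # drop the whole hashtag
    s = _NONWORD_RE.sub(" ", s).lower()
    return [
        t
        for t in s.split()
        if len(t) >= config.min_token_length and t not in config.stopword_list
    ]


# ---------------------------------------------------------------------------
# spelling correction


def damerau_levenshtein(a: str, b: str, max_dist: int | None = None) -> int:
    """Restricted Damerau-Levenshtein distance (substitution, insertion,
    deletion, adjacent transposition).  With *max_dist*, returns
    ``max_dist + 1`` as soon as the distance provably exceeds it."""
    if a == b:
        return 0
    la, lb = len(a), len(b)
    if max_dist is not None and abs(la - lb) > max_dist:
        return max_dist + 1
    prev2: list[int] | None = None
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if (
                i > 1
                and j > 1
                and a[i - 1] == b[j - 2]
                and a[i - 2] == b[j - 1]
            ):
                cur[j] = min(cur[j], prev2[j - 2] + 1)
        if max_dist is not None and min(cur) > max_dist:
            return max_dist + 1
        prev2, prev = prev, cur
    return prev[lb]


@dataclass
class CorrectionMap:
    """misspelling -> correction entries plus build metadata."""

    entries: dict[str, str] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, token: str) -> bool:
        return token in self.entries


def _deletions(word: str, depth: int) -> set[str]:
    out = {word}
    frontier = {word}
    for _ in range(depth):
        nxt = set()
        for w in frontier:
            for i in range(len(w)):
                nxt.add(w[:i] + w[i + 1 :])
        out |= nxt
        frontier = nxt
    return out


def build_correction_map(
    corpus_tokens: Iterable[Sequence[str]],
    lexicon: set[str],
    top_n: int = 3000,
    max_edit: int = 2,
) -> CorrectionMap:
    """Build a spelling-correction map from corpus statistics.

    Candidate misspellings are the tokens absent from the lexicon, ranked by
    corpus frequency (ties lexicographic).  For each of the ``top_n``
    candidates, the correction is the lexicon word at minimal
    Damerau-Levenshtein distance, accepted only when that distance is
    <= ``max_edit``; distance ties prefer the lexicon word that is more
    frequent in the corpus, then the lexicographically smaller one.

    Candidate lookup uses a deletion-neighbourhood index (depth
    ``max_edit``) over the lexicon, so only words that can possibly be
    within range are compared exactly.
    """
    if not lexicon:
        raise ValueError("lexicon must be non-empty")
    freq: Counter[str] = Counter()
    for sent in corpus_tokens:
        freq.update(sent)
    if not freq:
        return CorrectionMap(metadata={"top_n": top_n, "max_edit": max_edit})

    oov = sorted(
        (t for t in freq if t not in lexicon), key=lambda t: (-freq[t], t)
    )[:top_n]

    index: dict[str, list[str]] = {}
    for w in lexicon:
        for key in _deletions(w, max_edit):
            index.setdefault(key, []).append(w)

    entries: dict[str, str] = {}
    for token in oov:
        candidates: set[str] = set()
        for key in _deletions(token, max_edit):
            candidates.update(index.get(key, ()))
        best: tuple[int, int, str] | None = None
        for cand in candidates:
            d = damerau_levenshtein(token, cand, max_dist=max_edit)
            if d > max_edit:
                continue
            key_t = (d, -freq.get(cand, 0), cand)
            if best is None or key_t < best:
                best = key_t
        if best is not None and best[2] != token:
            entries[token] = best[2]

    return CorrectionMap(
        entries=entries,
        metadata={
            "top_n": top_n,
            "max_edit": max_edit,
            "lexicon_size": len(lexicon),
            "oov_considered": len(oov),
        },
    )


def apply_corrections(tokens: Sequence[str], cmap: CorrectionMap) -> list[str]:
    """Exact-token substitution in a single pass (corrections are not
    themselves re-corrected)."""
    return [cmap.entries.get(t, t) for t in tokens]


# ---------------------------------------------------------------------------
# filtering


def filter_by_keywords(
    corpus: Corpus,
    keywords: set[str] | Sequence[str],
    config: CleanConfig = CleanConfig(),
    correction_map: CorrectionMap | None = None,
) -> Corpus:
    """Retain exactly the tweets whose cleaned (optionally spell-corrected)
    token set contains at least one keyword.  Matching is exact-token and
    case-insensitive through cleaning."""
    keyset = set(keywords)
    if not keyset:
        raise ValueError("keyword set must be non-empty")
    kept = []
    for rec in corpus:
        toks = clean_text(rec.text, config)
        if correction_map is not None:
            toks = apply_corrections(toks, correction_map)
        if keyset.intersection(toks):
            kept.append(rec)
    out = Corpus(records=kept, provenance=list(corpus.provenance))
    out.provenance.append(
        f"keyword filter: {len(keyset)} keywords, retained {len(kept)}/{len(corpus)}"
    )
    return out


@dataclass
class BotFilterConfig:
    """An author is bot-like when it has >= ``min_posts`` posts but at most
    ``max_distinct_texts`` distinct texts once mentions are stripped."""

    min_posts: int = 100
    max_distinct_texts: int = 3

    def __post_init__(self) -> None:
        if self.min_posts < 1 or self.max_distinct_texts < 1:
            raise ValueError("min_posts and max_distinct_texts must be >= 1")


def _mention_stripped(text: str) -> str:
    return " ".join(_MENTION_RE.sub(" ", text).split())


def detect_and_remove_bots(
    corpus: Corpus, config: BotFilterConfig = BotFilterConfig()
) -> tuple[Corpus, list[str]]:
    """Flag bot-like authors and remove every one of their posts (all posts
    of an author are removed or none)."""
    by_author: dict[str, list[str]] = {}
    for rec in corpus:
        by_author.setdefault(rec.author_id, []).append(rec.text)
    flagged = sorted(
        author
        for author, texts in by_author.items()
        if len(texts) >= config.min_posts
        and len({_mention_stripped(t) for t in texts}) <= config.max_distinct_texts
    )
    flagged_set = set(flagged)
    kept = [rec for rec in corpus if rec.author_id not in flagged_set]
    removed = len(corpus) - len(kept)
    if flagged:
        warnings.warn(
            f"removed {removed} post(s) from {len(flagged)} bot-like author(s)",
            stacklevel=2,
        )
    out = Corpus(records=kept, provenance=list(corpus.provenance))
    out.provenance.append(
        f"bot filter: flagged {len(flagged)} author(s), removed {removed} post(s)"
    )
    return out, flagged
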