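"""Synthetic tweet-corpus generator with planted ground truth.

Real vaccine-discourse collections hydrated from platform APIs cannot be
redistributed, so every downstream stage of this package is exercised on a
generated corpus that emulates the statistical features the pipeline relies
on:

* a small *semantic field* of topically related words (seeded on "vaccin")
  that co-occurs tightly inside a minority of tweets, against a Zipf-like
  background vocabulary;
* a lexical sentiment signal: class-specific marker words mixed into tweets
  at a configurable rate, with imbalanced class priors
  (neutral/negative/positive ≈ 52/27/21);
* character-level misspelling noise (exactly one edit per perturbed token)
  with a full substitution log, so spelling-correction recall is measurable;
* one bot author that posts a small set of fixed templates with a different
  @-mention each time;
* URL / mention / hashtag decorations and timestamps spanning months.

Tweets are bags of tokens rendered as space-separated text: enough to
exercise cleaning, embedding, filtering and classification without
modelling grammar.  Identical (config, seed) produces byte-identical
output.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field, asdict
from datetime import date, datetime, timedelta, timezone
from pathlib import Path

import numpy as np

from .corpus_io import Corpus, TweetRecord

#: Planted semantic field: the designated seed word first, then 23 companions
#: (drug/treatment names, manufacturers, conspiracy vocabulary) — the kind of
#: lexical neighbourhood a vaccine-mistrust corpus exhibits.
DEFAULT_FIELD_VOCAB = (
    "vaccin",
    "vaccination",
    "vacciner",
    "chloroquine",
    "hydroxychloroquine",
    "remdesivir",
    "azithromycine",
    "dexamethasone",
    "antiviraux",
    "traitement",
    "pfizer",
    "moderna",
    "sanofi",
    "astrazeneca",
    "novartis",
    "gilead",
    "laboratoire",
    "complot",
    "conspiration",
    "lobby",
    "puce",
    "cobaye",
    "charlatan",
    "mondialiste",
)

DEFAULT_SENTIMENT_WORDS = {
    "positive": (
        "efficace",
        "encourageant",
        "espoir",
        "prometteur",
        "confiance",
        "protection",
        "progres",
        "bravo",
    ),
    "negative": (
        "dangereux",
        "mefiance",
        "refus",
        "toxique",
        "scandale",
        "peur",
        "mensonge",
        "corruption",
    ),
    "neutral": (
        "annonce",
        "information",
        "article",
        "selon",
        "communique",
        "chiffres",
        "journal",
        "reportage",
    ),
}

DEFAULT_BOT_TEMPLATES = (
    "decouvrez la verite sur le virus suivez notre chaine",
    "grande promotion masques et gel achetez maintenant lien en bio",
    "rejoignez notre groupe pour des infos exclusives sur la pandemie",
)


class GeneratorConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic corpus.

    Class priors default to the neutral/negative/positive shares of a
    hand-labelled vaccine-discourse sample (51.9 / 26.9 / 21.2 %); the bot
    posts 2343 copies of 3 templates; misspelling noise hits 10 % of
    eligible tokens.  Corpus size and vocabulary shape are engineering
    defaults sized so the planted structure is learnable by the embedding
    stage in seconds, not hours.
    """

    n_tweets: int = 5000
    date_start: date = date(2020, 2, 1)
    date_end: date = date(2020, 8, 31)
    #: (neutral, negative, positive)
    class_priors: tuple[float, float, float] = (0.519, 0.269, 0.212)
    field_vocab: tuple[str, ...] = DEFAULT_FIELD_VOCAB
    background_vocab_size: int = 2000
    zipf_exponent: float = 1.1
    #: fraction of tweets that belong to the planted topic at all
    field_tweet_rate: float = 0.09
    #: probability that a field tweet draws >= 2 field words
    field_cooccurrence_rate: float = 0.8
    sentiment_signal_words: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SENTIMENT_WORDS)
    )
    #: probability that a tweet carries at least one class marker word
    sentiment_signal_rate: float = 0.9
    misspelling_rate: float = 0.1
    bot_templates: tuple[str, ...] = DEFAULT_BOT_TEMPLATES
    bot_post_count: int = 2343
    bot_author_id: str = "bot_7355608"
    #: min/max background tokens per tweet (inclusive)
    tokens_per_tweet: tuple[int, int] = (4, 9)
    url_rate: float = 0.15
    mention_rate: float = 0.15
    hashtag_rate: float = 0.10
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_tweets < 0:
            raise GeneratorConfigError("n_tweets must be >= 0")
        if self.bot_post_count < 0:
            raise GeneratorConfigError("bot_post_count must be >= 0")
        if len(self.class_priors) != 3 or abs(sum(self.class_priors) - 1.0) > 1e-9:
            raise GeneratorConfigError("class_priors must be 3 values summing to 1")
        if any(p < 0 for p in self.class_priors):
            raise GeneratorConfigError("class_priors must be nonnegative")
        for name in (
            "field_tweet_rate",
            "field_cooccurrence_rate",
            "sentiment_signal_rate",
            "misspelling_rate",
            "url_rate",
            "mention_rate",
            "hashtag_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GeneratorConfigError(f"{name} must be in [0, 1]")
        if self.zipf_exponent <= 0:
            raise GeneratorConfigError("zipf_exponent must be > 0")
        if self.background_vocab_size < 1:
            raise GeneratorConfigError("background_vocab_size must be >= 1")
        if not self.field_vocab:
            raise GeneratorConfigError("field_vocab must be non-empty")
        if self.date_end < self.date_start:
            raise GeneratorConfigError("date_end must not precede date_start")
        if self.bot_post_count and not self.bot_templates:
            raise GeneratorConfigError("bot_templates must be non-empty")

    @property
    def seed_word(self) -> str:
        return self.field_vocab[0]


@dataclass
class GroundTruth:
    """Planted truth for one generated corpus, keyed by tweet id."""

    labels: dict[str, str] = field(default_factory=dict)
    misspellings: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    bot_author_ids: set[str] = field(default_factory=set)
    planted_field: set[str] = field(default_factory=set)
    seed_word: str = ""
    #: every intended (pre-noise) vocabulary item: background + field + markers
    lexicon: set[str] = field(default_factory=set)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "labels": self.labels,
            "misspellings": {k: [list(p) for p in v] for k, v in self.misspellings.items()},
            "bot_author_ids": sorted(self.bot_author_ids),
            "planted_field": sorted(self.planted_field),
            "seed_word": self.seed_word,
            "lexicon": sorted(self.lexicon),
        }
        Path(path).write_text(json.dumps(obj, ensure_ascii=False, indent=1), "utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        obj = json.loads(Path(path).read_text("utf-8"))
        return cls(
            labels=obj["labels"],
            misspellings={
                k: [tuple(p) for p in v] for k, v in obj["misspellings"].items()
            },
            bot_author_ids=set(obj["bot_author_ids"]),
            planted_field=set(obj["planted_field"]),
            seed_word=obj["seed_word"],
            lexicon=set(obj["lexicon"]),
        )


_LETTERS = string.ascii_lowercase


def _one_edit(token: str, rng: np.random.Generator) -> str:
    """Apply exactly one character edit (substitution, deletion, insertion or
    adjacent transposition), guaranteed to change the token."""
    ops = ["sub", "del", "ins", "swap"]
    op = ops[int(rng.integers(len(ops)))]
    if op == "swap":
        positions = [i for i in range(len(token) - 1) if token[i] != token[i + 1]]
        if positions:
            i = positions[int(rng.integers(len(positions)))]
            return token[:i] + token[i + 1] + token[i] + token[i + 2 :]
        op = "sub"  # e.g. "aaaa": no effective transposition exists
    if op == "sub":
        i = int(rng.integers(len(token)))
        alternatives = [c for c in _LETTERS if c != token[i]]
        return token[:i] + alternatives[int(rng.integers(len(alternatives)))] + token[i + 1 :]
    if op == "del":
        i = int(rng.integers(len(token)))
        return token[:i] + token[i + 1 :]
    i = int(rng.integers(len(token) + 1))
    return token[:i] + _LETTERS[int(rng.integers(26))] + token[i:]


def inject_misspellings(
    tokens: list[str],
    rate: float,
    rng: np.random.Generator,
    min_length: int = 4,
) -> tuple[list[str], list[tuple[str, str]]]:
    """Independently perturb each token of length >= *min_length* with
    probability *rate* by exactly one character edit.

    Returns the perturbed sequence and a log of ``(misspelled, intended)``
    substitutions, one entry per change.
    """
    if not 0.0 <= rate <= 1.0:
        raise GeneratorConfigError("misspelling rate must be in [0, 1]")
    if not tokens:
        return [], []
    draws = rng.random(len(tokens))
    out: list[str] = []
    log: list[tuple[str, str]] = []
    for tok, u in zip(tokens, draws):
        if len(tok) >= min_length and u < rate:
            bad = _one_edit(tok, rng)
            out.append(bad)
            log.append((bad, tok))
        else:
            out.append(tok)
    return out, log


def _make_background_vocab(
    size: int, reserved: set[str], rng: np.random.Generator
) -> list[str]:
    """Deterministic pseudo-word background vocabulary (unique, disjoint from
    the planted field and marker words)."""
    words: list[str] = []
    seen = set(reserved)
    while len(words) < size:
        n = int(rng.integers(4, 10))
        w = "".join(_LETTERS[i] for i in rng.integers(0, 26, size=n))
        if w not in seen:
            seen.add(w)
            words.append(w)
    return words


def generate_corpus(config: GeneratorConfig) -> tuple[Corpus, GroundTruth]:
    """Generate a corpus and its ground truth.

    Organic tweets are emitted in timestamp order; the bot's posts (fixed
    templates, varying mentions, a burst inside one afternoon) are appended
    after them.  Exactly ``n_tweets + bot_post_count`` records are produced.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)

    classes = ("neutral", "negative", "positive")
    markers = {c: tuple(config.sentiment_signal_words.get(c, ())) for c in classes}
    reserved = set(config.field_vocab)
    for words in markers.values():
        reserved.update(words)
    background = _make_background_vocab(config.background_vocab_size, reserved, rng)

    ranks = np.arange(1, len(background) + 1, dtype=float)
    zipf_p = ranks ** (-config.zipf_exponent)
    zipf_p /= zipf_p.sum()

    truth = GroundTruth(
        planted_field=set(config.field_vocab),
        seed_word=config.seed_word,
        lexicon=set(background) | reserved,
    )

    n = config.n_tweets
    start_dt = datetime.combine(config.date_start, datetime.min.time(), timezone.utc)
    end_dt = datetime.combine(
        config.date_end, datetime.min.time(), timezone.utc
    ) + timedelta(days=1)
    span = int((end_dt - start_dt).total_seconds())

    label_idx = rng.choice(3, size=n, p=np.asarray(config.class_priors)) if n else []
    is_field = rng.random(n) < config.field_tweet_rate if n else []
    lengths = (
        rng.integers(config.tokens_per_tweet[0], config.tokens_per_tweet[1] + 1, size=n)
        if n
        else []
    )
    timestamps = np.sort(rng.integers(0, span, size=n)) if n else []
    n_authors = max(1, n // 3)
    author_idx = rng.integers(0, n_authors, size=n) if n else []

    total_bg = int(np.sum(lengths)) if n else 0
    bg_draw = rng.choice(len(background), size=total_bg, p=zipf_p) if total_bg else []

    records: list[TweetRecord] = []
    pos = 0
    for i in range(n):
        label = classes[int(label_idx[i])]
        toks = [background[j] for j in bg_draw[pos : pos + int(lengths[i])]]
        pos += int(lengths[i])

        if is_field[i]:
            if rng.random() < config.field_cooccurrence_rate:
                k = 2 + int(rng.integers(2))  # 2 or 3 field words
            else:
                k = 1
            k = min(k, len(config.field_vocab))
            picks = rng.choice(len(config.field_vocab), size=k, replace=False)
            toks.extend(config.field_vocab[j] for j in picks)

        if markers[label] and rng.random() < config.sentiment_signal_rate:
            m = 1 + int(rng.integers(2))  # 1 or 2 markers
            picks = rng.choice(len(markers[label]), size=min(m, len(markers[label])), replace=False)
            toks.extend(markers[label][j] for j in picks)

        rng.shuffle(toks)
        toks, log = inject_misspellings(toks, config.misspelling_rate, rng)

        if rng.random() < config.hashtag_rate and toks:
            j = int(rng.integers(len(toks)))
            toks[j] = "#" + toks[j]
        if rng.random() < config.mention_rate:
            j = int(rng.integers(len(toks) + 1))
            toks.insert(j, f"@user{int(rng.integers(100000))}")
        if rng.random() < config.url_rate:
            tail = "".join(
                "abcdefghijklmnopqrstuvwxyz0123456789"[c]
                for c in rng.integers(0, 36, size=8)
            )
            toks.append("https://t.co/" + tail)

        tid = f"t{i:07d}"
        records.append(
            TweetRecord(
                id=tid,
                created_at=start_dt + timedelta(seconds=int(timestamps[i])),
                author_id=f"u{int(author_idx[i]):05d}",
                lang="fr",
                text=" ".join(toks),
            )
        )
        truth.labels[tid] = label
        if log:
            truth.misspellings[tid] = log

    # Bot burst: fixed templates, a fresh mention each post, one short window.
    if config.bot_post_count:
        truth.bot_author_ids.add(config.bot_author_id)
        mid = start_dt + timedelta(seconds=span // 2)
        burst = np.sort(rng.integers(0, 6 * 3600, size=config.bot_post_count))
        for j in range(config.bot_post_count):
            template = config.bot_templates[j % len(config.bot_templates)]
            text = f"{template} @user{int(rng.integers(1000000))}"
            tid = f"b{j:07d}"
            records.append(
                TweetRecord(
                    id=tid,
                    created_at=mid + timedelta(seconds=int(burst[j])),
                    author_id=config.bot_author_id,
                    lang="fr",
                    text=text,
                )
            )
            truth.labels[tid] = "neutral"

    corpus = Corpus(records=records)
    corpus.provenance.append(
        f"synthetic corpus: n_tweets={n}, bot_posts={config.bot_post_count}, "
        f"seed={config.rng_seed}"
    )
    return corpus, truth


def config_to_dict(config: GeneratorConfig) -> dict:
    """JSON-serialisable view of a config (dates as ISO strings)."""
    d = asdict(config)
    d["date_start"] = config.date_start.isoformat()
    d["date_end"] = config.date_end.isoformat()
    return d
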