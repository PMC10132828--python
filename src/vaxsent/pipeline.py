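"""End-to-end orchestration of the study as configurable stages.

Stage order mirrors the study design: generate (or ingest) → bot filter →
clean → spelling correction → embedding training (optionally tuned on a
grid with the DCG criterion) → semantic-field expansion → keyword filter →
stratified split + MNB training → prediction → evaluation → trends.

Each executed stage appends a manifest entry (parameters, record counts
in/out, output files, wall time) and every file written to the output
directory is referenced by the manifest.  One global seed fans out to
per-stage seeds through CRC-32 of the stage name, so stages stay
individually reproducible; reruns with an identical config produce
byte-identical artifacts for every deterministic stage.
"""

from __future__ import annotations

import copy
import json
import time
import zlib
from dataclasses import replace
from pathlib import Path

import yaml

from . import corpus_io, embed_semfield, preprocess, sentiment, synthetic_corpus, trends
from .corpus_io import Corpus
from .embed_semfield import DcgConfig, EmbeddingSettings
from .preprocess import BotFilterConfig, CleanConfig
from .sentiment import LabeledSet

__all__ = [
    "DEFAULT_CONFIG",
    "load_config",
    "validate_config",
    "run_pipeline",
    "stage_seed",
    "PipelineError",
]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": {
        "generate": True,
        "bots": True,
        "clean": True,
        "correct": True,
        "embed": True,
        "tune": False,
        "expand": True,
        "filter": True,
        "train": True,
        "encoder": False,
        "evaluate": True,
        "trends": True,
    },
    "input": {"corpus_path": None, "labels_path": None, "lexicon_path": None},
    "generator": {},  # overrides for synthetic_corpus.GeneratorConfig fields
    # word-level vectors: at desk scale, character n-gram composition dilutes
    # word identity faster than the n-grams can be trained, so the pipeline
    # trains plain skip-gram vectors; subwords stay available via min_n/max_n
    "embedding": {
        "dim": 100,
        "window": 5,
        "epochs": 25,
        "learning_rate": 0.05,
        "negative": 5,
        "min_count": 15,
        "min_n": 0,
        "max_n": 0,
    },
    "dcg": {"rank_cutoff": 100, "pairs_path": None},
    "expand": {"seed_word": None, "theta": 0.85, "max_iter": 100},
    "clean": {"stopwords_path": None, "min_token_length": 2},
    "correction": {"top_n": 3000, "max_edit": 2},
    "bots": {"min_posts": 100, "max_distinct_texts": 3},
    "split": {"test_fraction": 0.2},
    "mnb": {"alpha": 1.0},
    "trends": {"top_k": 30},
}


def _deep_update(base: dict, overrides: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in overrides.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Default config, optionally merged with a YAML file and/or a dict."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text("utf-8")) or {}
        if not isinstance(loaded, dict):
            raise PipelineError(f"config file must hold a mapping: {path}")
        cfg = _deep_update(cfg, loaded)
    if overrides:
        cfg = _deep_update(cfg, overrides)
    return cfg


def validate_config(config: dict) -> dict:
    """Collect (not fail-fast) every configuration error.

    Returns ``{"valid": bool, "errors": [str, ...]}``.
    """
    errors: list[str] = []
    stages = config.get("stages", {})

    if not isinstance(config.get("seed"), int):
        errors.append("seed: must be an integer")

    if stages.get("generate"):
        try:
            _generator_config(config)
        except Exception as exc:
            errors.append(f"generator: {exc}")
    else:
        cpath = config.get("input", {}).get("corpus_path")
        if not cpath:
            errors.append("input.corpus_path: required when generate stage is off")
        elif not Path(cpath).exists():
            errors.append(f"input.corpus_path: file not found: {cpath}")

    if stages.get("expand"):
        theta = config.get("expand", {}).get("theta")
        if theta is None:
            errors.append("expand.theta: required when expand stage is enabled")
        elif not (-1.0 < float(theta) <= 1.0):
            errors.append("expand.theta: must be in (-1, 1]")
        if not stages.get("generate") and not config.get("expand", {}).get("seed_word"):
            errors.append("expand.seed_word: required when not generating")

    tf = config.get("split", {}).get("test_fraction")
    if not isinstance(tf, (int, float)) or not 0.0 < float(tf) < 1.0:
        errors.append("split.test_fraction: must be in (0, 1)")

    alpha = config.get("mnb", {}).get("alpha", 1.0)
    if not isinstance(alpha, (int, float)) or alpha <= 0:
        errors.append("mnb.alpha: must be > 0")

    if stages.get("embed"):
        try:
            _embedding_settings(config, seed=0)
        except Exception as exc:
            errors.append(f"embedding: {exc}")

    for key in ("min_posts", "max_distinct_texts"):
        v = config.get("bots", {}).get(key, 1)
        if not isinstance(v, int) or v < 1:
            errors.append(f"bots.{key}: must be an integer >= 1")

    sp = config.get("clean", {}).get("stopwords_path")
    if sp and not Path(sp).exists():
        errors.append(f"clean.stopwords_path: file not found: {sp}")
    pp = config.get("dcg", {}).get("pairs_path")
    if pp and not Path(pp).exists():
        errors.append(f"dcg.pairs_path: file not found: {pp}")

    return {"valid": not errors, "errors": errors}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: global seed XOR CRC-32 of the name."""
    return (int(global_seed) ^ zlib.crc32(stage.encode("utf-8"))) % (2**31)


def _generator_config(config: dict) -> synthetic_corpus.GeneratorConfig:
    from datetime import date

    overrides = dict(config.get("generator", {}))
    for key in ("date_start", "date_end"):
        if key in overrides and isinstance(overrides[key], str):
            overrides[key] = date.fromisoformat(overrides[key])
    for key in ("class_priors", "field_vocab", "bot_templates", "tokens_per_tweet"):
        if key in overrides and isinstance(overrides[key], list):
            overrides[key] = tuple(overrides[key])
    gen_cfg = synthetic_corpus.GeneratorConfig(**overrides)
    gen_cfg.validate()
    return gen_cfg


def _embedding_settings(config: dict, seed: int) -> EmbeddingSettings:
    settings = EmbeddingSettings(seed=seed, **config.get("embedding", {}))
    settings.validate()
    return settings


def _clean_config(config: dict) -> CleanConfig:
    block = config.get("clean", {})
    stopwords: frozenset[str] = frozenset()
    if block.get("stopwords_path"):
        stopwords = frozenset(corpus_io.read_keywords(block["stopwords_path"]))
    return CleanConfig(
        stopword_list=stopwords,
        min_token_length=int(block.get("min_token_length", 2)),
    )


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute every enabled stage; return (and write) the run manifest.

    Raises :class:`PipelineError` naming the failing stage; the partial
    manifest is still written to ``manifest.json``.
    """
    report = validate_config(config)
    if not report["valid"]:
        raise PipelineError("invalid config: " + "; ".join(report["errors"]))

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages_on = config["stages"]
    seed = int(config["seed"])
    manifest: dict = {"seed": seed, "stages": [], "files": []}

    def emit(name: str, content_writer, filename: str) -> str:
        path = out / filename
        content_writer(path)
        manifest["files"].append(filename)
        return filename

    def record(stage: str, t0: float, **info) -> None:
        manifest["stages"].append(
            {"stage": stage, "seconds": round(time.perf_counter() - t0, 3), **info}
        )

    current_stage = "init"
    try:
        # ------------------------------------------------ generate / ingest
        current_stage = "generate"
        t0 = time.perf_counter()
        truth = None
        if stages_on.get("generate"):
            gen_cfg = _generator_config(config)
            gen_cfg.rng_seed = stage_seed(seed, "generate")
            corpus, truth = synthetic_corpus.generate_corpus(gen_cfg)
            labels = dict(truth.labels)
            lexicon = set(truth.lexicon)
            seed_word = truth.seed_word
            emit("generate", lambda p: corpus_io.write_corpus(corpus, p), "corpus.jsonl")
            emit("generate", truth.to_json, "ground_truth.json")
            record(
                "generate",
                t0,
                n_records=len(corpus),
                params={"rng_seed": gen_cfg.rng_seed, "n_tweets": gen_cfg.n_tweets},
            )
        else:
            corpus = corpus_io.read_corpus(config["input"]["corpus_path"])
            labels = (
                corpus_io.read_labels(config["input"]["labels_path"])
                if config["input"].get("labels_path")
                else {}
            )
            lexicon = (
                set(corpus_io.read_keywords(config["input"]["lexicon_path"]))
                if config["input"].get("lexicon_path")
                else set()
            )
            seed_word = config["expand"].get("seed_word")
            record("ingest", t0, n_records=len(corpus))

        # ------------------------------------------------ bot filter
        if stages_on.get("bots"):
            current_stage = "bots"
            t0 = time.perf_counter()
            bot_cfg = BotFilterConfig(**config.get("bots", {}))
            before = len(corpus)
            corpus, flagged = preprocess.detect_and_remove_bots(corpus, bot_cfg)
            emit("bots", lambda p: corpus_io.write_corpus(corpus, p), "corpus_nobots.jsonl")
            record(
                "bots",
                t0,
                n_in=before,
                n_out=len(corpus),
                flagged_authors=flagged,
                removed=before - len(corpus),
            )

        # ------------------------------------------------ clean + correct
        clean_cfg = _clean_config(config)
        current_stage = "clean"
        t0 = time.perf_counter()
        tokens = {rec.id: preprocess.clean_text(rec.text, clean_cfg) for rec in corpus}
        record("clean", t0, n_records=len(tokens))

        correction_map = None
        if stages_on.get("correct") and lexicon:
            current_stage = "correct"
            t0 = time.perf_counter()
            corr_cfg = config.get("correction", {})
            correction_map = preprocess.build_correction_map(
                tokens.values(),
                lexicon,
                top_n=int(corr_cfg.get("top_n", 3000)),
                max_edit=int(corr_cfg.get("max_edit", 2)),
            )
            tokens = {
                tid: preprocess.apply_corrections(toks, correction_map)
                for tid, toks in tokens.items()
            }
            emit(
                "correct",
                lambda p: corpus_io.write_correction_map(correction_map.entries, p),
                "correction_map.tsv",
            )
            record("correct", t0, entries=len(correction_map))

        token_lists = [tokens[rec.id] for rec in corpus]

        # ------------------------------------------------ embeddings
        table = None
        if stages_on.get("embed"):
            current_stage = "embed"
            t0 = time.perf_counter()
            emb_seed = stage_seed(seed, "embed")
            pairs_path = config["dcg"].get("pairs_path")
            if pairs_path:
                pairs = corpus_io.read_word_pairs(pairs_path)
            elif truth is not None:
                fv = sorted(truth.planted_field)
                pairs = [(fv[i], fv[(i + 1) % len(fv)]) for i in range(len(fv))]
            else:
                pairs = []
            dcg_cfg = (
                DcgConfig(pairs=pairs, rank_cutoff=int(config["dcg"]["rank_cutoff"]))
                if pairs
                else None
            )
            if stages_on.get("tune") and dcg_cfg is not None:
                base = _embedding_settings(config, seed=emb_seed)
                grid = [base, replace(base, window=max(2, base.window - 2))]
                best, score_rows = embed_semfield.tune_hyperparams(
                    token_lists, grid, dcg_cfg
                )
                table = embed_semfield.train_embeddings(token_lists, best)
                tune_info = [
                    {
                        "window": r["settings"].window,
                        "score": r["score"],
                        "error": r["error"],
                    }
                    for r in score_rows
                ]
            else:
                settings = _embedding_settings(config, seed=emb_seed)
                table = embed_semfield.train_embeddings(token_lists, settings)
                tune_info = None
            if pairs:
                emit(
                    "embed",
                    lambda p: corpus_io.write_word_pairs(pairs, p),
                    "word_pairs.tsv",
                )
            emit("embed", table.save_word2vec, "embeddings.vec")
            dcg_val = (
                embed_semfield.dcg_score(table, dcg_cfg) if dcg_cfg is not None else None
            )
            record(
                "embed",
                t0,
                vocab=len(table),
                dim=table.dim,
                dcg=None if dcg_val is None else dcg_val[0],
                dcg_coverage=None if dcg_val is None else dcg_val[1],
                tune=tune_info,
            )

        # ------------------------------------------------ semantic field
        keywords = None
        if stages_on.get("expand"):
            current_stage = "expand"
            t0 = time.perf_counter()
            if table is None:
                raise PipelineError("expand stage requires the embed stage")
            if not seed_word:
                raise PipelineError("no seed word available for expansion")
            sf = embed_semfield.expand_semantic_field(
                table,
                seed_word,
                theta=float(config["expand"]["theta"]),
                max_iter=int(config["expand"].get("max_iter", 100)),
            )
            keywords = list(sf.members)
            emit(
                "expand",
                lambda p: corpus_io.write_keywords(keywords, p),
                "field_keywords.txt",
            )
            record(
                "expand",
                t0,
                n_keywords=len(keywords),
                theta=sf.threshold,
                iterations=sf.iterations,
                converged=sf.converged,
            )

        # ------------------------------------------------ keyword filter
        if stages_on.get("filter") and keywords:
            current_stage = "filter"
            t0 = time.perf_counter()
            before = len(corpus)
            keyset = set(keywords)
            kept = [rec for rec in corpus if keyset.intersection(tokens[rec.id])]
            corpus = Corpus(records=kept, provenance=list(corpus.provenance))
            corpus.provenance.append(
                f"keyword filter: {len(keyset)} keywords, retained {len(kept)}/{before}"
            )
            emit("filter", lambda p: corpus_io.write_corpus(corpus, p), "corpus_field.jsonl")
            record("filter", t0, n_in=before, n_out=len(corpus))

        # ------------------------------------------------ train + predict
        report_obj = None
        predictions: dict[str, str] = {}
        if stages_on.get("train"):
            current_stage = "train"
            t0 = time.perf_counter()
            labelled = [rec.id for rec in corpus if rec.id in labels]
            data = LabeledSet(
                docs=[tokens[tid] for tid in labelled],
                labels=[labels[tid] for tid in labelled],
            )
            train_set, test_set = sentiment.stratified_split(
                data, float(config["split"]["test_fraction"]), stage_seed(seed, "split")
            )
            tfidf = sentiment.fit_tfidf(train_set.docs)
            X_train = sentiment.tfidf_transform(tfidf, train_set.docs)
            mnb = sentiment.fit_mnb(
                X_train, train_set.labels, alpha=float(config["mnb"]["alpha"])
            )
            baseline = sentiment.majority_baseline(train_set)

            encoder_used = False
            if stages_on.get("encoder"):
                spec = sentiment.EncoderClassifierSpec(seed=stage_seed(seed, "encoder"))
                encoder_used = (
                    sentiment.train_encoder_classifier(spec, train_set) is not None
                )

            X_test = sentiment.tfidf_transform(tfidf, test_set.docs)
            y_pred, _ = sentiment.mnb_predict(mnb, X_test)
            y_base, _ = baseline.predict(test_set.docs)

            # predict the whole (filtered) corpus for the trend stage
            X_all = sentiment.tfidf_transform(tfidf, [tokens[t] for t in labelled])
            all_pred, all_probs = sentiment.mnb_predict(mnb, X_all)
            predictions = dict(zip(labelled, all_pred))

            def write_predictions(path):
                with Path(path).open("w", encoding="utf-8") as fh:
                    fh.write("id\tlabel\t" + "\t".join(f"p_{c}" for c in mnb.classes) + "\n")
                    for tid, lab, row in zip(labelled, all_pred, all_probs):
                        fh.write(
                            f"{tid}\t{lab}\t" + "\t".join(f"{p:.6f}" for p in row) + "\n"
                        )

            emit("train", write_predictions, "predictions.tsv")
            cm = None
            if stages_on.get("evaluate"):
                from .evalmetrics import classification_report, confusion_matrix

                cm = confusion_matrix(test_set.labels, y_pred)
                report_obj = classification_report(cm)
                base_cm = confusion_matrix(test_set.labels, y_base)
                base_report = classification_report(base_cm)
                emit("evaluate", lambda p: Path(p).write_text(cm.to_tsv(), "utf-8"), "confusion.tsv")
                emit(
                    "evaluate",
                    lambda p: Path(p).write_text(report_obj.to_tsv(), "utf-8"),
                    "report.tsv",
                )
            record(
                "train",
                t0,
                n_labelled=len(labelled),
                n_train=len(train_set),
                n_test=len(test_set),
                encoder_used=encoder_used,
                mnb_accuracy=None if report_obj is None else report_obj.accuracy,
                baseline_accuracy=None if report_obj is None else base_report.accuracy,
            )

        # ------------------------------------------------ trends
        if stages_on.get("trends") and predictions:
            current_stage = "trends"
            t0 = time.perf_counter()
            series = trends.daily_counts(corpus, predictions)
            emit(
                "trends",
                lambda p: series.to_csv(p, sep="\t"),
                "daily_counts.tsv",
            )
            by_class: dict[str, list[list[str]]] = {}
            for rec in corpus:
                lab = predictions.get(rec.id)
                if lab is not None:
                    by_class.setdefault(lab, []).append(tokens[rec.id])
            k = int(config["trends"].get("top_k", 30))
            for n in (1, 2):
                tables = trends.top_ngrams(by_class, n=n, k=k)
                for cls in sorted(tables):
                    fname = f"ngrams_{n}_{cls}.tsv"
                    content = trends.ngram_table_tsv(tables[cls])
                    emit(
                        "trends",
                        lambda p, c=content: Path(p).write_text(c, "utf-8"),
                        fname,
                    )
            record("trends", t0, n_days=len(series))

    except PipelineError:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1), "utf-8")
        raise
    except Exception as exc:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1), "utf-8")
        raise PipelineError(f"stage {current_stage!r} failed: {exc}") from exc

    manifest["files"].append("manifest.json")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1), "utf-8")
    return manifest
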