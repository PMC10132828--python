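"""Shared fixtures: one synthetic corpus and one full pipeline run per
session, so the expensive stages (embedding training) happen once."""

from __future__ import annotations

import warnings

import pytest

from vaxsent.pipeline import load_config, run_pipeline
from vaxsent.synthetic_corpus import GeneratorConfig, GroundTruth, generate_corpus

SESSION_SEED = 1234


@pytest.fixture(scope="session")
def default_corpus():
    """Default-condition synthetic corpus with its ground truth."""
    cfg = GeneratorConfig(rng_seed=SESSION_SEED)
    return generate_corpus(cfg)


@pytest.fixture(scope="session")
def small_corpus():
    """A light corpus (no bot) for cheap unit tests."""
    cfg = GeneratorConfig(n_tweets=800, bot_post_count=0, rng_seed=7)
    return generate_corpus(cfg)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full default-config pipeline run: (manifest, out_dir, truth)."""
    out = tmp_path_factory.mktemp("pipeline")
    cfg = load_config(overrides={"seed": SESSION_SEED})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        manifest = run_pipeline(cfg, out)
    truth = GroundTruth.from_json(out / "ground_truth.json")
    return manifest, out, truth
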