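"""Embedding trainer contract, DCG scoring, semantic-field expansion, PCA."""

import itertools

import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from vaxsent.embed_semfield import (
    DcgConfig,
    EmbeddingSettings,
    EmbeddingTable,
    TrainingError,
    cosine_similarity,
    dcg_score,
    expand_semantic_field,
    neighbor_rank,
    pca_project,
    train_embeddings,
    tune_hyperparams,
)
from vaxsent.preprocess import clean_text

TINY_SETTINGS = EmbeddingSettings(
    dim=16, epochs=3, min_count=1, min_n=0, max_n=0, seed=5, window=3
)


def _random_table(rng, vocab_size, dim=8):
    words = [f"w{i:03d}" for i in range(vocab_size)]
    vecs = rng.normal(size=(vocab_size, dim))
    return EmbeddingTable(words, vecs)


@pytest.fixture(scope="module")
def trained_table(pipeline_run):
    """Embeddings trained by the session pipeline run, with ground truth."""
    _, out, truth = pipeline_run
    return EmbeddingTable.load_word2vec(out / "embeddings.vec"), truth


# ---------------------------------------------------------------- cosine


def test_cosine_identity_orthogonal_and_closed_form():
    assert cosine_similarity([1, 0], [1, 0]) == pytest.approx(1.0)
    assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)
    assert cosine_similarity([1, 0], [1, 1]) == pytest.approx(0.70711, abs=1e-5)


def test_cosine_scale_invariant_and_symmetric():
    u, v = np.array([1.0, 2.0, -3.0]), np.array([0.5, -1.0, 2.0])
    assert cosine_similarity(u, v) == pytest.approx(cosine_similarity(v, u))
    assert cosine_similarity(10 * u, 0.1 * v) == pytest.approx(cosine_similarity(u, v))


def test_cosine_zero_vector_and_dim_mismatch_raise():
    with pytest.raises(ValueError, match="zero vector"):
        cosine_similarity([0, 0], [1, 0])
    with pytest.raises(ValueError, match="mismatch"):
        cosine_similarity([1, 0, 0], [1, 0])


# ---------------------------------------------------------------- ranks


def test_neighbor_rank_unique_nearest_is_one():
    table = EmbeddingTable(
        ["a", "b", "c"], np.array([[1.0, 0.0], [0.99, 0.1], [-1.0, 0.0]])
    )
    assert neighbor_rank(table, "a", "b") == 1
    assert neighbor_rank(table, "a", "c") == 2


def test_neighbor_rank_matches_brute_force_sort():
    rng = np.random.default_rng(0)
    table = _random_table(rng, 20)
    for a in ("w000", "w007"):
        va = table.vector(a)
        ordering = sorted(
            (w for w in table.words if w != a),
            key=lambda w: (-cosine_similarity(va, table.vector(w)), w),
        )
        for b in ("w003", "w011", "w019"):
            assert neighbor_rank(table, a, b) == ordering.index(b) + 1


def test_neighbor_rank_tie_broken_lexicographically():
    table = EmbeddingTable(
        ["a", "b", "c"], np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
    )
    # b and c are tied relative to a
    assert neighbor_rank(table, "a", "b") == 1
    assert neighbor_rank(table, "a", "c") == 2


def test_neighbor_rank_oov_raises():
    table = _random_table(np.random.default_rng(0), 4)
    with pytest.raises(KeyError, match="w999"):
        neighbor_rank(table, "w000", "w999")


# ---------------------------------------------------------------- DCG


def _mutual_nn_table():
    return EmbeddingTable(
        ["a", "b", "c", "d"],
        np.array([[1.0, 0.0], [0.99, 0.14], [-1.0, 0.2], [-1.0, -0.2]]),
    )


def test_dcg_mutual_nearest_neighbors_scores_two():
    score, coverage = dcg_score(_mutual_nn_table(), DcgConfig(pairs=[("a", "b")]))
    assert score == pytest.approx(2.0)
    assert coverage == 1.0


def test_dcg_rank_three_plus_rank_one_scores_one_point_five():
    # hand-built table: rank_a(b) = 3 and rank_b(a) = 1
    table = EmbeddingTable(
        ["a", "b", "c", "d"],
        np.array(
            [[1.0, 0.0], [0.0, 1.0], [0.995, -0.0998], [0.99, -0.141]]
        ),
    )
    assert neighbor_rank(table, "a", "b") == 3
    assert neighbor_rank(table, "b", "a") == 1
    score, _ = dcg_score(table, DcgConfig(pairs=[("a", "b")]))
    assert score == pytest.approx(1.0 / np.log2(4) + 1.0, abs=1e-9)


def test_dcg_missing_word_skip_and_error_policies():
    table = _mutual_nn_table()
    cfg = DcgConfig(pairs=[("a", "b"), ("a", "zzz")])
    score, coverage = dcg_score(table, cfg)
    assert score == pytest.approx(2.0)
    assert coverage == pytest.approx(0.5)
    with pytest.raises(KeyError, match="zzz"):
        dcg_score(table, DcgConfig(pairs=[("a", "zzz")], missing_word_policy="error"))
    with pytest.raises(ValueError, match="usable"):
        dcg_score(table, DcgConfig(pairs=[("zzz", "yyy")]))


def test_dcg_rank_beyond_cutoff_contributes_zero():
    table = _mutual_nn_table()
    score, _ = dcg_score(table, DcgConfig(pairs=[("a", "b")], rank_cutoff=1))
    assert score == pytest.approx(2.0)  # both directions rank 1
    score_cd, _ = dcg_score(table, DcgConfig(pairs=[("a", "c")], rank_cutoff=1))
    assert score_cd == pytest.approx(0.0)


def test_dcg_monotone_in_rank():
    # improving a rank never decreases the gain
    gains = [1.0 / np.log2(1 + r) for r in range(1, 50)]
    assert all(g1 >= g2 for g1, g2 in zip(gains, gains[1:]))


# ---------------------------------------------------------------- training


def test_training_covers_repeated_sentence_vocabulary():
    sentence = ["le", "vaccin", "sera", "efficace"]
    table = train_embeddings([sentence] * 30, TINY_SETTINGS)
    assert set(sentence) <= set(table.words)
    assert table.dim == 16


def test_training_deterministic_same_seed():
    corpus = [["aa", "bb", "cc", "dd"], ["aa", "cc", "ee", "ff"]] * 20
    t1 = train_embeddings(corpus, TINY_SETTINGS)
    t2 = train_embeddings(corpus, TINY_SETTINGS)
    assert t1.words == t2.words
    np.testing.assert_array_equal(t1.vectors, t2.vectors)


def test_training_empty_or_tiny_corpus_raises():
    with pytest.raises(TrainingError):
        train_embeddings([], TINY_SETTINGS)
    with pytest.raises(TrainingError):
        train_embeddings([["solo"]], TINY_SETTINGS)


def test_planted_field_more_similar_than_background(trained_table):
    table, truth = trained_table
    field = [w for w in truth.planted_field if w in table]
    assert len(field) >= 20
    bg = [w for w in table.words if w not in truth.planted_field][:60]
    ff = [table.similarity(a, b) for a, b in itertools.combinations(field[:12], 2)]
    fb = [table.similarity(a, b) for a in field[:12] for b in bg[:30]]
    assert np.mean(ff) > np.mean(fb) + 0.3


def test_subword_model_composes_oov_vectors():
    corpus = [["vaccin", "vaccination", "virus", "pandemie"]] * 40
    settings = EmbeddingSettings(
        dim=16, epochs=2, min_count=1, min_n=3, max_n=4, seed=3, window=3
    )
    table = train_embeddings(corpus, settings)
    vec = table.vector("vaccinx")  # OOV, shares n-grams with "vaccin"
    assert vec.shape == (16,)
    word_only = train_embeddings(corpus, TINY_SETTINGS)
    with pytest.raises(KeyError):
        word_only.vector("vaccinx")


# ---------------------------------------------------------------- tuning


def test_tune_single_candidate_returned_with_score(small_corpus):
    from collections import Counter

    corpus, _ = small_corpus
    tokens = [clean_text(r.text) for r in corpus.records[:300]]
    common = [w for w, _ in Counter(t for s in tokens for t in s).most_common(2)]
    best, rows = tune_hyperparams(
        tokens, [TINY_SETTINGS], DcgConfig(pairs=[tuple(common)])
    )
    assert best == TINY_SETTINGS
    assert len(rows) == 1 and rows[0]["error"] is None
    assert rows[0]["score"] is not None and rows[0]["score"] >= 0.0


def test_tune_equal_scores_prefers_first_grid_entry():
    corpus = [["aa", "bb", "cc"], ["aa", "bb", "dd"]] * 15
    grid = [TINY_SETTINGS, TINY_SETTINGS]  # identical candidates tie exactly
    best, rows = tune_hyperparams(corpus, grid, DcgConfig(pairs=[("aa", "bb")]))
    assert best is grid[0]
    assert rows[0]["score"] == rows[1]["score"]


def test_intact_signal_beats_shuffled_corpus():
    from vaxsent.synthetic_corpus import GeneratorConfig, generate_corpus

    cfg_gen = GeneratorConfig(
        n_tweets=600,
        bot_post_count=0,
        field_tweet_rate=0.5,
        misspelling_rate=0.0,
        rng_seed=13,
    )
    corpus, truth = generate_corpus(cfg_gen)
    tokens = [clean_text(r.text) for r in corpus]
    rng = np.random.default_rng(0)
    flat = [t for s in tokens for t in s]
    rng.shuffle(flat)
    shuffled, pos = [], 0
    for s in tokens:
        shuffled.append(flat[pos : pos + len(s)])
        pos += len(s)
    settings = EmbeddingSettings(
        dim=32, epochs=10, min_count=3, min_n=0, max_n=0, seed=2
    )
    fv = sorted(truth.planted_field)
    cfg = DcgConfig(
        pairs=[(fv[i], fv[i + 1]) for i in range(0, 12, 2)],
        rank_cutoff=50,
        missing_word_policy="skip",
    )
    intact_score, _ = dcg_score(train_embeddings(tokens, settings), cfg)
    shuffled_score, _ = dcg_score(train_embeddings(shuffled, settings), cfg)
    assert intact_score > shuffled_score


# ---------------------------------------------------------------- expansion


def test_expansion_theta_above_max_similarity_is_seed_alone():
    table = _random_table(np.random.default_rng(1), 10)
    sf = expand_semantic_field(table, "w000", theta=1.0)
    assert sf.members == ["w000"]


def test_expansion_chain_through_similarity_links():
    # s-a 0.9, a-b 0.8, everything else far below theta=0.7
    vecs = np.array(
        [
            [1.0, 0.0, 0.0],
            [0.9, 0.43589, 0.0],
            [0.62324, 0.78203, 0.0],
            [-1.0, 0.0, 0.0],
        ]
    )
    table = EmbeddingTable(["s", "a", "b", "z"], vecs)
    assert table.similarity("s", "a") == pytest.approx(0.9, abs=1e-4)
    assert table.similarity("a", "b") == pytest.approx(0.9018, abs=1e-3)
    assert table.similarity("s", "b") < 0.7
    sf = expand_semantic_field(table, "s", theta=0.85)
    assert set(sf.members) == {"s", "a", "b"}
    assert sf.iterations == 2


def test_expansion_theta_minus_one_returns_whole_vocabulary():
    table = _random_table(np.random.default_rng(2), 15)
    sf = expand_semantic_field(table, "w000", theta=-1.0)
    assert set(sf.members) == set(table.words)


def test_expansion_seed_oov_raises():
    table = _random_table(np.random.default_rng(3), 5)
    with pytest.raises(KeyError, match="nope"):
        expand_semantic_field(table, "nope", theta=0.5)


def _bfs_component(table, seed, theta):
    """Independent oracle: connected component over the explicit
    theta-similarity adjacency matrix."""
    U = table.vectors / np.linalg.norm(table.vectors, axis=1, keepdims=True)
    sims = U @ U.T
    adj = sims >= theta
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    target = labels[table.index[seed]]
    return {w for w, lab in zip(table.words, labels) if lab == target}


def test_expansion_equals_bfs_oracle_on_random_tables():
    rng = np.random.default_rng(42)
    for _ in range(20):
        vocab = int(rng.integers(5, 200))
        table = _random_table(rng, vocab, dim=5)
        theta = float(rng.uniform(0.2, 0.95))
        sf = expand_semantic_field(table, "w000", theta=theta)
        assert set(sf.members) == _bfs_component(table, "w000", theta)


def test_expansion_monotone_lower_theta_never_shrinks():
    rng = np.random.default_rng(7)
    table = _random_table(rng, 60, dim=5)
    prev: set[str] = set()
    for theta in (0.9, 0.7, 0.5, 0.3, 0.0):
        members = set(expand_semantic_field(table, "w000", theta=theta).members)
        assert prev <= members
        prev = members


def test_expansion_recovers_planted_field(trained_table):
    table, truth = trained_table
    sf = expand_semantic_field(table, truth.seed_word, theta=0.85)
    members = set(sf.members)
    tp = len(members & truth.planted_field)
    assert tp / len(members) >= 0.8
    assert tp / len(truth.planted_field) >= 0.8


# ---------------------------------------------------------------- PCA


def test_pca_collinear_points_second_component_zero():
    table = EmbeddingTable(
        ["a", "b", "c"],
        np.array([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0], [3.0, 3.0, 3.0]]),
    )
    proj = pca_project(table, ["a", "b", "c"], k=2)
    second = np.array([proj[w][1] for w in ("a", "b", "c")])
    assert np.var(second) == pytest.approx(0.0, abs=1e-12)


def test_pca_matches_covariance_eigendecomposition():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(10, 5))
    words = [f"w{i}" for i in range(10)]
    table = EmbeddingTable(words, X)
    proj = pca_project(table, words, k=2)
    P = np.stack([proj[w] for w in words])
    C = np.cov((X - X.mean(0)).T, bias=False)
    eigvals = np.sort(np.linalg.eigvalsh(C))[::-1]
    # table vectors are stored float32, so agreement is to single precision
    assert np.var(P[:, 0], ddof=1) == pytest.approx(eigvals[0], rel=1e-5)
    assert np.var(P[:, 1], ddof=1) == pytest.approx(eigvals[1], rel=1e-5)


def test_pca_order_invariant_up_to_sign():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(8, 4))
    words = [f"w{i}" for i in range(8)]
    table = EmbeddingTable(words, X)
    p1 = pca_project(table, words, k=2)
    p2 = pca_project(table, words[::-1], k=2)
    for w in words:
        assert np.allclose(np.abs(p1[w]), np.abs(p2[w]), atol=1e-8)


def test_pca_too_few_words_raises():
    table = _random_table(np.random.default_rng(0), 5)
    with pytest.raises(ValueError, match="at least 3"):
        pca_project(table, ["w000", "w001"], k=2)


def test_pca_separates_field_from_background(trained_table):
    table, truth = trained_table
    field = [w for w in truth.planted_field if w in table][:15]
    bg = [w for w in table.words if w not in truth.planted_field][:15]
    proj = pca_project(table, field + bg, k=2)
    fc = np.mean([proj[w] for w in field], axis=0)
    bc = np.mean([proj[w] for w in bg], axis=0)
    spread = np.std([proj[w] for w in field + bg], axis=0).mean()
    assert np.linalg.norm(fc - bc) > spread


# ---------------------------------------------------------------- persistence


def test_word2vec_text_round_trip(tmp_path):
    table = _random_table(np.random.default_rng(5), 12, dim=6)
    p = tmp_path / "emb.vec"
    table.save_word2vec(p)
    back = EmbeddingTable.load_word2vec(p)
    assert back.words == table.words
    np.testing.assert_allclose(back.vectors, table.vectors, atol=1e-5)
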