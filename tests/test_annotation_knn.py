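import numpy as np
import pytest

from acetknn.annotation_knn import (
    DistanceWeights,
    KnnGrid,
    PAAC_SOURCE,
    fuzzy_distance,
    jaccard_dissimilarity,
    knn_feature_matrix,
    knn_score_block,
    pseaac_cache,
)
from acetknn.dataio import Corpus
from acetknn.synthetic_data import SimParams, simulate_corpus
from conftest import make_record


class TestGrid:
    def test_default_grid_is_50_points_from_0001_to_0148(self):
        g = KnnGrid()
        assert len(g) == 50
        assert g.fractions[0] == pytest.approx(0.001)
        assert g.fractions[1] == pytest.approx(0.004)
        assert g.fractions[-1] == pytest.approx(0.148)
        assert np.allclose(np.diff(g.fractions), 0.003)

    def test_k_values_round_half_up_with_floor_one(self):
        g = KnnGrid(fractions=(0.001, 0.05, 0.148))
        np.testing.assert_array_equal(g.k_values(100), [1, 5, 15])
        np.testing.assert_array_equal(g.k_values(10), [1, 1, 1])

    def test_invalid_grids_rejected(self):
        with pytest.raises(ValueError):
            KnnGrid(fractions=())
        with pytest.raises(ValueError):
            KnnGrid(fractions=(0.2, 0.1))
        with pytest.raises(ValueError):
            KnnGrid(fractions=(0.0, 0.1))


class TestFuzzyDistance:
    def test_identical_records_have_zero_distance(self):
        p = make_record("p", annotations={"GO": frozenset({"a", "b"})})
        q = make_record("q", sequence=p.sequence,
                        annotations={"GO": frozenset({"a", "b"})})
        assert fuzzy_distance(p, q, "GO") == pytest.approx(0.0, abs=1e-12)

    def test_jaccard_mix_hand_example(self):
        # {a,b,c} vs {b,c,d}: Jaccard similarity 2/4, set term 0.5
        p = make_record("p", annotations={"GO": frozenset("abc")})
        q = make_record("q", sequence=p.sequence,
                        annotations={"GO": frozenset("bcd")})
        d = fuzzy_distance(p, q, "GO", DistanceWeights(w1=1.0, w2=0.0))
        assert d == pytest.approx(0.5, abs=1e-12)

    def test_disjoint_sets_identical_sequences_boundary(self):
        p = make_record("p", annotations={"GO": frozenset("ab")})
        q = make_record("q", sequence=p.sequence,
                        annotations={"GO": frozenset("cd")})
        d = fuzzy_distance(p, q, "GO", DistanceWeights(w1=0.7, w2=0.3))
        assert d == pytest.approx(0.7, abs=1e-12)

    def test_symmetric_for_random_pairs(self):
        rng = np.random.default_rng(2)
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for i in range(10):
            p = make_record(f"p{i}", "".join(rng.choice(aa, 35)),
                            annotations={"Pfam": frozenset(rng.choice(list("uvwxyz"), 3))})
            q = make_record(f"q{i}", "".join(rng.choice(aa, 35)),
                            annotations={"Pfam": frozenset(rng.choice(list("uvwxyz"), 3))})
            assert fuzzy_distance(p, q, "Pfam") == pytest.approx(
                fuzzy_distance(q, p, "Pfam"), abs=1e-12
            )

    def test_both_sets_empty_is_maximal_dissimilarity(self):
        assert jaccard_dissimilarity(frozenset(), frozenset()) == 1.0

    def test_paac_source_uses_only_euclidean_term(self):
        p = make_record("p", annotations={"GO": frozenset("ab")})
        q = make_record("q", sequence=p.sequence, annotations={})
        assert fuzzy_distance(p, q, PAAC_SOURCE) == pytest.approx(0.0, abs=1e-12)


def oracle_knn_scores(query, reference, source, grid, weights, exclude_self):
    """Brute force: full sort of raw pairwise fuzzy distances.

    Uses per-query max-normalization of the Euclidean term to mirror the
    commensurate-scale convention, then a full stable sort with id
    tie-breaks and exhaustive counting at each k.
    """
    cache = pseaac_cache(list(reference) + [query])
    refs = [r for r in reference if not (exclude_self and r.id == query.id)]
    euclid = {
        r.id: float(np.linalg.norm(cache[query.id] - cache[r.id])) for r in refs
    }
    max_e = max(euclid.values()) or 1.0
    dists = []
    for r in refs:
        if source == PAAC_SOURCE:
            d = euclid[r.id]
        else:
            d = (weights.w1 * jaccard_dissimilarity(
                    query.annotation_set(source), r.annotation_set(source))
                 + weights.w2 * euclid[r.id] / max_e)
        dists.append((d, r.id, r.label))
    dists.sort()
    scores = []
    for f in grid.fractions:
        k = max(1, int(np.floor(f * len(refs) + 0.5)))
        scores.append(sum(lab for _, _, lab in dists[:k]) / k)
    return np.array(scores)


def _random_reference(n=50, seed=9):
    rng = np.random.default_rng(seed)
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    vocab = [f"kw{i}" for i in range(12)]
    recs = []
    for i in range(n):
        recs.append(
            make_record(
                f"ref{i:02d}",
                "".join(rng.choice(aa, size=int(rng.integers(30, 60)))),
                label=int(rng.integers(0, 2)),
                annotations={"GO": frozenset(
                    rng.choice(vocab, size=int(rng.integers(0, 5)), replace=False)
                )},
            )
        )
    return Corpus(recs)


class TestKnnScoreBlock:
    def test_all_positive_reference_scores_one_everywhere(self):
        ref = Corpus([make_record(f"r{i}", label=1) for i in range(5)])
        q = make_record("q")
        block = knn_score_block(q, ref, "GO", exclude_self=False)
        assert np.allclose(block.scores, 1.0)

    def test_matches_bruteforce_oracle_on_50_record_fixture(self):
        ref = _random_reference(50)
        grid, weights = KnnGrid(), DistanceWeights()
        for qi in (0, 17, 43):
            q = ref.records[qi]
            block = knn_score_block(q, ref, "GO", grid, weights, exclude_self=True)
            expected = oracle_knn_scores(q, ref, "GO", grid, weights, True)
            np.testing.assert_array_equal(block.scores, expected)
        # and an unseen query with exclude_self=False
        q = make_record("query", annotations={"GO": frozenset({"kw0", "kw3"})})
        block = knn_score_block(q, ref, "GO", grid, weights, exclude_self=False)
        expected = oracle_knn_scores(q, ref, "GO", grid, weights, False)
        np.testing.assert_array_equal(block.scores, expected)

    def test_paac_block_matches_oracle(self):
        ref = _random_reference(30, seed=4)
        q = ref.records[5]
        block = knn_score_block(q, ref, PAAC_SOURCE, exclude_self=True)
        expected = oracle_knn_scores(q, ref, PAAC_SOURCE, KnnGrid(),
                                     DistanceWeights(), True)
        np.testing.assert_array_equal(block.scores, expected)

    def test_default_grid_yields_block_of_length_50(self):
        ref = _random_reference(20, seed=1)
        block = knn_score_block(ref.records[0], ref, "GO")
        assert block.scores.shape == (50,)
        assert ((block.scores >= 0) & (block.scores <= 1)).all()

    def test_including_self_counts_the_query_at_k1(self):
        # a record included in its own reference is its own nearest
        # neighbor, so the k=1 score equals its own label: the training
        # pipeline must exclude self
        ref = _random_reference(12, seed=6)
        for q in ref.records[:6]:
            block = knn_score_block(q, ref, "GO", exclude_self=False)
            assert block.scores[0] == q.label

    def test_empty_reference_after_exclusion_rejected(self):
        only = make_record("solo", label=1)
        with pytest.raises(ValueError, match="empty"):
            knn_score_block(only, Corpus([only]), "GO", exclude_self=True)


class TestKnnFeatureMatrix:
    def test_seven_sources_give_350_columns(self, toy_corpus):
        sources = ["GO", "Pfam", "Smart", "PROSITE", "SUPFAM", "InterPro", "PRINTS"]
        m, names = knn_feature_matrix(toy_corpus, sources=sources)
        assert m.shape == (10, 350)
        assert names[0] == "GO_knn_0"
        assert names[-1] == "PRINTS_knn_49"

    def test_nine_sources_give_450_columns(self, toy_corpus):
        from acetknn.annotation_knn import ALL_KNN_SOURCES

        m, _ = knn_feature_matrix(toy_corpus, sources=ALL_KNN_SOURCES)
        assert m.shape == (10, 450)

    def test_rows_match_per_record_blocks(self, toy_corpus):
        m, _ = knn_feature_matrix(toy_corpus, sources=["GO"])
        for i, rec in enumerate(toy_corpus):
            block = knn_score_block(rec, toy_corpus, "GO", exclude_self=True)
            np.testing.assert_array_equal(m[i], block.scores)

    def test_single_record_corpus_rejected(self):
        solo = Corpus([make_record("solo", label=1)])
        with pytest.raises(ValueError):
            knn_feature_matrix(solo, sources=["GO"])

    def test_mean_score_near_half_on_label_independent_reference(self):
        # balanced labels, annotations independent of label: the average
        # KNN score over records converges to 0.5 (within 3 SE)
        params = SimParams(n_pos=40, n_neg=40, enrichment=0.0, pssm_signal=0.0,
                           seq_len=(30, 60), seed=21)
        corpus = simulate_corpus(params)
        m, _ = knn_feature_matrix(corpus, sources=["GO"])
        mean = m.mean()
        se = m.mean(axis=1).std(ddof=1) / np.sqrt(m.shape[0])
        assert abs(mean - 0.5) < 3 * max(se, 1e-3)

    def test_positive_scores_dominate_under_enrichment(self, small_strong_corpus):
        m, _ = knn_feature_matrix(small_strong_corpus, sources=["GO"])
        y = small_strong_corpus.labels.astype(bool)
        pos_mean = m[y].mean(axis=0)
        neg_mean = m[~y].mean(axis=0)
        assert (pos_mean > neg_mean).all()
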