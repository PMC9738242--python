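"""K-medoid vocabulary learning, elbow selection, and document encoding."""

from fractions import Fraction

import numpy as np
import pytest

from wristbow.bow import (
    DEFAULT_K_CANDIDATES,
    SubjectDocument,
    VocabularyError,
    VocabularyModel,
    build_vocabulary,
    concatenate_strategies,
    encode_document,
    kmedoids,
    kmedoids_exhaustive,
    select_k_elbow,
    term_frequencies,
    word_feature_table,
)


def planted_blobs(rng, n_modes=2, per_mode=30, sep=8.0, dim=4):
    centers = rng.normal(size=(n_modes, dim)) * sep
    pts = np.vstack([c + rng.normal(size=(per_mode, dim)) for c in centers])
    labels = np.repeat(np.arange(n_modes), per_mode)
    return pts, labels


class TestKMedoids:
    def test_k_equals_n_zero_wcss(self, rng):
        pts = rng.normal(size=(6, 3))
        med, assign, wcss = kmedoids(pts, 6, seed=0)
        assert wcss == 0.0
        assert sorted(med.tolist()) == list(range(6))

    def test_planted_blobs_recovered(self, rng):
        pts, labels = planted_blobs(rng)
        med, assign, _ = kmedoids(pts, 2, seed=0)
        # assignments must be a relabelling of the planted partition
        for mode in (0, 1):
            assert len(set(assign[labels == mode])) == 1
        assert assign[labels == 0][0] != assign[labels == 1][0]

    def test_matches_exhaustive_on_tiny_instances(self, rng):
        for trial in range(30):
            n = int(rng.integers(4, 9))
            k = int(rng.integers(1, 4))
            pts = rng.normal(size=(n, 2))
            _, _, wcss = kmedoids(pts, k, seed=trial, n_restarts=10)
            _, opt = kmedoids_exhaustive(pts, k)
            assert wcss == pytest.approx(opt, abs=1e-9)

    def test_k_larger_than_n_or_distinct_raises(self, rng):
        pts = rng.normal(size=(5, 2))
        with pytest.raises(VocabularyError):
            kmedoids(pts, 6)
        dup = np.tile(pts[:2], (3, 1))
        with pytest.raises(VocabularyError):
            kmedoids(dup, 3)

    def test_deterministic_given_seed(self, rng):
        pts = rng.normal(size=(40, 5))
        a = kmedoids(pts, 4, seed=7, n_restarts=3)
        b = kmedoids(pts, 4, seed=7, n_restarts=3)
        np.testing.assert_array_equal(a[0], b[0])
        assert a[2] == b[2]


class TestElbow:
    def test_sharp_knee_recovered(self):
        ks = [4, 8, 12, 16, 20, 24, 28, 32]
        curve = [(k, 100.0 - 4.5 * min(k, 20) - 0.05 * max(0, k - 20)) for k in ks]
        assert select_k_elbow(curve) == 20

    def test_linear_curve_smallest_interior(self):
        curve = [(k, 100.0 - 2 * k) for k in (4, 8, 12, 16)]
        assert select_k_elbow(curve) == 8

    def test_hand_computed_two_scale_curve(self):
        # two-scale WCSS: steep to k=8, shallow after; chord distances by hand
        curve = [(2, 90.0), (4, 50.0), (8, 20.0), (16, 15.0), (32, 10.0)]
        ks = np.array([2, 4, 8, 16, 32], float)
        ws = np.array([90, 50, 20, 15, 10], float)
        chord = np.array([30.0, -80.0])
        d = [
            abs((k - 2) * chord[1] - (w - 90) * chord[0]) / np.linalg.norm(chord)
            for k, w in zip(ks, ws)
        ]
        assert select_k_elbow(curve) == ks[int(np.argmax(d))] == 8

    def test_increasing_curve_raises(self):
        with pytest.raises(VocabularyError):
            select_k_elbow([(2, 10.0), (4, 12.0), (8, 9.0)])

    def test_too_few_candidates_raises(self):
        with pytest.raises(VocabularyError):
            select_k_elbow([(2, 10.0), (4, 5.0)])


class TestBuildVocabulary:
    def make_mode_cohort(self, rng, n_modes=4, subjects=6, per=40, sep=10.0):
        centers = rng.normal(size=(n_modes, 10)) * sep
        out = {}
        for s in range(subjects):
            modes = rng.integers(n_modes, size=per)
            out[f"S{s}"] = centers[modes] + rng.normal(size=(per, 10))
        return out

    def test_planted_mode_count_recovered_across_seeds(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            cohort = self.make_mode_cohort(rng)
            vocab = build_vocabulary(
                cohort, 3.0, k_candidates=(2, 4, 8, 12, 16), seed=seed,
                subsample_size=300,
            )
            hits += vocab.k == 4
        assert hits >= 9

    def test_one_subject_rejected(self, rng):
        with pytest.raises(VocabularyError, match="2 subjects"):
            build_vocabulary({"A": rng.normal(size=(30, 10))}, 3.0)

    def test_subsample_smaller_than_k_rejected(self, rng):
        cohort = {"A": rng.normal(size=(30, 10)), "B": rng.normal(size=(30, 10))}
        with pytest.raises(VocabularyError, match="subsample"):
            build_vocabulary(cohort, 3.0, subsample_size=8)

    def test_wcss_curve_non_increasing_and_k_in_candidates(self, rng):
        cohort = {f"S{i}": rng.normal(size=(50, 10)) for i in range(4)}
        vocab = build_vocabulary(cohort, 3.0, k_candidates=(2, 4, 8, 12), seed=0)
        ws = [w for _, w in vocab.wcss_curve]
        assert all(a >= b - 1e-9 for a, b in zip(ws, ws[1:]))
        assert vocab.k in (2, 4, 8, 12)

    def test_determinism_and_json_round_trip(self, rng, tmp_path):
        cohort = {f"S{i}": rng.normal(size=(60, 10)) for i in range(3)}
        v1 = build_vocabulary(cohort, 3.0, k_candidates=(2, 4, 8), seed=5)
        v2 = build_vocabulary(cohort, 3.0, k_candidates=(2, 4, 8), seed=5)
        np.testing.assert_array_equal(v1.medoids, v2.medoids)
        back = VocabularyModel.from_json(v1.to_json(tmp_path / "v.json"))
        assert back.k == v1.k
        np.testing.assert_allclose(back.medoids, v1.medoids)
        np.testing.assert_allclose(back.loc, v1.loc)
        assert back.wcss_curve == v1.wcss_curve


class TestEncoding:
    def make_vocab(self, medoids):
        medoids = np.asarray(medoids, dtype=float)
        return VocabularyModel(
            window_s=3.0, k=medoids.shape[0], medoids=medoids,
            loc=np.zeros(medoids.shape[1]), scale=np.ones(medoids.shape[1]),
            wcss_curve=[], k_candidates=(medoids.shape[0],), seed=0,
        )

    def test_segments_on_medoid_count_there(self):
        vocab = self.make_vocab([[0.0, 0.0], [5.0, 5.0]])
        desc = np.tile([5.0, 5.0], (7, 1))
        doc = encode_document("A", desc, vocab)
        assert doc.counts.tolist() == [0, 7]

    def test_counts_equal_distance_scan(self, rng):
        vocab = self.make_vocab(rng.normal(size=(4, 6)))
        desc = rng.normal(size=(50, 6))
        doc = encode_document("A", desc, vocab)
        brute = np.zeros(4, dtype=int)
        for d in desc:
            dists = [np.sum((d - m) ** 2) for m in vocab.medoids]
            brute[int(np.argmin(dists))] += 1
        assert doc.counts.tolist() == brute.tolist()

    def test_empty_or_nonfinite_rejected(self, rng):
        vocab = self.make_vocab(rng.normal(size=(2, 3)))
        with pytest.raises(VocabularyError, match="no segments"):
            encode_document("A", np.empty((0, 3)), vocab)
        desc = rng.normal(size=(5, 3))
        desc[2, 1] = np.nan
        with pytest.raises(VocabularyError, match="segment 2"):
            encode_document("A", desc, vocab)

    def test_encoding_idempotent(self, rng):
        vocab = self.make_vocab(rng.normal(size=(3, 4)))
        desc = rng.normal(size=(30, 4))
        a = encode_document("A", desc, vocab)
        b = encode_document("A", desc, vocab)
        assert a.counts.tolist() == b.counts.tolist()


class TestTermFrequencies:
    def test_examples(self):
        np.testing.assert_allclose(
            term_frequencies([2, 1, 0]), [2 / 3, 1 / 3, 0.0]
        )
        np.testing.assert_allclose(term_frequencies([0, 9]), [0.0, 1.0])
        with pytest.raises(VocabularyError):
            term_frequencies([0, 0])

    def test_probability_vector_rational_exact(self, rng):
        """TF sums to 1 exactly, checked in rational arithmetic on the counts."""
        counts = rng.integers(0, 50, size=12)
        counts[0] += 1
        tf = term_frequencies(counts)
        total = int(counts.sum())
        assert all(
            Fraction(int(c), total) == Fraction(t).limit_denominator(10**12)
            for c, t in zip(counts, tf)
        )
        assert sum(Fraction(int(c), total) for c in counts) == 1


class TestConcatenation:
    def test_fixed_order_and_length(self, rng):
        ks = {3.0: 22, 10.0: 22, 60.0: 20, 300.0: 20, 900.0: 16}
        tfs = {w: rng.dirichlet(np.ones(k)) for w, k in ks.items()}
        combined = concatenate_strategies(tfs, list(ks))
        assert combined.size == 100
        np.testing.assert_allclose(combined[:22], tfs[3.0])
        np.testing.assert_allclose(combined[-16:], tfs[900.0])

    def test_order_normalized_and_identity(self, rng):
        tfs = {10.0: rng.dirichlet(np.ones(3)), 3.0: rng.dirichlet(np.ones(2))}
        a = concatenate_strategies(tfs, [10.0, 3.0])
        b = concatenate_strategies(tfs, [3.0, 10.0])
        np.testing.assert_array_equal(a, b)
        single = concatenate_strategies({3.0: tfs[3.0]}, [3.0])
        np.testing.assert_array_equal(single, tfs[3.0])

    def test_missing_strategy_raises(self, rng):
        with pytest.raises(VocabularyError, match="missing"):
            concatenate_strategies({3.0: np.ones(2)}, [3.0, 10.0])


def test_word_feature_table_shape(rng):
    docs = {
        3.0: [SubjectDocument("A", 3.0, np.array([1, 2])), SubjectDocument("B", 3.0, np.array([3, 1]))],
        10.0: [SubjectDocument("A", 10.0, np.array([4])), SubjectDocument("B", 10.0, np.array([2]))],
    }
    table = word_feature_table(docs)
    assert list(table.columns) == ["w3s_0", "w3s_1", "w10s_0"]
    np.testing.assert_allclose(table.loc["A"], [1 / 3, 2 / 3, 1.0])
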