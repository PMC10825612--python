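"""K-means contracts: restart selection, convergence, mapping, elbow."""

import numpy as np
import pytest

import marrowsect as ms
from tests.conftest import random_binary_vectors

SL = ms.SectionLabel


class TestFitKmeans:
    def test_two_repeated_locations_separate_perfectly(self):
        X = np.array([[0, 0], [0, 0], [1, 1], [1, 1]], dtype=float)
        model = ms.fit_kmeans(X, k=2, seed=0)
        assert model.sse == 0.0

    def test_closed_form_single_centroid(self):
        model = ms.fit_kmeans(np.array([[0.0], [1.0]]), k=1, seed=0)
        assert model.centroids[0, 0] == pytest.approx(0.5)
        assert model.sse == pytest.approx(0.5)  # 0.5^2 + 0.5^2

    def test_chosen_sse_is_minimum_over_restarts(self, rng):
        X = random_binary_vectors(rng, 30, 8)
        model = ms.fit_kmeans(X, k=3, restarts=10, seed=42)
        assert len(model.restart_sses) == 10
        assert model.sse == min(model.restart_sses)
        assert all(model.sse <= s for s in model.restart_sses)

    def test_iteration_sse_non_increasing(self, rng):
        X = random_binary_vectors(rng, 80, 12)
        model = ms.fit_kmeans(X, k=5, restarts=10, seed=7)
        diffs = np.diff(model.iteration_sses)
        assert np.all(diffs <= 1e-9)

    def test_sse_zero_when_k_covers_distinct_points(self, rng):
        X = np.array([[0, 0], [1, 0], [0, 1], [1, 0], [0, 0]], dtype=float)
        model = ms.fit_kmeans(X, k=3, seed=3)  # 3 distinct points
        assert model.sse == 0.0
        model = ms.fit_kmeans(X, k=4, seed=3)  # k beyond distinct points
        assert model.sse == 0.0

    def test_fixed_seed_gives_bit_identical_refit(self, rng):
        X = random_binary_vectors(rng, 50, 10)
        a = ms.fit_kmeans(X, k=4, seed=99)
        b = ms.fit_kmeans(X, k=4, seed=99)
        assert np.array_equal(a.centroids, b.centroids)
        assert a.sse == b.sse
        assert a.restart_sses == b.restart_sses

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            ms.fit_kmeans(np.zeros((3, 2)), k=4)

    def test_matches_sklearn_on_separated_blobs(self):
        """Independent check: best-of-restarts SSE agrees with sklearn's
        inertia on well-separated clusters, where both find the optimum."""
        sklearn_cluster = pytest.importorskip("sklearn.cluster")
        rng = np.random.default_rng(0)
        centers = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0]], dtype=float)
        X = np.vstack([c + 0.5 * rng.normal(size=(40, 3)) for c in centers])
        ours = ms.fit_kmeans(X, k=3, restarts=10, seed=5)
        ref = sklearn_cluster.KMeans(n_clusters=3, n_init=10, random_state=0).fit(X)
        assert ours.sse == pytest.approx(ref.inertia_, rel=1e-6)


class TestAssignClusterSections:
    def _model(self, centroids):
        C = np.asarray(centroids, dtype=float)
        return ms.KMeansModel(k=len(C), centroids=C, sse=0.0, seed=0)

    def test_majority_wins(self):
        model = self._model([[0.0], [10.0]])
        X = np.array([[0.1], [0.2], [0.0], [9.9], [10.1]])
        labels = [SL.bone_marrow_aspirate] * 3 + [SL.comment] * 2
        # contaminate cluster 0 with one comment
        X = np.vstack([X, [[0.3]]])
        labels.append(SL.comment)
        mapping = ms.assign_cluster_sections(model, X, labels)
        assert mapping[0] is SL.bone_marrow_aspirate
        assert mapping[1] is SL.comment

    def test_tie_breaks_to_smallest_canonical_index(self):
        model = self._model([[0.0]])
        X = np.zeros((4, 1))
        labels = [SL.comment, SL.comment, SL.diagnosis, SL.diagnosis]
        mapping = ms.assign_cluster_sections(model, X, labels)
        assert mapping[0] is SL.comment  # canonical index 7 < 8

    def test_empty_cluster_falls_back_to_global_modal(self):
        model = self._model([[0.0], [100.0]])
        X = np.zeros((3, 1))
        labels = [SL.clinical_information] * 2 + [SL.iron_content]
        mapping = ms.assign_cluster_sections(model, X, labels)
        assert mapping[1] is SL.clinical_information

    def test_every_cluster_mapped(self, rng):
        X = random_binary_vectors(rng, 40, 6)
        model = ms.fit_kmeans(X, k=6, seed=1)
        labels = [list(SL)[int(i)] for i in rng.integers(0, 10, size=40)]
        mapping = ms.assign_cluster_sections(model, X, labels)
        assert set(mapping) == set(range(6))


class TestPredictSections:
    def test_training_block_gets_its_clusters_label(self, small_split):
        train, _ = small_split
        assigner = ms.fit_section_assigner(train.blocks, n=1, k=5, seed=2)
        block = train.blocks[0]
        cluster = assigner.predict_clusters([block])[0]
        assert assigner.predict([block])[0] is assigner.cluster_sections[cluster]

    def test_all_zero_vector_goes_to_smallest_norm_centroid(self):
        vocab = ms.NgramVocabulary(1, [(("bone",), 2), (("iron",), 1)], capacity=2)
        model = ms.KMeansModel(
            k=2,
            centroids=np.array([[0.9, 0.9], [0.1, 0.2]]),
            sse=0.0,
            seed=0,
        )
        assigner = ms.SectionAssigner(
            model=model,
            cluster_sections={0: SL.comment, 1: SL.disclaimer},
            vocab=vocab,
        )
        assert assigner.predict(["unrelated words only"])[0] is SL.disclaimer

    def test_matches_brute_force_nearest_centroid(self, small_split):
        train, test = small_split
        assigner = ms.fit_section_assigner(train.blocks, n=1, k=8, seed=3)
        blocks = test.blocks[:50]
        got = assigner.predict(blocks)
        for block, label in zip(blocks, got):
            vec = assigner.featurize_block(block)
            d2 = ((assigner.model.centroids - vec) ** 2).sum(axis=1)
            assert label is assigner.cluster_sections[int(np.argmin(d2))]

    def test_serialization_round_trip(self, small_split, tmp_path):
        train, test = small_split
        assigner = ms.fit_section_assigner(train.blocks, n=2, k=6, seed=4)
        path = tmp_path / "model.json"
        assigner.save(path)
        loaded = ms.SectionAssigner.load(path)
        assert loaded.predict(test.blocks) == assigner.predict(test.blocks)
        assert np.array_equal(loaded.model.centroids, assigner.model.centroids)


class TestSseCurve:
    def test_k_equal_distinct_points_reaches_zero(self):
        X = np.array([[0, 0], [1, 0], [0, 1]], dtype=float)
        curve = ms.sse_curve(X, k_min=1, k_max=3, restarts=5, seed=0)
        assert curve[3] == 0.0

    def test_k1_equals_total_scatter_about_mean(self, rng):
        X = random_binary_vectors(rng, 40, 6)
        curve = ms.sse_curve(X, k_min=1, k_max=3, restarts=3, seed=0)
        scatter = float(((X - X.mean(axis=0)) ** 2).sum())
        assert curve[1] == pytest.approx(scatter)

    def test_curve_roughly_non_increasing(self, small_split):
        train, _ = small_split
        assigner = ms.fit_section_assigner(train.blocks, n=1, k=5, seed=0)
        X = assigner.featurize_blocks(train.blocks)
        curve = ms.sse_curve(X, k_min=1, k_max=8, restarts=5, seed=1)
        ks = sorted(curve)
        for a, b in zip(ks, ks[1:]):
            assert curve[b] <= curve[a] * 1.01  # 1% slack for restart noise


class TestElbowPoint:
    def test_fixture_curve(self):
        assert ms.elbow_point([100, 40, 20, 15, 13, 12]) == 2

    def test_linear_curve_ties_to_smallest_k(self):
        assert ms.elbow_point([50, 40, 30, 20]) == 2

    def test_planted_kink_recovered(self):
        # piecewise-linear convex curve: steep descent until the bend at
        # k=6, nearly flat afterwards; all other second differences are 0
        planted = 6
        curve = {}
        for k in range(1, 13):
            if k <= planted:
                curve[k] = 400.0 - 30.0 * k
            else:
                curve[k] = (400.0 - 30.0 * planted) - 0.5 * (k - planted)
        assert ms.elbow_point(curve) == planted

    def test_matches_brute_force_second_difference(self, rng):
        for _ in range(50):
            sses = np.sort(rng.uniform(0, 100, size=rng.integers(3, 12)))[::-1]
            got = ms.elbow_point(list(sses))
            d2 = [
                (sses[i - 1] - sses[i]) - (sses[i] - sses[i + 1])
                for i in range(1, len(sses) - 1)
            ]
            assert got == int(np.argmax(d2)) + 2

    def test_short_curve_rejected(self):
        with pytest.raises(ValueError):
            ms.elbow_point([10, 5])
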