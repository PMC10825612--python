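"""Structural features, target-cluster routing, and the two-stage model."""

import re
import statistics

import numpy as np
import pytest

import marrowsect as ms

SL = ms.SectionLabel


def _report_with(texts, labels=None):
    labels = labels or [SL.comment] * len(texts)
    blocks = [
        ms.TextBlock("r0", i, text, label)
        for i, (text, label) in enumerate(zip(texts, labels))
    ]
    return ms.Report("r0", 0, blocks)


class TestComputeEnsembleFeatures:
    def test_worked_example(self):
        report = _report_with(["a", "b", "Hb NUM\nWBC NUM NUM", "d", "e"])
        feats = ms.compute_ensemble_features(report.blocks[2], report)
        assert feats.numeric_count == 3
        assert feats.median_paragraph_length == 2.5  # lines of 2 and 3 words
        assert feats.relative_location == 0.5  # index 2 of 5 blocks

    def test_empty_text_degenerate_case(self):
        report = _report_with(["", "x", "y"])
        feats = ms.compute_ensemble_features(report.blocks[0], report)
        assert feats.numeric_count == 0
        assert feats.median_paragraph_length == 0.0
        assert feats.relative_location == 0.0

    def test_single_block_report_location_zero(self):
        report = _report_with(["only block"])
        assert ms.compute_ensemble_features(report.blocks[0], report).relative_location == 0.0

    def test_counts_numbers_via_token_replacement(self):
        report = _report_with(["Blasts 2.5 of 500 cells and CD34"])
        feats = ms.compute_ensemble_features(report.blocks[0], report)
        assert feats.numeric_count == 2  # CD34 is a CD token, not a number

    def test_number_token_not_counted_inside_other_tokens(self):
        report = _report_with(["CD34 CD117 S21-00123"])
        feats = ms.compute_ensemble_features(report.blocks[0], report)
        assert feats.numeric_count == 0  # CDNUM/ACCNUM contain NUM as substring only

    def test_raw_regex_counting_when_rules_disabled(self):
        report = _report_with(["Blasts 2.5 of 500 cells"])
        feats = ms.compute_ensemble_features(report.blocks[0], report, rules=None)
        assert feats.numeric_count == 2

    def test_matches_brute_force_recount_on_generated_blocks(self, small_corpus):
        pairs = list(small_corpus.iter_blocks())[:100]
        for report, block in pairs:
            feats = ms.compute_ensemble_features(block, report)
            replaced = ms.replace_tokens(block.text)
            brute_count = len(
                re.findall(r"(?<![A-Za-z0-9_])NUM(?![A-Za-z0-9_])", replaced)
            )
            lines = [ln for ln in replaced.splitlines() if ln.strip()]
            brute_median = (
                float(statistics.median(len(ln.split()) for ln in lines))
                if lines
                else 0.0
            )
            assert feats.numeric_count == brute_count
            assert feats.median_paragraph_length == brute_median
            n = len(report.blocks)
            expected_loc = 0.0 if n == 1 else block.block_index / (n - 1)
            assert feats.relative_location == pytest.approx(expected_loc)
            assert 0.0 <= feats.relative_location <= 1.0


class TestLowestPurityCluster:
    def test_argmin_purity(self):
        report = ms.build_cluster_report(
            [0] * 10 + [1] * 10 + [2] * 10,
            [SL.comment] * 9 + [SL.diagnosis]
            + [SL.comment] * 5 + [SL.diagnosis] * 5
            + [SL.iron_content] * 8 + [SL.comment] * 2,
        )
        assert ms.lowest_purity_cluster(report) == 1

    def test_tie_breaks_to_smallest_id(self):
        report = ms.build_cluster_report(
            [0, 0, 3, 3],
            [SL.comment, SL.diagnosis, SL.comment, SL.diagnosis],
            n_clusters=4,
        )
        assert ms.lowest_purity_cluster(report) == 0

    def test_matches_brute_force_argmin(self, rng):
        labels = list(SL)
        for _ in range(30):
            n = int(rng.integers(8, 80))
            ids = [int(i) for i in rng.integers(0, 5, size=n)]
            truth = [labels[int(i)] for i in rng.integers(0, 10, size=n)]
            report = ms.build_cluster_report(ids, truth, n_clusters=5)
            purities = report.purities
            brute = min(sorted(purities), key=lambda c: purities[c])
            assert ms.lowest_purity_cluster(report) == brute


@pytest.fixture(scope="module")
def trained_two_stage(small_split):
    train, test = small_split
    first = ms.fit_section_assigner(train.blocks, n=1, k=6, seed=5)
    predictor = ms.fit_two_stage(first, train, seed=6)
    return train, test, first, predictor


class TestFitTwoStage:
    def test_target_is_lowest_training_purity_cluster(self, trained_two_stage):
        train, _, first, predictor = trained_two_stage
        clusters = first.predict_clusters(train.blocks)
        truth = [b.true_section for b in train.blocks]
        report = ms.build_cluster_report(clusters, truth, n_clusters=first.model.k)
        assert predictor.target_cluster == ms.lowest_purity_cluster(report)

    def test_second_stage_sees_only_target_blocks(self, trained_two_stage):
        train, _, first, predictor = trained_two_stage
        pairs = list(train.iter_blocks())
        clusters = first.predict_clusters([b for _, b in pairs])
        routed = [
            (r, b) for (r, b), c in zip(pairs, clusters)
            if c == predictor.target_cluster
        ]
        feats = np.array(
            [
                ms.compute_ensemble_features(b, r, first.rules).as_array()
                for r, b in routed
            ]
        )
        # standardization offsets/scales come from exactly those blocks
        assert predictor.feature_mean == pytest.approx(feats.mean(axis=0))
        expected_scale = np.where(feats.std(axis=0) > 0, feats.std(axis=0), 1.0)
        assert predictor.feature_scale == pytest.approx(expected_scale)

    def test_five_distinct_points_give_zero_second_sse(self):
        texts = [f"words {'x ' * (i + 1)}" for i in range(5)]
        blocks = [
            ms.TextBlock("r0", i, t, SL.comment) for i, t in enumerate(texts)
        ]
        report = ms.Report("r0", 0, blocks)
        # build a degenerate first stage whose single cluster holds all blocks
        vocab = ms.build_vocabulary([b.text for b in blocks], n=1, capacity=10)
        X = np.array([ms.featurize_text(b.text, vocab) for b in blocks], dtype=float)
        model = ms.fit_kmeans(X, k=1, seed=0)
        first = ms.SectionAssigner(model, {0: SL.comment}, vocab)
        predictor = ms.fit_two_stage(first, ms.Corpus([report]), seed=0)
        assert predictor.second.sse == pytest.approx(0.0)

    def test_too_few_target_blocks_rejected(self):
        blocks = [ms.TextBlock("r0", i, f"w{i}", SL.comment) for i in range(3)]
        report = ms.Report("r0", 0, blocks)
        vocab = ms.build_vocabulary([b.text for b in blocks], n=1, capacity=10)
        X = np.array([ms.featurize_text(b.text, vocab) for b in blocks], dtype=float)
        model = ms.fit_kmeans(X, k=1, seed=0)
        first = ms.SectionAssigner(model, {0: SL.comment}, vocab)
        with pytest.raises(ValueError, match="cannot place"):
            ms.fit_two_stage(first, ms.Corpus([report]), seed=0)

    def test_deterministic_for_fixed_seed(self, small_split):
        train, _ = small_split
        first = ms.fit_section_assigner(train.blocks, n=1, k=6, seed=5)
        a = ms.fit_two_stage(first, train, seed=17)
        b = ms.fit_two_stage(first, train, seed=17)
        assert a.target_cluster == b.target_cluster
        assert np.array_equal(a.second.centroids, b.second.centroids)
        assert a.second_sections == b.second_sections


class TestPredictTwoStage:
    def test_non_target_blocks_keep_first_stage_labels(self, trained_two_stage):
        _, test, first, predictor = trained_two_stage
        labels, first_labels, clusters = predictor.predict(test, return_detail=True)
        for label, first_label, cluster in zip(labels, first_labels, clusters):
            if cluster != predictor.target_cluster:
                assert label is first_label

    def test_target_blocks_use_second_stage_map(self, trained_two_stage):
        _, test, first, predictor = trained_two_stage
        pairs = list(test.iter_blocks())
        labels, _, clusters = predictor.predict(test, return_detail=True)
        for (report, block), label, cluster in zip(pairs, labels, clusters):
            if cluster == predictor.target_cluster:
                feats = ms.compute_ensemble_features(block, report, first.rules)
                z = (feats.as_array() - predictor.feature_mean) / predictor.feature_scale
                sc = int(predictor.second.assign(z[None, :])[0])
                assert label is predictor.second_sections[sc]

    def test_serialization_round_trip(self, trained_two_stage, tmp_path):
        _, test, _, predictor = trained_two_stage
        path = tmp_path / "two_stage.json"
        predictor.save(path)
        loaded = ms.TwoStagePredictor.load(path)
        assert loaded.predict(test) == predictor.predict(test)
        assert loaded.target_cluster == predictor.target_cluster
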