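"""Two-stage ensemble: re-classify the first stage's least pure cluster.

One cluster of the n-gram model typically ends up much less pure than the
rest, mixing short or position-dependent sections (clinical information,
iron content, comment, peripheral blood smear). Those sections are better
separated by structural cues than by word content, so blocks routed to the
lowest-purity cluster are handed to a second 5-centroid K-means over three
hand-crafted features:

* ``numeric_count`` — how many number tokens the block contains (the blood
  smear and the aspirate differential are numeric-dense);
* ``median_paragraph_length`` — median word count over the block's
  paragraphs (iron content is conspicuously short);
* ``relative_location`` — the block's position in its report, 0 at the
  start and 1 at the end (clinical information leads, comments trail).

The three features live on incomparable scales, so they are standardized
with the training mean and standard deviation before clustering. Blocks
outside the target cluster keep their first-stage label untouched.
"""

from __future__ import annotations

import json
import re
import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .clustering import (
    KMeansModel,
    SectionAssigner,
    assign_cluster_sections,
    fit_kmeans,
)
from .metrics import ClusterReport, build_cluster_report
from .sections import Corpus, Report, SectionLabel, TextBlock
from .tokenization import DEFAULT_RULES, TokenRules, replace_tokens

SECOND_STAGE_K = 5


@dataclass(frozen=True)
class EnsembleFeatures:
    numeric_count: int
    median_paragraph_length: float
    relative_location: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.numeric_count, self.median_paragraph_length, self.relative_location],
            dtype=float,
        )


def _count_word(text: str, word: str) -> int:
    # boundaries keep NUM from matching inside CDNUM/ACCNUM
    pattern = rf"(?<![A-Za-z0-9_]){re.escape(word)}(?![A-Za-z0-9_])"
    return len(re.findall(pattern, text))


def compute_ensemble_features(
    block: TextBlock,
    report: Report,
    rules: TokenRules | None = DEFAULT_RULES,
) -> EnsembleFeatures:
    """Structural features of one block within its parent report.

    Number tokens are counted after token replacement so the count matches
    what the first stage saw; with ``rules=None`` raw numeric literals are
    counted instead. Paragraphs are the non-blank newline-delimited
    segments of the text; their lengths are whitespace word counts and the
    median averages the middle two for even counts. ``relative_location``
    is ``block_index / (blocks_in_report - 1)``, defined as 0 for a
    single-block report.
    """
    if rules is not None:
        text = replace_tokens(block.text, rules)
        numeric_count = _count_word(text, rules.number.token)
    else:
        text = block.text
        numeric_count = len(re.findall(DEFAULT_RULES.number.pattern, text))
    paragraphs = [line for line in text.splitlines() if line.strip()]
    if paragraphs:
        median_len = float(statistics.median(len(p.split()) for p in paragraphs))
    else:
        median_len = 0.0
    n_blocks = len(report.blocks)
    relative = 0.0 if n_blocks == 1 else block.block_index / (n_blocks - 1)
    return EnsembleFeatures(numeric_count, median_len, relative)


def lowest_purity_cluster(report: ClusterReport) -> int:
    """Id of the non-empty cluster with minimum purity (ties -> smallest id)."""
    purities = report.purities
    if not purities:
        raise ValueError("all clusters are empty")
    return min(sorted(purities), key=lambda c: purities[c])


@dataclass
class TwoStagePredictor:
    """First-stage assigner plus the 5-centroid second stage for its
    lowest-purity cluster."""

    first: SectionAssigner
    target_cluster: int
    second: KMeansModel
    second_sections: dict[int, SectionLabel]
    feature_mean: np.ndarray
    feature_scale: np.ndarray

    def _standardize(self, features: np.ndarray) -> np.ndarray:
        return (features - self.feature_mean) / self.feature_scale

    def predict(
        self, corpus: Corpus, return_detail: bool = False
    ) -> list[SectionLabel] | tuple[list[SectionLabel], list[SectionLabel], np.ndarray]:
        """Predicted section per block, in ``corpus.iter_blocks()`` order.

        Blocks whose first-stage cluster is not the target keep the
        first-stage label; target-cluster blocks get the second stage's
        label from their standardized structural features. With
        ``return_detail`` the first-stage labels and cluster ids come back
        too.
        """
        pairs = list(corpus.iter_blocks())
        blocks = [b for _, b in pairs]
        clusters = self.first.predict_clusters(blocks)
        labels = [self.first.cluster_sections[c] for c in clusters]
        first_labels = list(labels)
        routed = [i for i, c in enumerate(clusters) if c == self.target_cluster]
        if routed:
            features = np.array(
                [
                    compute_ensemble_features(
                        pairs[i][1], pairs[i][0], self.first.rules
                    ).as_array()
                    for i in routed
                ]
            )
            second_clusters = self.second.assign(self._standardize(features))
            for i, sc in zip(routed, second_clusters):
                labels[i] = self.second_sections[int(sc)]
        if return_detail:
            return labels, first_labels, clusters
        return labels

    # -- JSON round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "first": self.first.to_dict(),
            "target_cluster": self.target_cluster,
            "second": self.second.to_dict(),
            "second_sections": {
                str(c): s.value for c, s in self.second_sections.items()
            },
            "feature_mean": self.feature_mean.tolist(),
            "feature_scale": self.feature_scale.tolist(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "TwoStagePredictor":
        return cls(
            first=SectionAssigner.from_dict(payload["first"]),
            target_cluster=payload["target_cluster"],
            second=KMeansModel.from_dict(payload["second"]),
            second_sections={
                int(c): SectionLabel(s)
                for c, s in payload["second_sections"].items()
            },
            feature_mean=np.asarray(payload["feature_mean"], dtype=float),
            feature_scale=np.asarray(payload["feature_scale"], dtype=float),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "TwoStagePredictor":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def fit_two_stage(
    first: SectionAssigner,
    train: Corpus,
    seed: int = 0,
    restarts: int = 10,
) -> TwoStagePredictor:
    """Fit the second stage on the first stage's lowest-purity cluster.

    Training blocks are routed through the first stage; the non-empty
    cluster with the lowest training-label purity becomes the target.
    The second 5-centroid K-means is fit on the standardized structural
    features of the target-cluster blocks and its clusters are mapped to
    sections by training-label majority (same tie rules as the first
    stage).

    Raises
    ------
    ValueError
        If the target cluster holds fewer than 5 training blocks.
    """
    pairs = list(train.iter_blocks())
    blocks = [b for _, b in pairs]
    truth = [b.true_section for b in blocks]
    if any(t is None for t in truth):
        raise ValueError("all training blocks need a true_section")
    clusters = first.predict_clusters(blocks)
    report = build_cluster_report(clusters, truth, n_clusters=first.model.k)  # type: ignore[arg-type]
    target = lowest_purity_cluster(report)

    routed = [i for i, c in enumerate(clusters) if c == target]
    if len(routed) < SECOND_STAGE_K:
        raise ValueError(
            f"target cluster {target} holds only {len(routed)} blocks; "
            f"cannot place {SECOND_STAGE_K} centroids"
        )
    features = np.array(
        [
            compute_ensemble_features(pairs[i][1], pairs[i][0], first.rules).as_array()
            for i in routed
        ]
    )
    mean = features.mean(axis=0)
    std = features.std(axis=0)
    scale = np.where(std > 0, std, 1.0)
    standardized = (features - mean) / scale

    second = fit_kmeans(standardized, k=SECOND_STAGE_K, restarts=restarts, seed=seed)
    second_sections = assign_cluster_sections(
        second, standardized, [truth[i] for i in routed]  # type: ignore[arg-type]
    )
    return TwoStagePredictor(
        first=first,
        target_cluster=target,
        second=second,
        second_sections=second_sections,
        feature_mean=mean,
        feature_scale=scale,
    )


def predict_two_stage(
    predictor: TwoStagePredictor, corpus: Corpus
) -> list[SectionLabel]:
    """Functional alias for :meth:`TwoStagePredictor.predict`."""
    return predictor.predict(corpus)  # type: ignore[return-value]
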