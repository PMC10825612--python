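"""The experiment harness: the full comparison grid on one corpus.

The grid reproduces the study design: token replacement on/off crossed
with n-gram sizes 1-5 at k=10 (the primary comparison), an SSE-versus-k
sweep with elbow detection for the 1- and 2-gram models, and the two-stage
ensemble for the 1- and 2-gram models. All randomness flows from one root
seed through per-cell derived seeds, so a rerun with the same configuration
is byte-identical.

The harness never lets test text reach vocabulary construction or model
fitting; test labels are read only at scoring time (except in the
explicitly flagged ``map_on_test`` evaluation mode, provided for
protocol-comparison purposes).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .clustering import (
    SectionAssigner,
    assign_cluster_sections,
    elbow_point,
    fit_kmeans,
    fit_section_assigner,
    sse_curve,
)
from .corpus_io import chronological_split
from .ensemble import fit_two_stage
from .metrics import build_cluster_report, model_accuracy
from .sections import Corpus, SectionLabel
from .synthetic import GeneratorConfig, generate_corpus
from .tokenization import DEFAULT_RULES

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised for invalid experiment configuration before any computation."""


@dataclass(frozen=True)
class ExperimentConfig:
    """The experiment grid definition.

    The defaults run the full study grid: tokens on/off x n in 1..5 at
    k=10 (10 rows), a k sweep over 1..19 with elbow detection for
    n in {1, 2} (2 rows), and the ensemble for n in {1, 2} (2 rows).
    """

    generator: GeneratorConfig = GeneratorConfig()
    token_options: tuple[bool, ...] = (True, False)
    ngram_sizes: tuple[int, ...] = (1, 2, 3, 4, 5)
    capacity: int = 200
    k: int = 10
    k_sweep_ns: tuple[int, ...] = (1, 2)
    k_sweep_range: tuple[int, int] = (1, 19)
    ensemble_ns: tuple[int, ...] = (1, 2)
    restarts: int = 10
    seed: int = 0
    train_fraction: float = 0.8

    def validate(self) -> None:
        for n in (*self.ngram_sizes, *self.k_sweep_ns, *self.ensemble_ns):
            if n not in range(1, 6):
                raise ConfigError(f"n-gram size {n} outside 1..5")
        ks = [self.k, *self.k_sweep_range]
        for k in ks:
            if k not in range(1, 20):
                raise ConfigError(f"centroid count {k} outside 1..19")
        if self.k_sweep_range[0] > self.k_sweep_range[1]:
            raise ConfigError("empty k sweep range")
        if self.capacity < 1:
            raise ConfigError("vocabulary capacity must be >= 1")
        if self.restarts < 1:
            raise ConfigError("restarts must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigError("train_fraction must be in (0, 1)")
        for n in self.ensemble_ns:
            if n not in self.ngram_sizes:
                raise ConfigError(f"ensemble n={n} not in ngram_sizes")


def _config_hash(config: ExperimentConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _child_seed(child: np.random.SeedSequence) -> int:
    return int(child.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class ExperimentResult:
    """Tidy metrics table plus the per-fit run log and trained assigners."""

    table: pd.DataFrame
    runlog: list[dict] = field(default_factory=list)
    assigners: dict[tuple[bool, int], SectionAssigner] = field(default_factory=dict)
    config_hash: str = ""


def run_experiment(
    config: ExperimentConfig = ExperimentConfig(),
    corpus: Corpus | None = None,
    out_dir: str | Path | None = None,
) -> ExperimentResult:
    """Run the grid and (optionally) write metrics.csv / manifest / run log.

    Returns one CSV row per grid cell with accuracy, per-cluster purities
    and minimal purity on the test subset; sweep rows add the elbow k and
    the accuracy refit at that k; ensemble rows add the two-stage accuracy
    next to the first-stage one. Every row carries the derived seed and the
    configuration hash needed to regenerate it.
    """
    config.validate()
    cfg_hash = _config_hash(config)
    if corpus is None:
        corpus = generate_corpus(config.generator)
    train, test = chronological_split(corpus, config.train_fraction)
    train_blocks = train.blocks
    test_blocks = test.blocks
    train_truth = [b.true_section for b in train_blocks]
    test_truth = [b.true_section for b in test_blocks]

    primary_cells = [(t, n) for t in config.token_options for n in config.ngram_sizes]
    n_cells = len(primary_cells) + len(config.k_sweep_ns) + len(config.ensemble_ns)
    children = np.random.SeedSequence(config.seed).spawn(n_cells)
    seeds = iter(_child_seed(c) for c in children)

    rows: list[dict] = []
    runlog: list[dict] = []
    assigners: dict[tuple[bool, int], SectionAssigner] = {}

    for tokens_on, n in primary_cells:
        cell_seed = next(seeds)
        rules = DEFAULT_RULES if tokens_on else None
        assigner = fit_section_assigner(
            train_blocks,
            n=n,
            capacity=config.capacity,
            k=config.k,
            restarts=config.restarts,
            seed=cell_seed,
            rules=rules,
        )
        assigners[(tokens_on, n)] = assigner
        predicted = assigner.predict(test_blocks)
        clusters = assigner.predict_clusters(test_blocks)
        report = build_cluster_report(
            clusters, test_truth, predicted, n_clusters=config.k
        )
        rows.append(
            {
                "row_type": "primary",
                "tokens": tokens_on,
                "n": n,
                "k": config.k,
                "accuracy": report.accuracy,
                "minimal_purity": report.minimal_purity,
                "purities": json.dumps(
                    {str(c): p for c, p in sorted(report.purities.items())}
                ),
                "elbow_k": None,
                "accuracy_at_elbow": None,
                "first_stage_accuracy": None,
                "target_cluster": None,
                "seed": cell_seed,
                "config_hash": cfg_hash,
            }
        )
        runlog.append(
            {
                "cell": f"primary tokens={tokens_on} n={n} k={config.k}",
                "seed": cell_seed,
                "restart_sses": assigner.model.restart_sses,
                "sse": assigner.model.sse,
            }
        )
        logger.info(
            "primary tokens=%s n=%d: accuracy %.3f min purity %.3f",
            tokens_on, n, report.accuracy, report.minimal_purity,
        )

    for n in config.k_sweep_ns:
        cell_seed = next(seeds)
        base = assigners[(True, n)]
        X_train = base.featurize_blocks(train_blocks)
        curve = sse_curve(
            X_train,
            k_min=config.k_sweep_range[0],
            k_max=config.k_sweep_range[1],
            restarts=config.restarts,
            seed=cell_seed,
        )
        elbow = elbow_point(curve)
        elbow_model = fit_kmeans(
            X_train, k=elbow, restarts=config.restarts, seed=cell_seed
        )
        mapping = assign_cluster_sections(elbow_model, X_train, train_truth)  # type: ignore[arg-type]
        X_test = base.featurize_blocks(test_blocks)
        elbow_pred = [mapping[c] for c in elbow_model.assign(X_test)]
        rows.append(
            {
                "row_type": "sweep",
                "tokens": True,
                "n": n,
                "k": elbow,
                "accuracy": None,
                "minimal_purity": None,
                "purities": json.dumps({str(k): v for k, v in curve.items()}),
                "elbow_k": elbow,
                "accuracy_at_elbow": model_accuracy(elbow_pred, test_truth),  # type: ignore[arg-type]
                "first_stage_accuracy": None,
                "target_cluster": None,
                "seed": cell_seed,
                "config_hash": cfg_hash,
            }
        )
        runlog.append(
            {"cell": f"sweep n={n}", "seed": cell_seed, "curve": curve}
        )
        logger.info("sweep n=%d: elbow at k=%d", n, elbow)

    for n in config.ensemble_ns:
        cell_seed = next(seeds)
        first = assigners[(True, n)]
        predictor = fit_two_stage(
            first, train, seed=cell_seed, restarts=config.restarts
        )
        two_stage_pred = predictor.predict(test)
        first_pred = first.predict(test_blocks)
        rows.append(
            {
                "row_type": "ensemble",
                "tokens": True,
                "n": n,
                "k": config.k,
                "accuracy": model_accuracy(two_stage_pred, test_truth),  # type: ignore[arg-type]
                "minimal_purity": None,
                "purities": None,
                "elbow_k": None,
                "accuracy_at_elbow": None,
                "first_stage_accuracy": model_accuracy(first_pred, test_truth),  # type: ignore[arg-type]
                "target_cluster": predictor.target_cluster,
                "seed": cell_seed,
                "config_hash": cfg_hash,
            }
        )
        runlog.append(
            {
                "cell": f"ensemble n={n}",
                "seed": cell_seed,
                "restart_sses": predictor.second.restart_sses,
                "target_cluster": predictor.target_cluster,
            }
        )
        logger.info("ensemble n=%d: accuracy %.3f", n, rows[-1]["accuracy"])

    table = pd.DataFrame(rows)
    result = ExperimentResult(
        table=table, runlog=runlog, assigners=assigners, config_hash=cfg_hash
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "metrics.csv", index=False)
        manifest = {
            "package_version": __version__,
            "config": dataclasses.asdict(config),
            "config_hash": cfg_hash,
            "n_reports": len(corpus),
            "n_train_blocks": len(train_blocks),
            "n_test_blocks": len(test_blocks),
        }
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, default=str), encoding="utf-8"
        )
        with (out_dir / "runlog.jsonl").open("w", encoding="utf-8") as fh:
            for entry in runlog:
                fh.write(json.dumps(entry) + "\n")
    return result


def evaluate_assigner(
    assigner: SectionAssigner,
    corpus: Corpus,
    map_on_test: bool = False,
):
    """Score a trained assigner on a labeled corpus.

    With ``map_on_test`` the cluster -> section map is re-derived by
    majority vote on this corpus's labels before scoring (a protocol
    variant that peeks at evaluation labels; off by default).
    """
    blocks = corpus.blocks
    truth = [b.true_section for b in blocks]
    X = assigner.featurize_blocks(blocks)
    clusters = assigner.model.assign(X)
    if map_on_test:
        mapping = assign_cluster_sections(assigner.model, X, truth)  # type: ignore[arg-type]
    else:
        mapping = assigner.cluster_sections
    predicted = [mapping[c] for c in clusters]
    return build_cluster_report(
        clusters, truth, predicted, n_clusters=assigner.model.k  # type: ignore[arg-type]
    )


def majority_baseline_accuracy(labels: Sequence[SectionLabel]) -> float:
    """Accuracy of always predicting the most common section."""
    counts: dict[SectionLabel, int] = {}
    for label in labels:
        counts[label] = counts.get(label, 0) + 1
    return max(counts.values()) / len(labels)
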