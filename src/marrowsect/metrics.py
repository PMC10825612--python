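"""Evaluation metrics: cluster purity, accuracy, and the uniformity test.

Purity measures how homogeneous one cluster is (fraction of its members
belonging to its most common true section); accuracy measures the whole
model (fraction of blocks whose predicted section matches the truth). When
the cluster -> section map is derived by majority vote on the same labeled
set being scored, accuracy equals the size-weighted mean of cluster
purities. The chi-square test compares a cluster's section composition
against the null of an even spread over all sections.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sections import SectionLabel

SectionCounts = Mapping[SectionLabel, int]


def cluster_purity(section_counts: SectionCounts) -> float:
    """max section count / total count for one non-empty cluster."""
    total = sum(section_counts.values())
    if total < 1:
        raise ValueError("purity is undefined for an empty cluster")
    return max(section_counts.values()) / total


def model_accuracy(
    predicted: Sequence[SectionLabel], truth: Sequence[SectionLabel]
) -> float:
    """Fraction of predictions matching the true section."""
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth differ in length")
    if len(predicted) == 0:
        raise ValueError("no predictions to score")
    matches = sum(p == t for p, t in zip(predicted, truth))
    return matches / len(predicted)


@dataclass
class ClusterReport:
    """Per-cluster section composition for one scored model.

    ``section_counts`` maps cluster id -> true-section counts of the blocks
    the cluster captured; clusters that captured nothing have empty
    counters and are excluded from purity aggregation. ``accuracy`` is
    filled in when predictions were scored alongside.
    """

    section_counts: dict[int, Counter]
    accuracy: float | None = None

    @property
    def purities(self) -> dict[int, float]:
        """Purity per non-empty cluster."""
        return {
            c: cluster_purity(counts)
            for c, counts in self.section_counts.items()
            if sum(counts.values()) > 0
        }

    @property
    def minimal_purity(self) -> float:
        return minimal_cluster_purity(self)

    @property
    def sizes(self) -> dict[int, int]:
        return {c: sum(counts.values()) for c, counts in self.section_counts.items()}


def build_cluster_report(
    cluster_ids: Sequence[int],
    truth: Sequence[SectionLabel],
    predicted: Sequence[SectionLabel] | None = None,
    n_clusters: int | None = None,
) -> ClusterReport:
    """Tally true sections per cluster; optionally score accuracy too."""
    if len(cluster_ids) != len(truth):
        raise ValueError("cluster_ids and truth differ in length")
    k = n_clusters if n_clusters is not None else (max(cluster_ids) + 1)
    counts: dict[int, Counter] = {c: Counter() for c in range(k)}
    for c, t in zip(cluster_ids, truth):
        counts[int(c)][t] += 1
    accuracy = model_accuracy(predicted, truth) if predicted is not None else None
    return ClusterReport(section_counts=counts, accuracy=accuracy)


def minimal_cluster_purity(report: ClusterReport) -> float:
    """Smallest purity over the non-empty clusters."""
    purities = report.purities
    if not purities:
        raise ValueError("all clusters are empty")
    return min(purities.values())


def chi_square_uniform(
    section_counts: SectionCounts, n_sections: int | None = None
) -> tuple[float, int, float]:
    """Chi-square test of one cluster's composition against an even spread.

    The null expects ``total / S`` blocks in each of the ``S`` possible
    sections (all ten by default, even when the cluster lacks some).
    Returns ``(statistic, degrees of freedom, upper-tail p-value)``.
    """
    if n_sections is None:
        n_sections = len(SectionLabel)
    if n_sections < 2:
        raise ValueError("need at least 2 sections")
    total = sum(section_counts.values())
    if total < 1:
        raise ValueError("chi-square is undefined for an empty cluster")
    expected = total / n_sections
    observed = list(section_counts.values())
    observed += [0] * (n_sections - len(observed))
    statistic = sum((obs - expected) ** 2 / expected for obs in observed)
    df = n_sections - 1
    pvalue = float(stats.chi2.sf(statistic, df))
    return float(statistic), df, pvalue


def chi_square_uniform_pooled(
    report: ClusterReport, n_sections: int | None = None
) -> tuple[float, int, float]:
    """Model-level variant: sum statistics and dfs over non-empty clusters."""
    total_stat, total_df = 0.0, 0
    any_cluster = False
    for counts in report.section_counts.values():
        if sum(counts.values()) < 1:
            continue
        stat, df, _ = chi_square_uniform(counts, n_sections)
        total_stat += stat
        total_df += df
        any_cluster = True
    if not any_cluster:
        raise ValueError("all clusters are empty")
    return total_stat, total_df, float(stats.chi2.sf(total_stat, total_df))


# ---------------------------------------------------------------------------
# tidy export


def report_to_frame(report: ClusterReport) -> pd.DataFrame:
    """One row per cluster (id, size, modal section, purity) + summary rows."""
    rows = []
    for c in sorted(report.section_counts):
        counts = report.section_counts[c]
        size = sum(counts.values())
        if size:
            modal = max(counts, key=lambda s: (counts[s], -s.canonical_index))
            rows.append(
                {
                    "cluster": str(c),
                    "size": size,
                    "modal_section": modal.value,
                    "purity": cluster_purity(counts),
                }
            )
        else:
            rows.append(
                {"cluster": str(c), "size": 0, "modal_section": None, "purity": None}
            )
    rows.append(
        {
            "cluster": "minimal_purity",
            "size": sum(report.sizes.values()),
            "modal_section": None,
            "purity": report.minimal_purity,
        }
    )
    if report.accuracy is not None:
        rows.append(
            {
                "cluster": "accuracy",
                "size": sum(report.sizes.values()),
                "modal_section": None,
                "purity": report.accuracy,
            }
        )
    return pd.DataFrame(rows)


def report_to_json(report: ClusterReport, path: str | Path | None = None) -> dict:
    payload = {
        "clusters": {
            str(c): {s.value: int(v) for s, v in counts.items()}
            for c, counts in report.section_counts.items()
        },
        "purities": {str(c): p for c, p in report.purities.items()},
        "minimal_purity": report.minimal_purity,
        "accuracy": report.accuracy,
    }
    if path is not None:
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")
    return payload
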