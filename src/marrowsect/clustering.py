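"""K-means with random restarts, majority-label cluster mapping, and the
SSE elbow analysis.

The clustering stage is deliberately transparent: Lloyd's algorithm is
implemented directly so every restart's final SSE and the winning run's
per-iteration SSE trajectory are recorded on the returned model. Restart
selection keeps the run with the lowest sum of squared errors; cluster ids
are then mapped to report sections by the majority true label of the
training blocks each cluster captured.

Geometry is squared Euclidean distance on the binary presence vectors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .sections import SectionLabel, TextBlock
from .tokenization import (
    DEFAULT_RULES,
    NgramVocabulary,
    TokenRules,
    featurize_text,
)

_MAX_ITER = 300


@dataclass
class KMeansModel:
    """A fitted K-means model plus the restart/iteration bookkeeping.

    Attributes
    ----------
    k : int
        Number of centroids.
    centroids : ndarray of shape (k, d)
        Cluster centers in feature space.
    sse : float
        Sum of squared Euclidean distances of the training points to their
        nearest centroid; the minimum over all restarts.
    seed : int
        Root seed the restarts were derived from.
    restart_sses : list of float
        Final SSE of every restart, in restart order.
    iteration_sses : list of float
        SSE after each assignment step of the winning restart;
        non-increasing by construction of Lloyd's algorithm.
    """

    k: int
    centroids: np.ndarray
    sse: float
    seed: int
    restart_sses: list[float] = field(default_factory=list)
    iteration_sses: list[float] = field(default_factory=list)

    def assign(self, vectors: np.ndarray) -> np.ndarray:
        """Nearest-centroid cluster id per row (ties -> lowest id)."""
        return nearest_centroid(vectors, self.centroids)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "centroids": self.centroids.tolist(),
            "sse": self.sse,
            "seed": self.seed,
            "restart_sses": list(self.restart_sses),
            "iteration_sses": list(self.iteration_sses),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "KMeansModel":
        return cls(
            k=payload["k"],
            centroids=np.asarray(payload["centroids"], dtype=float),
            sse=payload["sse"],
            seed=payload["seed"],
            restart_sses=list(payload["restart_sses"]),
            iteration_sses=list(payload["iteration_sses"]),
        )


def nearest_centroid(vectors: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Index of the nearest centroid per row; argmin breaks ties low."""
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    d2 = cdist(vectors, centroids, metric="sqeuclidean")
    return d2.argmin(axis=1)


def _init_centroids(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random selection of k distinct data points as centroids."""
    unique = np.unique(X, axis=0)
    if len(unique) >= k:
        idx = rng.choice(len(unique), size=k, replace=False)
        return unique[idx].astype(float).copy()
    # fewer distinct points than centroids: take all distinct points and pad
    # with duplicates; empty-cluster repair resolves the rest
    idx = rng.choice(len(X), size=k, replace=False)
    return X[idx].astype(float).copy()


def _lloyd(
    X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = _MAX_ITER
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    """One Lloyd's run: returns (centroids, assignments, sse, sse history)."""
    n = len(X)
    centroids = _init_centroids(X, k, rng)
    prev_assign: np.ndarray | None = None
    history: list[float] = []
    assign = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        d2 = cdist(X, centroids, metric="sqeuclidean")
        assign = d2.argmin(axis=1)
        own = d2[np.arange(n), assign]
        # repair empty clusters with the globally worst-fit point
        occupied = np.bincount(assign, minlength=k) > 0
        for c in np.flatnonzero(~occupied):
            far = int(own.argmax())
            centroids[c] = X[far]
            assign[far] = c
            own[far] = 0.0
        sse = float(own.sum())
        history.append(sse)
        if prev_assign is not None and np.array_equal(assign, prev_assign):
            return centroids, assign, sse, history
        prev_assign = assign
        for c in range(k):
            members = X[assign == c]
            if len(members):
                centroids[c] = members.mean(axis=0)
    # iteration cap hit: report SSE consistent with the final centroids
    d2 = cdist(X, centroids, metric="sqeuclidean")
    assign = d2.argmin(axis=1)
    sse = float(d2[np.arange(n), assign].sum())
    history.append(sse)
    return centroids, assign, sse, history


def fit_kmeans(
    vectors: np.ndarray | Sequence[Sequence[float]],
    k: int,
    restarts: int = 10,
    seed: int = 0,
) -> KMeansModel:
    """Fit K-means, keeping the lowest-SSE run of ``restarts`` restarts.

    Each restart draws fresh random centroid initializations (k distinct
    data points) from a seed derived from ``seed``, runs Lloyd's iterations
    to convergence, and logs its final SSE; the model returned is the run
    with the minimum SSE (first such run on ties). Fixed seed implies a
    bit-identical refit.

    Raises
    ------
    ValueError
        If there are no vectors, ``k < 1``, ``k`` exceeds the number of
        vectors, or ``restarts < 1``.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("vectors must be a non-empty 2-D array")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(X):
        raise ValueError(f"k={k} exceeds the number of vectors ({len(X)})")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")

    children = np.random.SeedSequence(seed).spawn(restarts)
    best: tuple[np.ndarray, float, list[float]] | None = None
    restart_sses: list[float] = []
    for child in children:
        rng = np.random.default_rng(child)
        centroids, _, sse, history = _lloyd(X, k, rng)
        restart_sses.append(sse)
        if best is None or sse < best[1]:
            best = (centroids, sse, history)
    assert best is not None
    centroids, sse, history = best
    return KMeansModel(
        k=k,
        centroids=centroids,
        sse=sse,
        seed=seed,
        restart_sses=restart_sses,
        iteration_sses=history,
    )


def assign_cluster_sections(
    model: KMeansModel,
    vectors: np.ndarray,
    labels: Sequence[SectionLabel],
) -> dict[int, SectionLabel]:
    """Map every cluster id to the modal true section of its members.

    Each labeled point goes to its nearest centroid; within a cluster the
    most common section wins, ties breaking toward the smallest canonical
    section index. A cluster that captured no points falls back to the
    modal section of the whole labeled set (same tie rule).
    """
    if len(labels) == 0:
        raise ValueError("no labeled points")
    X = np.asarray(vectors, dtype=float)
    if len(X) != len(labels):
        raise ValueError("vectors and labels differ in length")
    assign = model.assign(X)

    def modal(section_list: Iterable[SectionLabel]) -> SectionLabel:
        counts: dict[SectionLabel, int] = {}
        for s in section_list:
            counts[s] = counts.get(s, 0) + 1
        return max(counts, key=lambda s: (counts[s], -s.canonical_index))

    global_modal = modal(labels)
    mapping: dict[int, SectionLabel] = {}
    for c in range(model.k):
        members = [labels[i] for i in np.flatnonzero(assign == c)]
        mapping[c] = modal(members) if members else global_modal
    return mapping


@dataclass
class SectionAssigner:
    """Trained first-stage model: featurization rules + K-means + label map."""

    model: KMeansModel
    cluster_sections: dict[int, SectionLabel]
    vocab: NgramVocabulary
    rules: TokenRules | None = DEFAULT_RULES

    def featurize_block(self, block: TextBlock | str) -> np.ndarray:
        text = block.text if isinstance(block, TextBlock) else block
        return featurize_text(text, self.vocab, self.rules)

    def featurize_blocks(self, blocks: Iterable[TextBlock | str]) -> np.ndarray:
        return np.array([self.featurize_block(b) for b in blocks], dtype=float)

    def predict_clusters(self, blocks: Iterable[TextBlock | str]) -> np.ndarray:
        return self.model.assign(self.featurize_blocks(blocks))

    def predict(self, blocks: Sequence[TextBlock | str]) -> list[SectionLabel]:
        """Predicted section per block (featurize -> nearest centroid -> map)."""
        return [self.cluster_sections[c] for c in self.predict_clusters(blocks)]

    # -- JSON round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        rules = None
        if self.rules is not None:
            rules = {
                "accession": vars(self.rules.accession),
                "cd": vars(self.rules.cd),
                "letter_number": vars(self.rules.letter_number),
                "number": vars(self.rules.number),
                "end_of_report_token": self.rules.end_of_report_token,
            }
        return {
            "model": self.model.to_dict(),
            "cluster_sections": {
                str(c): s.value for c, s in self.cluster_sections.items()
            },
            "vocab": self.vocab.to_dict(),
            "rules": rules,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "SectionAssigner":
        rules = None
        if payload["rules"] is not None:
            raw = payload["rules"]
            from .tokenization import TokenRule

            rules = TokenRules(
                accession=TokenRule(**raw["accession"]),
                cd=TokenRule(**raw["cd"]),
                letter_number=TokenRule(**raw["letter_number"]),
                number=TokenRule(**raw["number"]),
                end_of_report_token=raw["end_of_report_token"],
            )
        return cls(
            model=KMeansModel.from_dict(payload["model"]),
            cluster_sections={
                int(c): SectionLabel(s)
                for c, s in payload["cluster_sections"].items()
            },
            vocab=NgramVocabulary.from_dict(payload["vocab"]),
            rules=rules,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "SectionAssigner":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def fit_section_assigner(
    blocks: Sequence[TextBlock],
    *,
    n: int = 2,
    capacity: int = 200,
    k: int = 10,
    restarts: int = 10,
    seed: int = 0,
    rules: TokenRules | None = DEFAULT_RULES,
) -> SectionAssigner:
    """Train the full first stage on labeled training blocks.

    Pipeline: token replacement (when ``rules`` is given) -> top-``capacity``
    n-gram vocabulary from the training blocks only -> binary featurization
    -> restart-selected K-means -> majority-label cluster map.
    """
    from .tokenization import build_vocabulary, replace_tokens

    labels = [b.true_section for b in blocks]
    if any(label is None for label in labels):
        raise ValueError("all training blocks need a true_section")
    texts = [
        replace_tokens(b.text, rules) if rules is not None else b.text for b in blocks
    ]
    vocab = build_vocabulary(texts, n=n, capacity=capacity)
    X = np.array(
        [featurize_text(t, vocab, rules=None) for t in texts], dtype=float
    )  # texts already replaced
    model = fit_kmeans(X, k=k, restarts=restarts, seed=seed)
    mapping = assign_cluster_sections(model, X, labels)  # type: ignore[arg-type]
    return SectionAssigner(model=model, cluster_sections=mapping, vocab=vocab, rules=rules)


def predict_sections(
    assigner: SectionAssigner, blocks: Sequence[TextBlock | str]
) -> list[SectionLabel]:
    """Functional alias for :meth:`SectionAssigner.predict`."""
    return assigner.predict(blocks)


def sse_curve(
    vectors: np.ndarray,
    k_min: int = 1,
    k_max: int = 19,
    restarts: int = 10,
    seed: int = 0,
) -> dict[int, float]:
    """Best-of-restarts SSE for every k in ``[k_min, k_max]``.

    Each k gets its own derived seed, so the curve is deterministic for a
    fixed root seed. Random restarts make strict monotonicity in k likely
    but not guaranteed.
    """
    X = np.asarray(vectors, dtype=float)
    if k_max > len(X):
        raise ValueError(f"k_max={k_max} exceeds the number of vectors ({len(X)})")
    if k_min < 1 or k_min > k_max:
        raise ValueError("need 1 <= k_min <= k_max")
    ks = range(k_min, k_max + 1)
    children = np.random.SeedSequence(seed).spawn(len(ks))
    curve: dict[int, float] = {}
    for k, child in zip(ks, children):
        child_seed = int(child.generate_state(1)[0] & 0x7FFFFFFF)
        curve[k] = fit_kmeans(X, k=k, restarts=restarts, seed=child_seed).sse
    return curve


def elbow_point(curve: Mapping[int, float] | Sequence[float]) -> int:
    """The k maximizing the second forward difference of the SSE curve.

    The elbow is the interior k where the marginal SSE reduction drops the
    most: argmax of ``(sse[k-1] - sse[k]) - (sse[k] - sse[k+1])``, ties
    breaking toward the smallest k. Requires at least 3 points.
    """
    if isinstance(curve, Mapping):
        ks = sorted(curve)
        sses = [curve[k] for k in ks]
    else:
        sses = list(curve)
        ks = list(range(1, len(sses) + 1))
    if len(sses) < 3:
        raise ValueError("need at least 3 points to locate an elbow")
    best_k, best_d2 = None, -np.inf
    for i in range(1, len(sses) - 1):
        d2 = (sses[i - 1] - sses[i]) - (sses[i] - sses[i + 1])
        if d2 > best_d2:
            best_k, best_d2 = ks[i], d2
    assert best_k is not None
    return best_k
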