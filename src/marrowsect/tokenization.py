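"""Token replacement, whitespace tokenization, n-grams and binary features.

Accession numbers, cluster-of-differentiation (CD) markers and numeric
values carry strong section information, but each surface form ("S21-00123",
"CD34", "2.5") is nearly unique, so none of them recurs often enough to
enter a frequency-ranked vocabulary. Replacing every match with a fixed
placeholder word (ACCNUM, CDNUM, NUM) collapses them to single vocabulary
entries a clustering model can exploit.

Tokenization is deliberately minimal: split on whitespace, keep case and
attached punctuation. Capitalization is informative in pathology reports
(diagnosis lines are often fully capitalized), so no case folding is done.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .sections import TextBlock

Ngram = tuple[str, ...]


@dataclass(frozen=True)
class TokenRule:
    """One replacement rule: a regex pattern and the placeholder word."""

    pattern: str
    token: str
    enabled: bool = True

    def __post_init__(self) -> None:
        if any(ch.isspace() for ch in self.token):
            raise ValueError(
                f"replacement token {self.token!r} contains whitespace and would "
                "be split apart by whitespace tokenization"
            )


@dataclass(frozen=True)
class TokenRules:
    """The full replacement rule set, in precedence order.

    Precedence is accession > CD > letter+number > number, so "CD34" becomes
    CDNUM rather than having its digits eaten by the number rule, and an
    accession id like "S21-00123" stays one ACCNUM token. The letter+number
    rule and the end-of-report marker exist but are off by default.

    Application is idempotent: no placeholder contains a digit, so a second
    pass matches nothing.
    """

    accession: TokenRule = TokenRule(r"[A-Z]{1,2}\d{2}-\d{3,6}", "ACCNUM")
    cd: TokenRule = TokenRule(r"CD\d+", "CDNUM")
    letter_number: TokenRule = TokenRule(
        r"(?<![A-Za-z0-9])[A-Za-z]\d+(?!\d)", "LETTERNUM", enabled=False
    )
    number: TokenRule = TokenRule(r"[+-]?\d+(?:\.\d+)?", "NUM")
    end_of_report_token: str | None = None


DEFAULT_RULES = TokenRules()

_GROUPS = ("accession", "cd", "letter_number", "number")


@lru_cache(maxsize=32)
def _compiled(rules: TokenRules) -> re.Pattern[str] | None:
    parts = []
    for name in _GROUPS:
        rule: TokenRule = getattr(rules, name)
        if rule.enabled:
            parts.append(f"(?P<{name}>{rule.pattern})")
    return re.compile("|".join(parts)) if parts else None


def replace_tokens(text: str, rules: TokenRules = DEFAULT_RULES) -> str:
    """Replace accession/CD/number matches with their placeholder words.

    All other characters, including case, punctuation and whitespace
    structure, are untouched; text without matches is returned unchanged.
    """
    pattern = _compiled(rules)
    if pattern is None:
        return text
    tokens = {name: getattr(rules, name).token for name in _GROUPS}
    return pattern.sub(lambda m: tokens[m.lastgroup], text)


def tokenize_words(text: str) -> list[str]:
    """Split on runs of whitespace, preserving case and punctuation."""
    return text.split()


def extract_ngrams(tokens: Sequence[str], n: int) -> list[Ngram]:
    """All contiguous length-``n`` windows of a token sequence, in order."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1)]


@dataclass
class NgramVocabulary:
    """The top-V n-grams of a training corpus, in fixed order.

    Entries are (n-gram, total occurrence count) pairs sorted by frequency
    descending with lexicographic tie-breaking, so construction is
    deterministic. The entry order defines the feature-vector layout.
    """

    n: int
    entries: list[tuple[Ngram, int]]
    capacity: int

    def __post_init__(self) -> None:
        if len(self.entries) > self.capacity:
            raise ValueError("more entries than capacity")
        self._index = {ngram: i for i, (ngram, _) in enumerate(self.entries)}
        if len(self._index) != len(self.entries):
            raise ValueError("duplicate n-grams in vocabulary")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def ngrams(self) -> list[Ngram]:
        return [ng for ng, _ in self.entries]

    def index_of(self, ngram: Ngram) -> int | None:
        return self._index.get(ngram)

    # -- TSV interchange (two columns: space-joined n-gram, frequency) -----

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for ngram, freq in self.entries:
                fh.write(f"{' '.join(ngram)}\t{freq}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, n: int, capacity: int) -> "NgramVocabulary":
        entries: list[tuple[Ngram, int]] = []
        with Path(path).open("r", encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                joined, freq = line.rstrip("\n").split("\t")
                ngram = tuple(joined.split(" "))
                if len(ngram) != n:
                    raise ValueError(f"n-gram {joined!r} is not a {n}-gram")
                entries.append((ngram, int(freq)))
        return cls(n=n, entries=entries, capacity=capacity)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "capacity": self.capacity,
            "entries": [[list(ng), freq] for ng, freq in self.entries],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "NgramVocabulary":
        return cls(
            n=payload["n"],
            entries=[(tuple(ng), freq) for ng, freq in payload["entries"]],
            capacity=payload["capacity"],
        )


def build_vocabulary(
    blocks: Iterable[TextBlock | str], n: int, capacity: int = 200
) -> NgramVocabulary:
    """Count n-grams over training blocks and keep the ``capacity`` most frequent.

    Frequency is total occurrences summed over all blocks (not document
    frequency). Ties at the cutoff break lexicographically so the result is
    deterministic. Blocks are expected to be token-replaced already if a
    replacement rule set is in use.

    Raises
    ------
    ValueError
        If ``capacity < 1`` or no block yields a single n-gram.
    """
    if capacity < 1:
        raise ValueError("capacity must be >= 1")
    counts: Counter[Ngram] = Counter()
    for block in blocks:
        text = block.text if isinstance(block, TextBlock) else block
        counts.update(extract_ngrams(tokenize_words(text), n))
    if not counts:
        raise ValueError("no n-grams found in any block; vocabulary would be empty")
    ranked = sorted(counts.items(), key=lambda item: (-item[1], item[0]))
    return NgramVocabulary(n=n, entries=ranked[:capacity], capacity=capacity)


def featurize(tokens: Sequence[str], vocab: NgramVocabulary) -> np.ndarray:
    """Binary presence vector over the vocabulary, aligned to entry order.

    Element i is 1 iff vocabulary entry i occurs at least once among the
    token sequence's n-grams; occurrence counts and out-of-vocabulary
    n-grams are ignored.
    """
    if len(vocab) == 0:
        raise ValueError("vocabulary is empty")
    vector = np.zeros(len(vocab), dtype=np.uint8)
    for ngram in set(extract_ngrams(tokens, vocab.n)):
        idx = vocab.index_of(ngram)
        if idx is not None:
            vector[idx] = 1
    return vector


def featurize_text(
    text: str, vocab: NgramVocabulary, rules: TokenRules | None = DEFAULT_RULES
) -> np.ndarray:
    """Replace tokens (if rules given), tokenize and featurize in one step."""
    if rules is not None:
        text = replace_tokens(text, rules)
    return featurize(tokenize_words(text), vocab)
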