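"""Seeded generator of bone-marrow-like reports with known section labels.

Real marrow report corpora live inside hospital laboratory information
systems and cannot be redistributed, so the pipeline is exercised on
synthetic reports that emulate the structural signals the method exploits
without imitating any institution's actual phrasing:

* ten sections in canonical order, each opened by a header line;
* templated, section-specific vocabulary (pathology reporting is highly
  formulaic) mixed with a shared pool of function words;
* an accession identifier in the specimen-received section;
* a numeric-dense aspirate differential and blood smear;
* a conspicuously short iron-content section;
* CD marker mentions concentrated in the aspirate and biopsy sections.

``shared_vocab_overlap`` is the difficulty dial: the probability that any
content word is drawn from the shared pool instead of the section's own
pool. At 1.0 (with ``equalize_structure``) sections are statistically
indistinguishable and no classifier can beat the majority baseline.

Generation is fully deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .sections import Corpus, Report, SectionLabel, TextBlock

# ---------------------------------------------------------------------------
# word pools (synthetic hematology-flavored vocabulary; structure, not prose)

SHARED_WORDS: tuple[str, ...] = (
    "the", "of", "and", "is", "are", "with", "a", "an", "in", "for", "to",
    "no", "not", "was", "were", "this", "that", "on", "by", "at", "or",
    "as", "be", "there", "within", "seen", "noted", "present", "overall",
    "mild", "mildly",
)

SECTION_WORDS: dict[SectionLabel, tuple[str, ...]] = {
    SectionLabel.specimen_received: (
        "specimen", "received", "container", "labelled", "clot", "fixative",
        "formalin", "cassette", "submitted", "pieces", "aggregate",
        "measuring", "decalcification", "grossed", "processed", "intact",
    ),
    SectionLabel.clinical_information: (
        "history", "referred", "investigation", "anemia", "lymphoma",
        "staging", "thrombocytopenia", "pancytopenia", "surveillance",
        "monitoring", "suspected", "myeloma", "presenting", "fatigue",
        "workup", "restaging",
    ),
    SectionLabel.peripheral_blood_smear: (
        "smear", "peripheral", "erythrocytes", "platelets", "neutrophils",
        "normochromic", "normocytic", "anisocytosis", "poikilocytosis",
        "polychromasia", "leukocytes", "film", "indices", "hemoglobin",
        "morphology", "unremarkable",
    ),
    SectionLabel.bone_marrow_aspirate: (
        "aspirate", "particles", "cellularity", "trilineage",
        "hematopoiesis", "megakaryocytes", "erythropoiesis",
        "granulopoiesis", "maturation", "spicules", "myeloid", "erythroid",
        "ratio", "blasts", "dysplasia", "adequate",
    ),
    SectionLabel.bone_marrow_aspirate_differential: (
        "promyelocytes", "myelocytes", "metamyelocytes", "segmented",
        "bands", "eosinophils", "basophils", "monocytes", "lymphocytes",
        "erythroblasts", "counted", "percent", "differential", "cells",
        "total", "plasma",
    ),
    SectionLabel.iron_content: (
        "iron", "hemosiderin", "stores", "stainable", "sideroblasts",
        "absent", "reduced", "increased", "granules", "depleted",
    ),
    SectionLabel.bone_marrow_biopsy: (
        "biopsy", "trephine", "cores", "architecture", "trabeculae",
        "interstitial", "infiltrate", "cellular", "fibrosis", "reticulin",
        "immunohistochemistry", "stains", "highlights", "paratrabecular",
        "aggregates", "lymphoid",
    ),
    SectionLabel.comment: (
        "comment", "correlation", "recommended", "discussed", "findings",
        "consistent", "favor", "interpretation", "ancillary",
        "cytogenetics", "flow", "pending", "clinicopathologic", "review",
        "followup", "correlate",
    ),
    SectionLabel.diagnosis: (
        "BONE", "MARROW", "NEGATIVE", "INVOLVEMENT", "ACUTE", "CHRONIC",
        "LEUKEMIA", "MYELODYSPLASTIC", "SYNDROME", "NORMOCELLULAR",
        "HYPERCELLULAR", "HYPOCELLULAR", "REMISSION", "NEOPLASM",
        "RESIDUAL", "INVOLVED",
    ),
    SectionLabel.disclaimer: (
        "electronically", "verified", "signature", "pathologist", "report",
        "laboratory", "accredited", "amendments", "addenda", "testing",
        "performed", "validated", "purposes", "document", "responsibility",
        "issued",
    ),
}

CD_MARKERS: tuple[int, ...] = (3, 5, 10, 13, 19, 20, 33, 34, 38, 45, 56, 61, 117, 138)

#: Sections every report must contain; the rest may be dropped.
MANDATORY_SECTIONS: frozenset[SectionLabel] = frozenset(
    {
        SectionLabel.specimen_received,
        SectionLabel.bone_marrow_aspirate,
        SectionLabel.diagnosis,
    }
)


@dataclass(frozen=True)
class SectionProfile:
    """Structural recipe for generating one section's text."""

    label: SectionLabel
    vocabulary: tuple[str, ...]
    paragraphs: tuple[int, int]  # inclusive count range
    words_per_paragraph: tuple[int, int]  # inclusive count range
    numeric_density: float  # expected number tokens per paragraph
    cd_density: float = 0.0  # expected CD mentions per paragraph
    emits_accession: bool = False

    def __post_init__(self) -> None:
        if self.paragraphs[0] < 1 or self.paragraphs[0] > self.paragraphs[1]:
            raise ValueError("invalid paragraph count range")
        if (
            self.words_per_paragraph[0] < 1
            or self.words_per_paragraph[0] > self.words_per_paragraph[1]
        ):
            raise ValueError("invalid words-per-paragraph range")
        if self.numeric_density < 0 or self.cd_density < 0:
            raise ValueError("densities must be >= 0")


def default_profiles() -> dict[SectionLabel, SectionProfile]:
    """The default structural recipes, one per section."""
    spec = {
        SectionLabel.specimen_received: dict(
            paragraphs=(1, 2), words_per_paragraph=(6, 14),
            numeric_density=0.6, emits_accession=True,
        ),
        SectionLabel.clinical_information: dict(
            paragraphs=(1, 2), words_per_paragraph=(8, 18), numeric_density=0.3,
        ),
        SectionLabel.peripheral_blood_smear: dict(
            paragraphs=(1, 3), words_per_paragraph=(8, 16), numeric_density=2.5,
        ),
        SectionLabel.bone_marrow_aspirate: dict(
            paragraphs=(1, 3), words_per_paragraph=(8, 18),
            numeric_density=0.8, cd_density=0.8,
        ),
        SectionLabel.bone_marrow_aspirate_differential: dict(
            paragraphs=(2, 4), words_per_paragraph=(3, 7), numeric_density=4.0,
        ),
        SectionLabel.iron_content: dict(
            paragraphs=(1, 1), words_per_paragraph=(3, 7), numeric_density=0.4,
        ),
        SectionLabel.bone_marrow_biopsy: dict(
            paragraphs=(1, 3), words_per_paragraph=(8, 18),
            numeric_density=0.6, cd_density=1.2,
        ),
        SectionLabel.comment: dict(
            paragraphs=(1, 3), words_per_paragraph=(8, 18),
            numeric_density=0.5, cd_density=0.4,
        ),
        SectionLabel.diagnosis: dict(
            paragraphs=(1, 2), words_per_paragraph=(4, 10), numeric_density=0.2,
        ),
        SectionLabel.disclaimer: dict(
            paragraphs=(1, 2), words_per_paragraph=(10, 20), numeric_density=0.1,
        ),
    }
    return {
        label: SectionProfile(label=label, vocabulary=SECTION_WORDS[label], **kw)
        for label, kw in spec.items()
    }


def equalized_profiles() -> dict[SectionLabel, SectionProfile]:
    """Structurally identical profiles: the no-signal control condition."""
    return {
        label: SectionProfile(
            label=label,
            vocabulary=SECTION_WORDS[label],
            paragraphs=(1, 2),
            words_per_paragraph=(6, 12),
            numeric_density=1.0,
            cd_density=0.5,
            emits_accession=False,
        )
        for label in SectionLabel
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic corpus.

    Defaults: 500 reports, a 0.3 probability of drawing any content word
    from the shared pool rather than the section pool, and a 0.1
    probability of dropping each non-mandatory section from a report.
    """

    n_reports: int = 500
    seed: int = 7
    shared_vocab_overlap: float = 0.3
    section_dropout: float = 0.1
    equalize_structure: bool = False
    date_mode: bool = False  # ISO date chronology keys instead of integers

    def __post_init__(self) -> None:
        if self.n_reports < 0:
            raise ValueError("n_reports must be >= 0")
        if not 0.0 <= self.shared_vocab_overlap <= 1.0:
            raise ValueError("shared_vocab_overlap must be in [0, 1]")
        if not 0.0 <= self.section_dropout < 1.0:
            raise ValueError("section_dropout must be in [0, 1)")


def no_signal_config(**overrides) -> GeneratorConfig:
    """Config with all section signal removed (overlap 1.0, equal structure)."""
    overrides.setdefault("shared_vocab_overlap", 1.0)
    overrides.setdefault("equalize_structure", True)
    return GeneratorConfig(**overrides)


def _accession_id(rng: np.random.Generator) -> str:
    letter = rng.choice(list("SHB"))
    year = int(rng.integers(21, 24))
    serial = int(rng.integers(0, 100000))
    return f"{letter}{year:02d}-{serial:05d}"


def _number_literal(rng: np.random.Generator) -> str:
    if rng.random() < 0.5:
        value = f"{int(rng.integers(0, 101))}"
    else:
        value = f"{rng.uniform(0.0, 100.0):.1f}"
    if rng.random() < 0.3:
        value += "%"
    return value


def _section_text(
    profile: SectionProfile,
    rng: np.random.Generator,
    overlap: float,
) -> str:
    paragraphs = []
    n_par = int(rng.integers(profile.paragraphs[0], profile.paragraphs[1] + 1))
    for _ in range(n_par):
        wpp = int(
            rng.integers(
                profile.words_per_paragraph[0], profile.words_per_paragraph[1] + 1
            )
        )
        words = [
            str(rng.choice(SHARED_WORDS))
            if rng.random() < overlap
            else str(rng.choice(profile.vocabulary))
            for _ in range(wpp)
        ]
        for _ in range(rng.poisson(profile.numeric_density)):
            pos = int(rng.integers(0, len(words) + 1))
            words.insert(pos, _number_literal(rng))
        for _ in range(rng.poisson(profile.cd_density)):
            pos = int(rng.integers(0, len(words) + 1))
            words.insert(pos, f"CD{rng.choice(CD_MARKERS)}")
        paragraphs.append(" ".join(words))
    return "\n\n".join(paragraphs)


def generate_corpus(
    config: GeneratorConfig = GeneratorConfig(),
    profiles: Mapping[SectionLabel, SectionProfile] | None = None,
) -> Corpus:
    """Generate a labeled corpus under the configured conditions.

    Reports carry strictly increasing chronology keys; sections appear in
    canonical order; the specimen-received section contains an accession
    identifier matching the default accession pattern. Deterministic for a
    fixed seed.
    """
    if profiles is None:
        profiles = (
            equalized_profiles() if config.equalize_structure else default_profiles()
        )
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    reports: list[Report] = []
    for i in range(config.n_reports):
        report_id = f"BM-{i:05d}"
        blocks: list[TextBlock] = []
        for label in SectionLabel:
            if (
                label not in MANDATORY_SECTIONS
                and rng.random() < config.section_dropout
            ):
                continue
            profile = profiles[label]
            text = _section_text(profile, rng, config.shared_vocab_overlap)
            if profile.emits_accession:
                text = f"specimen {_accession_id(rng)} received\n\n" + text
            blocks.append(
                TextBlock(
                    report_id=report_id,
                    block_index=len(blocks),
                    text=text,
                    true_section=label,
                )
            )
        key: object
        if config.date_mode:
            day = np.datetime64("2021-06-01") + np.timedelta64(i, "D")
            key = str(day)
        else:
            key = i
        reports.append(Report(report_id=report_id, chronology_key=key, blocks=blocks))
    return Corpus(reports)


def config_to_dict(config: GeneratorConfig) -> dict:
    return dataclasses.asdict(config)
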