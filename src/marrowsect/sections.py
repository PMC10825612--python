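"""Domain types for sectioned bone marrow reports.

A bone marrow report is a sequence of named sections (specimen received,
clinical information, ... disclaimer) in a canonical institutional order.
Splitting a report on its section headers yields one :class:`TextBlock` per
section; the block keeps its position in the report and, when known, the
ground-truth section it came from.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Any, Iterator


class SectionLabel(str, enum.Enum):
    """The ten canonical bone marrow report sections, in report order."""

    specimen_received = "specimen_received"
    clinical_information = "clinical_information"
    peripheral_blood_smear = "peripheral_blood_smear"
    bone_marrow_aspirate = "bone_marrow_aspirate"
    bone_marrow_aspirate_differential = "bone_marrow_aspirate_differential"
    iron_content = "iron_content"
    bone_marrow_biopsy = "bone_marrow_biopsy"
    comment = "comment"
    diagnosis = "diagnosis"
    disclaimer = "disclaimer"

    @property
    def canonical_index(self) -> int:
        """Position of this section in the canonical report order (0-9)."""
        return _CANONICAL_ORDER[self]


_CANONICAL_ORDER: dict[SectionLabel, int] = {
    label: i for i, label in enumerate(SectionLabel)
}


@dataclass
class TextBlock:
    """One header-stripped section of a report.

    Parameters
    ----------
    report_id : str
        Identifier of the parent report.
    block_index : int
        0-based position of the block within its report.
    text : str
        Free text of the section with the header line removed.
    true_section : SectionLabel, optional
        Ground-truth section, when known (training / evaluation data).
    """

    report_id: str
    block_index: int
    text: str
    true_section: SectionLabel | None = None

    def __post_init__(self) -> None:
        if self.block_index < 0:
            raise ValueError("block_index must be >= 0")


@dataclass
class Report:
    """An ordered collection of text blocks from one report."""

    report_id: str
    chronology_key: Any
    blocks: list[TextBlock] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError(f"report {self.report_id!r} has no blocks")
        for i, block in enumerate(self.blocks):
            if block.block_index != i:
                raise ValueError(
                    f"report {self.report_id!r}: block_index not contiguous from 0"
                )

    def __len__(self) -> int:
        return len(self.blocks)


@dataclass
class Corpus:
    """An ordered collection of reports with unique identifiers."""

    reports: list[Report] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.report_id for r in self.reports]
        if len(set(ids)) != len(ids):
            raise ValueError("report_ids are not unique")

    def __len__(self) -> int:
        return len(self.reports)

    def iter_blocks(self) -> Iterator[tuple[Report, TextBlock]]:
        """Yield ``(report, block)`` pairs in report, then block, order."""
        for report in self.reports:
            for block in report.blocks:
                yield report, block

    @property
    def blocks(self) -> list[TextBlock]:
        return [b for _, b in self.iter_blocks()]

    @property
    def n_blocks(self) -> int:
        return sum(len(r) for r in self.reports)
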