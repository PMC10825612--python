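"""Reading, splitting and writing sectioned reports.

Reports arrive as free text in which each section starts with a header line
("Clinical Information:", "Iron Content", ...). :func:`split_into_blocks`
cuts a report at those header lines, strips the headers, and labels each
block with the section its header names. :func:`chronological_split`
performs the train/test partition on report chronology so that a model
trained on older reports is evaluated on newer ones.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Iterable, Mapping

from .sections import Corpus, Report, SectionLabel, TextBlock

logger = logging.getLogger(__name__)

#: Default header spelling for each section. Institutions differ; pass your
#: own mapping (including any local variants) to the readers if needed.
DEFAULT_HEADERS: dict[str, SectionLabel] = {
    "Specimen Received": SectionLabel.specimen_received,
    "Clinical Information": SectionLabel.clinical_information,
    "Peripheral Blood Smear": SectionLabel.peripheral_blood_smear,
    "Bone Marrow Aspirate": SectionLabel.bone_marrow_aspirate,
    "Bone Marrow Aspirate Differential": SectionLabel.bone_marrow_aspirate_differential,
    "Iron Content": SectionLabel.iron_content,
    "Bone Marrow Biopsy": SectionLabel.bone_marrow_biopsy,
    "Comment": SectionLabel.comment,
    "Diagnosis": SectionLabel.diagnosis,
    "Disclaimer": SectionLabel.disclaimer,
}

#: Canonical header string for each label (first spelling wins).
DEFAULT_HEADER_BY_LABEL: dict[SectionLabel, str] = {}
for _header, _label in DEFAULT_HEADERS.items():
    DEFAULT_HEADER_BY_LABEL.setdefault(_label, _header)


def _match_header(line: str, headers: Mapping[str, SectionLabel]) -> SectionLabel | None:
    """Return the section a line names, or None.

    A header matches only when the whole line (ignoring surrounding
    whitespace) equals the header string, optionally with a trailing colon.
    Full-line matching is what keeps "Bone Marrow Aspirate" from swallowing
    "Bone Marrow Aspirate Differential". Matching is case-sensitive.
    """
    stripped = line.strip()
    if stripped.endswith(":"):
        stripped = stripped[:-1].rstrip()
    return headers.get(stripped)


def split_into_blocks(
    report_text: str,
    headers: Mapping[str, SectionLabel] | None = None,
    *,
    report_id: str = "<unknown>",
) -> list[TextBlock]:
    """Split a report into header-delimited, header-stripped text blocks.

    Parameters
    ----------
    report_text : str
        The full free text of one report, headers included.
    headers : mapping of header string to SectionLabel, optional
        Recognized header spellings. Defaults to :data:`DEFAULT_HEADERS`.
    report_id : str
        Used to label the resulting blocks and error messages.

    Returns
    -------
    list of TextBlock
        One block per matched header, in order of appearance, with
        ``true_section`` set from the header and surrounding whitespace
        trimmed. Sections with empty bodies are kept as empty-text blocks.

    Raises
    ------
    ValueError
        If no header matches anywhere in the text (malformed report), or the
        inputs are empty.
    """
    if not report_text:
        raise ValueError(f"report {report_id!r}: empty report text")
    if headers is None:
        headers = DEFAULT_HEADERS
    if not headers:
        raise ValueError("headers mapping is empty")

    lines = report_text.splitlines()
    hits: list[tuple[int, SectionLabel]] = []
    for lineno, line in enumerate(lines):
        label = _match_header(line, headers)
        if label is not None:
            hits.append((lineno, label))

    if not hits:
        raise ValueError(f"report {report_id!r}: no section header matched")

    if hits[0][0] > 0:
        preamble = "\n".join(lines[: hits[0][0]]).strip()
        if preamble:
            logger.warning(
                "report %r: %d chars of text before the first header dropped",
                report_id,
                len(preamble),
            )

    blocks: list[TextBlock] = []
    for i, (lineno, label) in enumerate(hits):
        end = hits[i + 1][0] if i + 1 < len(hits) else len(lines)
        body = "\n".join(lines[lineno + 1 : end]).strip()
        blocks.append(
            TextBlock(
                report_id=report_id,
                block_index=i,
                text=body,
                true_section=label,
            )
        )
    return blocks


def render_report(
    report: Report,
    header_by_label: Mapping[SectionLabel, str] | None = None,
    *,
    colon: bool = True,
) -> str:
    """Reconstruct report free text by interleaving headers with block texts.

    Inverse of :func:`split_into_blocks` up to whitespace normalization;
    blocks lacking a ``true_section`` cannot be rendered.
    """
    if header_by_label is None:
        header_by_label = DEFAULT_HEADER_BY_LABEL
    parts: list[str] = []
    for block in report.blocks:
        if block.true_section is None:
            raise ValueError(
                f"report {report.report_id!r}: block {block.block_index} has no section"
            )
        header = header_by_label[block.true_section]
        if colon:
            header += ":"
        parts.append(header + ("\n" + block.text if block.text else ""))
    return "\n\n".join(parts) + "\n"


def chronological_split(
    corpus: Corpus, train_fraction: float = 0.8
) -> tuple[Corpus, Corpus]:
    """Split a corpus into train/test subsets by report chronology.

    Reports are stably sorted ascending by ``chronology_key``; the oldest
    ``floor(n * train_fraction)`` reports form the training corpus and the
    remainder the testing corpus, so the model is always evaluated on
    reports newer than anything it was trained on.

    Raises
    ------
    ValueError
        If the corpus has fewer than 2 reports, the fraction is outside
        (0, 1), or the floor leaves either subset empty.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(corpus)
    if n < 2:
        raise ValueError("need at least 2 reports to form train and test subsets")
    ordered = sorted(corpus.reports, key=lambda r: r.chronology_key)
    n_train = math.floor(n * train_fraction)
    if n_train == 0 or n_train == n:
        raise ValueError(
            f"train_fraction {train_fraction} leaves an empty subset for {n} reports"
        )
    return Corpus(ordered[:n_train]), Corpus(ordered[n_train:])


# ---------------------------------------------------------------------------
# serialization


def write_corpus_jsonl(
    corpus: Corpus,
    path: str | Path,
    header_by_label: Mapping[SectionLabel, str] | None = None,
) -> None:
    """Write a corpus as JSONL records of rendered report text."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for report in corpus.reports:
            record = {
                "report_id": report.report_id,
                "chronology_key": report.chronology_key,
                "text": render_report(report, header_by_label),
            }
            fh.write(json.dumps(record) + "\n")


def read_corpus_jsonl(
    path: str | Path, headers: Mapping[str, SectionLabel] | None = None
) -> Corpus:
    """Read a JSONL corpus (report_id, chronology_key, text) and split it."""
    reports: list[Report] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            record = json.loads(line)
            blocks = split_into_blocks(
                record["text"], headers, report_id=record["report_id"]
            )
            reports.append(
                Report(
                    report_id=record["report_id"],
                    chronology_key=record["chronology_key"],
                    blocks=blocks,
                )
            )
    return Corpus(reports)


def read_corpus_dir(
    path: str | Path, headers: Mapping[str, SectionLabel] | None = None
) -> Corpus:
    """Read a directory of UTF-8 ``*.txt`` reports, one report per file.

    Chronology comes from a ``chronology.json`` sidecar mapping report id
    (the file stem) to a sortable key; without the sidecar, files sort by
    name and their sort rank is the key.
    """
    path = Path(path)
    files = sorted(path.glob("*.txt"))
    if not files:
        raise ValueError(f"no .txt reports found in {path}")
    sidecar = path / "chronology.json"
    keys: dict[str, object] = {}
    if sidecar.exists():
        keys = json.loads(sidecar.read_text(encoding="utf-8"))
    reports = []
    for rank, file in enumerate(files):
        report_id = file.stem
        blocks = split_into_blocks(
            file.read_text(encoding="utf-8"), headers, report_id=report_id
        )
        reports.append(
            Report(
                report_id=report_id,
                chronology_key=keys.get(report_id, rank),
                blocks=blocks,
            )
        )
    return Corpus(reports)


def write_corpus_dir(
    corpus: Corpus,
    path: str | Path,
    header_by_label: Mapping[SectionLabel, str] | None = None,
) -> None:
    """Write one ``<report_id>.txt`` per report plus a chronology sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    keys = {}
    for report in corpus.reports:
        (path / f"{report.report_id}.txt").write_text(
            render_report(report, header_by_label), encoding="utf-8"
        )
        keys[report.report_id] = report.chronology_key
    (path / "chronology.json").write_text(json.dumps(keys, indent=1), encoding="utf-8")


def write_blocks_jsonl(blocks: Iterable[TextBlock], path: str | Path) -> None:
    """Write text blocks as JSONL (report_id, block_index, section, text)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for block in blocks:
            record = {
                "report_id": block.report_id,
                "block_index": block.block_index,
                "section": block.true_section.value if block.true_section else None,
                "text": block.text,
            }
            fh.write(json.dumps(record) + "\n")
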