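"""SSSOM TSV writer for ontology-to-ontology mappings.

One row per mapping with the fixed column order subject_id, subject_label,
predicate_id, object_id, object_label, mapping_justification, confidence.
Metadata is written as a ``# key: value`` comment block.  Output is
deterministic byte-for-byte for a given row list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from ..model import Curie, OntologyError

#: semapv justifications used by this package.
JUSTIFICATION_LEXICAL = "semapv:LexicalMatching"
JUSTIFICATION_LOGICAL = "semapv:LogicalReasoning"
JUSTIFICATION_MANUAL = "semapv:ManualMappingCuration"

VALID_JUSTIFICATIONS = {
    JUSTIFICATION_LEXICAL, JUSTIFICATION_LOGICAL, JUSTIFICATION_MANUAL,
}

COLUMNS = ("subject_id", "subject_label", "predicate_id", "object_id",
           "object_label", "mapping_justification", "confidence")


@dataclass(frozen=True)
class SSSOMRow:
    """One mapping row linking an external/phenotype term to a trait term."""

    subject_id: Curie
    subject_label: str
    predicate_id: str
    object_id: Curie
    object_label: str
    mapping_justification: str
    confidence: Optional[float] = None

    def __post_init__(self):
        if self.mapping_justification not in VALID_JUSTIFICATIONS:
            raise OntologyError(
                f"invalid mapping justification "
                f"{self.mapping_justification!r}; expected one of "
                f"{sorted(VALID_JUSTIFICATIONS)}")
        if self.confidence is not None and not 0 <= self.confidence <= 1:
            raise OntologyError(
                f"confidence {self.confidence} outside [0, 1]")


def write_sssom(rows: list[SSSOMRow],
                metadata: Optional[dict[str, str]] = None) -> str:
    """Serialise mapping rows as SSSOM TSV text."""
    lines: list[str] = []
    for key in sorted(metadata or {}):
        lines.append(f"# {key}: {metadata[key]}")
    lines.append("\t".join(COLUMNS))
    for row in rows:
        confidence = "" if row.confidence is None else repr(row.confidence)
        lines.append("\t".join((
            str(row.subject_id), row.subject_label, row.predicate_id,
            str(row.object_id), row.object_label,
            row.mapping_justification, confidence)))
    return "\n".join(lines) + "\n"


def parse_sssom(text: str, prefixes: Optional[dict[str, str]] = None
                ) -> list[SSSOMRow]:
    """Read back SSSOM TSV produced by :func:`write_sssom`."""
    from ..model import parse_curie

    rows: list[SSSOMRow] = []
    header: Optional[list[str]] = None
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cells = line.split("\t")
        if header is None:
            header = cells
            if tuple(header) != COLUMNS:
                raise OntologyError(
                    f"unexpected SSSOM columns {header!r}")
            continue
        record = dict(zip(header, cells))
        rows.append(SSSOMRow(
            subject_id=parse_curie(record["subject_id"], prefixes),
            subject_label=record["subject_label"],
            predicate_id=record["predicate_id"],
            object_id=parse_curie(record["object_id"], prefixes),
            object_label=record["object_label"],
            mapping_justification=record["mapping_justification"],
            confidence=(float(record["confidence"])
                        if record["confidence"] else None),
        ))
    return rows
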