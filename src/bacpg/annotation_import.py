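"""Import of known-protein annotations (pipeline step 1).

Annotations arrive either as a delimiter-separated table whose relevant
columns the user points at (:class:`ColumnSpec`), or as a protein FASTA whose
headers are mined with user-supplied regular expressions
(:class:`HeaderPatternSpec`).  Both paths produce :class:`ProteinRecord`
objects of category ``known`` and can be rendered as an annotation GFF3.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from .sequence_io import Gff3Feature, read_fasta, split_header, write_gff3

logger = logging.getLogger("bacpg")

CATEGORIES = ("known", "pseudo", "orf-pseudo", "decoy")

_STRAND_VOCAB = {
    "+": "+", "forward": "+", "1": "+", "f": "+",
    "-": "-", "reverse": "-", "-1": "-", "r": "-",
}


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


@dataclass(frozen=True)
class RelationTag:
    """Outcome of comparing two protein sequences, carrying the partner.

    Rendered into protein descriptions exactly as "equal to X",
    "elongation by X" or "elongation of X".
    """

    kind: str  # equal_to | elongation_by | elongation_of
    partner_accession: str

    _PHRASES = {
        "equal_to": "equal to",
        "elongation_by": "elongation by",
        "elongation_of": "elongation of",
    }

    def __post_init__(self) -> None:
        if self.kind not in self._PHRASES:
            raise ValueError(f"invalid relation kind {self.kind!r}")
        if not self.partner_accession:
            raise ValueError("relation partner accession must be non-empty")

    def render(self) -> str:
        return f"{self._PHRASES[self.kind]} {self.partner_accession}"


@dataclass
class ProteinRecord:
    """A protein entry of the search database.

    Sequence and genomic coordinates may each be absent (TSV-only imports
    have no sequence until joined with a FASTA; appended host/contaminant
    proteins have no position on the bacterial genome).
    """

    accession: str
    description: str = ""
    sequence: str | None = None
    seq_id: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None
    category: str = "known"
    relations: list[RelationTag] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"invalid category {self.category!r}")
        if (self.start is None) != (self.end is None):
            raise ValueError(f"{self.accession}: start/end must be given together")
        if self.start is not None:
            if self.start < 1:
                raise ValueError(f"{self.accession}: start must be >= 1")
            if self.end - self.start + 1 < 3:
                raise ValueError(f"{self.accession}: interval shorter than one codon")
        if self.strand is not None and self.strand not in {"+", "-"}:
            raise ValueError(f"{self.accession}: invalid strand {self.strand!r}")

    @property
    def has_coordinates(self) -> bool:
        return self.start is not None and self.strand is not None

    def add_relation(self, tag: RelationTag) -> None:
        """Attach a relation tag and append its phrase to the description."""
        self.relations.append(tag)
        phrase = tag.render()
        self.description = f"{self.description} {phrase}".strip()

    def full_description(self) -> str:
        return self.description


@dataclass(frozen=True)
class ColumnSpec:
    """0-based column indices for the separated-values annotation format.

    ``strand`` may be None, in which case orientation is inferred from the
    coordinate order (start > end means reverse strand).
    """

    accession: int
    start: int
    end: int
    strand: int | None = None
    description: int | None = None
    seq_id: int | None = None
    delimiter: str = "\t"
    header_rows: int = 0

    def __post_init__(self) -> None:
        required = [self.accession, self.start, self.end]
        if self.strand is not None:
            required.append(self.strand)
        if any(i < 0 for i in required):
            raise ValueError("column indices must be >= 0")
        if len(set(required)) != len(required):
            raise ValueError("column indices must be distinct")
        if self.header_rows < 0:
            raise ValueError("header_rows must be >= 0")


@dataclass(frozen=True)
class HeaderPatternSpec:
    """One regular expression with a single capturing group per field.

    Only ``accession`` is mandatory; records whose header defeats any
    supplied pattern are collected in the skip report rather than aborting
    the import.
    """

    accession: str
    start: str | None = None
    end: str | None = None
    strand: str | None = None
    description: str | None = None
    seq_id: str | None = None

    def __post_init__(self) -> None:
        for name in ("accession", "start", "end", "strand", "description", "seq_id"):
            pattern = getattr(self, name)
            if pattern is None:
                continue
            if re.compile(pattern).groups != 1:
                raise ValueError(
                    f"pattern for {name!r} must contain exactly one capturing group"
                )

    def fields(self) -> dict[str, re.Pattern]:
        return {
            name: re.compile(pattern)
            for name in ("accession", "start", "end", "strand", "description", "seq_id")
            if (pattern := getattr(self, name)) is not None
        }


def parse_strand(text: str) -> str:
    """Normalise strand vocabulary {+,-,forward,reverse,1,-1,F,R} to +/-."""
    try:
        return _STRAND_VOCAB[text.strip().lower()]
    except KeyError:
        raise AnnotationError(f"unrecognised strand value {text!r}") from None


def parse_annotation_tsv(path: str | Path, spec: ColumnSpec) -> list[ProteinRecord]:
    """Parse a separated-values annotation into known ProteinRecords.

    One record per data row; sequences stay absent until joined with the
    known-protein FASTA.  Unparsable coordinates or duplicate accessions
    raise :class:`AnnotationError` naming the offending line.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    max_required = max(
        i for i in (spec.accession, spec.start, spec.end, spec.strand) if i is not None
    )
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter=spec.delimiter)
        for line_no, row in enumerate(reader, start=1):
            if line_no <= spec.header_rows or not row or not "".join(row).strip():
                continue
            if len(row) <= max_required:
                raise AnnotationError(
                    f"{path}: line {line_no}: expected at least {max_required + 1} "
                    f"fields, got {len(row)}"
                )
            accession = row[spec.accession].strip()
            if not accession:
                raise AnnotationError(f"{path}: line {line_no}: empty accession")
            if accession in seen:
                raise AnnotationError(
                    f"{path}: line {line_no}: duplicate accession {accession!r}"
                )
            coords = {}
            for name, col in (("start", spec.start), ("end", spec.end)):
                try:
                    coords[name] = int(row[col].strip())
                except ValueError:
                    raise AnnotationError(
                        f"{path}: line {line_no}, column {col}: "
                        f"unparsable integer {row[col]!r} for {name}"
                    ) from None
            start, end = coords["start"], coords["end"]
            if spec.strand is not None:
                try:
                    strand = parse_strand(row[spec.strand])
                except AnnotationError as exc:
                    raise AnnotationError(f"{path}: line {line_no}: {exc}") from None
                if start > end:
                    raise AnnotationError(
                        f"{path}: line {line_no}: start {start} > end {end} "
                        "with an explicit strand column"
                    )
            elif start > end:
                start, end, strand = end, start, "-"
            else:
                strand = "+"
            description = (
                row[spec.description].strip()
                if spec.description is not None and spec.description < len(row)
                else ""
            )
            seq_id = (
                row[spec.seq_id].strip()
                if spec.seq_id is not None and spec.seq_id < len(row)
                else None
            )
            seen.add(accession)
            records.append(
                ProteinRecord(
                    accession=accession,
                    description=description,
                    seq_id=seq_id or None,
                    start=start,
                    end=end,
                    strand=strand,
                    category="known",
                )
            )
    return records


@dataclass
class FastaImportResult:
    records: list[ProteinRecord]
    skipped: list[tuple[str, str]]  # (header, reason)


def parse_annotation_fasta(
    path: str | Path, spec: HeaderPatternSpec
) -> FastaImportResult:
    """Mine protein-FASTA headers with capture patterns into ProteinRecords.

    A header on which any supplied pattern fails sends that record to the
    skip report instead of raising; the parsed records plus the skip report
    partition the input.
    """
    result = FastaImportResult(records=[], skipped=[])
    patterns = spec.fields()
    seen: set[str] = set()
    for header, residues in read_fasta(path):
        captured: dict[str, str] = {}
        failed = None
        for name, pattern in patterns.items():
            match = pattern.search(header)
            if match is None:
                failed = name
                break
            captured[name] = match.group(1)
        if failed is not None:
            result.skipped.append((header, f"pattern for {failed!r} did not match"))
            continue
        accession = captured["accession"]
        if accession in seen:
            result.skipped.append((header, f"duplicate accession {accession!r}"))
            continue
        try:
            start = int(captured["start"]) if "start" in captured else None
            end = int(captured["end"]) if "end" in captured else None
        except ValueError:
            result.skipped.append((header, "non-integer coordinate capture"))
            continue
        try:
            strand = parse_strand(captured["strand"]) if "strand" in captured else None
            record = ProteinRecord(
                accession=accession,
                description=captured.get("description", ""),
                sequence=residues,
                seq_id=captured.get("seq_id"),
                start=start,
                end=end,
                strand=strand,
                category="known",
            )
        except (AnnotationError, ValueError) as exc:
            result.skipped.append((header, str(exc)))
            continue
        seen.add(accession)
        result.records.append(record)
    if result.skipped:
        logger.warning(
            "annotation FASTA import skipped %d of %d records",
            len(result.skipped),
            len(result.skipped) + len(result.records),
        )
    return result


def join_sequences(
    records: list[ProteinRecord], fasta_path: str | Path
) -> list[str]:
    """Attach sequences from the known-protein FASTA by exact accession match.

    Returns the accessions that found no sequence (matching is exact; the
    FASTA is expected to use the same accessions as the annotation).
    """
    by_accession = {
        split_header(header)[0]: residues for header, residues in read_fasta(fasta_path)
    }
    missing = []
    for record in records:
        seq = by_accession.get(record.accession)
        if seq is None:
            missing.append(record.accession)
        else:
            record.sequence = seq
    if missing:
        logger.warning("%d annotation records found no FASTA sequence", len(missing))
    return missing


_RELATION_RE = re.compile(
    r"\b(equal to|elongation by|elongation of)\s+(\S+)"
)
_PHRASE_TO_KIND = {
    "equal to": "equal_to",
    "elongation by": "elongation_by",
    "elongation of": "elongation_of",
}


def parse_relation_phrases(description: str) -> list[RelationTag]:
    """Recover relation tags from the phrases stored in a description.

    Inverse of :meth:`RelationTag.render`, used when a protein database is
    reloaded from FASTA where relations survive only as description text.
    """
    return [
        RelationTag(kind=_PHRASE_TO_KIND[phrase], partner_accession=partner)
        for phrase, partner in _RELATION_RE.findall(description)
    ]


def protein_index(records: list[ProteinRecord]) -> dict[str, ProteinRecord]:
    """Index records by accession, enforcing uniqueness."""
    index: dict[str, ProteinRecord] = {}
    for record in records:
        if record.accession in index:
            raise AnnotationError(f"duplicate accession {record.accession!r}")
        index[record.accession] = record
    return index


def annotation_features(records: list[ProteinRecord]) -> list[Gff3Feature]:
    """One ``protein`` feature per record; seqid falls back to "unknown"."""
    features = []
    for record in records:
        if not record.has_coordinates:
            continue
        attributes = {"ID": record.accession}
        if record.full_description():
            attributes["Description"] = record.full_description()
        features.append(
            Gff3Feature(
                seqid=record.seq_id or "unknown",
                ftype="protein",
                start=record.start,
                end=record.end,
                strand=record.strand,
                attributes=attributes,
            )
        )
    return features


def write_annotation_gff3(records: list[ProteinRecord], path: str | Path) -> None:
    write_gff3(annotation_features(records), path)
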