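"""FASTA and GFF3 input/output plus the reverse-complement primitive.

All genomic coordinates in this package are 1-based and inclusive on the
forward strand, matching GFF3 directly; the only conversions happen at
parse/serialisation boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("bacpg")

DNA_ALPHABET = frozenset("ACGTN")

#: GFF3 ``source`` column used for every feature this package writes.
GFF3_SOURCE = "BPP"


class FastaFormatError(ValueError):
    """Raised when a file violates the FASTA format."""


class Gff3Error(ValueError):
    """Raised when a feature cannot be serialised as valid GFF3."""


@dataclass(frozen=True)
class GenomeRecord:
    """One nucleotide sequence (chromosome or plasmid).

    ``residues`` is an uppercase string over {A,C,G,T,N}; ``seq_id`` must be
    unique within a genome set.
    """

    seq_id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"genome record {self.seq_id!r} has an empty sequence")
        bad = set(self.residues) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"genome record {self.seq_id!r} contains non-DNA symbols: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Gff3Feature:
    """One 9-column GFF3 line (1-based, inclusive coordinates)."""

    seqid: str
    ftype: str
    start: int
    end: int
    strand: str = "."
    score: float | int | None = None
    phase: str = "."
    source: str = GFF3_SOURCE
    attributes: dict[str, str] = field(default_factory=dict)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(header, residues)`` pairs in file order.

    The header is the full line after ``>``; residues are uppercased with
    whitespace stripped.  A file whose first non-blank character is not ``>``
    or a header with no sequence under it is a :class:`FastaFormatError`.
    """
    path = Path(path)
    with open(path) as handle:
        first = handle.read(1)
        if first != ">":
            raise FastaFormatError(
                f"{path}: not a FASTA file (first character {first!r}, expected '>')"
            )
    records: list[tuple[str, str]] = []
    for rec in SeqIO.parse(path, "fasta"):
        residues = str(rec.seq).upper()
        if not residues:
            raise FastaFormatError(f"{path}: record {rec.id!r} has no sequence")
        records.append((rec.description, residues))
    return records


def split_header(header: str) -> tuple[str, str]:
    """Split a FASTA header into (first token, remainder)."""
    parts = header.split(None, 1)
    return parts[0], (parts[1] if len(parts) > 1 else "")


def write_fasta(
    records: Iterable[tuple[str, str, str]],
    path: str | Path,
    wrap: int = 60,
) -> None:
    """Write ``(id, description, residues)`` triples as FASTA.

    Ids must be non-empty, whitespace-free and unique (search engines require
    unique accessions); lines are wrapped at ``wrap`` residues.
    """
    seen: set[str] = set()
    seq_records = []
    for rec_id, description, residues in records:
        if not rec_id or any(c.isspace() for c in rec_id):
            raise ValueError(f"invalid FASTA id {rec_id!r}")
        if rec_id in seen:
            raise ValueError(f"duplicate FASTA id {rec_id!r}")
        seen.add(rec_id)
        # pre-compose the full title: Biopython would otherwise drop a
        # description whose first word coincides with the id
        seq_records.append(
            SeqRecord(
                Seq(residues),
                id=rec_id,
                description=f"{rec_id} {description}".strip(),
            )
        )
    with open(path, "w") as handle:
        FastaWriter(handle, wrap=wrap).write_file(seq_records)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(residues: str) -> str:
    """Reverse-complement a DNA string over {A,C,G,T,N}; N maps to N."""
    bad = set(residues) - DNA_ALPHABET
    if bad:
        raise ValueError(f"cannot reverse-complement symbols {sorted(bad)}")
    return residues.translate(_COMPLEMENT)[::-1]


# Percent-escaping per the GFF3 spec: '%' first, then the structural characters.
_GFF3_ESCAPES = [("%", "%25"), (";", "%3B"), ("=", "%3D"), (",", "%2C"), ("\t", "%09"), ("\n", "%0A")]


def _escape_attr(value: str) -> str:
    for char, repl in _GFF3_ESCAPES:
        value = value.replace(char, repl)
    return value


def _format_score(score: float | int | None) -> str:
    if score is None:
        return "."
    if isinstance(score, int):
        return str(score)
    if float(score).is_integer():
        return str(int(score))
    return f"{score:g}"


def feature_line(feature: Gff3Feature) -> str:
    """Serialise one feature as a 9-column GFF3 line (no newline)."""
    if feature.start < 1:
        raise Gff3Error(f"GFF3 start must be >= 1, got {feature.start}")
    if feature.start > feature.end:
        raise Gff3Error(f"GFF3 start {feature.start} > end {feature.end}")
    if feature.strand not in {"+", "-", "."}:
        raise Gff3Error(f"invalid strand {feature.strand!r}")
    if feature.phase not in {"0", "1", "2", "."}:
        raise Gff3Error(f"invalid phase {feature.phase!r}")
    attrs = ";".join(
        f"{_escape_attr(k)}={_escape_attr(v)}" for k, v in feature.attributes.items()
    )
    return "\t".join(
        [
            feature.seqid,
            feature.source,
            feature.ftype,
            str(feature.start),
            str(feature.end),
            _format_score(feature.score),
            feature.strand,
            feature.phase,
            attrs or ".",
        ]
    )


def write_gff3(features: Sequence[Gff3Feature], path: str | Path) -> None:
    """Write features to ``path`` with the ``##gff-version 3`` pragma."""
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for feature in features:
            handle.write(feature_line(feature) + "\n")
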