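"""Naive six-frame translation of bacterial genomes (pipeline step 3).

Each of the six reading frames is split at stop codons; every maximal
stop-free stretch becomes a "pseudo protein" (no start codon required — a new
pseudo protein begins immediately after each stop).  When a stretch contains
at least one in-frame start codon, its longest open reading frame (first
start codon to the stop) is additionally emitted as an "ORF pseudo protein"
with the start codon rendered as methionine, so that search engines can match
N-terminal peptides.

Genomes are treated as linear (no origin-spanning ORFs).  The bacterial
genetic code (translation table 11) is used: stop codons TAA/TAG/TGA and
start codons ATG, TTG, CTG, ATT, ATC, ATA, GTG.  Codons containing N
translate to X and never count as start or stop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from Bio.Data import CodonTable

from .annotation_import import ProteinRecord, RelationTag
from .sequence_io import GenomeRecord, reverse_complement

logger = logging.getLogger("bacpg")

_TABLE = CodonTable.unambiguous_dna_by_id[11]

#: Codon -> amino acid for the bacterial code, stops as '*'.
CODON_MAP: dict[str, str] = dict(_TABLE.forward_table)
CODON_MAP.update({codon: "*" for codon in _TABLE.stop_codons})

START_CODONS: frozenset[str] = frozenset(_TABLE.start_codons)
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

FRAMES = (1, 2, 3, -1, -2, -3)


def codon_to_aa(codon: str) -> str:
    """Translate one codon; any codon containing N yields X."""
    aa = CODON_MAP.get(codon)
    if aa is None:
        if "N" in codon:
            return "X"
        raise ValueError(f"invalid codon {codon!r}")
    return aa


def translate(residues: str, as_orf_start: bool = False) -> str:
    """Translate an in-frame nucleotide string under the bacterial code.

    ``as_orf_start`` renders the first codon as methionine when it is one of
    the seven start codons.  A terminal stop codon is allowed and dropped; an
    internal stop raises ValueError.
    """
    if len(residues) % 3:
        raise ValueError(f"length {len(residues)} is not a multiple of 3")
    codons = [residues[i : i + 3] for i in range(0, len(residues), 3)]
    aas = []
    for index, codon in enumerate(codons):
        aa = codon_to_aa(codon)
        if aa == "*":
            if index == len(codons) - 1:
                break
            raise ValueError(f"internal stop codon {codon} at codon {index}")
        if index == 0 and as_orf_start and codon in START_CODONS:
            aa = "M"
        aas.append(aa)
    return "".join(aas)


@dataclass(frozen=True)
class FrameSegment:
    """One maximal stop-free stretch of a reading frame.

    ``start``/``end`` are 1-based, inclusive, forward-strand genomic
    coordinates of the translated codons (the stop codon is excluded), so
    ``end - start + 1 == 3 * len(aa_sequence)`` on either strand.
    """

    frame: int  # one of +1,+2,+3,-1,-2,-3
    aa_sequence: str
    start: int
    end: int
    has_terminal_stop: bool

    @property
    def strand(self) -> str:
        return "+" if self.frame > 0 else "-"

    @property
    def stop_inclusive_interval(self) -> tuple[int, int]:
        """The interval extended over the terminal stop codon, if present."""
        if not self.has_terminal_stop:
            return (self.start, self.end)
        if self.frame > 0:
            return (self.start, self.end + 3)
        return (self.start - 3, self.end)


def _frame_codons(genome: GenomeRecord, frame: int) -> tuple[list[str], list[tuple[int, int]]]:
    """Codons of one frame in translation order with forward-strand intervals."""
    length = len(genome.residues)
    offset = abs(frame) - 1
    if frame > 0:
        residues = genome.residues
    else:
        residues = reverse_complement(genome.residues)
    n_codons = (length - offset) // 3
    codons = [residues[offset + 3 * i : offset + 3 * i + 3] for i in range(n_codons)]
    if frame > 0:
        intervals = [(offset + 3 * i + 1, offset + 3 * i + 3) for i in range(n_codons)]
    else:
        # position p in the reverse-complement maps to forward position L-p+1
        intervals = [
            (length - offset - 3 * i - 2, length - offset - 3 * i) for i in range(n_codons)
        ]
    return codons, intervals


def enumerate_pseudo_proteins(genome: GenomeRecord) -> list[FrameSegment]:
    """Split all six frames at stop codons into pseudo-protein segments.

    Trailing nucleotides that do not fill a codon are ignored; a trailing
    stop-free stretch at the end of a frame is emitted with
    ``has_terminal_stop=False``; zero-codon stretches (consecutive stops) are
    dropped.
    """
    segments: list[FrameSegment] = []
    for frame in FRAMES:
        codons, intervals = _frame_codons(genome, frame)
        run_start: int | None = None
        for index, codon in enumerate(codons + ["TAA"]):  # sentinel stop flushes
            at_end = index == len(codons)
            if not at_end and codon_to_aa(codon) != "*":
                if run_start is None:
                    run_start = index
                continue
            if run_start is not None:
                run = range(run_start, index)
                aa = "".join(codon_to_aa(codons[i]) for i in run)
                covered = intervals[run_start], intervals[index - 1]
                start = min(covered[0][0], covered[1][0])
                end = max(covered[0][1], covered[1][1])
                segments.append(
                    FrameSegment(
                        frame=frame,
                        aa_sequence=aa,
                        start=start,
                        end=end,
                        has_terminal_stop=not at_end,
                    )
                )
                run_start = None
    return segments


def _segment_codons(segment: FrameSegment, genome: GenomeRecord) -> list[str]:
    slice_ = genome.residues[segment.start - 1 : segment.end]
    if segment.frame < 0:
        slice_ = reverse_complement(slice_)
    return [slice_[i : i + 3] for i in range(0, len(slice_), 3)]


def extract_orf_pseudo(
    segment: FrameSegment, genome: GenomeRecord, emit_duplicate: bool = False
) -> FrameSegment | None:
    """Longest ORF inside a segment: first in-frame start codon to the stop.

    Returns None when the segment holds no start codon, and — unless
    ``emit_duplicate`` — also when the first start codon is the segment's
    first codon (the ORF would duplicate the pseudo protein up to the
    leading methionine).
    """
    codons = _segment_codons(segment, genome)
    first_start = next(
        (i for i, codon in enumerate(codons) if codon in START_CODONS), None
    )
    if first_start is None:
        return None
    if first_start == 0 and not emit_duplicate:
        return None
    aa = "M" + "".join(codon_to_aa(c) for c in codons[first_start + 1 :])
    if segment.frame > 0:
        start, end = segment.start + 3 * first_start, segment.end
    else:
        start, end = segment.start, segment.end - 3 * first_start
    return replace(segment, aa_sequence=aa, start=start, end=end)


def _known_site_variants(record: ProteinRecord) -> list[tuple[int, int]]:
    """A known gene's coding interval under both stop conventions.

    Annotation sources differ on whether gene coordinates include the stop
    codon; pseudo-protein intervals always exclude it, so the annotated
    interval is offered both verbatim and with the stop codon trimmed.
    """
    variants = [(record.start, record.end)]
    if record.end - record.start + 1 >= 6:
        if record.strand == "+":
            variants.append((record.start, record.end - 3))
        else:
            variants.append((record.start + 3, record.end))
    return variants


def build_pseudo_database(
    genomes: list[GenomeRecord],
    known: list[ProteinRecord] | None = None,
    min_aa: int = 1,
    emit_duplicate_orfs: bool = False,
) -> list[ProteinRecord]:
    """Build the pseudo-protein database for one or more sequences.

    Every frame segment and every ORF becomes a ProteinRecord with a
    deterministic accession ``{seqid}_F{frame}_p{index}`` (ORFs suffixed
    ``_orf``).  Entries translating from exactly the same genomic site as a
    known protein — under either stop convention — are dropped; entries
    strictly containing a known protein's interval on the same strand and
    frame are tagged "elongation of <accession>".
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    known_by_seq: dict[str, list[ProteinRecord]] = {}
    for record in known or []:
        if not (record.has_coordinates and record.seq_id):
            continue
        known_by_seq.setdefault(record.seq_id, []).append(record)

    records: list[ProteinRecord] = []
    dropped = 0
    for genome in genomes:
        sites = known_by_seq.get(genome.seq_id, [])
        counters = {frame: 0 for frame in FRAMES}
        for segment in enumerate_pseudo_proteins(genome):
            counters[segment.frame] += 1
            accession = (
                f"{genome.seq_id}_F{segment.frame:+d}_p{counters[segment.frame]:06d}"
            )
            orf = extract_orf_pseudo(segment, genome, emit_duplicate=emit_duplicate_orfs)
            for frag, category, acc in (
                (segment, "pseudo", accession),
                (orf, "orf-pseudo", accession + "_orf"),
            ):
                if frag is None or len(frag.aa_sequence) < min_aa:
                    continue
                match, elongated = _match_known(frag, sites)
                if match is not None:
                    dropped += 1
                    continue
                record = ProteinRecord(
                    accession=acc,
                    sequence=frag.aa_sequence,
                    seq_id=genome.seq_id,
                    start=frag.start,
                    end=frag.end,
                    strand=frag.strand,
                    category=category,
                )
                for partner in elongated:
                    record.add_relation(
                        RelationTag(kind="elongation_of", partner_accession=partner)
                    )
                records.append(record)
    if dropped:
        logger.info("same-site deduplication dropped %d entries", dropped)
    return records


def _match_known(
    frag: FrameSegment, sites: list[ProteinRecord]
) -> tuple[ProteinRecord | None, list[str]]:
    """Same-site match (→ drop) and strict-containment partners (→ tag)."""
    elongated: list[str] = []
    for site in sites:
        if site.strand != frag.strand:
            continue
        for v_start, v_end in _known_site_variants(site):
            if (frag.start, frag.end) == (v_start, v_end):
                return site, []
            same_frame = (
                frag.start % 3 == v_start % 3
                if frag.strand == "+"
                else frag.end % 3 == v_end % 3
            )
            if (
                same_frame
                and frag.start <= v_start
                and frag.end >= v_end
                and (frag.end - frag.start) > (v_end - v_start)
            ):
                elongated.append(site.accession)
                break
    return None, elongated


def pseudo_database_features(records: list[ProteinRecord]):
    """GFF3 features for a pseudo-protein database."""
    from .sequence_io import Gff3Feature

    features = []
    for record in records:
        attributes = {"ID": record.accession, "category": record.category}
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
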