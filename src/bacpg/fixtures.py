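"""Synthetic, fully self-contained test inputs.

Generates bacterial-genome fixtures with planted genes (reverse-translated
ORFs with ATG start and TAA stop), matching annotation TSV / known-protein
FASTA, and mzTab identification files with a controlled per-file
distinct-spectrum count matrix.  Everything is deterministic under its seed.

The intergenic background is uniform over A,C,G,T with a stop cassette
salted in every ~120 nt.  The cassette ``TAATTAATTAATTAA`` contains a stop
codon in every forward frame offset (TAA at 0, 4, 8) and in every reverse
frame offset (its reverse complement holds TAA at 1, 5, 9), so wherever it
lands it terminates all six reading frames; pseudo proteins arising from
background are therefore short (bounded by ~50 codons).  A planted gene is
preceded, in its own reading order, by a forced in-frame stop, so its frame
segment starts exactly at the annotated start: a gene planted with no
upstream extension is recovered by same-site deduplication, while a gene
planted with ``elongation_aa`` extra coding residues upstream of the
annotated start yields a surviving pseudo protein tagged as an elongation
(its ORF, starting at the annotated ATG, is same-site-dropped instead).

Reverse translation uses the lexicographically first codon per residue to
keep fixtures human-checkable; extension residues exclude M and I, whose
first codons (ATG, ATA) are start codons and would shift the ORF.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .annotation_import import ProteinRecord
from .sequence_io import GenomeRecord, reverse_complement, write_fasta
from .six_frame import CODON_MAP

#: Stops all six frames wherever it is placed (see module docstring).
STOP_CASSETTE = "TAATTAATTAATTAA"

_BACKGROUND_CHUNK = 105  # random nt between cassettes; 105+15 = 40 codons max

#: Lexicographically first codon per amino acid (bacterial code).
FIRST_CODON: dict[str, str] = {}
for _codon in sorted(CODON_MAP):
    _aa = CODON_MAP[_codon]
    if _aa != "*" and _aa not in FIRST_CODON:
        FIRST_CODON[_aa] = _codon

#: Residues safe for upstream extensions (their codons are never start codons).
EXTENSION_ALPHABET = "".join(
    sorted(aa for aa, codon in FIRST_CODON.items() if aa not in "MI")
)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def reverse_translate(protein: str) -> str:
    """DNA for a protein using the first codon per residue (no stop added)."""
    return "".join(FIRST_CODON[aa] for aa in protein)


@dataclass(frozen=True)
class PlantedGene:
    """One gene to plant: length in residues (incl. the leading M), strand,
    and the number of stop-free coding residues upstream of the annotated
    start (0 = the annotation covers the whole frame segment)."""

    aa_length: int
    strand: str
    elongation_aa: int = 0

    def __post_init__(self) -> None:
        if self.aa_length < 2:
            raise ValueError("planted genes need at least 2 residues")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.elongation_aa < 0:
            raise ValueError("elongation_aa must be >= 0")


@dataclass
class GenomeFixture:
    """A synthetic genome plus its planted known-protein annotation."""

    genome: GenomeRecord
    proteins: list[ProteinRecord]
    #: per planted gene: the stop-free coding residues upstream of the
    #: annotated start (empty string when elongation_aa is 0)
    extensions: dict[str, str] = field(default_factory=dict)

    def write(self, directory: str | Path) -> dict[str, Path]:
        """Write genome FASTA, annotation TSV and known-protein FASTA."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": directory / "genome.fasta",
            "annotation": directory / "annotation.tsv",
            "proteins": directory / "proteins.fasta",
        }
        write_fasta(
            [(self.genome.seq_id, self.genome.description, self.genome.residues)],
            paths["genome"],
        )
        with open(paths["annotation"], "w") as handle:
            for record in self.proteins:
                handle.write(
                    "\t".join(
                        [
                            record.accession,
                            str(record.start),
                            str(record.end),
                            record.strand,
                            record.description or "planted gene",
                            record.seq_id,
                        ]
                    )
                    + "\n"
                )
        write_fasta(
            [
                (record.accession, record.description, record.sequence)
                for record in self.proteins
            ],
            paths["proteins"],
        )
        return paths


def _background(rng: random.Random, length: int) -> str:
    """Random intergenic DNA with the stop cassette salted in."""
    pieces: list[str] = []
    remaining = length
    while remaining > 0:
        chunk = min(_BACKGROUND_CHUNK, remaining)
        pieces.append("".join(rng.choice("ACGT") for _ in range(chunk)))
        remaining -= chunk
        if remaining >= len(STOP_CASSETTE):
            pieces.append(STOP_CASSETTE)
            remaining -= len(STOP_CASSETTE)
    return "".join(pieces)


def _planted_block(
    rng: random.Random, gene: PlantedGene
) -> tuple[str, str, str, int]:
    """Build one planted block in forward-strand orientation.

    Returns (block_nt, protein_seq, extension_aas, gene_offset) where
    gene_offset is the 0-based offset of the annotated gene's first base
    (its length is 3*aa_length + 3, stop codon included) within the block.
    """
    protein = "M" + "".join(
        rng.choice(AA_ALPHABET) for _ in range(gene.aa_length - 1)
    )
    extension = "".join(
        rng.choice(EXTENSION_ALPHABET) for _ in range(gene.elongation_aa)
    )
    gene_nt = reverse_translate(protein) + "TAA"
    # reading-frame layout: [forced stop][extension][gene incl. stop]
    reading = "TAA" + reverse_translate(extension) + gene_nt
    if gene.strand == "+":
        return reading, protein, extension, 3 + 3 * len(extension)
    return reverse_complement(reading), protein, extension, 0


def generate_genome(
    seed: int,
    length: int,
    planted_genes: list[PlantedGene | tuple],
    seq_id: str = "chr",
) -> GenomeFixture:
    """Generate a genome of ``length`` nt with the given planted genes.

    Genes are placed left to right with equal intergenic background gaps;
    an error is raised when they do not fit.  Deterministic under ``seed``.
    """
    genes = [
        gene if isinstance(gene, PlantedGene) else PlantedGene(*gene)
        for gene in planted_genes
    ]
    rng = random.Random(seed)
    blocks = [_planted_block(rng, gene) for gene in genes]
    total_block_nt = sum(len(block) for block, *_ in blocks)
    n_gaps = len(genes) + 1
    if length - total_block_nt < n_gaps * len(STOP_CASSETTE):
        raise ValueError(
            f"planted genes ({total_block_nt} nt) do not fit in {length} nt"
        )
    gap = (length - total_block_nt) // n_gaps
    remainder = (length - total_block_nt) - gap * n_gaps

    pieces: list[str] = []
    proteins: list[ProteinRecord] = []
    extensions: dict[str, str] = {}
    position = 0  # 0-based running offset
    for index, (gene, (block, protein, extension, gene_offset)) in enumerate(
        zip(genes, blocks), start=1
    ):
        background = _background(rng, gap)
        pieces.append(background)
        position += len(background)
        accession = f"g{index}"
        gene_start = position + gene_offset + 1  # 1-based, stop codon included
        gene_end = gene_start + 3 * gene.aa_length + 3 - 1
        proteins.append(
            ProteinRecord(
                accession=accession,
                description=f"planted {gene.strand} gene",
                sequence=protein,
                seq_id=seq_id,
                start=gene_start,
                end=gene_end,
                strand=gene.strand,
                category="known",
            )
        )
        extensions[accession] = extension
        pieces.append(block)
        position += len(block)
    pieces.append(_background(rng, gap + remainder))
    residues = "".join(pieces)
    assert len(residues) == length
    return GenomeFixture(
        genome=GenomeRecord(seq_id=seq_id, residues=residues, description="synthetic"),
        proteins=proteins,
        extensions=extensions,
    )


_MZTAB_HEADER = [
    "sequence", "PSM_ID", "accession", "unique", "database", "database_version",
    "search_engine", "search_engine_score[1]", "modifications", "retention_time",
    "charge", "exp_mass_to_charge", "calc_mass_to_charge", "spectra_ref",
    "pre", "post", "start", "end",
]


def generate_mztab(
    plan: list[tuple[str, str, int]],
    protein_db: dict[str, ProteinRecord],
    seed: int,
    out_dir: str | Path,
    charge_duplicates: bool = False,
) -> dict[str, Path]:
    """Write one mzTab 1.0 file per planned file id.

    ``plan`` holds (peptide, file_id, n_spectra) triples; every peptide must
    be a substring of at least one protein in ``protein_db`` (its accession
    column lists all containing proteins).  Each planned spectrum gets a
    distinct spectra_ref; with ``charge_duplicates`` every first spectrum is
    emitted twice at different charges, which must not change
    distinct-spectrum counts downstream.
    """
    rng = random.Random(seed)
    by_file: dict[str, list[tuple[str, int]]] = {}
    for peptide, file_id, n_spectra in plan:
        if n_spectra < 1:
            raise ValueError(f"planned count for {peptide!r} must be >= 1")
        by_file.setdefault(file_id, []).append((peptide, n_spectra))

    accessions_of: dict[str, list[str]] = {}
    for peptide, _, _ in plan:
        if peptide not in accessions_of:
            hits = [
                acc
                for acc, record in protein_db.items()
                if record.sequence and peptide in record.sequence
            ]
            if not hits:
                raise ValueError(
                    f"planned peptide {peptide!r} occurs in no database protein"
                )
            accessions_of[peptide] = sorted(hits)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for file_id, entries in by_file.items():
        path = out_dir / f"{file_id}.mztab"
        scan = 0
        psm_id = 0
        lines = [
            "MTD\tmzTab-version\t1.0.0",
            "MTD\tmzTab-mode\tSummary",
            "MTD\tmzTab-type\tIdentification",
            f"MTD\tdescription\tsynthetic identifications for run {file_id}",
            f"MTD\tms_run[1]-location\tfile:///{file_id}.mgf",
            "MTD\tpsm_search_engine_score[1]\t[MS, MS:1002352, PSM-level FDRScore, ]",
            "PSH\t" + "\t".join(_MZTAB_HEADER),
        ]
        for peptide, n_spectra in entries:
            accession = ",".join(accessions_of[peptide])
            for spectrum_index in range(n_spectra):
                scan += 1
                ref = f"ms_run[1]:scan={scan}"
                charges = [2]
                if charge_duplicates and spectrum_index == 0:
                    charges.append(3)
                for charge in charges:
                    psm_id += 1
                    score = f"{rng.uniform(1e-4, 9e-3):.6f}"
                    lines.append(
                        "PSM\t"
                        + "\t".join(
                            [
                                peptide, str(psm_id), accession, "null", "fixture",
                                "1.0", "[MS, MS:1002048, MS-GF+, ]", score, "null",
                                "null", str(charge), "500.25", "500.25", ref,
                                "null", "null", "null", "null",
                            ]
                        )
                    )
        path.write_text("\n".join(lines) + "\n")
        paths[file_id] = path
    return paths
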