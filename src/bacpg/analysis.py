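"""Peptide-level analysis of combined identifications (pipeline step 6).

Spectral counts are normalized per identification file under the assumption
that the total amount of identifiable protein is equal per sample:

    c'_i = max_t nf_t * c_i / nf_i

where ``c_i`` is the raw distinct-spectrum count of peptide *i* in one file,
``nf_i`` the total number of counts in that file, and the quotient is scaled
by the largest file total ``max_t nf_t`` to keep values human-readable.
Peptides are classified (pseudo-only / elongation / standalone / known),
flagged as proteotypic, filtered by a minimum number of identifications,
mapped back to genomic coordinates and exported as TSV or GFF3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .annotation_import import ProteinRecord
from .id_combine import CombinedResultSet, export_peptide_gff3, is_pseudo_only

logger = logging.getLogger("bacpg")

PSEUDO_CATEGORIES = ("pseudo", "orf-pseudo")


@dataclass
class SpectralCountTable:
    """Raw and normalized peptides × files spectral counts."""

    raw: pd.DataFrame  # peptides × files, integer distinct-spectrum counts
    groups: dict[str, str]  # file_id -> condition-group label
    normalized: pd.DataFrame | None = None

    @classmethod
    def from_results(cls, results: CombinedResultSet) -> "SpectralCountTable":
        return cls(raw=results.to_matrix(), groups=dict(results.groups))

    @property
    def file_totals(self) -> pd.Series:
        return self.raw.sum(axis=0)

    @property
    def max_total(self) -> int:
        return int(self.file_totals.max())


def normalize_counts(table: SpectralCountTable) -> SpectralCountTable:
    """Fill the normalized counts: c'_i = max_t nf_t * c_i / nf_i per file.

    Files with a zero total would divide by zero and are excluded from the
    normalized matrix with a warning; raw counts are left untouched.
    """
    totals = table.file_totals
    zero_files = [fid for fid, nf in totals.items() if nf == 0]
    if zero_files:
        logger.warning(
            "excluding %d identification files with zero total counts: %s",
            len(zero_files), zero_files,
        )
    kept = [fid for fid in table.raw.columns if fid not in zero_files]
    if not kept:
        raise ValueError("no identification file has a nonzero total count")
    raw = table.raw[kept]
    nf = totals[kept]
    normalized = raw.astype(float) * (int(nf.max()) / nf)
    return SpectralCountTable(raw=table.raw, groups=table.groups, normalized=normalized)


def group_normalized(
    table: SpectralCountTable, aggregate: str = "sum"
) -> pd.DataFrame:
    """Per-group normalized counts: sum (default) or mean of per-file values."""
    if table.normalized is None:
        raise ValueError("normalize_counts has not been applied")
    if aggregate not in ("sum", "mean"):
        raise ValueError(f"aggregate must be 'sum' or 'mean', got {aggregate!r}")
    by_group = table.normalized.T.groupby(
        lambda fid: table.groups[fid]
    )
    return (by_group.sum() if aggregate == "sum" else by_group.mean()).T


def _linked(accessions, protein_db: dict[str, ProteinRecord]) -> list[ProteinRecord]:
    return [protein_db[acc] for acc in accessions if acc in protein_db]


def classify_peptide(
    peptide: str, accessions, protein_db: dict[str, ProteinRecord]
) -> tuple[bool, str]:
    """Classify a peptide by the categories and tags of its linked proteins.

    Returns ``(pseudo_only, classification)``: a peptide found in pseudo
    proteins only is an ``elongation`` when at least one of them extends an
    annotated protein ("elongation of" tag), else ``standalone``; any link
    to a known protein makes it ``known``.
    """
    linked = _linked(accessions, protein_db)
    if not linked:
        raise ValueError(f"peptide {peptide!r} is not linked to any known accession")
    pseudo_only = all(record.category in PSEUDO_CATEGORIES for record in linked)
    if not pseudo_only:
        return False, "known"
    has_elongation = any(
        tag.kind == "elongation_of"
        for record in linked
        for tag in record.relations
    )
    return True, ("elongation" if has_elongation else "standalone")


def _protein_identity_key(record: ProteinRecord):
    """Collapse an ORF pseudo protein with its parent frame segment.

    Pseudo and ORF pseudo proteins of the same segment share seq_id, strand
    and the stop-side boundary (the end on +, the start on -), so they count
    as one protein for the proteotypic flag.
    """
    if record.category in PSEUDO_CATEGORIES and record.has_coordinates:
        boundary = record.end if record.strand == "+" else record.start
        return ("segment", record.seq_id, record.strand, boundary)
    return ("accession", record.accession)


def is_proteotypic(
    peptide: str, accessions, protein_db: dict[str, ProteinRecord]
) -> bool:
    """True iff the peptide maps to exactly one protein after collapsing
    each ORF pseudo protein with its parent pseudo protein."""
    linked = _linked(accessions, protein_db)
    if not linked:
        raise ValueError(f"peptide {peptide!r} is not linked to any known accession")
    return len({_protein_identity_key(record) for record in linked}) == 1


def map_peptide_to_genomic(
    peptide: str, protein: ProteinRecord
) -> list[tuple[str, int, int, str]]:
    """Genomic interval(s) of a peptide inside one located protein.

    With ``o`` the 0-based offset of an occurrence: on the + strand the
    interval is ``[start + 3o, start + 3o + 3|pep| - 1]``; on the - strand
    it is anchored at the high-coordinate end, ``[end - 3o - 3|pep| + 1,
    end - 3o]``.  Every occurrence yields one interval.
    """
    if not protein.sequence or peptide not in protein.sequence:
        raise ValueError(
            f"peptide {peptide!r} is not a substring of protein {protein.accession}"
        )
    if not protein.has_coordinates:
        raise ValueError(f"protein {protein.accession} has no genomic coordinates")
    intervals = []
    offset = protein.sequence.find(peptide)
    while offset != -1:
        span = 3 * len(peptide)
        if protein.strand == "+":
            start = protein.start + 3 * offset
            end = start + span - 1
        else:
            end = protein.end - 3 * offset
            start = end - span + 1
        intervals.append((protein.seq_id or "unknown", start, end, protein.strand))
        offset = protein.sequence.find(peptide, offset + 1)
    return intervals


@dataclass
class PeptideReportRow:
    """One analysed peptide, ready for TSV/GFF3 export."""

    sequence: str
    seq_ids: list[str]
    accessions: list[str]
    pseudo_only: bool
    classification: str  # elongation | standalone | known
    proteotypic: bool
    total: int  # distinct identifications over all files
    group_raw: dict[str, int] = field(default_factory=dict)
    group_normalized: dict[str, float] = field(default_factory=dict)
    intervals: list[tuple[str, int, int, str]] = field(default_factory=list)


def build_report_rows(
    results: CombinedResultSet,
    protein_db: dict[str, ProteinRecord],
    aggregate: str = "sum",
) -> tuple[list[PeptideReportRow], list[str]]:
    """Analyse every combined peptide into a report row.

    Peptides whose accessions cannot be resolved in the protein database are
    returned separately instead of raising, so one stray accession does not
    abort a whole analysis.
    """
    table = normalize_counts(SpectralCountTable.from_results(results))
    norm_by_group = group_normalized(table, aggregate=aggregate)
    rows: list[PeptideReportRow] = []
    unresolved: list[str] = []
    for peptide in results.peptides:
        accessions = results.peptide_accessions.get(peptide, ())
        linked = _linked(accessions, protein_db)
        if not linked:
            unresolved.append(peptide)
            continue
        pseudo_only, classification = classify_peptide(peptide, accessions, protein_db)
        intervals = []
        for protein in linked:
            if protein.sequence and protein.has_coordinates and peptide in protein.sequence:
                intervals.extend(map_peptide_to_genomic(peptide, protein))
        rows.append(
            PeptideReportRow(
                sequence=peptide,
                seq_ids=sorted(
                    {record.seq_id for record in linked if record.seq_id}
                ),
                accessions=sorted(accessions),
                pseudo_only=pseudo_only,
                classification=classification,
                proteotypic=is_proteotypic(peptide, accessions, protein_db),
                total=results.total(peptide),
                group_raw=results.group_counts(peptide),
                group_normalized={
                    group: float(norm_by_group.loc[peptide, group])
                    for group in norm_by_group.columns
                },
                intervals=sorted(set(intervals)),
            )
        )
    if unresolved:
        logger.warning("%d peptides had no resolvable protein accession", len(unresolved))
    return rows, unresolved


def filter_peptides(
    rows: list[PeptideReportRow],
    min_identifications: int,
    pseudo_only: bool = False,
    normalized: bool = False,
) -> list[PeptideReportRow]:
    """Keep rows with total distinct identifications >= the minimum.

    The threshold is inclusive and always applies to raw totals;
    ``normalized`` only selects which counts downstream display/export
    emphasises, never which rows pass.  ``pseudo_only`` additionally
    restricts to peptides found in pseudo proteins only.
    """
    del normalized  # display-only toggle; row membership never depends on it
    if min_identifications < 0:
        raise ValueError("min_identifications must be >= 0")
    kept = [row for row in rows if row.total >= min_identifications]
    if pseudo_only:
        kept = [row for row in kept if row.pseudo_only]
    return kept


def export_report_tsv(rows: list[PeptideReportRow], path: str | Path) -> None:
    """Write the peptide report as a TSV (one row per peptide, '.' missing).

    Normalized counts are printed with two decimals; raw counts and all
    other fields verbatim.
    """
    groups = sorted({group for row in rows for group in row.group_raw})
    columns = (
        ["sequence", "seq_ids", "accessions", "pseudo_only", "classification",
         "proteotypic", "total_identifications"]
        + [f"count_{g}" for g in groups]
        + [f"normalized_{g}" for g in groups]
        + ["genomic_intervals"]
    )
    records = []
    for row in rows:
        rec = {
            "sequence": row.sequence,
            "seq_ids": ",".join(row.seq_ids) or ".",
            "accessions": ",".join(row.accessions) or ".",
            "pseudo_only": str(row.pseudo_only).lower(),
            "classification": row.classification,
            "proteotypic": str(row.proteotypic).lower(),
            "total_identifications": row.total,
        }
        for g in groups:
            rec[f"count_{g}"] = row.group_raw.get(g, 0)
            rec[f"normalized_{g}"] = f"{row.group_normalized.get(g, 0.0):.2f}"
        rec["genomic_intervals"] = (
            ";".join(f"{s}:{a}-{b}({st})" for s, a, b, st in row.intervals) or "."
        )
        records.append(rec)
    frame = pd.DataFrame(records, columns=columns)
    frame.to_csv(path, sep="\t", index=False)


def export_report(
    rows: list[PeptideReportRow],
    results: CombinedResultSet,
    protein_db: dict[str, ProteinRecord],
    fmt: str,
    path: str | Path,
) -> None:
    """Export the analysis as ``tsv`` (one file) or ``gff3`` (two files,
    pseudo-only peptides vs the rest, ``path`` used as prefix)."""
    if fmt == "tsv":
        export_report_tsv(rows, path)
    elif fmt == "gff3":
        kept = {row.sequence for row in rows}
        subset = CombinedResultSet(
            counts={k: v for k, v in results.counts.items() if k[0] in kept},
            groups=dict(results.groups),
            peptide_accessions={
                pep: accs
                for pep, accs in results.peptide_accessions.items()
                if pep in kept
            },
        )
        prefix = str(path)
        export_peptide_gff3(
            subset, protein_db, f"{prefix}.pseudo.gff3", f"{prefix}.remaining.gff3"
        )
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def plot_group_counts(
    rows: list[PeptideReportRow], path: str | Path, normalized: bool = False
) -> None:
    """Static bar chart of per-group counts summed over the given peptides."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = sorted({group for row in rows for group in row.group_raw})
    values = [
        sum(
            (row.group_normalized if normalized else row.group_raw).get(g, 0)
            for row in rows
        )
        for g in groups
    ]
    fig, ax = plt.subplots(figsize=(max(4, len(groups) * 1.2), 4))
    ax.bar(groups, values)
    ax.set_ylabel("normalized counts" if normalized else "spectral counts")
    ax.set_xlabel("condition group")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
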