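"""Combination of mzTab peptide identifications (pipeline step 5).

One mzTab file per MS/MS run is parsed (PSM section of mzTab 1.0), the runs
are assigned free-form condition-group labels, and the identifications are
combined into a peptides × files matrix of distinct-spectrum counts.  A
peptide is defined by its bare amino-acid sequence — modifications and
charge states are ignored, so PSM rows sharing sequence and spectra_ref
collapse to one counted spectrum.  The combined set persists to a single
SQLite file and reloads losslessly; further identification files can be
appended to an existing set.
"""

from __future__ import annotations

import logging
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from pyteomics.mztab import MzTab

from .annotation_import import ProteinRecord
from .decoy import DECOY_PREFIX
from .sequence_io import Gff3Feature, write_gff3

logger = logging.getLogger("bacpg")

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


class MzTabFormatError(ValueError):
    """Raised when a file lacks a usable mzTab PSM section."""


@dataclass(frozen=True)
class PsmObservation:
    """One peptide-spectrum match from one mzTab file."""

    peptide_sequence: str
    spectrum_ref: str
    accessions: tuple[str, ...]
    file_id: str


def parse_mztab(path: str | Path, file_id: str | None = None) -> list[PsmObservation]:
    """Parse the PSM section of an mzTab 1.0 file into observations.

    Reads the ``sequence``, ``accession`` and ``spectra_ref`` columns by
    header name.  Rows with an empty sequence are skipped with a warning;
    decoy accessions (``DECOY_`` prefix) are dropped with a warning, since
    validated target identifications are expected upstream.
    """
    path = Path(path)
    if file_id is None:
        file_id = path.stem
    try:
        tables = MzTab(str(path))
    except Exception as exc:  # pyteomics raises assorted errors on malformed input
        raise MzTabFormatError(f"{path}: not parseable as mzTab: {exc}") from exc
    psm = tables.spectrum_match_table
    if psm is None or len(psm) == 0:
        raise MzTabFormatError(f"{path}: no PSM section (PSH/PSM lines) found")
    for column in ("sequence", "spectra_ref"):
        if column not in psm.columns:
            raise MzTabFormatError(f"{path}: PSM section lacks column {column!r}")

    observations: list[PsmObservation] = []
    n_skipped = n_decoy = 0
    for _, row in psm.iterrows():
        sequence = row["sequence"]
        if not isinstance(sequence, str) or not sequence.strip():
            n_skipped += 1
            continue
        sequence = sequence.strip().upper()
        if not set(sequence) <= AMINO_ACIDS:
            n_skipped += 1
            continue
        accession = row.get("accession")
        accessions = []
        if isinstance(accession, str) and accession.strip() not in ("", "null"):
            for acc in accession.split(","):
                acc = acc.strip()
                if acc.startswith(DECOY_PREFIX):
                    n_decoy += 1
                elif acc:
                    accessions.append(acc)
        spectrum_ref = str(row["spectra_ref"]).strip()
        if not spectrum_ref or spectrum_ref == "null":
            n_skipped += 1
            continue
        observations.append(
            PsmObservation(
                peptide_sequence=sequence,
                spectrum_ref=spectrum_ref,
                accessions=tuple(accessions),
                file_id=file_id,
            )
        )
    if n_skipped:
        logger.warning("%s: skipped %d malformed PSM rows", path, n_skipped)
    if n_decoy:
        logger.warning("%s: dropped %d decoy accessions", path, n_decoy)
    return observations


@dataclass
class CombinedResultSet:
    """Peptides × files distinct-spectrum count matrix with group labels."""

    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    groups: dict[str, str] = field(default_factory=dict)
    peptide_accessions: dict[str, tuple[str, ...]] = field(default_factory=dict)

    # -- construction ------------------------------------------------------

    def add_file(
        self, path: str | Path, group_label: str, file_id: str | None = None
    ) -> None:
        """Parse one mzTab file and fold its identifications in."""
        observations = parse_mztab(path, file_id=file_id)
        file_id = observations[0].file_id
        if file_id in self.groups:
            raise ValueError(f"duplicate file id {file_id!r}")
        self.groups[file_id] = group_label
        spectra: dict[str, set[str]] = {}
        for obs in observations:
            spectra.setdefault(obs.peptide_sequence, set()).add(obs.spectrum_ref)
            merged = set(self.peptide_accessions.get(obs.peptide_sequence, ()))
            merged.update(obs.accessions)
            self.peptide_accessions[obs.peptide_sequence] = tuple(sorted(merged))
        for peptide, refs in spectra.items():
            self.counts[(peptide, file_id)] = len(refs)

    # -- queries -----------------------------------------------------------

    @property
    def peptides(self) -> list[str]:
        return sorted({peptide for peptide, _ in self.counts})

    @property
    def file_ids(self) -> list[str]:
        return list(self.groups)

    def count(self, peptide: str, file_id: str) -> int:
        return self.counts.get((peptide, file_id), 0)

    def total(self, peptide: str) -> int:
        """Distinct identifications of a peptide summed over all files."""
        return sum(n for (pep, _), n in self.counts.items() if pep == peptide)

    def group_counts(self, peptide: str) -> dict[str, int]:
        """Raw distinct-spectrum counts per condition group."""
        result = {group: 0 for group in dict.fromkeys(self.groups.values())}
        for (pep, file_id), n in self.counts.items():
            if pep == peptide:
                result[self.groups[file_id]] += n
        return result

    def file_totals(self) -> dict[str, int]:
        """nf_t: total number of counts per identification file."""
        totals = {file_id: 0 for file_id in self.groups}
        for (_, file_id), n in self.counts.items():
            totals[file_id] += n
        return totals

    def to_matrix(self) -> pd.DataFrame:
        """Peptides × files matrix of raw distinct-spectrum counts."""
        matrix = pd.DataFrame(
            0, index=self.peptides, columns=self.file_ids, dtype=int
        )
        for (peptide, file_id), n in self.counts.items():
            matrix.loc[peptide, file_id] = n
        return matrix

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Persist to a single-file SQLite store (overwrites)."""
        path = Path(path)
        if path.exists():
            path.unlink()
        with sqlite3.connect(path) as conn:
            conn.executescript(
                """
                CREATE TABLE files (file_id TEXT PRIMARY KEY, group_label TEXT NOT NULL);
                CREATE TABLE counts (
                    peptide TEXT NOT NULL, file_id TEXT NOT NULL, n INTEGER NOT NULL,
                    PRIMARY KEY (peptide, file_id),
                    FOREIGN KEY (file_id) REFERENCES files (file_id)
                );
                CREATE TABLE peptide_protein (
                    peptide TEXT NOT NULL, accession TEXT NOT NULL,
                    PRIMARY KEY (peptide, accession)
                );
                """
            )
            conn.executemany(
                "INSERT INTO files VALUES (?, ?)", list(self.groups.items())
            )
            conn.executemany(
                "INSERT INTO counts VALUES (?, ?, ?)",
                [(pep, fid, n) for (pep, fid), n in self.counts.items()],
            )
            conn.executemany(
                "INSERT INTO peptide_protein VALUES (?, ?)",
                [
                    (pep, acc)
                    for pep, accs in self.peptide_accessions.items()
                    for acc in accs
                ],
            )

    @classmethod
    def load(cls, path: str | Path) -> "CombinedResultSet":
        result = cls()
        with sqlite3.connect(path) as conn:
            result.groups = dict(conn.execute("SELECT file_id, group_label FROM files"))
            result.counts = {
                (pep, fid): n
                for pep, fid, n in conn.execute("SELECT peptide, file_id, n FROM counts")
            }
            accessions: dict[str, list[str]] = {}
            for pep, acc in conn.execute("SELECT peptide, accession FROM peptide_protein"):
                accessions.setdefault(pep, []).append(acc)
        result.peptide_accessions = {
            pep: tuple(sorted(accs)) for pep, accs in accessions.items()
        }
        return result


def combine(files: list[tuple[str | Path, str]]) -> CombinedResultSet:
    """Combine mzTab files (path, condition-group label) into one result set."""
    if not files:
        raise ValueError("at least one identification file is required")
    result = CombinedResultSet()
    for path, group_label in files:
        result.add_file(path, group_label)
    return result


def is_pseudo_only(accessions, protein_db: dict[str, ProteinRecord]) -> bool:
    """True iff every resolvable linked protein is pseudo / ORF pseudo."""
    linked = [protein_db[acc] for acc in accessions if acc in protein_db]
    return bool(linked) and all(
        record.category in ("pseudo", "orf-pseudo") for record in linked
    )


def export_peptide_gff3(
    results: CombinedResultSet,
    protein_db: dict[str, ProteinRecord],
    pseudo_path: str | Path,
    remaining_path: str | Path,
) -> list[str]:
    """Write two peptide GFF3 files: pseudo-protein-only peptides vs the rest.

    A peptide lands in the pseudo-only file iff all of its linked proteins
    are pseudo / ORF pseudo.  Each located genomic interval yields one
    feature per condition group with a nonzero count (score = the group's
    distinct-spectrum count) and one feature for the overall number of
    identifications.  Returns the peptides that could not be located in any
    linked protein (omitted from both files).
    """
    from .analysis import map_peptide_to_genomic  # deferred: analysis imports us

    pseudo_features: list[Gff3Feature] = []
    rest_features: list[Gff3Feature] = []
    unlocatable: list[str] = []
    feature_no = 0
    for peptide in results.peptides:
        accessions = results.peptide_accessions.get(peptide, ())
        intervals: list[tuple[str, int, int, str, str]] = []
        for acc in accessions:
            protein = protein_db.get(acc)
            if protein is None or not protein.sequence or not protein.has_coordinates:
                continue
            if peptide not in protein.sequence:
                continue
            for seq_id, start, end, strand in map_peptide_to_genomic(peptide, protein):
                intervals.append((seq_id, start, end, strand, acc))
        if not intervals:
            unlocatable.append(peptide)
            continue
        target = (
            pseudo_features
            if is_pseudo_only(accessions, protein_db)
            else rest_features
        )
        group_counts = results.group_counts(peptide)
        for seq_id, start, end, strand, acc in intervals:
            scored = [
                (label, n) for label, n in group_counts.items() if n > 0
            ] + [("overall", results.total(peptide))]
            for label, score in scored:
                feature_no += 1
                target.append(
                    Gff3Feature(
                        seqid=seq_id,
                        ftype="polypeptide",
                        start=start,
                        end=end,
                        strand=strand,
                        score=score,
                        attributes={
                            "ID": f"pep{feature_no:06d}",
                            "sequence": peptide,
                            "group": label,
                            "protein": acc,
                        },
                    )
                )
    write_gff3(pseudo_features, pseudo_path)
    write_gff3(rest_features, remaining_path)
    if unlocatable:
        logger.warning("%d peptides could not be located in any protein", len(unlocatable))
    return unlocatable
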