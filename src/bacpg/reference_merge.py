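"""Compare-and-combine with a reference protein FASTA (pipeline step 2).

Each reference entry is resolved against the known-protein list, first via an
optional accession-mapping file, otherwise by exact containment of amino-acid
sequences.  Identical pairs are tagged "equal to X", containment pairs
"elongation by/of X" (storing the longer sequence); reference entries without
a partner are appended verbatim to the known list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .annotation_import import ProteinRecord, RelationTag
from .sequence_io import read_fasta, split_header

logger = logging.getLogger("bacpg")

#: Sequence-compared pairs whose lengths differ by more than this many
#: amino acids are never related.
LENGTH_GATE = 100


def read_accession_mapping(path: str | Path) -> dict[str, str]:
    """Read a two-column target→reference accession mapping.

    Tab-separated, '#' comment lines allowed; keys (target accessions) must
    be unique.
    """
    mapping: dict[str, str] = {}
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}: line {line_no}: expected two tab-separated columns"
                )
            target, reference = parts[0].strip(), parts[1].strip()
            if target in mapping:
                raise ValueError(
                    f"{path}: line {line_no}: duplicate target accession {target!r}"
                )
            mapping[target] = reference
    return mapping


def classify_relation(
    target_seq: str, ref_seq: str, apply_length_gate: bool = True
) -> str:
    """Classify the relation of a reference sequence to a target sequence.

    Returns ``equal_to`` for identical sequences, ``elongation_by`` when the
    reference is longer and wholly contains the target, ``elongation_of``
    when it is shorter and contained in the target, else ``unrelated``.
    Containment is substring containment anywhere (no anchoring, no
    N-terminal-methionine trimming).  With the length gate on, a length
    difference above 100 amino acids is ``unrelated`` regardless of
    containment.
    """
    if not target_seq or not ref_seq:
        raise ValueError("cannot classify an empty protein sequence")
    if apply_length_gate and abs(len(ref_seq) - len(target_seq)) > LENGTH_GATE:
        return "unrelated"
    if target_seq == ref_seq:
        return "equal_to"
    if len(ref_seq) > len(target_seq) and target_seq in ref_seq:
        return "elongation_by"
    if len(ref_seq) < len(target_seq) and ref_seq in target_seq:
        return "elongation_of"
    return "unrelated"


@dataclass
class MergeReport:
    matched: list[tuple[str, str, str]] = field(default_factory=list)  # (known, ref, kind)
    appended: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def warn(self, message: str) -> None:
        self.warnings.append(message)
        logger.warning(message)


def merge_reference(
    known: list[ProteinRecord],
    reference: list[tuple[str, str]],
    mapping: dict[str, str] | None = None,
) -> tuple[list[ProteinRecord], MergeReport]:
    """Enrich the known-protein list from reference ``(header, sequence)`` pairs.

    Known records must already carry sequences.  For each reference entry the
    partner is resolved via the mapping first, else by sequence comparison
    against the known records in input order (first hit wins; further hits
    produce a multi-hit warning).  Elongations store the longer sequence on
    the known record; unmatched reference entries are appended as new known
    records without genomic coordinates.
    """
    report = MergeReport()
    for record in known:
        if not record.sequence:
            raise ValueError(f"known record {record.accession} carries no sequence")
    merged = list(known)
    by_accession = {record.accession: record for record in known}
    # mapping is target accession -> reference accession; invert for lookup
    ref_to_targets: dict[str, list[str]] = {}
    for target, ref_acc in (mapping or {}).items():
        ref_to_targets.setdefault(ref_acc, []).append(target)

    for header, ref_seq in reference:
        ref_acc, ref_desc = split_header(header)
        partner: ProteinRecord | None = None
        kind: str | None = None
        for target_acc in ref_to_targets.get(ref_acc, []):
            candidate = by_accession.get(target_acc)
            if candidate is None:
                report.warn(
                    f"mapping entry {target_acc} -> {ref_acc} refers to an unknown "
                    "accession; falling back to sequence comparison"
                )
                continue
            # Mapped pairs are classified without the 100-aa length gate.
            mapped_kind = classify_relation(
                candidate.sequence, ref_seq, apply_length_gate=False
            )
            if mapped_kind != "unrelated":
                partner, kind = candidate, mapped_kind
                break
            report.warn(
                f"mapped pair {target_acc} -> {ref_acc} has unrelated sequences; "
                "falling back to sequence comparison"
            )
        if partner is None:
            hits = [
                (candidate, candidate_kind)
                for candidate in known
                if (candidate_kind := classify_relation(candidate.sequence, ref_seq))
                != "unrelated"
            ]
            if hits:
                partner, kind = hits[0]
                if len(hits) > 1:
                    report.warn(
                        f"reference entry {ref_acc} relates to {len(hits)} known "
                        f"records; linking the first ({partner.accession})"
                    )
        if partner is None:
            merged.append(
                ProteinRecord(
                    accession=ref_acc,
                    description=ref_desc,
                    sequence=ref_seq,
                    category="known",
                )
            )
            report.appended.append(ref_acc)
        else:
            partner.add_relation(RelationTag(kind=kind, partner_accession=ref_acc))
            if kind == "elongation_by":
                partner.sequence = ref_seq  # the longer sequence is stored
            report.matched.append((partner.accession, ref_acc, kind))
    return merged, report


def load_reference_fasta(path: str | Path) -> list[tuple[str, str]]:
    return read_fasta(path)
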