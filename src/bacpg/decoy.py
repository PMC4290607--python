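"""Shuffled decoy databases for target-decoy searching (pipeline step 4).

Each decoy is a uniform random permutation (Fisher-Yates, via
``random.Random.shuffle``) of one target's residues, so per-entry length and
amino-acid composition are conserved.  The output is either a concatenated
target+decoy database or a decoy-only database.
"""

from __future__ import annotations

import random
from dataclasses import replace

from .annotation_import import ProteinRecord

DECOY_PREFIX = "DECOY_"

MODES = ("concatenated", "decoy_only")


def shuffle_decoy(record: ProteinRecord, rng: random.Random) -> ProteinRecord:
    """Shuffle one target into a decoy entry.

    The accession gains the ``DECOY_`` prefix, the category becomes
    ``decoy`` and genomic coordinates are dropped (a shuffled sequence has
    no genomic locus).
    """
    if not record.sequence:
        raise ValueError(f"{record.accession}: cannot shuffle an empty sequence")
    residues = list(record.sequence)
    rng.shuffle(residues)
    return ProteinRecord(
        accession=DECOY_PREFIX + record.accession,
        description=record.description,
        sequence="".join(residues),
        category="decoy",
    )


def build_decoy_db(
    records: list[ProteinRecord], mode: str, seed: int
) -> list[ProteinRecord]:
    """Build the decoy database: 2n entries (concatenated) or n (decoy_only).

    Deterministic under ``seed``; the seed is recorded in each decoy's
    description for provenance.  Targets already carrying the decoy prefix
    are rejected (their decoys would collide).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if not records:
        raise ValueError("no target records")
    for record in records:
        if record.accession.startswith(DECOY_PREFIX):
            raise ValueError(
                f"target accession {record.accession!r} already carries the "
                f"{DECOY_PREFIX!r} prefix"
            )
    rng = random.Random(seed)
    decoys = []
    for record in records:
        decoy = shuffle_decoy(record, rng)
        note = f"decoy_seed={seed}"
        decoy = replace(
            decoy, description=f"{decoy.description} {note}".strip()
        )
        decoys.append(decoy)
    if mode == "concatenated":
        return list(records) + decoys
    return decoys
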