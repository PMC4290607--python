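"""Independent brute-force six-frame scanner used as a test oracle.

Deliberately implemented along a different path than the package: frames are
translated as whole strings and split on the stop sentinel with str.split,
and reverse-strand coordinates are derived from an explicit per-codon
position list instead of interval arithmetic.
"""

from __future__ import annotations

_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_STARTS = {"ATG", "TTG", "CTG", "ATT", "ATC", "ATA", "GTG"}

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def _aa(codon: str) -> str:
    if "N" in codon:
        return "X"
    return _CODE[codon]


def _frame_positions(length: int, frame: int) -> list[tuple[int, int]]:
    """Forward-strand (start, end) of each codon of a frame, in reading order."""
    offset = abs(frame) - 1
    positions = []
    if frame > 0:
        base = offset + 1
        while base + 2 <= length:
            positions.append((base, base + 2))
            base += 3
    else:
        base = length - offset  # reading starts at the high-coordinate end
        while base - 2 >= 1:
            positions.append((base - 2, base))
            base -= 3
    return positions


def scan_genome(residues: str):
    """All pseudo proteins and ORF pseudo proteins of a linear genome.

    Yields dicts with frame, category, aa, start, end, has_terminal_stop.
    ORFs run from the first in-frame start codon to the segment end and are
    suppressed when that codon is the segment's first (duplicate of the
    segment itself).
    """
    length = len(residues)
    reverse = "".join(_COMP[c] for c in reversed(residues))
    out = []
    for frame in (1, 2, 3, -1, -2, -3):
        source = residues if frame > 0 else reverse
        offset = abs(frame) - 1
        n_codons = (length - offset) // 3
        codons = [source[offset + 3 * i : offset + 3 * i + 3] for i in range(n_codons)]
        positions = _frame_positions(length, frame)
        translated = "".join(_aa(c) for c in codons)
        cursor = 0
        chunks = translated.split("*")
        for chunk_index, chunk in enumerate(chunks):
            has_stop = chunk_index < len(chunks) - 1
            if chunk:
                codon_range = list(range(cursor, cursor + len(chunk)))
                covered = [positions[i] for i in codon_range]
                start = min(p for p, _ in covered)
                end = max(q for _, q in covered)
                out.append(
                    dict(frame=frame, category="pseudo", aa=chunk, start=start,
                         end=end, has_terminal_stop=has_stop)
                )
                first_start = next(
                    (k for k, i in enumerate(codon_range) if codons[i] in _STARTS),
                    None,
                )
                if first_start is not None and first_start > 0:
                    orf_range = codon_range[first_start:]
                    orf_covered = [positions[i] for i in orf_range]
                    out.append(
                        dict(
                            frame=frame,
                            category="orf-pseudo",
                            aa="M" + "".join(_aa(codons[i]) for i in orf_range[1:]),
                            start=min(p for p, _ in orf_covered),
                            end=max(q for _, q in orf_covered),
                            has_terminal_stop=has_stop,
                        )
                    )
            cursor += len(chunk) + 1
    return out


def random_genome(rng, length: int, n_fraction: float = 0.01) -> str:
    alphabet = "ACGT"
    return "".join(
        "N" if rng.random() < n_fraction else rng.choice(alphabet)
        for _ in range(length)
    )
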