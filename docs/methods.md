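# Methods

## Coordinate and sequence conventions

All genomic coordinates are 1-based and inclusive on the forward strand,
matching GFF3 directly; reverse-strand features carry `strand = -` with
their interval still expressed in forward coordinates. Genomes are DNA over
{A, C, G, T, N}; lowercase input is uppercased, U is rejected. Genomes are
treated as linear: no reading frame spans the origin. The genetic code is
the bacterial table (translation table 11): stop codons TAA, TAG, TGA;
start codons ATG, TTG, CTG, ATT, ATC, ATA, GTG, all rendered as methionine
when in start position. Codons containing N translate to X and never count
as start or stop — an ambiguous base can neither open nor close a reading
frame.

## Six-frame translation

Each frame (offsets 0–2 on the forward strand and on the reverse
complement) is read codon by codon and split at stop codons. Every maximal
stop-free stretch with at least one codon is a *pseudo protein*; the
trailing stretch of a frame, which has no terminating stop, is emitted too,
and 1–2 leftover nucleotides that do not fill a codon are ignored. No
minimum length is imposed by default (`--min-aa`, default 1): a search
engine will simply never match the very short entries, and dropping them
silently would make the database's relationship to the genome harder to
reason about.

Within a stretch, the *longest ORF* is by construction the one starting at
the first in-frame start codon and running to the stretch's stop; it is
emitted additionally as an *ORF pseudo protein* with a leading M. When the
first start codon is the stretch's very first codon the ORF would duplicate
the pseudo protein at the same site (differing at most in the leading
residue), so it is suppressed; `--emit-duplicate-orfs` restores the literal
emit-both behaviour for database-size comparisons with other tools.

**Same-site deduplication.** When known-protein coordinates are supplied,
database entries translating from exactly a known gene's site are dropped.
Annotation sources disagree on whether gene coordinates include the stop
codon, so each annotated interval is matched both verbatim and with the
stop codon trimmed (high-coordinate end on +, low-coordinate end on −).
Entries that strictly contain a known gene's interval in the same frame and
strand are kept and tagged `elongation of <accession>` — these are the
candidates for gene-boundary corrections.

Accessions are deterministic and sortable: `{seqid}_F{frame}_p{index}`
(per-frame ordinal), ORFs suffixed `_orf`. The `translate` subcommand
stores each entry's coordinates in its FASTA description
(`loc=seqid:start-end:strand`) so later steps can relocate peptides without
re-reading the genome.

## Annotation import and reference merging

Separated-values annotations are read by user-supplied 0-based column
indices; strand vocabulary {+, −, forward, reverse, 1, −1, F, R} is
accepted case-insensitively. If no strand column exists, orientation is
inferred from coordinate order (start > end ⇒ reverse, coordinates
swapped); with an explicit strand column, inverted coordinates are an
error rather than silently corrected. FASTA-header import uses one regular
expression with a single capture group per field; headers that defeat a
pattern go to a skip report instead of aborting, and parsed records plus
skips always partition the input.

Reference merging classifies each reference entry against the known list:
identical sequences are `equal_to`, containment (substring anywhere, no
anchoring, no N-terminal-methionine trimming) is `elongation_by` /
`elongation_of` depending on which sequence is longer, and the longer
sequence is stored. Sequence-compared pairs with a length difference above
100 residues are never related — beyond that the pair is more plausibly a
domain repeat than a boundary correction. Pairs resolved through an
explicit accession mapping are classified regardless of length difference:
the user has asserted the correspondence. When several known records match
a reference entry, the first in input order is linked and a multi-hit
warning reported. Unmatched reference entries (typically host or
contaminant proteins) are appended verbatim; they carry no coordinates on
the bacterial genome and are excluded from GFF3 output.

## Decoys

Decoys are whole-sequence uniform permutations (Fisher–Yates) of their
targets — per-entry length and composition are conserved, cleavage sites
are not, which is the plain "shuffled" strategy. The decoy accession prefix
is `DECOY_`; target accessions already carrying it are rejected. The seed
is a required parameter and is recorded in each decoy's description
(`decoy_seed=N`), since FASTA has no comment syntax.

## Identification combination

The interface is the mzTab 1.0 PSM section, read by PSH header name
(`sequence`, `accession`, `spectra_ref`), one file per MS/MS run. A peptide
is its bare amino-acid sequence: modifications and charge states are
ignored, I and L are *not* merged. The counting unit is the distinct
`spectra_ref` string per peptide per file, so charge/modification
duplicates of one spectrum collapse to one count; a spectrum matched by two
different peptides counts once under each. Decoy accessions surviving into
the mzTab are dropped with a warning — FDR filtering belongs upstream.
Persistence is a single SQLite file (tables `files`, `counts`,
`peptide_protein`); save → load is lossless and further runs can be
appended to a reloaded set.

## Analysis

Normalization assumes equal identifiable protein per sample:
`c′ᵢ = max_t nf_t × cᵢ / nfᵢ`, applied per file; files with a zero total
are excluded with a warning. Per *group*, the normalized value is the sum
of the group's per-file normalized counts (matching the additivity of raw
per-group counts); a mean-per-file aggregation is available
(`--aggregate mean`) since either reading is defensible when several files
share a condition. Normalized values are displayed to two decimals and
stored at full precision.

Classification is a pure function of the peptide→protein links: a peptide
is `pseudo_only` iff no linked protein is a known protein; among those it
is an `elongation` iff some linked pseudo protein carries an
`elongation of` tag, else `standalone`. Proteotypic means exactly one
linked protein after collapsing each ORF pseudo protein with its parent
segment (same sequence id, strand and stop-side boundary — the invariant
pair share their stop).

The identification filter keeps peptides whose *raw* total of distinct
spectra over all files is ≥ the threshold (inclusive); the normalized
toggle only changes which counts are displayed, never which rows pass.
Peptide genomic mapping multiplies the residue offset by three from the
protein's anchored end (start on +, end on −); every occurrence of a
repeated peptide yields its own interval, and each reported interval
re-translates to the peptide (checked in the test suite and the acceptance
script).

## Synthetic fixtures

The fixture generator plants reverse-translated genes (ATG start, TAA
stop, lexicographically first codon per residue for hand-checkability) in
a uniform-random background. The background is salted every ≤ 120 nt with
the cassette `TAATTAATTAATTAA`, which contains a stop codon at every
forward offset and, via its reverse complement, at every reverse offset —
so wherever it lands it terminates all six frames and background pseudo
proteins stay short. Each planted gene is preceded in its own reading
order by a forced in-frame stop, so its frame segment starts exactly at
the annotated start; a gene may additionally carry stop-free coding
residues upstream of the annotated start (`elongation_aa`), in which case
the surviving segment is a true elongation of the annotation and the ORF
at the annotated start is same-site-dropped. Extension residues exclude M
and I (their chosen codons ATG/ATA are start codons and would shift the
ORF). Annotated coordinates include the stop codon, the common convention
in bacterial feature tables; the deduplication logic is convention-
agnostic either way. mzTab fixtures realise a planned (peptide, file,
count) matrix with distinct `spectra_ref`s and can salt charge-duplicate
rows that must not change distinct-spectrum counts.

What the fixtures do **not** emulate: realistic GC content or codon usage,
tryptic digestion constraints, spectrum-level noise, search-engine score
distributions, or FDR behaviour. Passing tests therefore demonstrate the
correctness of the combinatorics — translation, deduplication, counting,
normalization, classification, coordinate arithmetic — not the biological
performance of a search pipeline on real spectra.

## Problem sizes and determinism

The acceptance script uses a 50-kb genome with five planted genes, four
mzTab runs in two condition groups, a 200 × 10 normalization table and a
~23 000-entry decoy database; the test suite uses genomes of 0.3–14 kb and
200 random genomes for the brute-force six-frame cross-check. All
randomness flows from explicit seeds; fixture outputs are byte-identical
under a fixed seed.

## Known limitations

- Circular genomes are read as linear; ORFs spanning the origin are split.
- Only the bacterial genetic code is supported (no introns, no alternative
  tables).
- Reference merging tests exact containment only — a single substitution
  breaks the relation; no alignment is attempted.
- The real-data cross-check on the *B. japonicum* reference chromosome
  requires the NC_004463.1 genome to be present locally or downloadable;
  the repository ships no multi-megabyte data.
- mzTab 2.0 and mzIdentML are not read; the PSM section of mzTab 1.0 is
  the identification interface.
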