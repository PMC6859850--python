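"""Standard genetic code lookups shared across the package.

Everything is derived from Biopython's standard DNA codon table so the codon
inventory and amino-acid mapping cannot drift from the canonical code.
"""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"

#: all 64 DNA codons in lexicographic order
ALL_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in BASES for b in BASES for c in BASES
)

#: the three stop codons (TAA, TAG, TGA)
STOP_CODONS: tuple[str, ...] = tuple(sorted(standard_dna_table.stop_codons))

#: the 61 sense codons, lexicographic
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ALL_CODONS if c not in STOP_CODONS
)

#: sense codon -> one-letter amino acid
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)

#: the 20 standard amino acids, one-letter, alphabetical
AMINO_ACIDS: tuple[str, ...] = tuple(sorted(set(CODON_TO_AA.values())))

#: one-letter amino acid -> tuple of synonymous codons (lexicographic)
AA_TO_CODONS: dict[str, tuple[str, ...]] = {
    aa: tuple(c for c in SENSE_CODONS if CODON_TO_AA[c] == aa)
    for aa in AMINO_ACIDS
}

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")


def reverse_complement(seq: str) -> str:
    """DNA reverse complement; U is treated as T (RNA input tolerated)."""
    return seq.translate(_COMPLEMENT)[::-1]
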