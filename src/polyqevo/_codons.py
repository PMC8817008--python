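"""Standard genetic code lookups shared across modules.

Tables are built once from Biopython's standard codon table; everything
downstream treats codons as atomic 3-letter strings over {A,C,G,T} plus the
gap codon ``---``.
"""

from __future__ import annotations

from itertools import product

from Bio.Data.CodonTable import standard_dna_table

NUCLEOTIDES = ("A", "C", "G", "T")

#: codon -> one-letter amino acid, sense codons only
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)

STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)

SENSE_CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in product(NUCLEOTIDES, repeat=3) if "".join(c) not in STOP_CODONS
)

GAP_CODON = "---"

Q_CODONS = frozenset({"CAA", "CAG"})


def is_sense(codon: str) -> bool:
    return codon in CODON_TABLE


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a sense codon; ``*`` for a stop."""
    if codon in STOP_CODONS:
        return "*"
    try:
        return CODON_TABLE[codon]
    except KeyError:
        raise ValueError(f"not an unambiguous codon: {codon!r}") from None


def split_codons(cds: str) -> list[str]:
    """Split a nucleotide string into codons; length must be divisible by 3."""
    if len(cds) % 3 != 0:
        raise ValueError(f"sequence length {len(cds)} is not divisible by 3")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]
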