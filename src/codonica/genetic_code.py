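"""Standard genetic code tables and synonymous-family structure.

Everything downstream (ENC, CAI, X3s, the amino-acid column blocks of the
correspondence-analysis table, NG86 site counting) is driven by the family
structure defined here. Six-fold amino acids (Leu, Ser, Arg) are kept as
single six-membered families; Wright's degeneracy classes then contain
9 two-fold, 1 three-fold, 5 four-fold and 3 six-fold families.
"""

from __future__ import annotations

from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE = unambiguous_dna_by_id[1]  # standard code

BASES = ("T", "C", "A", "G")

#: codon -> one-letter amino acid, sense codons only
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)

STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

#: all 61 sense codons, in a fixed (alphabetical) order
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

#: amino acid -> tuple of synonymous codons (alphabetical)
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    FAMILIES.setdefault(CODON_TO_AA[_codon], ())
FAMILIES = {
    aa: tuple(c for c in SENSE_CODONS if CODON_TO_AA[c] == aa) for aa in FAMILIES
}

#: families with at least two synonymous codons (drops Met, Trp)
DEGENERATE_FAMILIES: dict[str, tuple[str, ...]] = {
    aa: codons for aa, codons in FAMILIES.items() if len(codons) >= 2
}

#: the default 59-codon set: sense codons minus ATG (Met) and TGG (Trp)
INCLUDED_59: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if CODON_TO_AA[c] in DEGENERATE_FAMILIES
)

#: amino acid -> degeneracy class size (2, 3, 4 or 6), degenerate families only
DEGENERACY_CLASS: dict[str, int] = {
    aa: len(codons) for aa, codons in DEGENERATE_FAMILIES.items()
}

#: Wright's class sizes: {2: 9, 3: 1, 4: 5, 6: 3}
CLASS_COUNTS: dict[int, int] = {}
for _k in DEGENERACY_CLASS.values():
    CLASS_COUNTS[_k] = CLASS_COUNTS.get(_k, 0) + 1

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def is_valid_cds(seq: str) -> bool:
    """ATG start, stop codon end, in frame, no internal stop."""
    if len(seq) < 6 or len(seq) % 3:
        return False
    if seq[:3] != "ATG" or seq[-3:] not in STOP_CODONS:
        return False
    return not any(seq[i : i + 3] in STOP_CODONS for i in range(3, len(seq) - 3, 3))
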