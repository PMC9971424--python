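"""Nei–Gojobori (1986) Ka/Ks for codon-aligned sequence pairs.

Synonymous and nonsynonymous site fractions per codon come from enumerating
the nine single-nucleotide mutations under the standard code (mutations to
stop codons count as nonsynonymous, so every codon contributes exactly 3
sites). Codons differing at several positions are resolved by averaging
observed synonymous/nonsynonymous differences over all minimal substitution
pathways with equal weight, excluding pathways that cross a stop codon
(falling back to all pathways when every ordering is blocked). Proportions
are corrected for multiple hits with Jukes–Cantor,
``d = -(3/4) ln(1 - 4p/3)``; p >= 3/4 means saturation and a missing
estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

from .genetic_code import CODON_TO_AA, STOP_CODONS

_VALID = frozenset("ACGT")


@dataclass
class KaKsEstimate:
    ka: float
    ks: float
    omega: float
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    n_codons: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("ka", "ks", "omega", "s_sites", "n_sites", "sd", "nd", "n_codons")}


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site count of one sense codon; sums to 3."""
    aa = CODON_TO_AA[codon]
    syn = 0.0
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1 :]
            if mutant not in STOP_CODONS and CODON_TO_AA[mutant] == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def codon_differences(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) observed differences."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool):
        cur = c1
        sd = nd = 0.0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                if not allow_stops:
                    return None
                nd += 1.0  # stop-crossing step counted nonsynonymous (fallback only)
            elif CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd

    paths = [walk(order, False) for order in permutations(diff)]
    valid = [p for p in paths if p is not None]
    if not valid:  # every ordering crosses a stop
        valid = [walk(order, True) for order in permutations(diff)]
    sd = sum(p[0] for p in valid) / len(valid)
    nd = sum(p[1] for p in valid) / len(valid)
    return sd, nd


def _jukes_cantor(p: float) -> float:
    if p < 0:
        return 0.0
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86(seq1: str, seq2: str) -> KaKsEstimate:
    """NG86 Ka, Ks and omega for one in-frame codon-aligned pair.

    Codon pairs containing gaps, ambiguous bases or stop codons are skipped
    pairwise; the estimate is symmetric in its arguments.
    """
    if len(seq1) != len(seq2):
        raise ValueError("aligned sequences must have equal length")
    if len(seq1) % 3:
        raise ValueError("alignment length must be divisible by 3")
    seq1, seq2 = seq1.upper(), seq2.upper()

    s_sites = n_sites = sd = nd = 0.0
    n_codons = 0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if not (_VALID.issuperset(c1) and _VALID.issuperset(c2)):
            continue
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            continue
        n_codons += 1
        s1, n1 = codon_sites(c1)
        s2, n2 = codon_sites(c2)
        s_sites += (s1 + s2) / 2.0
        n_sites += (n1 + n2) / 2.0
        a, b = (c1, c2) if c1 <= c2 else (c2, c1)  # symmetry
        dsd, dnd = codon_differences(a, b)
        sd += dsd
        nd += dnd

    ks = _jukes_cantor(sd / s_sites) if s_sites > 0 else math.nan
    ka = _jukes_cantor(nd / n_sites) if n_sites > 0 else math.nan
    omega = ka / ks if (ks and not math.isnan(ks) and not math.isnan(ka)) else math.nan
    return KaKsEstimate(ka, ks, omega, s_sites, n_sites, sd, nd, n_codons)


def read_pair_fasta(path) -> tuple[str, str, str, str]:
    """Read the first two records of a paired FASTA: (id1, seq1, id2, seq2)."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise ValueError(f"{path}: need two sequences per pair file")
    return (records[0].id, str(records[0].seq), records[1].id, str(records[1].seq))


def kaks_table(pairs: dict[str, tuple[str, str]]):
    """NG86 estimates for a mapping pair_id -> (seq1, seq2) as a DataFrame."""
    import pandas as pd

    rows = []
    for pair_id, (s1, s2) in pairs.items():
        est = ng86(s1, s2)
        rows.append({"pair_id": pair_id, **est.to_dict()})
    return pd.DataFrame(rows).set_index("pair_id")
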