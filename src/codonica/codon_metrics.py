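"""Per-gene codon-usage indices.

Implements the classical indices exactly as defined by their sources:

* ENC — Wright's effective number of codons, from per-family codon
  homozygosity ``F = (n * sum(p_i^2) - 1) / (n - 1)`` averaged within
  degeneracy classes, ``ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6``.
* RSCU — relative synonymous codon usage, observed count over the uniform
  expectation within the family.
* CAI — Sharp & Li's codon adaptation index: geometric mean of relative
  adaptiveness weights ``w = RSCU / max RSCU`` over the gene's codons,
  excluding Met, Trp and stops.
* A3s/T3s/C3s/G3s — Peden's synonymous third-position nucleotide usage:
  occurrences of X at synonymous third positions over the codons whose
  amino acid has a synonym ending in X.
* Positional GC — GC1/GC2/GC3 over sense codons, GC3s over synonymous
  third positions, GC12 = mean of GC1 and GC2, global GC over the CDS.

Missing values are returned as ``math.nan``, never silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .genetic_code import (
    CODON_TO_AA,
    DEGENERACY_CLASS,
    DEGENERATE_FAMILIES,
    FAMILIES,
    SENSE_CODONS,
    STOP_CODONS,
)

_VALID = frozenset("ACGT")
_GC = frozenset("GC")

# amino acids whose family has a synonym ending in X, per third-position letter
_X3S_ELIGIBLE: dict[str, frozenset[str]] = {
    nt: frozenset(
        aa for aa, codons in DEGENERATE_FAMILIES.items() if any(c[2] == nt for c in codons)
    )
    for nt in "ACGT"
}


@dataclass
class CodonCounts:
    """Frame-0 codon tally of one CDS (61 sense codons; stops and ambiguous
    codons never counted)."""

    counts: dict[str, int]
    n_codons_used: int

    def __post_init__(self) -> None:
        assert sum(self.counts.values()) == self.n_codons_used


@dataclass
class CaiWeights:
    """Relative adaptiveness w per codon (max 1 within each family);
    singleton families (Met, Trp) carry no weight."""

    w: dict[str, float]
    reference: str = "unspecified"


@dataclass
class CompositionProfile:
    """All per-gene indices used by the analysis."""

    gene_id: str = ""
    enc: float = math.nan
    cai: float = math.nan
    rscu: dict[str, float] = field(default_factory=dict)
    a3s: float = math.nan
    t3s: float = math.nan
    c3s: float = math.nan
    g3s: float = math.nan
    gc: float = math.nan
    gc1: float = math.nan
    gc2: float = math.nan
    gc3: float = math.nan
    gc3s: float = math.nan
    gc12: float = math.nan
    gcf: float = math.nan
    cds_length: int = 0


def count_codons(cds: str) -> CodonCounts:
    """Tally frame-0 codons; stop codons and codons containing ambiguous
    bases are skipped."""
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    cds = cds.upper()
    counts: dict[str, int] = {}
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if codon in STOP_CODONS or not _VALID.issuperset(codon):
            continue
        counts[codon] = counts.get(codon, 0) + 1
    return CodonCounts(counts, sum(counts.values()))


def enc(counts: CodonCounts) -> float:
    """Wright's effective number of codons, capped at 61.

    Families observed fewer than twice, or with homozygosity exactly 0
    (unusable in the harmonic form), contribute nothing. A missing
    three-fold class (Ile unobserved) is imputed as the mean of the two- and
    four-fold class averages; a missing two-, four- or six-fold class makes
    ENC undefined (nan).
    """
    class_f: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, codons in DEGENERATE_FAMILIES.items():
        ns = [counts.counts.get(c, 0) for c in codons]
        n = sum(ns)
        if n < 2:
            continue
        sum_p2 = sum((x / n) ** 2 for x in ns)
        f_hat = (n * sum_p2 - 1) / (n - 1)
        if f_hat > 0:
            class_f[DEGENERACY_CLASS[aa]].append(f_hat)

    means: dict[int, float] = {}
    for k, fs in class_f.items():
        if fs:
            means[k] = sum(fs) / len(fs)
    if 2 not in means or 4 not in means or 6 not in means:
        return math.nan
    if 3 not in means:
        means[3] = (means[2] + means[4]) / 2
    value = 2 + 9 / means[2] + 1 / means[3] + 5 / means[4] + 3 / means[6]
    return min(value, 61.0)


def rscu(counts: CodonCounts) -> dict[str, float]:
    """RSCU per sense codon; families with zero total are nan (missing)."""
    out: dict[str, float] = {}
    for codons in FAMILIES.values():
        total = sum(counts.counts.get(c, 0) for c in codons)
        k = len(codons)
        for c in codons:
            out[c] = k * counts.counts.get(c, 0) / total if total else math.nan
    return out


def cai_weights(reference_counts: CodonCounts, reference: str = "pooled reference set",
                pseudo_count: float = 0.5) -> CaiWeights:
    """Sharp & Li relative adaptiveness from pooled reference counts.

    ``w = n / max(n)`` within each degenerate family; zero counts are lifted
    to ``pseudo_count`` before the ratio, so no weight is exactly 0.
    """
    if reference_counts.n_codons_used == 0:
        raise ValueError("empty reference set")
    w: dict[str, float] = {}
    for codons in DEGENERATE_FAMILIES.values():
        ns = [max(reference_counts.counts.get(c, 0), pseudo_count) for c in codons]
        top = max(ns)
        for c, n in zip(codons, ns):
            w[c] = n / top
    return CaiWeights(w, reference)


def cai(counts: CodonCounts, weights: CaiWeights) -> float:
    """Geometric mean of w over the gene's codons (Met/Trp/stops excluded)."""
    log_sum = 0.0
    n = 0
    for codon, count in counts.counts.items():
        if codon in weights.w:
            log_sum += count * math.log(weights.w[codon])
            n += count
    return math.exp(log_sum / n) if n else math.nan


def composition(cds: str) -> dict[str, float]:
    """Positional GC and Peden's X3s for one frame-0 CDS.

    gc is computed over every unambiguous base of the CDS (stops included);
    gc1/gc2/gc3 over the 61 sense codons; a3s/t3s/c3s/g3s and gc3s over the
    synonymously variable third positions (Met/Trp/stops excluded). Codons
    containing ambiguous bases are skipped throughout.
    """
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    cds = cds.upper()

    gc_num = gc_den = 0
    pos_gc = [0, 0, 0]
    pos_n = 0
    x3_num = dict.fromkeys("ACGT", 0)
    x3_den = dict.fromkeys("ACGT", 0)
    gc3s_num = gc3s_den = 0

    for base in cds:
        if base in _VALID:
            gc_den += 1
            if base in _GC:
                gc_num += 1

    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if not _VALID.issuperset(codon) or codon in STOP_CODONS:
            continue
        pos_n += 1
        for j in range(3):
            if codon[j] in _GC:
                pos_gc[j] += 1
        aa = CODON_TO_AA[codon]
        if aa in DEGENERACY_CLASS:  # synonymously variable
            third = codon[2]
            for nt in "ACGT":
                if aa in _X3S_ELIGIBLE[nt]:
                    x3_den[nt] += 1
                    if third == nt:
                        x3_num[nt] += 1
            gc3s_den += 1
            if third in _GC:
                gc3s_num += 1

    def frac(num: int, den: int) -> float:
        return num / den if den else math.nan

    gc1 = frac(pos_gc[0], pos_n)
    gc2 = frac(pos_gc[1], pos_n)
    return {
        "gc": frac(gc_num, gc_den),
        "gc1": gc1,
        "gc2": gc2,
        "gc3": frac(pos_gc[2], pos_n),
        "gc3s": frac(gc3s_num, gc3s_den),
        "gc12": (gc1 + gc2) / 2,
        "a3s": frac(x3_num["A"], x3_den["A"]),
        "t3s": frac(x3_num["T"], x3_den["T"]),
        "c3s": frac(x3_num["C"], x3_den["C"]),
        "g3s": frac(x3_num["G"], x3_den["G"]),
    }


def profile(cds: str, weights: CaiWeights | None = None, gene_id: str = "",
            gcf: float = math.nan) -> CompositionProfile:
    """Assemble the full CompositionProfile for one CDS."""
    counts = count_codons(cds)
    comp = composition(cds)
    return CompositionProfile(
        gene_id=gene_id,
        enc=enc(counts),
        cai=cai(counts, weights) if weights is not None else math.nan,
        rscu=rscu(counts),
        gcf=gcf,
        cds_length=len(cds),
        **comp,
    )


def profile_table(cds_by_gene: dict[str, str], weights: CaiWeights | None = None,
                  gcf_by_gene: dict[str, float] | None = None):
    """Per-gene profile DataFrame (one row per gene, scalar indices only).

    When *weights* is None, the CAI reference defaults to the pooled counts
    of the 5% of genes with lowest ENC (the most biased genes).
    """
    import pandas as pd

    counts_by_gene = {g: count_codons(c) for g, c in cds_by_gene.items()}
    if weights is None:
        weights = default_cai_weights(counts_by_gene)
    rows = []
    for gene_id, cds in cds_by_gene.items():
        gcf = (gcf_by_gene or {}).get(gene_id, math.nan)
        p = profile(cds, weights, gene_id, gcf)
        rows.append({k: v for k, v in p.__dict__.items() if k != "rscu"})
    return pd.DataFrame(rows).set_index("gene_id")


def default_cai_weights(counts_by_gene: dict[str, CodonCounts],
                        fraction: float = 0.05) -> CaiWeights:
    """Reference = pooled counts of the lowest-ENC *fraction* of genes."""
    scored = sorted(
        ((enc(c), g) for g, c in counts_by_gene.items() if not math.isnan(enc(c)))
    )
    n_ref = max(1, int(round(fraction * len(scored))))
    pooled: dict[str, int] = {}
    for _, g in scored[:n_ref]:
        for codon, n in counts_by_gene[g].counts.items():
            pooled[codon] = pooled.get(codon, 0) + n
    ref = CodonCounts(pooled, sum(pooled.values()))
    return cai_weights(ref, f"pooled lowest-ENC {fraction:.0%} ({n_ref} genes)")


def codon_count_matrix(cds_by_gene: dict[str, str], codons=SENSE_CODONS):
    """Genes x codons count DataFrame (default all 61 sense codons)."""
    import pandas as pd

    data = {
        g: [count_codons(c).counts.get(codon, 0) for codon in codons]
        for g, c in cds_by_gene.items()
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=list(codons))
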