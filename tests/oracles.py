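"""Independent brute-force re-implementations used as oracles.

Everything here is derived from Biopython's translation of the standard
code and naive loops/double sums, deliberately sharing no code with the
package implementation.
"""

from __future__ import annotations

import math
from itertools import permutations, product

from Bio.Seq import Seq

_ALL_CODONS = ["".join(p) for p in product("ACGT", repeat=3)]


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


_SENSE = [c for c in _ALL_CODONS if _aa(c) != "*"]
_FAM: dict[str, list[str]] = {}
for _c in _SENSE:
    _FAM.setdefault(_aa(_c), []).append(_c)
_DEGEN = {aa: cods for aa, cods in _FAM.items() if len(cods) > 1}


def oracle_codon_counts(cds: str) -> dict[str, int]:
    out: dict[str, int] = {}
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3].upper()
        if len(codon) == 3 and all(b in "ACGT" for b in codon) and _aa(codon) != "*":
            out[codon] = out.get(codon, 0) + 1
    return out


def oracle_enc(counts: dict[str, int]) -> float:
    by_class: dict[int, list[float]] = {}
    for aa, codons in _DEGEN.items():
        ns = [counts.get(c, 0) for c in codons]
        n = sum(ns)
        if n < 2:
            continue
        f = (n * sum((x / n) ** 2 for x in ns) - 1) / (n - 1)
        if f > 0:
            by_class.setdefault(len(codons), []).append(f)
    means = {k: sum(v) / len(v) for k, v in by_class.items()}
    if not all(k in means for k in (2, 4, 6)):
        return math.nan
    if 3 not in means:
        means[3] = (means[2] + means[4]) / 2
    return min(61.0, 2 + 9 / means[2] + 1 / means[3] + 5 / means[4] + 3 / means[6])


def oracle_rscu(counts: dict[str, int]) -> dict[str, float]:
    out = {}
    for aa, codons in _FAM.items():
        tot = sum(counts.get(c, 0) for c in codons)
        for c in codons:
            out[c] = len(codons) * counts.get(c, 0) / tot if tot else math.nan
    return out


def oracle_cai_weights(ref_counts: dict[str, int]) -> dict[str, float]:
    w = {}
    for aa, codons in _DEGEN.items():
        adj = {c: max(ref_counts.get(c, 0), 0.5) for c in codons}
        top = max(adj.values())
        for c in codons:
            w[c] = adj[c] / top
    return w


def oracle_cai(counts: dict[str, int], w: dict[str, float]) -> float:
    prod, n = 1.0, 0
    for c, k in counts.items():
        if c in w:
            prod *= w[c] ** k
            n += k
    return prod ** (1.0 / n) if n else math.nan


def oracle_composition(cds: str) -> dict[str, float]:
    codons = [cds[i : i + 3].upper() for i in range(0, len(cds), 3)]
    codons = [c for c in codons if all(b in "ACGT" for b in c)]
    sense = [c for c in codons if _aa(c) != "*"]
    degen = [c for c in sense if _aa(c) in _DEGEN]

    def gc_at(pos):
        vals = [c[pos] in "GC" for c in sense]
        return sum(vals) / len(vals) if vals else math.nan

    out = {"gc1": gc_at(0), "gc2": gc_at(1), "gc3": gc_at(2)}
    out["gc12"] = (out["gc1"] + out["gc2"]) / 2
    valid = [b for b in cds.upper() if b in "ACGT"]
    out["gc"] = sum(b in "GC" for b in valid) / len(valid) if valid else math.nan
    for nt in "ACGT":
        eligible = [c for c in degen if any(s[2] == nt for s in _DEGEN[_aa(c)])]
        out[f"{nt.lower()}3s"] = (
            sum(c[2] == nt for c in eligible) / len(eligible) if eligible else math.nan
        )
    gc_eligible = [c for c in degen if any(s[2] in "GC" for s in _DEGEN[_aa(c)])]
    out["gc3s"] = (
        sum(c[2] in "GC" for c in gc_eligible) / len(gc_eligible)
        if gc_eligible else math.nan
    )
    return out


def oracle_inertia(matrix) -> float:
    import numpy as np

    N = np.asarray(matrix, dtype=float)
    total = N.sum()
    acc = 0.0
    for i in range(N.shape[0]):
        for j in range(N.shape[1]):
            f = N[i, j] / total
            ri = N[i].sum() / total
            cj = N[:, j].sum() / total
            if ri > 0 and cj > 0:
                acc += (f - ri * cj) ** 2 / (ri * cj)
    return acc


def oracle_ng86_codon(c1: str, c2: str):
    """(s_sites averaged over both codons, sd, nd) by explicit enumeration."""

    def sites(codon):
        syn = 0.0
        for pos in range(3):
            for nt in "ACGT":
                if nt != codon[pos]:
                    mut = codon[:pos] + nt + codon[pos + 1 :]
                    if _aa(mut) not in ("*",) and _aa(mut) == _aa(codon):
                        syn += 1 / 3
        return syn

    diff = [i for i in range(3) if c1[i] != c2[i]]
    results = []
    for order in permutations(diff):
        cur, sd, nd, blocked = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _aa(nxt) == "*":
                blocked = True
                break
            if _aa(nxt) == _aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            results.append((sd, nd))
    if not results:
        for order in permutations(diff):
            cur, sd, nd = c1, 0, 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if _aa(nxt) == "*" or _aa(nxt) != _aa(cur):
                    nd += 1
                else:
                    sd += 1
                cur = nxt
            results.append((sd, nd))
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return (sites(c1) + sites(c2)) / 2, sd, nd


def oracle_spearman(x, y) -> float:
    """Rank correlation via explicit average ranks + Pearson formula."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den
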