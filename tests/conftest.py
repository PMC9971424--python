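"""Shared fixtures: random CDS generation and a hand-built annotation
fixture in which each exclusion filter fires exactly once."""

from __future__ import annotations

import numpy as np
import pytest

from codonica.genetic_code import SENSE_CODONS, STOP_CODONS, reverse_complement

NON_STOP = [c for c in SENSE_CODONS]


def random_cds(rng: np.random.Generator, n_codons: int, start_stop: bool = True) -> str:
    body = "".join(NON_STOP[i] for i in rng.integers(0, len(NON_STOP), n_codons))
    return ("ATG" + body + "TAA") if start_stop else body


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def _spacer(rng: np.random.Generator, n: int = 250) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def filter_genome(tmp_path_factory):
    """8-gene genome: one gene violating each of the six filters plus two
    clean genes (one SEG, one MEG). Returns (fasta, gff, expected) where
    expected maps gene_id -> label or exclusion reason."""
    rng = np.random.default_rng(7)
    lines = ["##gff-version 3"]
    chr1_parts = []
    pos = 0
    expected: dict[str, str] = {}

    def add_simple(gene_id, cds, featuretype="mRNA", exons=None, strand="+"):
        """Place one gene with given CDS on Chr1; exons = list of
        transcription-order lengths summing to len(cds)."""
        nonlocal pos
        chr1_parts.append(_spacer(rng))
        pos += 250
        exons = exons or [len(cds)]
        introns = [_spacer(rng, 80) for _ in exons[:-1]]
        parts, spans, p, q = [], [], 0, 0
        for k, el in enumerate(exons):
            parts.append(cds[p : p + el])
            spans.append((q, q + el))
            p += el
            q += el
            if k < len(introns):
                parts.append(introns[k])
                q += len(introns[k])
        region = "".join(parts)
        if strand == "-":
            genomic = reverse_complement(region)
            spans = [(len(region) - b, len(region) - a) for a, b in spans]
        else:
            genomic = region
        start0 = pos
        chr1_parts.append(genomic)
        pos += len(genomic)
        g1, g2 = start0 + 1, start0 + len(genomic)
        lines.append(f"Chr1\ttest\tgene\t{g1}\t{g2}\t.\t{strand}\t.\tID={gene_id}")
        lines.append(
            f"Chr1\ttest\t{featuretype}\t{g1}\t{g2}\t.\t{strand}\t.\t"
            f"ID={gene_id}.1;Parent={gene_id}")
        if featuretype == "mRNA":
            for a, b in sorted(spans):
                e1, e2 = start0 + a + 1, start0 + b
                lines.append(f"Chr1\ttest\texon\t{e1}\t{e2}\t.\t{strand}\t.\t"
                             f"Parent={gene_id}.1")
                lines.append(f"Chr1\ttest\tCDS\t{e1}\t{e2}\t.\t{strand}\t0\t"
                             f"Parent={gene_id}.1")
        return g1, g2

    # 1. clean single-exon gene
    cds_seg = random_cds(rng, 108)
    add_simple("g_seg", cds_seg)
    expected["g_seg"] = "SEG"
    # 2. clean multiple-exon gene on the minus strand
    cds_meg = random_cds(rng, 118)
    add_simple("g_meg", cds_meg, exons=[200, len(cds_meg) - 200], strand="-")
    expected["g_meg"] = "MEG"
    # 3. internal stop codon
    body = random_cds(rng, 110)
    cds_stop = body[:150] + "TAA" + body[153:]
    assert cds_stop[:3] == "ATG" and cds_stop[-3:] in STOP_CODONS
    add_simple("g_internal_stop", cds_stop)
    expected["g_internal_stop"] = "internal_stop"
    # 4. abnormal start codon
    cds_bad = "GTG" + random_cds(rng, 108)[3:]
    add_simple("g_bad_start", cds_bad)
    expected["g_bad_start"] = "bad_start_stop"
    # 5. noncoding RNA gene
    add_simple("g_trna", _spacer(rng, 90), featuretype="tRNA")
    expected["g_trna"] = "noncoding_rna"
    # 6. CDS shorter than 300 bp
    add_simple("g_short", random_cds(rng, 40))
    expected["g_short"] = "short_cds"
    # 7. longest isoform single-exon, alternative isoform multi-exon
    nonlocal_cds = random_cds(rng, 200)  # 606 bp
    g1, g2 = add_simple("g_sei", nonlocal_cds)
    # second, shorter isoform with two exons inside the same span
    lines.append(f"Chr1\ttest\tmRNA\t{g1}\t{g1 + 599}\t.\t+\t.\t"
                 f"ID=g_sei.2;Parent=g_sei")
    for a, b in [(g1, g1 + 299), (g1 + 450, g1 + 599)]:
        lines.append(f"Chr1\ttest\texon\t{a}\t{b}\t.\t+\t.\tParent=g_sei.2")
        lines.append(f"Chr1\ttest\tCDS\t{a}\t{b}\t.\t+\t0\tParent=g_sei.2")
    expected["g_sei"] = "single_exon_isoform"

    chr1 = "".join(chr1_parts) + _spacer(rng)

    # 8. clean gene on a scaffold-named chromosome
    cds_un = random_cds(rng, 108)
    chrsy = _spacer(rng) + cds_un + _spacer(rng)
    lines.append(f"ChrSy\ttest\tgene\t251\t{250 + len(cds_un)}\t.\t+\t.\tID=g_scaffold")
    lines.append(f"ChrSy\ttest\tmRNA\t251\t{250 + len(cds_un)}\t.\t+\t.\t"
                 f"ID=g_scaffold.1;Parent=g_scaffold")
    lines.append(f"ChrSy\ttest\texon\t251\t{250 + len(cds_un)}\t.\t+\t.\tParent=g_scaffold.1")
    lines.append(f"ChrSy\ttest\tCDS\t251\t{250 + len(cds_un)}\t.\t+\t0\tParent=g_scaffold.1")
    expected["g_scaffold"] = "unknown_chromosome"

    d = tmp_path_factory.mktemp("filter_genome")
    fasta = d / "genome.fa"
    with open(fasta, "w") as fh:
        for name, seq in [("Chr1", chr1), ("ChrSy", chrsy)]:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    gff = d / "genes.gff3"
    gff.write_text("\n".join(lines) + "\n")
    return fasta, gff, expected, {"g_seg": cds_seg, "g_meg": cds_meg}


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """Small synthetic genome on disk plus its loaded catalog."""
    from codonica.gene_catalog import load_catalog
    from codonica.simulate import SyntheticConfig, simulate_catalog

    cfg = SyntheticConfig(n_seg=40, n_meg=144, n_chromosomes=4)
    out = tmp_path_factory.mktemp("small_sim")
    paths = simulate_catalog(cfg, out, seed=11)
    catalog = load_catalog(paths["fasta"], paths["gff3"])
    return cfg, paths, catalog
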