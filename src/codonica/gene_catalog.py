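"""Gene catalog: genome + annotation loading, exclusion filters, SEG/MEG
classification, flank extraction and chromosome-region summaries.

Genes are read from a GFF3 (gene/mRNA/exon/CDS with Parent links, via
gffutils) against a genome FASTA. For multi-isoform genes the longest-CDS
isoform is the representative. A gene is retained only if it passes, in
this order, the filters

    unknown_chromosome -> noncoding_rna -> bad_start_stop -> internal_stop
    -> short_cds -> single_exon_isoform

(the first failing filter is the recorded exclusion reason). Retained genes
are SEG when the representative isoform has one exon and MEG otherwise. A
gene whose representative isoform is single-exon while another isoform has
several exons is excluded as a single-exon isoform of a multi-exon gene
rather than counted as a SEG.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

from .genetic_code import STOP_CODONS, reverse_complement

EXCLUSION_REASONS = (
    "unknown_chromosome",
    "noncoding_rna",
    "bad_start_stop",
    "internal_stop",
    "short_cds",
    "single_exon_isoform",
)

_NONCODING_TYPES = {
    "tRNA", "rRNA", "ncRNA", "snRNA", "snoRNA", "miRNA", "lnc_RNA",
    "tRNA_gene", "rRNA_gene", "ncRNA_gene",
}


@dataclass
class CatalogConfig:
    min_cds_len: int = 300        # bp, applied to the CDS
    flank: int = 200              # bp of noncoding sequence on each side
    chromosome_exclude: str = r"^(ChrSy|ChrUn)"  # scaffold name pattern
    start_codons: tuple = ("ATG",)


@dataclass
class GeneRecord:
    gene_id: str
    chromosome: str
    start: int                    # 1-based inclusive
    end: int
    strand: str
    exon_count: int
    cds: str
    flank_up: str = ""
    flank_down: str = ""
    label: str = "EXCLUDED"       # SEG | MEG | EXCLUDED
    exclusion_reason: str = ""


@dataclass
class GeneCatalog:
    records: list[GeneRecord]
    genome_lengths: dict[str, int]
    provenance: dict = field(default_factory=dict)
    genome: dict[str, str] | None = field(default=None, repr=False)

    @property
    def retained(self) -> list[GeneRecord]:
        return [r for r in self.records if r.label in ("SEG", "MEG")]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": r.gene_id, "chromosome": r.chromosome,
                    "start": r.start, "end": r.end, "strand": r.strand,
                    "exon_count": r.exon_count, "label": r.label,
                    "exclusion_reason": r.exclusion_reason,
                }
                for r in self.records
            ]
        ).set_index("gene_id")

    def cds_by_gene(self) -> dict[str, str]:
        return {r.gene_id: r.cds for r in self.retained}

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    def write_cds_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.retained:
                fh.write(f">{r.gene_id}\n")
                for i in range(0, len(r.cds), 80):
                    fh.write(r.cds[i : i + 80] + "\n")


def _spliced_cds(segments: list[tuple[int, int]], strand: str, seq: str) -> str:
    """Concatenate CDS segments in genomic order; reverse-complement for -."""
    parts = [seq[a - 1 : b] for a, b in sorted(segments)]
    cds = "".join(parts)
    return reverse_complement(cds) if strand == "-" else cds


def load_catalog(fasta_path, gff_path, config: CatalogConfig | None = None) -> GeneCatalog:
    """Read genome + GFF3 into a labeled GeneCatalog (classification
    included)."""
    config = config or CatalogConfig()
    genome = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise ValueError(
                    f"malformed GFF3 {gff_path}: line {lineno} has "
                    f"{len(line.split(chr(9)))} fields, expected 9")
    try:
        db = gffutils.create_db(
            str(gff_path), ":memory:", merge_strategy="create_unique",
            keep_order=True, force=True,
        )
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"malformed GFF3 {gff_path}: {exc}") from exc

    excl_re = re.compile(config.chromosome_exclude)
    records: list[GeneRecord] = []
    seen: set[str] = set()
    for gene in db.features_of_type("gene"):
        gene_id = gene.id
        if gene_id in seen:
            raise ValueError(f"duplicate gene id {gene_id}")
        seen.add(gene_id)
        rec = GeneRecord(gene_id, gene.seqid, gene.start, gene.end,
                         gene.strand, 0, "")

        if excl_re.search(gene.seqid) or gene.seqid not in genome:
            rec.exclusion_reason = "unknown_chromosome"
            records.append(rec)
            continue
        seq = genome[gene.seqid]

        children = list(db.children(gene, level=1))
        if any(ch.featuretype in _NONCODING_TYPES for ch in children):
            rec.exclusion_reason = "noncoding_rna"
            records.append(rec)
            continue
        mrnas = [ch for ch in children if ch.featuretype in ("mRNA", "transcript")]
        isoforms = []
        for m in mrnas:
            cds_segs = [(c.start, c.end) for c in db.children(m, featuretype="CDS")]
            if not cds_segs:
                continue
            exons = list(db.children(m, featuretype="exon"))
            isoforms.append(
                (sum(b - a + 1 for a, b in cds_segs),
                 len(exons) if exons else len(cds_segs), cds_segs)
            )
        if not isoforms:
            rec.exclusion_reason = "noncoding_rna"
            records.append(rec)
            continue

        isoforms.sort(key=lambda t: -t[0])
        cds_len, exon_count, cds_segs = isoforms[0]
        rec.cds = _spliced_cds(cds_segs, gene.strand, seq)
        rec.exon_count = exon_count

        up = seq[max(0, gene.start - 1 - config.flank) : gene.start - 1]
        down = seq[gene.end : gene.end + config.flank]
        if gene.strand == "-":
            up, down = reverse_complement(down), reverse_complement(up)
        rec.flank_up, rec.flank_down = up, down

        cds = rec.cds
        if (len(cds) % 3 or cds[:3] not in config.start_codons
                or cds[-3:] not in STOP_CODONS):
            rec.exclusion_reason = "bad_start_stop"
        elif any(cds[i : i + 3] in STOP_CODONS for i in range(0, len(cds) - 3, 3)):
            rec.exclusion_reason = "internal_stop"
        elif len(cds) < config.min_cds_len:
            rec.exclusion_reason = "short_cds"
        elif exon_count == 1 and any(iso[1] >= 2 for iso in isoforms[1:]):
            rec.exclusion_reason = "single_exon_isoform"
        records.append(rec)

    catalog = GeneCatalog(
        records,
        {name: len(s) for name, s in genome.items()},
        {"fasta": str(fasta_path), "gff3": str(gff_path), "config": vars(config)},
        genome=genome,
    )
    return classify(catalog)


def classify(catalog: GeneCatalog) -> GeneCatalog:
    """Label every record: SEG (one exon), MEG (several), or EXCLUDED."""
    for rec in catalog.records:
        if rec.exclusion_reason:
            rec.label = "EXCLUDED"
        else:
            rec.label = "SEG" if rec.exon_count == 1 else "MEG"
    return catalog


def flank_gc(record: GeneRecord) -> float:
    """GC fraction pooled over both flanks; ambiguous bases dropped; both
    flanks empty -> nan."""
    pooled = (record.flank_up + record.flank_down).upper()
    den = sum(pooled.count(b) for b in "ACGT")
    if den == 0:
        return math.nan
    return (pooled.count("G") + pooled.count("C")) / den


def bin_chromosomes(catalog: GeneCatalog, n_bins: int = 10) -> pd.DataFrame:
    """Equal-region chromosome summary: per region, GC of the genomic
    sequence and the number of SEGs/MEGs whose midpoint falls inside.

    Regions partition [1, length] into *n_bins* near-equal (±1 bp) spans.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if catalog.genome is None:
        raise ValueError("catalog carries no genome sequence")
    rows = []
    mid_counts: dict[tuple[str, int], dict[str, int]] = {}
    for rec in catalog.retained:
        length = catalog.genome_lengths[rec.chromosome]
        edges = [round(i * length / n_bins) for i in range(n_bins + 1)]
        mid = (rec.start + rec.end) // 2
        region = int(np.searchsorted(edges, mid, side="left"))  # 1..n_bins
        region = min(max(region, 1), n_bins)
        key = (rec.chromosome, region)
        mid_counts.setdefault(key, {"SEG": 0, "MEG": 0})[rec.label] += 1
    for chrom, seq in catalog.genome.items():
        length = len(seq)
        edges = [round(i * length / n_bins) for i in range(n_bins + 1)]
        for i in range(n_bins):
            piece = seq[edges[i] : edges[i + 1]]
            den = sum(piece.count(b) for b in "ACGT")
            gc = (piece.count("G") + piece.count("C")) / den if den else math.nan
            counts = mid_counts.get((chrom, i + 1), {"SEG": 0, "MEG": 0})
            rows.append(
                {"chromosome": chrom, "region_index": i + 1, "region_gc": gc,
                 "seg_count": counts["SEG"], "meg_count": counts["MEG"]}
            )
    return pd.DataFrame(rows)
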