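"""Synthetic genomes, expression values and diverged codon alignments.

The generator emulates the structure of a plant genome study contrasting
single-exon genes (SEGs) with multiple-exon genes (MEGs):

* two gene classes sharing one amino-acid composition, whose *synonymous*
  within-family codon preferences diverge by a controllable tilt ``delta``
  (class SEG multiplies GC-ending codon weights by ``exp(+delta/2)`` and
  AT-ending ones by ``exp(-delta/2)``; MEG the opposite; amino-acid
  marginals are exact by construction, so any between-class signal is
  purely synonymous);
* heterogeneous GC3 across genes through a per-gene latent GC pressure
  (logit-normal), shared between the classes so that at ``delta = 0`` the
  two classes are exchangeable;
* exon structures — SEGs get one exon, MEGs 2–10 exons with random-DNA
  introns — plus noncoding intergenic spacers, written as FASTA + GFF3;
* per-gene expression values, log-normal with a configurable Spearman
  coupling to GC3 and none to flank GC;
* ortholog-style codon alignment pairs evolved under a continuous-time
  codon model with known omega (time is scaled so that ``t`` is roughly
  the expected number of synonymous substitutions per synonymous site).

All randomness flows from a single integer seed; outputs (including file
bytes) are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genetic_code import (
    CODON_TO_AA,
    FAMILIES,
    SENSE_CODONS,
    STOP_CODONS,
    reverse_complement,
)

_AA_ORDER = tuple(sorted(FAMILIES))
_GC_ENDING = np.array([1.0 if c[2] in "GC" else -1.0 for c in SENSE_CODONS])
_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
# family layout: per aa, global codon indices (alphabetical within family)
_FAM_IDX = [np.array([_CODON_INDEX[c] for c in FAMILIES[aa]]) for aa in _AA_ORDER]
_MAX_FAM = max(len(f) for f in _FAM_IDX)


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort (defaults are the
    conditions every calibration-style check runs under)."""

    n_seg: int = 1800
    n_meg: int = 6480                      # 3.6:1, the rice SEG:MEG ratio
    n_chromosomes: int = 12
    mean_len_codons: dict = field(default_factory=lambda: {"SEG": 300, "MEG": 530})
    len_sigma: float = 0.35                # lognormal sd of gene length
    min_len_codons: int = 100
    max_len_codons: int = 1500
    delta: float = 0.50                    # between-class synonymous tilt
    gc3_mu: float = 0.4                    # latent GC pressure, logit scale
    gc3_sd: float = 0.8
    expression_sigma: float = 1.5
    expression_gc3_coupling: float = 0.58  # Spearman(expr, GC3) ~ 0.5
    flank_gc: float = 0.43                 # noncoding / intergenic GC level
    intergenic_len: tuple = (500, 1000)
    intron_len: tuple = (100, 400)
    max_exons: int = 10
    omega: float = 0.2                     # ortholog-pair dN/dS
    t: float = 0.25                        # total pair divergence
    pair_len_codons: int = 300


def _gene_codon_cum(tilt: float) -> np.ndarray:
    """Per-family cumulative codon probabilities for one gene.

    *tilt* is the total log-weight applied to GC-ending third positions
    (class tilt plus the gene's latent GC pressure)."""
    w = np.exp(_GC_ENDING * tilt)
    cum = np.ones((len(_AA_ORDER), _MAX_FAM))
    for a, idx in enumerate(_FAM_IDX):
        fam_w = w[idx]
        cum[a, : len(idx)] = np.cumsum(fam_w) / fam_w.sum()
        cum[a, len(idx) :] = 1.0
    return cum


def _sample_gene_codons(rng: np.random.Generator, length: int, tilt: float) -> np.ndarray:
    """Codon indices (into SENSE_CODONS) of one gene body."""
    cum = _gene_codon_cum(tilt)
    aa_idx = rng.integers(0, len(_AA_ORDER), size=length)
    u = rng.random(length)
    local = (u[:, None] > cum[aa_idx]).sum(axis=1)
    pad = np.full((len(_AA_ORDER), _MAX_FAM), -1, dtype=int)
    for a, idx in enumerate(_FAM_IDX):
        pad[a, : len(idx)] = idx
    return pad[aa_idx, local]


def simulate_codon_usage(config: SyntheticConfig, seed: int = 0):
    """Sample per-gene codon counts without genome assembly.

    Returns ``(counts, labels, truth)``: a genes x 61 count DataFrame, a
    gene -> class Series, and a truth DataFrame (class, length, latent GC
    pressure, realized GC3). This is the fast path used for resampling and
    calibration studies; :func:`simulate_catalog` reuses the same draws to
    emit FASTA/GFF3.
    """
    counts, labels, truth, _ = _simulate_core(config, seed, keep_codons=False)
    return counts, labels, truth


def _simulate_core(config: SyntheticConfig, seed: int, keep_codons: bool):
    rng = np.random.default_rng(seed)
    n = config.n_seg + config.n_meg
    classes = ["SEG"] * config.n_seg + ["MEG"] * config.n_meg
    ids = [f"{cls}{i:05d}" for i, cls in enumerate(classes, 1)]

    means = np.array([config.mean_len_codons[c] for c in classes], dtype=float)
    lengths = np.exp(rng.normal(np.log(means), config.len_sigma))
    lengths = np.clip(np.round(lengths), config.min_len_codons,
                      config.max_len_codons).astype(int)
    gamma = rng.normal(config.gc3_mu, config.gc3_sd, size=n)

    count_rows = np.zeros((n, len(SENSE_CODONS)), dtype=int)
    codon_lists: list[np.ndarray] = []
    for i in range(n):
        tilt = gamma[i] + (config.delta / 2 if classes[i] == "SEG" else -config.delta / 2)
        codons = _sample_gene_codons(rng, lengths[i], tilt)
        count_rows[i] = np.bincount(codons, minlength=len(SENSE_CODONS))
        if keep_codons:
            codon_lists.append(codons)

    gc_mask = _GC_ENDING > 0
    gc3 = count_rows[:, gc_mask].sum(axis=1) / count_rows.sum(axis=1)
    counts = pd.DataFrame(count_rows, index=ids, columns=list(SENSE_CODONS))
    labels = pd.Series(classes, index=ids, name="label")
    truth = pd.DataFrame(
        {"label": classes, "length_codons": lengths, "gamma": gamma, "gc3": gc3},
        index=pd.Index(ids, name="gene_id"),
    )
    return counts, labels, truth, codon_lists


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _split_exons(rng: np.random.Generator, cds_len: int, n_exons: int,
                 min_exon: int = 30) -> list[int]:
    """Exon lengths summing to cds_len, each at least min_exon bp."""
    free = cds_len - min_exon * n_exons
    w = rng.dirichlet(np.ones(n_exons))
    extra = np.floor(w * free).astype(int)
    extra[0] += free - extra.sum()
    return list(min_exon + extra)


def simulate_catalog(config: SyntheticConfig, outdir, seed: int = 0):
    """Write genome FASTA + GFF3 + truth/expression TSVs; return the paths
    and truth table.

    Genes from :func:`simulate_codon_usage` (same seed, same draws) are laid
    onto ``n_chromosomes`` chromosomes with intergenic spacers at the
    configured flank GC; MEGs are split into 2–10 exons with random-DNA
    introns; strands alternate. CDS strings are ATG + body + stop, so every
    generated gene passes the catalog filters.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _, labels, truth, codon_lists = _simulate_core(config, seed, keep_codons=True)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    stops = sorted(STOP_CODONS)

    chrom_seqs = {f"Chr{k + 1}": [] for k in range(config.n_chromosomes)}
    chrom_pos = {name: 0 for name in chrom_seqs}
    gff_lines = ["##gff-version 3"]
    order = rng.permutation(len(labels))

    for j, gi in enumerate(order):
        gene_id = labels.index[gi]
        cls = labels.iloc[gi]
        cds = "ATG" + "".join(SENSE_CODONS[k] for k in codon_lists[gi]) + stops[rng.integers(3)]
        chrom = f"Chr{(j % config.n_chromosomes) + 1}"
        strand = "+" if rng.random() < 0.5 else "-"

        if cls == "SEG":
            exon_lens = [len(cds)]
        else:
            n_exons = int(rng.integers(2, config.max_exons + 1))
            exon_lens = _split_exons(rng, len(cds), n_exons)
        introns = [
            _random_dna(rng, int(rng.integers(*config.intron_len)), config.flank_gc)
            for _ in range(len(exon_lens) - 1)
        ]
        # gene region in transcription orientation
        parts, exon_spans, p, q = [], [], 0, 0
        for k, el in enumerate(exon_lens):
            parts.append(cds[p : p + el])
            exon_spans.append((q, q + el))  # 0-based half-open, gene-local
            p += el
            q += el
            if k < len(introns):
                parts.append(introns[k])
                q += len(introns[k])
        region = "".join(parts)
        if strand == "-":
            genomic = reverse_complement(region)
            exon_spans = [(len(region) - b, len(region) - a) for a, b in exon_spans]
        else:
            genomic = region

        spacer = _random_dna(rng, int(rng.integers(*config.intergenic_len)), config.flank_gc)
        chrom_seqs[chrom].append(spacer)
        chrom_pos[chrom] += len(spacer)
        start0 = chrom_pos[chrom]
        chrom_seqs[chrom].append(genomic)
        chrom_pos[chrom] += len(genomic)

        g1, g2 = start0 + 1, start0 + len(genomic)  # 1-based inclusive
        mrna_id = f"{gene_id}.1"
        gff_lines.append(
            f"{chrom}\tcodonica\tgene\t{g1}\t{g2}\t.\t{strand}\t.\tID={gene_id}"
        )
        gff_lines.append(
            f"{chrom}\tcodonica\tmRNA\t{g1}\t{g2}\t.\t{strand}\t.\t"
            f"ID={mrna_id};Parent={gene_id}"
        )
        for k, (a, b) in enumerate(sorted(exon_spans), 1):
            e1, e2 = start0 + a + 1, start0 + b
            gff_lines.append(
                f"{chrom}\tcodonica\texon\t{e1}\t{e2}\t.\t{strand}\t.\t"
                f"ID={mrna_id}.exon{k};Parent={mrna_id}"
            )
            gff_lines.append(
                f"{chrom}\tcodonica\tCDS\t{e1}\t{e2}\t.\t{strand}\t0\t"
                f"ID={mrna_id}.cds;Parent={mrna_id}"
            )

    for name in chrom_seqs:  # trailing spacer so last genes have flanks
        tail = _random_dna(rng, int(rng.integers(*config.intergenic_len)), config.flank_gc)
        chrom_seqs[name].append(tail)

    fasta_path = outdir / "genome.fa"
    with open(fasta_path, "w") as fh:
        for name, parts in chrom_seqs.items():
            seq = "".join(parts)
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    gff_path = outdir / "annotation.gff3"
    gff_path.write_text("\n".join(gff_lines) + "\n")
    truth_path = outdir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t")
    return {"fasta": fasta_path, "gff3": gff_path, "truth": truth_path, "truth_table": truth}


def simulate_expression(truth: pd.DataFrame, config: SyntheticConfig, seed: int = 0,
                        path=None) -> pd.Series:
    """Log-normal per-gene expression with Spearman coupling to GC3.

    ``log expr = sigma * (c*z(GC3) + noise) / sqrt(1 + c^2)`` — the implied
    Spearman correlation with GC3 is approximately ``c / sqrt(1 + c^2)``
    (~0.5 at the default coupling), with no dependence on flank GC.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))
    gc3 = truth["gc3"].to_numpy(dtype=float)
    z = (gc3 - gc3.mean()) / gc3.std() if gc3.std() > 0 else np.zeros_like(gc3)
    c = config.expression_gc3_coupling
    latent = (c * z + rng.normal(size=len(gc3))) / math.sqrt(1 + c * c)
    expr = pd.Series(np.exp(config.expression_sigma * latent), index=truth.index,
                     name="expression")
    if path is not None:
        expr.to_frame().to_csv(path, sep="\t")
    return expr


# ---------------------------------------------------------------------------
# codon-level evolver for ortholog alignment pairs


def _neighbor_tables(omega: float):
    """Per sense codon: neighbor codon indices and substitution rates.

    Single-nucleotide moves only; synonymous rate 1/3, nonsynonymous
    omega/3, stop-codon moves forbidden — so one time unit is about one
    expected synonymous substitution per synonymous site.
    """
    nbr_idx, nbr_rate = [], []
    for codon in SENSE_CODONS:
        idx, rate = [], []
        for pos in range(3):
            for nt in "ACGT":
                if nt == codon[pos]:
                    continue
                mutant = codon[:pos] + nt + codon[pos + 1 :]
                if mutant in STOP_CODONS:
                    continue
                idx.append(_CODON_INDEX[mutant])
                rate.append((1.0 if CODON_TO_AA[mutant] == CODON_TO_AA[codon] else omega) / 3.0)
        nbr_idx.append(np.array(idx))
        nbr_rate.append(np.array(rate))
    return nbr_idx, nbr_rate


def _evolve_branch(rng: np.random.Generator, codons: np.ndarray, t: float,
                   nbr_idx, nbr_rate) -> np.ndarray:
    codons = codons.copy()
    site_rate = np.array([nbr_rate[c].sum() for c in codons])
    elapsed = 0.0
    while True:
        total = site_rate.sum()
        elapsed += rng.exponential(1.0 / total)
        if elapsed > t:
            return codons
        site = rng.choice(len(codons), p=site_rate / total)
        rates = nbr_rate[codons[site]]
        move = rng.choice(len(rates), p=rates / rates.sum())
        codons[site] = nbr_idx[codons[site]][move]
        site_rate[site] = nbr_rate[codons[site]].sum()


def evolve_pair(length_codons: int, omega: float, t: float, seed: int = 0) -> tuple[str, str]:
    """Two codon-aligned CDS diverged by total time *t* (two branches of
    t/2 from a random sense-codon ancestor) at dN/dS = *omega*."""
    if omega <= 0 or t < 0:
        raise ValueError("need omega > 0 and t >= 0")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 3)))
    nbr_idx, nbr_rate = _neighbor_tables(omega)
    ancestor = rng.integers(0, len(SENSE_CODONS), size=length_codons)
    seqs = []
    for _ in range(2):
        leaf = _evolve_branch(rng, ancestor, t / 2, nbr_idx, nbr_rate) if t > 0 else ancestor
        seqs.append("".join(SENSE_CODONS[c] for c in leaf))
    return seqs[0], seqs[1]
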