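# codonica

Codon-usage bias analysis of single-exon versus multiple-exon genes.

Intronless (single-exon) genes — SEGs — form a distinctive minority of
plant and animal gene complements, and in GC-heterogeneous genomes such as
rice they carry markedly different synonymous codon usage from their
multiple-exon (MEG) counterparts. `codonica` is a library for quantifying
that difference end to end: it classifies genes from a genome FASTA +
GFF3, computes the classical codon-bias indices, partitions codon-usage
variability with an internal correspondence analysis, tests the
partition's significance by resampling, and estimates evolutionary rates
with the Nei–Gojobori method. A synthetic-data module generates complete
toy genomes with controllable class divergence, so every stage runs and is
testable without any download.

## The statistics at the core

* **ENC** (Wright). Per amino acid with `n ≥ 2` observed codons, codon
  homozygosity `F̂ = (n Σ p_i² − 1)/(n − 1)`; averaging F̂ within Wright's
  degeneracy classes (9 two-fold, 1 three-fold, 5 four-fold, 3 six-fold),
  `ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆`, capped at 61.
* **CAI** (Sharp & Li). Relative adaptiveness `w_ij = RSCU_ij / max_j
  RSCU_ij` from a reference set; CAI is the geometric mean of `w` over a
  gene's codons (Met, Trp, stops excluded).
* **X3s / positional GC** (Peden). A3s/T3s/C3s/G3s are third-position
  nucleotide usages relative to the amino acids that could carry that
  nucleotide synonymously; GC1/GC2/GC3, GC3s, GC12 = (GC1+GC2)/2, and the
  GC of 200-bp flanks (GCf).
* **Internal correspondence analysis.** The genes × codons table's total
  chi-square inertia `Σ (f_gc − f_g·f_·c)²/(f_g·f_·c)` is decomposed
  exactly additively into between/within gene class × between/within
  amino-acid block. The between-class within-block cell is the purely
  synonymous between-class signal; nine elementary analyses report
  inertias, percentages and leading eigenvalues.
* **Selection diagnostics.** ENC plot against the expected curve
  `ENC_exp = 2 + GC3s + 29/(GC3s² + (1−GC3s)²)`; neutrality plot
  (OLS of GC12 on GC3, Spearman correlations, interaction-term slope
  comparison).
* **Resampling.** Size-matched subsampling of the larger class and
  label permutation, each recomputing the synonymous between-class share,
  with add-one empirical p-values and substream-seeded reproducibility.
* **NG86 Ka/Ks.** Synonymous/nonsynonymous site counting by
  single-mutation enumeration, equal-weight pathway averaging for
  multi-hit codons (stop-crossing paths excluded), Jukes–Cantor
  correction, ω = Ka/Ks.

## Worked example

```python
from codonica import SyntheticConfig, build_table, ica_decompose, label_permutation
from codonica.simulate import simulate_codon_usage

cfg = SyntheticConfig(n_seg=300, n_meg=1080)
counts, labels, _ = simulate_codon_usage(cfg, seed=1)
table = build_table(counts, labels)          # 59 codons, 18 amino-acid blocks
dec = ica_decompose(table)
for key, pct in dec.percentages.items():
    print(f"{key}: {pct:.3f}%")
perm = label_permutation(table, n_iter=200, seed=0)
print(f"observed {perm.observed:.3f}%  null {perm.mean:.4f}%  p={perm.empirical_p:.4f}")
```

prints

```
BB: 0.009%
BW: 1.677%
WB: 8.575%
WW: 89.738%
observed 1.677%  null 0.0719%  p=0.0050
```

Reading: amino-acid usage differs negligibly between the classes (BB),
1.68% of all codon-usage variability is *synonymous* divergence between
single- and multiple-exon genes (BW), and that share is ~23× the
label-permutation chance level — the class difference is real and purely
synonymous by construction. The `examples/` directory holds one short
script per capability (catalog, indices, ICA, diagnostics, resampling,
Ka/Ks); each prints its numbers with a line on what they mean. A thin CLI
(`codonica classify|metrics|ica|resample|kaks|simulate|all`) wraps the
same functions for shell use.

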