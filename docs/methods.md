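# Methods

## Gene catalog

Genes are read from GFF3 (gene → mRNA → exon/CDS with Parent links;
gffutils backs the parsing) against a genome FASTA. For multi-isoform
genes the longest-CDS isoform is the representative; its exon count
classifies the gene (1 → SEG, ≥2 → MEG). Exclusion filters run in a fixed
order so a gene failing several gets a deterministic reason:
`unknown_chromosome → noncoding_rna → bad_start_stop → internal_stop →
short_cds → single_exon_isoform`. The length filter is applied to the CDS
(< 300 bp); start codon must be ATG, the final codon TAA/TAG/TGA, the
frame intact, and no internal stop under the standard code. A gene whose
representative isoform is single-exon while another isoform is
multi-exon is excluded as a single-exon isoform of a multi-exon gene
rather than counted as a SEG — counting such transcripts as SEGs would
conflate splice variants with genuinely intronless loci. Scaffold-style
sequence names (default pattern `^(ChrSy|ChrUn)`) are dropped.

Flanks are the 200 bp (configurable) of genomic sequence on each side of
the gene span, truncated at chromosome ends; GCf pools both flanks and
drops ambiguous bases, returning a missing value (never 0) when both are
empty. Chromosome-region summaries split each chromosome into n equal
(±1 bp) spans and assign genes by midpoint; the midpoint rule is a
convention choice — start- or overlap-based assignment shifts a small
number of boundary genes but not the rank correlations computed from the
table.

## Codon-usage indices

Codon counts cover the 61 sense codons; stop codons and codons containing
ambiguous bases are never counted, and each index applies its own further
exclusions. ENC follows Wright's estimator with six-fold families (Leu,
Ser, Arg) kept whole, giving class sizes 9/1/5/3. Numerical rules beyond
the formula: families observed fewer than twice contribute nothing; a
family whose F̂ is exactly 0 (perfectly even usage at tiny counts) cannot
enter the harmonic average and is dropped from its class mean; a missing
three-fold class is imputed as (F̄₂+F̄₄)/2; a missing two-, four- or
six-fold class leaves ENC undefined; finite-sample overshoot above 61 is
capped at 61.

CAI weights derive from pooled reference counts with a 0.5 pseudo-count
lifting zero cells, `w = n/max(n)` within each degenerate family. The
default reference is the pooled usage of the 5% of input genes with
lowest ENC — the most biased genes, standing in for a curated
highly-expressed set; a user-supplied weight table overrides it. Because
the reference choice shifts absolute CAI levels, CAI values are best read
comparatively within one run.

GC1/GC2/GC3 are computed over all 61 sense codons; X3s and GC3s over the
synonymously variable codons only (Met/Trp/stops excluded, per Peden).
Both GC3 and GC3s are reported since they differ exactly by the Met/Trp
contribution. Global GC spans the entire CDS.

## Internal correspondence analysis

The genes × codons table (default 59 columns; a 61-codon mode exists for
sensitivity analysis) carries a row partition into gene classes and a
column partition into 18 amino-acid blocks. With relative frequencies P,
row masses r, column masses c, total inertia is ‖(P − rcᵀ)/√(rcᵀ)‖².
Collapsing rows by class gives the between-class inertia; the within-class
part is the residual after subtracting each gene's class-profile
prediction, and analogously for columns, giving the exact 2×2 split
BB + BW + WB + WW = total with both margin identities. The nine
elementary analyses are the standardized residual matrices of every
{total, between, within} × {total, between, within} combination; each
reports its inertia, percentage of total and the leading ≤10 squared
singular values (clipped at 1e−12). Additivity is asserted at 1e−10
relative in the tests. Rows are individual genes, not class aggregates.

The quantity of interest for two classes with shared amino-acid
composition is the BW share — between-class, within-amino-acid — i.e. the
purely synonymous divergence. A fast path computes it from collapsed
tables only (BW = inertia(class×codon) − inertia(class×block)), which the
resampling procedures exploit.

## Resampling

Both procedures recompute the BW share per replicate: subsampling draws
the smaller class's size from the larger class without replacement
(rebuilding the table's total inertia each time); label permutation
shuffles class labels with sizes preserved against the fixed table.
Empirical p uses the add-one rule, so it is never exactly 0. Replicate i
draws from substream i of a spawned SeedSequence: results are bitwise
reproducible and independent of any replicate-level parallelism.

A known property of the statistic: the between-class inertia of a
two-class table scales with the product of class codon masses, so
equalizing class sizes by subsampling roughly doubles the share when the
smaller class held ~14% of the codon mass. On real data with strongly
biased minority-class profiles the total inertia (denominator) rises in
step and damps the effect; the synthetic generator, whose two classes are
equally dispersed, shows the undamped version. The subsampling check is
therefore about robustness of the signal's order of magnitude, not about
equality of the share.

## Selection diagnostics

`enc_expected` implements the composition-only ENC curve; the ENC plot
reports per-gene deviations, the fraction of each group strictly below
the curve, and a degree-2 polynomial fit per group (degree configurable —
the fitted line is descriptive, not inferential). The neutrality plot is
OLS of GC12 on GC3 with Spearman statistics alongside; slope comparison
between groups uses the interaction term of a pooled OLS, two-sided.
Grouping supports threshold bands closed on the upper edge (≥) and
rank-matched group sizes for expression bands matched to GC3-band sizes.

## NG86 Ka/Ks

Site fractions come from enumerating the nine single-nucleotide mutations
per codon; mutations creating stop codons count as nonsynonymous, so
s + n = 3 exactly per codon and site totals are conserved. Codons
differing at 2–3 positions average observed synonymous/nonsynonymous
differences over all minimal pathways with equal weight, excluding
pathways through stop codons (all-blocked pairs fall back to unrestricted
averaging with stop steps counted nonsynonymous). Jukes–Cantor corrects
both proportions; p ≥ 3/4 means saturation and a missing estimate, and ω
is missing when Ks = 0. The estimator is exactly symmetric in its
arguments. NG86 is a deliberate single-method choice where multi-model
averaged estimators exist; at the moderate divergences simulated here its
ω recovery is within a few percent (see the neutral calibration below).

## Synthetic data

The generator emulates the structure of a two-class plant gene cohort:

* **Conditions (defaults).** 1,800 SEGs and 6,480 MEGs (21.7% single-exon,
  the 3.6:1 class ratio of the motivating system), 12 chromosomes,
  class mean CDS lengths 300/530 codons (≈910/1,590 bp) with lognormal
  spread 0.35, clipped to [100, 1500] codons. The cohort size was chosen
  so the chance level of the BW share (which scales like 1/n_genes) sits
  two orders of magnitude below the structured value, matching the
  permutation regime of interest.
* **Synonymous divergence δ.** Within each family, GC-ending codons get
  log-weight +δ/2 in SEGs and −δ/2 in MEGs. Amino-acid marginals are
  shared exactly, so any between-class signal is purely synonymous and
  δ = 0 makes the classes exchangeable. The default δ = 0.50 was
  calibrated once so the BW share lands at ≈2.7% of total inertia (the
  1–5% regime), with the permuted-label null near 0.014% — an observed/
  null ratio around 200×.
* **GC3 heterogeneity.** A per-gene latent pressure γ ~ N(0.4, 0.8) on
  the logit scale tilts third-position choices toward G/C, identical in
  distribution for both classes. Because the pressure acts only at
  synonymous third positions, GC12 barely covaries with GC3 in synthetic
  cohorts — neutrality-plot slopes near 0 are expected there, and the
  slope-recovery checks use directly simulated (GC12, GC3) pairs instead.
* **Expression.** Log-normal with Spearman coupling to realized GC3 of
  ≈ c/√(1+c²) (default c = 0.58 → ρ ≈ 0.5) and no dependence on flank GC.
* **Genome layout.** Genes are placed with 500–1,000 bp intergenic
  spacers of random DNA at GC 0.43 (also the intron and flank level);
  MEGs get 2–10 exons with 100–400 bp introns; strands alternate at
  random. Every generated CDS is filter-clean by construction, so a
  catalog round trip retains exactly the generated genes. All outputs,
  including file bytes, are deterministic under a fixed seed.
* **Ortholog pairs.** Continuous-time single-nucleotide moves with
  synonymous rate 1/3 and nonsynonymous ω/3 per alternative nucleotide
  (stop moves forbidden), two branches of t/2 from a uniform sense-codon
  ancestor; one time unit ≈ one synonymous substitution per synonymous
  site, so t = 0.25 yields Ks ≈ 0.25. Neutral calibration: at ω = 1 the
  NG86 mean ω̂ is ≈0.95 (mild classical underestimation).

What the generator does not emulate: isochore structure, realistic
exon/intron length distributions, amino-acid composition differences
between classes, GC pressure at nonsynonymous positions, and expression
measurement noise structure. Passing tests therefore demonstrate
correctness of the estimators and of the decomposition's calibration
under a controlled null/alternative — not that real genomes will show any
particular effect size.

## Problem sizes and tolerances

Test-suite simulations use cohorts of 150–8,280 genes chosen as the
smallest sizes at which each property is stable; oracle-equivalence
checks compare 200 random CDS at 1e−12 absolute; ICA additivity is
checked on 1,000 random tables at 1e−10 relative; permutation checks use
99–1,000 iterations; NG86 recovery uses 100 replicates of 300 codons. The
acceptance script runs the full default cohort with 1,000 resampling
iterations and 50 evolved pairs.
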