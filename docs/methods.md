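# Methods

This note documents the models and procedures implemented in `loop2gene`,
the parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical conventions used throughout.

## Coordinates and loop geometry

All coordinates are 0-based half-open (BED convention); a reader flag handles
1-based dialects. Loop *span* is the absolute distance between anchor
midpoints (midpoints rounded down). This convention makes span independent of
anchor width; loop callers differ on whether they report midpoint or edge
distances, and the midpoint rule is the common default. Span bounds in the
filter are inclusive on both ends ("minimum 5 kb, maximum 2 Mb" read as a
closed interval), the PET threshold is inclusive (a *minimum* of two tags) and
the q-value threshold is strict (< 5%). Trans interactions are dropped at
read time with a logged count: the analysis is defined over cis loops only.

## Promoter association and nearest genes

A transcription start site is taken per transcript — feature start on the `+`
strand, last base on the `-` strand — and deduplicated per gene, so a
multi-promoter gene qualifies through any of its promoters. An anchor is
promoter-associated when its point-to-interval distance to a TSS is at most
the flank (default 3,000 bp, inclusive; a TSS inside the anchor has distance
0). Several genes can share one anchor, which is how divergent coding /
antisense pairs with a shared promoter region are both annotated.

The nearest gene to a variant is defined by TSS distance, not gene-body
distance, consistent with the promoter-centric framing; all genes attaining
the minimum are returned, and a locus's nearest set is the union over its
credible variants. Gene skipping is then the fraction of called target genes
appearing in no locus's nearest set.

## Target-gene calling

A gene G is called for locus L under two evidence modes: *distal_loop* (a
credible variant of L inside the anchor opposite a promoter anchor of G) and
*promoter_cv* (the variant inside G's looping promoter anchor itself).
Variant-in-anchor membership is half-open, matching BED. Calls are
deduplicated per (gene, locus) with evidence accumulated; any distal evidence
makes the call distal. A loop with credible variants and promoters at both
anchors yields reciprocal calls — promoter–promoter evidence is not excluded.
Locus labels come from the credible-variant table (cytoband-style input) and
are never re-derived from coordinates. The per-locus median counts only loci
with at least one call. Calling is deterministic interval logic, so on
synthetic data with planted truth, recovery is exact rather than statistical:
any discrepancy is a defect.

## Enrichment statistics

Fisher's exact test reports the sample cross-product odds ratio a·d/(b·c)
(infinite when b·c = 0 with a·d > 0) and the exact two-sided p-value (sum of
hypergeometric outcomes no more probable than the observed table, with the
customary 1 + 1e-7 tie tolerance). The 95% CI is Woolf's log-normal interval,
exp(log OR ± 1.96·√(1/a + 1/b + 1/c + 1/d)), undefined (NaN) when any cell
is zero; commercial packages often use exact (Baptista–Pike-style) intervals
instead, so CIs here are a documented artifact choice while the OR and p
match the exact computation. Gene-set over-representation uses the upper-tail
hypergeometric per set with a Bonferroni multiplier equal to the number of
tested sets; the universe and outcome list are explicit inputs — no default
universe is assumed because the result depends strongly on it. FDR control is
Benjamini–Hochberg step-up; the prioritization filter keeps FDR strictly
below alpha (default 0.05), so a record exactly at 0.05 is excluded.

## Stratified LD-score regression (simplified)

The model is E[χ²_j] = 1 + N·Σ_c τ_c·l(j,c), where l(j,c) is SNP j's LD score
restricted to annotation category c:

  l(j,c) = Σ_{k ∈ c, |pos_k − pos_j| ≤ W} r̂²_adj(j,k),
  r̂²_adj = r̂² − (1 − r̂²)/(n_ref − 2),

with window W = 1 Mb by default, the self-term included, and the adjustment
correcting the finite-sample upward bias of the squared sample correlation
(n_ref ≥ 3 required). The regression design is an intercept plus one column
N·l(j,c)/M_c per category, so the fitted coefficient is τ_c·M_c. Weighting is
two-step, following the practice of the reference implementations of this
method: a first pass with LD weights 1/max(l_base, 1) estimates the expected
χ² per SNP, and final weights divide additionally by that expectation squared
(the approximate variance of χ² under the model). The single-pass LD-only
weights are unbiased but markedly noisier at desk scale; the two-step weights
were adopted as the package's estimator after that was measured.

Heritability uses overlap accounting: per-SNP h² is Σ_c τ_c·1[j ∈ c], a
category's h² sums per-SNP h² over its members, total h² is the base
category's, and enrichment_c = (h²_c / h²_total)/(M_c / M). The base category
(all SNPs, required in every annotation matrix) has enrichment exactly 1 by
this definition — an identity used as a test. Standard errors come from a
delete-one-block jackknife over 20 contiguous SNP blocks (configurable);
p-values are two-sided normal against enrichment = 1. An optional region
filter drops SNPs in listed intervals before regression, mirroring the
conventional exclusion of complex-LD regions such as the MHC.

Deliberate simplifications relative to the published tool: one target
annotation conditional on the base instead of a many-category baseline model;
no variant-list pruning; empirical rather than 1000-Genomes LD. These are
desk-scale calibration choices; the module's claims are about parameter
recovery in simulation, not about reproducing published real-data
enrichments.

## GWAS forward simulation

`simulate_gwas` plants a known enrichment: with target SNP share f and true
enrichment E, target SNPs carry per-SNP effect variance h²·E/M and the rest
h²·(1 − E·f)/(M − M_t) (E·f ≤ 1 required). Effects are Gaussian on
standardized genotypes; phenotypes are genotype·effects plus Gaussian noise,
with the genetic component rescaled so the realized heritability is exactly
h²; per-SNP χ² statistics are squared t-statistics from marginal regression.
The simulation is reproducible under its seed.

## Synthetic data: what it emulates, and what it does not

The generator's defaults describe the study scale the package targets:
16 risk loci with 29 credible variants each (~460 in total), 13 loci (fraction
0.8125) carrying planted target genes, four cell lines with ~36% of planted
genes supported by two or more lines, loop spans log-normal with median
~200 kb (truncated to [8 kb, 1.9 Mb]) so promoter-associated loops are
long-range, and PET counts Poisson with rate 2 + 20·(5 kb/span)^γ, γ = 1 —
a 1/distance contact-frequency approximation. Decoy loops include
deliberately filter-failing rows (10% out-of-range spans, ~30% q ≥ 0.05,
occasional single-PET support) so the filter is exercised. Placement is
collision-free by construction: decoy variants are rejected from every
anchor, planted distal anchors avoid all TSS flanks and other planted
anchors, and decoy loops that would connect a planted variant to a promoter
are discarded. The recorded ground truth therefore equals the exact expected
output of the pipeline.

The LD block uses a latent-Gaussian AR(1) haplotype model: 10,000 SNPs at
~5 kb spacing, minor-allele frequencies uniform on [0.1, 0.5], and the LD
decay scale drawn log-uniformly on [4 kb, 120 kb] per ~200-SNP segment.
Regionally varying LD matters: with spatially uniform LD the base LD score is
nearly constant and collinear with the regression intercept, leaving total
heritability unidentifiable. A population pool of 4,000 haplotypes is
generated once; the reference panel (500 individuals, the scale of a
1000-Genomes European panel) and each simulated GWAS cohort (N = 5,000) are
random haplotype pairs from that pool, making the pool the finite population
being sampled and keeping repeated simulation affordable. These sizes were
chosen as the package's desk-scale study conditions.

Not emulated: real genome coordinates or gene density (synthetic genes are
~hundreds of kb apart, so nearest-gene skipping is rarer than in the real
analysis); realistic haplotype structure beyond AR(1) decay (no recombination
hotspot map, no MAF–LD coupling); population stratification or confounding
(the regression intercept should be ~1); tissue-specific looping differences
between cell lines (lines differ only in which planted loops they carry and
in decoys). Passing tests therefore demonstrate correctness of the interval
logic and calibration of the estimators under these idealized conditions, not
performance on real HiChIP or GWAS data.

## Packaged fixtures

Three published tables ship as plain-text fixtures: the target-gene table
(13 loci, 102 listed genes with their nearest-gene sets — the surrounding
text counts 103, a discrepancy the fixture preserves as printed; derived
statistics are pinned to the table), the 28-row interactor similarity-score
table including the FDR = 0.05 boundary row, and the interaction-network
counts (2135 / 387 / 85 / 55 / 28 / 19). A toy eQTL fixture embeds the four
known credible-variant/top-eQTL gene pairs among decoys.

## Numerical conventions and degenerate inputs

Empty loop lists filter to empty lists; a summary with no promoter loops has
an undefined (None) median and logs a warning; a locus set with no calls
yields empty statistics. A 2x2 table with an empty row or column raises a
zero-margin error rather than returning an arbitrary OR. BH on an empty
vector returns an empty vector. Rank-deficient LDSC designs raise an error
naming the collinear categories. All generators are deterministic under their
seed, and pipeline outputs are a pure function of (inputs, config).
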