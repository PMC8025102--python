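# Methods

This note records the models, parameter choices, and numerical conventions
behind `emsbias`, and what the simulation-based tests do and do not
demonstrate about real data.

## Coordinates and containers

All in-memory coordinates are 0-based half-open; VCF and GFF3 are written
and read 1-based per their standards, and the EMS-SNP TSV uses 1-based
positions to match VCF.  Sequences are uint8 code arrays (A=0, C=1, G=2,
T=3, N=4) so context scans and the CpG caller run vectorised.

## The caller

A candidate site is judged from its per-bulk evidence; bulks without a
record at a site contribute zero reads (the mean over "other bulks" divides
by n_bulks − 1, not by the number of bulks with records).  The
sequencing-error tolerance is composed with the mean-reads rule: alt
evidence in a non-test bulk with alt fraction ≤ 0.20 does not break
uniqueness, but the mean alt reads over other bulks must still be ≤ 1.
If two bulks both reach the support threshold the site is rejected as
shared rather than assigned to the stronger bulk.  ED^6 is computed in
allele-frequency space over the A/C/G/T 4-vector; bulks absent at the site
enter the "other" mean as pure reference.

Residual-fragment masking runs after the cross-bulk filter (before it,
shared natural SNPs would qualify every window): sliding windows of 100 kb
at a 50-kb step over each bulk's accepted candidates are masked when they
hold ≥ 20 SNPs, and overlapping qualifying windows merge.  The window and
threshold are configurable; the half-window step (rather than a
non-overlapping tiling) is used so a dense fragment straddling a window
boundary is still caught.

## Bin scan

Full windows start at 0, step, 2·step, … while start + window ≤ L; a final
clipped bin is emitted only when the full windows leave an uncovered tail.
The mean μ includes clipped bins by default (flag to exclude).  Classes are
coldspot = 0, [1, 5), [5, 10), hotspot ≥ 10 — the published 0–5 / 5–10 /
≥10 grouping is ambiguous at its boundaries; this resolution makes the four
groups mutually exclusive so their counts sum to the bin total.  The
hotspot call is the integer rule (≥ 10); the chi-square cuts
μ ± sqrt(χ²₁(1−α)·μ) are reported alongside as the significance
justification, not used as the call.

## CpG islands

The caller implements the pass/merge scheme directly: every 100-bp window
(shift 1) passes iff GC ≥ 0.50 and (N_CpG × L)/(N_C × N_G) ≥ 0.6; passing
windows' base coverage is merged and spans ≥ 200 bp are reported.  EMBOSS
newcpgreport additionally averages over 10 windows; only the four stated
parameters are honoured here, and span-level GC/obs-exp are reported
descriptively (the acceptance criterion is per-window).  N bases fail both
criteria: excluded from C/G and CpG counts, included in window length.
Island-to-bin assignment is by midpoint (an island whose midpoint falls in
the overlap of two bins counts in both).

## Chromatin overlays

Signal tracks are ingested as BedGraph (one file per experiment, grouped
into modifications by a manifest); "covered" means the SNP base lies inside
an interval.  The per-SNP value is the flat maximum over experiments at the
base, falling back to the maximum within ±10 bp, else missing; a
modification is retained only if it covers ≥ 50% of the SNPs.  A SNP in the
overlap of two bins inherits the class of the bin with the higher SNP
count.  DH sites and genes are assigned to bins by midpoint.  Mean FPKM is
unweighted across datasets; genes absent from the matrix are excluded, not
zero-filled.  A gene is EMS-targeted if ≥ 1 accepted SNP falls in its body
or ±3-kb flanks.

## Annotation

Precedence is exon > intron > upstream3k > downstream3k > intergenic, with
upstream/downstream strand-aware and upstream winning when a SNP is
upstream of one gene and downstream of another.  Overlapping genes resolve
to the gene giving the highest-precedence category, ties to the smaller
gene id.  Exonic SNPs outside the CDS are reported as a separate
"exon (non-coding)" subcategory and folded into exon totals.  "Gene body"
is the longest isoform's transcript span, consistent with the codon-usage
analysis, which counts genome codon composition from longest-isoform CDS
only.

## Context statistics

Flanking GC excludes the SNP base itself; for the ±1 analysis a SNP counts
as "G/C-adjacent" when at least one immediate neighbour is G or C.  The
five k-mer position sets place the SNP at offset 0 (−1/0, 0/+1, −2/−1/0,
−1/0/+1, 0/+1/+2), extracted from the reference plus strand.  Random-site
baselines draw 10,000 sites without replacement per replicate, 10
replicates, N bases excluded.  Enrichment uses a 2×2 chi-square without
Yates correction (flag available); raw p < 0.05 is the default decision
rule with Benjamini–Hochberg-adjusted values reported alongside.

## The simulator

The generator emulates the study design it is meant to test: bulks of 30
pooled F2 individuals at ~39× mean depth; each chromosome tiled by
euchromatin (GC 0.40) around a pericentromeric heterochromatin block
(middle 30%, GC 0.55 plus implanted CG dinucleotides at rate 0.02 to raise
CpG-island density).  Gene models (default 400, 40% TE) are placed with a
5:1 heterochromatin preference for TE genes and their CDS rewritten in
place to be translatable; heterochromatin genes draw low expression
(mean FPKM < 1) with probability 0.85 vs 0.35 in euchromatin, TE genes +0.10.

The mutation hazard per base is base_rate × gc_multiplier (at G/C) ×
kmer_multiplier (trinucleotide ending at the site, −2/−1/0) ×
heterochromatin_multiplier.  Defaults encode the observed biases:
gc_multiplier 3.0 is back-derived from the reported 69.94% G/C-site
fraction against ~44% genome GC (an odds ratio of ≈ 3); trinucleotide
multipliers default to empty because their magnitudes are not identifiable
from published percentages without the full genome composition;
heterochromatin_multiplier 3.0 reproduces the observed clustering of
hotspots in pericentromeric regions.  Conditional on a hit, G/C sites
transition (G→A, C→T) with probability 0.85; A/T sites follow the observed
spectrum (transition 0.47, A→T/T→A 0.36, A→C/T→G 0.17).  Unlinked
heterozygous sites are sampled at pooled frequency exactly 0.5 (individuals
are not resampled); one site per bulk is causal at frequency 1.0.

Backgrounds: shared natural SNPs (homozygous in the mutagenized line vs the
reference, alt fraction 1.0 in every bulk) at 2×10⁻⁴/bp; per-bulk residual
heterozygous fragments (probability 0.5 per bulk, 150 kb, SNP density
10⁻³/bp at alt fraction 0.5) that the caller must mask; sequencing-error
sites at 2×10⁻⁵/bp per bulk carrying 1–2 alt reads (at ~39× with per-base
error ~0.3%, three identical high-quality alt reads at one position are
negligible, so error sites exercise the tolerance rule rather than the
support threshold).  Depth is Poisson; the MQ-passing alt count is a
binomial thinning at 0.95.

Chromatin tracks: DH intervals Poisson-placed at 0.4/kb (euchromatin) vs
0.08/kb (heterochromatin); BedGraph signal intervals of 500 bp with
Gamma(2, mean/2) noise at a 3:1 matched:unmatched domain contrast
(methylation and MNase high in heterochromatin; acetylation and H2A.Z high
in euchromatin); 5% of intervals are dropped to exercise the ±10-bp
fallback and coverage filter.  The experiment census is scaled down (3
methylation, 2 each MNase/H3K9ac/H3K23ac/H2A.Z) relative to the dozens of
public experiments the design emulates; the expression matrix keeps the
full 284 datasets since it is cheap.

All randomness flows from one seed through named child streams
(SeedSequence.spawn), so identical configs produce byte-identical files.

## Scaled study for recovery tests

Tests and the acceptance script use a 2 × 2.5-Mb genome with 10 bulks and
the hazard model gc ×4, AAG ×3, heterochromatin ×3.  The base rate is not a
free constant: `calibrated_base_rate` normalises it so the expected
genome-wide density is 4.65 EMS SNPs per 100-kb bin — the density the
full-scale experiment exhibits — which at this genome size yields ~230 SNPs
total (~23 per bulk).  This preserves the per-bin count regime that the
hotspot/coldspot classification, the chi-square cuts, and the per-class
overlays all operate in, at ~1% of the real genome.

## What the tests show (and don't)

Ground-truth recovery (precision/recall ≥ 0.95, G/C and AAG enrichment,
per-class methylation/DH trends) demonstrates that the estimators recover
the biases the generator planted, under the generator's assumptions:
i.i.d. bases within domains, unlinked sites, no alignment artefacts, clean
biallelic records, block-structured chromatin.  Real data add mapping bias
near repeats, linked segregation around the causal locus, overdispersed
depth, and liftover noise in public chromatin tracks — none of which the
generator models — so passing tests validate the statistical machinery, not
the upstream variant calling.  Kernel correctness is established separately
against brute-force oracles, and the published summary arithmetic
(chi-square cuts at μ = 4.65, the percentage ratios) is reproduced in
closed form.

## Degenerate inputs and tie-breaks

Zero-depth SNP-index requests raise; malformed frequency vectors raise;
empty SNP sets produce all-zero counts with an undefined-fractions flag;
zero-margin chi-square tables return (0, p=1) with a degenerate flag; bins
with no genes (or no non-TE genes) carry explicit flags instead of
ratios; classes with no covered SNPs report missing means.  Multiallelic
panel records are skipped with a warning count.  Chromosomes shorter than
the CpG window yield an empty island list.
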