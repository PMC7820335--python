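# Methods

This note records the models, conventions and numerical choices behind
`intromap`, and what the simulation-based tests do and do not demonstrate.

## Data model and coordinates

All statistics operate on a dense sites × haplotypes matrix of allele codes
(`MISSING = -1`) with per-sample read depth. Samples may have any ploidy;
pooled libraries are represented as one sample owning `2 × pool size`
haplotype columns, so a pool of five diploids contributes ten columns.
Missingness fractions are computed over haplotype columns, not samples, so
pools weigh by the genomes they contain.

VCF positions are stored 1-based exactly as read (pysam handles parsing and
write-back, including arbitrary-ploidy GT fields). All windowing is
half-open 0-based (BED convention): windows tile each contig as
`[0,s), [s,2s), …` with the final window truncated, so window lengths sum
exactly to the contig length and every base is covered once.

Filtering follows the standard resequencing hygiene for this kind of data:
genotypes with depth below 5 are set to missing (calls without a DP value
are left untouched — the rule is a depth mask, not a requirement that depth
exist), then sites with strictly more than 20 % missing haplotype columns,
or with any allele of length ≠ 1, are removed. Filtering is idempotent and
never mutates its input.

## Windowed statistics

Per-site group allele frequencies are computed over called haplotypes only.
A site is *usable* for a statistic when every group involved has at least
one called haplotype (two for π). Averages run over all usable sites,
including monomorphic ones, so windows are comparable regardless of variant
density; an `NA` is reported when a window has no usable site. Multiallelic
sites are handled by the general forms
`d_XY = 1 − Σ_a x_a y_a` and `π = n/(n−1) · (1 − Σ_a x_a²)`.

Polarization for the four-taxon statistics: the ancestral state at a site is
the outgroup's major allele (ties broken toward the reference allele, then
the lowest allele code) and the derived allele is the most frequent
remaining allele in the outgroup, falling back to overall frequency;
additional alleles are pooled with the ancestral state. This is the standard
convention when no explicit ancestral reconstruction is available; sites
where the outgroup is entirely uncalled are skipped.

`ƒ_d` uses the dynamic-donor denominator (`p_D = max(p2, p3)` substituted
for both P2 and P3). Windows with negative D report `ƒ_d = 0` — a negative
ABBA–BABA excess means gene flow in the direction not being estimated — and
raw D is retained alongside so the convention is auditable. The estimate is
clipped to [0, 1]; `ΣABBA + ΣBABA = 0` yields undefined with a reason code.

## Local trees and topology weighting

Trees are built per window by neighbor joining on pairwise-deletion
haplotype distances (proportion of differing alleles over co-called sites;
optional Jukes–Cantor correction, with saturated pairs `p ≥ 0.75` mapped to
a fixed large distance of 5.0 with a warning). NJ is delegated to
scikit-bio; negative branch lengths are clamped to zero afterwards, and tie
handling is the library's deterministic agglomeration given input label
order. For the ≤ 1 kb–100 kb windows and ≤ ~16 haplotypes this pipeline
targets, topology is what downstream weighting consumes, and NJ is
deterministic and fast; externally built Newick trees can be supplied
instead wherever a tree is accepted.

A quartet's induced topology is read off through the four-point condition
on tip-to-tip path lengths: for haplotypes (h1, h2, h3, h4) the pairing with
the strictly smallest distance sum is the induced split, and a tie (within
1e-12) corresponds to a zero-length internal branch, counted as
*unresolved*. This is mathematically identical to pruning the tree to the
four leaves and reading the split, and it vectorizes over all
single-haplotype-per-group combinations, so exact enumeration is cheap
(group sizes multiply to ≤ a few hundred here). Monte-Carlo weighting
samples combinations with replacement under a caller-provided seed and
converges to the exact weights at the usual n^(−1/2) rate. Unresolved
combinations are excluded from the weight denominator and reported
separately. Pooled samples are excluded from trees (their haplotype columns
are not phased individuals in any meaningful sense); they still contribute
to π, d_XY and ƒ_d.

The genome pipeline builds one tree per statistics window (coarse windows
for the genome scan, fine windows during refinement) rather than a separate
1 kb tree grid; the weighting consumes the same windows the thresholds are
applied to.

## Candidate extraction, refinement, narrowing

A window is a candidate when `ƒ_d > 0.75` **and** the introgression-topology
weight `> 0.75`; undefined statistics never pass, and the selection is
monotone in both thresholds. The d_XY discordance flag is an explicit
operationalization of "recipient-vs-line divergence approaches the
interspecies baseline": a window is flagged when
`d_XY(P1,P2) ≥ 0.75 × median_genome d_XY(P1,P3)` and
`d_XY(P2,P3) ≤ 0.25 × median_genome d_XY(P2,P3)`; the elevation test is
judged against the recipient–donor baseline because the genome median of
d_XY(P1,P2) itself sits at the within-population level and a multiple of it
is unstable. Fewer than 10 windows genome-wide is an error (medians
unreliable).

Candidate windows merge into regions when gaps are at most one coarse
window — a locus can straddle an assembly break or a single failing window.
Each region, padded by one coarse window, is re-scanned at fine resolution
with the same statistics; the *maximum introgressed range* is the span from
the first to the last passing fine window (an explicit, reproducible
replacement for visual inspection of locus-scan tracks). The region is then
*narrowed* to its homozygous core: fine windows individually pass when the
line's π is ≤ `pi_max` (default 0.001) and the fraction of donor-diagnostic
sites at which every called line haplotype carries the donor allele is
≥ `donor_fix_min` (default 0.95); the narrowed bounds span the longest run
of passing windows, tolerating one interior failing window. Diagnostic
sites are those fixed-different between the recipient and donor samples
among called haplotypes.

Two numerical notes. First, π here is normalized per usable (genotyped)
site, so `pi_max = 0.001` effectively demands identical-by-descent
haplotypes — which is exactly what a tract fixed from a single introgressed
chromosome produces. Both homozygosity defaults are calibrated on simulated
data, not taken from any empirical source. Second, with only a handful of
donor haplotypes sampled, roughly half of within-donor polymorphic sites
masquerade as fixed differences; an occasional mid-tract window therefore
dips just below `donor_fix_min`, which is why the narrowing run tolerates a
single-window gap rather than splitting a fixed tract in two.

## Mutation annotation

`annotate_variant` applies a substitution or indel to a coding sequence
(must start ATG, length divisible by 3; reverse-strand CDS should be
reverse-complemented first), translates the mutant CDS with the standard
nuclear code, and classifies: `frameshift_premature_stop` /
`frameshift_no_stop` (indel length ≢ 0 mod 3), `inframe_deletion` /
`inframe_insertion` (with amino acids lost), `premature_stop_no_frameshift`,
or `none`. The new stop's offset is reported in bp from the CDS start to
the stop codon's last base, and from the transcription start as
`utr5_len + offset` when a transcript model is available. A stop is
*premature* when it precedes the original terminator's expected position
after accounting for the indel's length shift; any in-frame stop after a
frameshift is premature by construction.

## The breeding simulator

The generator emulates the introgression experiment directly rather than
sampling a coalescent. Genomes are mosaics over a founder-haplotype panel
(10 recipient, 10 donor, 10 outgroup haplotypes by default); each site
carries one allele per founder, and each simulated chromosome is a tract
list pointing into the panel, so ancestry truth is exact by construction.

Sites are placed by Poisson processes per chromosome: recipient/donor fixed
differences at 0.005/bp (the derived lineage chosen by fair coin; the
outgroup carries the ancestral state), outgroup-private fixed differences at
3 × that density, and within-lineage polymorphism at 0.001/bp with founder
allele frequencies drawn from Beta(0.5, 0.5) truncated to [0.05, 0.95]
(U-shaped, like a neutral frequency spectrum, avoiding invariant
"polymorphic" sites). The marker allele itself is an anchored 37 bp deletion
carried by every donor founder — an indel, so the scan's own filters remove
it and mapping must rely on linked variation, as in a real experiment.

Meiosis draws a Poisson number of crossovers per chromosome (default mean
1.5 per meiosis, no interference) with uniform breakpoints, and a fair coin
chooses the starting parental strand. The scheme is: donor female × recipient
males → F1; F1 intercross → F2, from which a marker-homozygous female is
selected; six backcrosses of selected (carrier) females to recipient males;
then an intercross of two final-generation carrier siblings, keeping
marker-homozygous offspring as the line. Selection acts on the marker
genotype directly (a fully penetrant recessive). All donor material descends
from the single F1 maternal gamete, so overlapping donor segments are
identical by descent — the homozygous tract around the marker has π = 0
exactly. An optional `reselect_homozygotes` mode inserts an intercross
before every backcross; optional `n_line_generations` (default 0) propagates
the fixed line by mass intercrossing. Brood size (50) and the number of
carriers retained per round are explicit assumptions exposed in `SimConfig`,
as the breeding literature rarely reports them.

Observed data are emitted as GT+DP VCF (depth Poisson with mean 30;
`P(DP < 5)` is negligible at that mean, so default missingness is driven by
the mask only), a sample map, and truth BED. Default sampling mirrors a
realistic sequencing design: two diploid individuals per group plus two
pools of five line individuals at ploidy 10 — 12 line genomes in total,
which matters because a linked donor-drag island must be homozygous in
every sampled genome to survive the homozygosity filter. Same seed ⇒
byte-identical outputs.

Expected behavior used by the tests: the haplotype transmitted by the
introgressed-line parent after n backcrosses carries, outside the selected
chromosome, an expected donor fraction of 2⁻ⁿ (Mendelian halving per
backcross; 2⁻⁶ ≈ 1.56 % at the default six rounds), while inside the
selected chromosome linked drag persists. Occasionally (~10 % of replicates)
that drag includes additional genuinely homozygous donor islands separated
from the main tract by a recipient gap — real features of single-lineage
backcross designs, which the mapper correctly reports as additional
homozygous candidate regions; the end-to-end tests score them against the
ancestry truth rather than calling them errors. And with ~1 % probability
the realized homozygous tract is smaller than a coarse window, in which case
no 100 kb window reaches the 0.75 thresholds and the locus is missed — a
limitation of window-scale mapping, not of the implementation.

## What the simulations do not show

The generator's mosaic-founder model has no incomplete lineage sorting, no
background gene flow, no mutation since the founders, no genotyping error
by default (a per-call flip probability exists, default 0), and no reference
or mapping bias; its divergence is literally fixed differences plus
within-lineage frequency noise. Passing the planted-locus tests therefore
demonstrates that the statistics, thresholds and boundary logic behave as
designed under the stated breeding model — not that the thresholds are
optimal for any particular pair of real species, where window sizes and the
0.75 cutoffs should be re-examined against genome-wide null variation.

## Problem sizes

The test suite and the acceptance script run the default design (5 × 10 Mb
chromosomes, ~1.15 M sites, 14 samples) end to end: 20 seeded replicates in
the planted-locus test, 500 breeding replicates for the dilution
expectation, 200 random matrices against the brute-force d_XY/π oracles,
100 random trees for NJ recovery, and 1,000 random CDS/deletion cases for
the annotation oracle. Smaller fixtures (1 Mb chromosomes) keep the per-bp
recombination density of the full design by scaling the per-chromosome
crossover rate.
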