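# Methods

## Coordinates, features, and densities

All intervals are 0-based half-open. A transcript is an ordered list of
disjoint exons; its introns are the gaps between consecutive exons.
Introns are deduplicated by un-masked (chrom, start, end): an intron shared
by several isoforms exists once and lists every parent transcript. Masking
subtracts the union of **all** exons in the annotation, on either strand —
antisense exonic overlap also removes intronic territory, because a read in
such a region cannot be attributed to the intron unambiguously. Introns
whose un-masked length is ≤ 30 nt are dropped at extraction (the spec of a
reliable density needs some minimum support; applying the threshold once
globally keeps every downstream dataset consistent), as are introns fully
covered by exons elsewhere.

A *locus* is a connected component of the same-strand genomic-overlap
graph over transcript spans. The definition is this package's own (the
field uses "locus" loosely); same-strand restriction prevents antisense
neighbours from merging into one gene, consistent with treating sense and
antisense transcription separately everywhere else.

Densities are reads per kb of feature length per 10 M informative reads.
"Informative" = uniquely mapped reads not overlapping an exclusion region
(rRNA genes/repeats) or the mitochondrial chromosome, by an any-overlap
(≥ 1 bp) rule. A read overlapping both exonic and masked-intronic bases
contributes 0.5 to each category; category weights always sum to 1, so
Table-style tallies conserve the informative total exactly. Per-feature
counts are independent across features: a read above an exon of gene A and
an intron of gene B adds its exonic weight to A and its intronic weight to
B. The exonic feature of a transcript is the union of its exons treated as
one feature ("the entire transcript"); exon-level DE tests (below) use the
individual exons instead.

## Concordance statistics

An intron found in k transcripts yields k intron-exon pairs; all pair
statistics are computed per pair and, where a per-intron value is needed,
aggregated conservatively (minimum ρ — the pair most consistent with
independent transcription; maximum for ratios). Two datasets are derived
from the 42-sample density matrices:

* **pooled**: every (pair, sample) point, both-zero points removed, then
  the top half by exonic density (ties at the cut all kept, for
  determinism);
* **timecourse**: whole 42-sample series per pair, pairs all-zero in
  either series removed, then the top half by mean exonic density.

Spearman's ρ is the Pearson correlation of average ranks; constant series
are excluded (logged), never assigned ρ = 0, since a constant series
carries no rank information. The histogram bins follow the narrative
convention ρ≤0, 0<ρ<0.2, 0.2≤ρ≤0.5, ρ>0.5.

Sibling-intron correlations are computed within transcripts having ≥ 2
introns, after keeping only transcripts in the top half of maximum
intronic density (a low-signal intron correlates with nothing for purely
stochastic reasons). Each intron's min/max ρ against its siblings is
stratified by its own exon-ρ in 0.1-wide bins.

CV uses the sample SD (ddof = 1) over the 7 animals of one timepoint —
seven animals are a sample, not a population. Because CV falls with
abundance, (pair, timepoint) combinations are ranked by mean intronic
density and the top half with positive mean exonic density retained before
flagging CV_intron ≤ CV_exon.

## The genomic-bin DE scan

Bins of 100/200/500/1000 bp tile each chromosome independently; a read is
assigned to the single bin containing its midpoint (keeps counts integral
and conserving; with 35-bp reads and ≥ 100-bp bins the distortion is
negligible). Each size is tested independently at p < 0.001 with no
cross-size correction — the within-animal shuffle is the global answer to
multiplicity.

The test: per bin, per treatment timepoint, per-animal densities of the 7
treated vs the 7 control animals, paired by animal index. The animals are
distinct individuals, so the pairing is a labelling convention; a Welch
alternative is available via the matrix test components. Fold is the ratio
of mean densities; the t-test is one-tailed in the direction of the
observed fold; a bin is DE iff fold > 2 (or < 1/2) and p < 0.001. When one
group is all zeros, 0.5 read is added to its first animal and subtracted
from its second before density conversion — the group mean stays 0 (fold
becomes ±∞, which passes the fold filter) while the difference vector
becomes non-degenerate. The recipient choice is a convention: when the
non-zero group is exchangeable the p-value is exactly invariant to it; for
spread values it is not, so the deterministic lowest-index rule is part of
the method definition. The fold filter applies to the adjusted densities
(adjustment precedes density computation). Bins where both groups are all
zero are never tested.

Because the reported p is one-tailed in the *observed* direction, the null
probability of p < 0.001 is ≈ 0.002 (0.001 per direction). Type-I
calibration is therefore asserted for a fixed direction: on 100,000 null
Poisson(50) bins the fraction significant in the up direction must lie
within 3 binomial SDs of 0.001. At mean 50 and n = 7 the t approximation
is accurate; at very low counts the test is conservative (discreteness
inflates the variance estimate), which biases against false positives.

Merging is smaller-bin-wins within (timepoint, direction): any call
overlapped by a call of a strictly smaller size is dropped; the operation
is idempotent. DE bins are annotated exonic / exon+intron / intronic /
intergenic (mutually exclusive, any-overlap against the exon and
masked-intron unions); user-supplied interval sets add non-exclusive
sub-rows. The exon-change filter removes an intronic DE bin when any exon
of any transcript harboring the overlapped intron is DE in the same
direction at the same timepoint under relaxed thresholds (fold > √2,
p < 0.01); opposite-direction exon changes do not filter.

The shuffle control permutes, within each animal's column independently
(seeded RNG, one round by default, configurable), the values of all bins
with ≥ 1 non-zero entry, then recounts p < 0.001 bins. Shuffling preserves
each animal's value distribution but destroys bin identity, so surviving
significance measures the multiple-testing background; before/after ≥ 100
corresponds to an empirical FDR below 1%.

## Criteria, strandedness, enrichment

Criterion thresholds are inclusive as printed: ρ(exon) ≤ 0,
ρ(siblings) ≤ −0.3 (aggregated by the **mean** over siblings by default —
the aggregation is genuinely ambiguous, so min/max are selectable),
relative-to-minimum density ≥ 10 in ≥ 1 timepoint (per-timepoint means of
7 animals), max intron/exon ratio ≥ 1, CV flag, DE-bin flag. Every
criterion is evaluated on its own eligible subset; an intron with no value
for a metric is excluded from that criterion's denominator N rather than
failed. Consequently an abundance filter upstream (top-half rules) shrinks
eligibility — e.g. hotspots in weakly expressed genes fall outside the
ratio criterion's tested dataset.

Junction calibration: reads spanning annotated exon-exon junctions can
only derive from the spliced (sense) transcript, so their antisense
fraction bounds the artifactual second-strand rate. With per-sample sense
percentages (mean μ, sample SD σ), introns with ≥ μ−σ % sense reads are
"sense", < 100−(μ−σ) % "antisense", otherwise "sense-antisense"; the sense
boundary is inclusive. Introns with no reads or ambiguous parent strand
are unclassified.

Enrichment is the hypergeometric upper tail P(X ≥ m) for m labeled introns
among M passers drawn from N tested with n labeled, computed through the
log-space survival function (scipy), stable for N ≥ 10^6, and verified
against exhaustive subset enumeration for all N ≤ 12.

## The synthetic-data generator

The generator emulates the study design — 7 animals × 6 timepoints, total
RNA, ~40% of uniquely mapped reads removed as rRNA/chrM contaminants,
~20% of informative reads intergenic background, 35-bp unspliced reads —
on a toy genome of 60 multi-exon genes on 2 chromosomes (≈ 0.7 Mb), with
isoforms carrying an extra internal exon for 15% of genes to exercise exon
masking. Expected exonic output per gene is log-normal across genes
(σ = 0.6) around 250 reads/sample, with a log-normal temporal profile
(σ = 0.25) and optional exon-level DE spikes (10% of genes, 3-fold at 3 h).

Each intron draws a generative class: **premrna** (density a log-normal
ratio around 0.12 of the exons — the published median intron/exon ratio —
sharing the exons' temporal profile and per-(gene, animal) noise),
**standalone** (ratio ≈ 0.3, own temporal profile and noise; half carry a
6-fold DE spike at 3 h, up or down with equal probability), **hotspot**
(ratio ≈ 12, snoRNA-like), **antisense** (standalone program on the
opposite strand), **silent** (ratio ≈ 0.02, following the exons — the
efficiently spliced background). Counts are negative-binomial via
Gamma-Poisson (dispersion 0.05; Poisson alone understates animal-to-animal
variance) with a shared per-(gene, animal) log-normal factor (σ = 0.3)
linking exons to their pre-mRNA introns; that factor also sets the
realized intron CV near the published median (~35%). Reads are placed
uniformly with starts allowed to straddle feature boundaries, so
exon-boundary spill-over into introns (~0.02 density-ratio units) arises
naturally. Junction reads carry a per-sample sense fidelity drawn from a
clipped Normal(0.83, 0.20), the printed calibration values; gene-body read
strands use the same fidelity.

What the generator does **not** emulate: sequence content and alignment
error, spliced/blocked alignments, multi-mappers, realistic genome size or
gene density, 5′/3′ coverage bias, and correlated contamination structure.
Passing recovery tests therefore demonstrate that the statistics measure
what they claim under the stated noise model — not that the pipeline is
robust to alignment artifacts.

Class recovery is scored one-vs-rest from measured metrics on the
*unfiltered* pair set (so low-expression introns are measurable): hotspot
if max intron/exon ratio ≥ 10; antisense by strand class; pre-mRNA vs
standalone by exon-ρ above/below 0.35 (the midpoint between the ρ≈0 and
ρ≈0.7 regimes); silent if mean intron/exon ratio < 0.08 (log-midpoint of
the background and pre-mRNA abundance regimes after boundary spill-over).
DE recovery compares introns overlapped by surviving
intronic-DE-without-exon-change bins against the planted spike list. At
the documented defaults and seed 1, every class exceeds 0.8 sensitivity
and specificity; the DE margins are the tightest (≈ 0.82–0.84) because
down-spiked introns in weakly expressed genes sit near the detection
boundary of a 7-vs-7 paired test, and premrna introns occasionally ride an
exonic swing whose exon-level test just misses the relaxed threshold.

## Problem sizes and numerical choices

The default simulation produces ~150 k reads per sample (~6 M total);
simulating plus analyzing the full design takes well under a minute on one
CPU, and the calibration/shuffle checks use 100,000-bin matrices computed
with fully vectorized t-tests. Interval overlap joins go through NCLS;
overlap against non-overlapping interval unions uses binary search.
Top-half selections keep boundary ties (deterministic and
order-independent); re-running any stage on identical inputs is
byte-identical. Percentages are printed at 1 decimal place in
read-distribution tables and 2 in DE tables, matching the conventions of
the corresponding study tables; every emitted percentage equals its
numerator/denominator cells to rounding.

## Known limitations

* Spliced reads are out of scope; each input record is one contiguous
  interval (junction reads live in separate files and are used only for
  calibration).
* The locus definition and the criterion-2 aggregation are package
  choices where the field's usage is ambiguous; both are configurable.
* The shuffle control runs by default on the smallest bin size at the
  first treatment timepoint; other slices are available through the API.
* The hypergeometric test treats introns as exchangeable units; length
  biases in label overlap are not modelled.
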