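# intronkit

Quantitative analysis of intronic RNA in bulk RNA-seq timecourses.

Most reads in a total-RNA sequencing experiment map outside annotated
exons, and the largest share of those fall in introns. The conventional
reading is that intronic signal is just pre-mRNA or excised introns on
their way to degradation — in which case intronic RNA levels should track
the exons of their host transcript. `intronkit` implements the full
battery of statistics needed to test that assumption in a multi-animal
design (7 animals at each of 6 timepoints, 0/3/6/12/24/48 h after an
inflammatory stimulus):

* **Exon-masked intron intervals.** Introns are the gaps between
  consecutive exons of a transcript, with every base overlapping *any*
  annotated exon subtracted; introns sharing (chrom, start, end) collapse
  to one record. Coordinates are 0-based half-open throughout.
* **Normalized read densities.** A feature's density is
  `raw / (L/10^3) / (N_inf/10^7)` — reads per kb per 10 M informative
  reads, where informative reads are the uniquely mapped reads left after
  removing rRNA/chrM contaminants. A read overlapping both exonic and
  intronic bases counts 0.5 in each category.
* **Concordance statistics.** Per intron-exon pair, the Spearman rank
  correlation ρ of the 42-sample density series; min/max ρ of each intron
  against its sibling introns; max/min intron density ratios within a
  transcript; the maximum intron/exon density ratio over all samples; and
  the per-timepoint coefficient of variation CV = 100·s/x̄ across the 7
  animals.
* **Genomic-bin differential expression.** Non-overlapping tilings at
  100/200/500/1000 bp; per bin and timepoint a one-tailed paired
  Student's t-test on per-animal densities (fold > 2, p < 0.001). An
  all-zero group receives +0.5/−0.5 reads in two animals before testing.
  Overlapping calls across sizes are merged smaller-bin-wins, and a
  within-animal shuffle of bin values measures the empirical FDR. Intronic
  DE bins whose host gene has a same-direction DE exon (fold > √2,
  p < 0.01) are filtered out to isolate intron-specific changes.
* **Six functional-RNA criteria and strandedness.** ρ(exon) ≤ 0;
  ρ(siblings) ≤ −0.3; density ≥ 10× the transcript's minimum intron;
  max intron/exon ratio ≥ 1; CV ≤ that of the exons; presence of a DE
  bin. Sense/antisense thresholds come from reads spanning annotated
  exon-exon junctions (sense fraction mean μ, SD σ → thresholds μ−σ and
  100−(μ−σ)). Enrichment of a label set (e.g. snoRNA-bearing introns)
  among criterion passers is the hypergeometric upper tail
  `p = Σ_{i=m}^{n} C(n,i)·C(N−n, M−i) / C(N,M)`.
* **A synthetic-data generator** that emulates the study design with
  per-intron ground truth (pre-mRNA / standalone / hotspot / antisense /
  silent classes, DE spikes, contaminants, junction reads), so every
  statistic can be validated against a known answer.

## Worked example

```bash
python examples/06_full_pipeline.py
```

simulates the default study (60 genes, 42 samples, ~6 M reads), runs every
stage, and scores recovery of the planted intron classes:

```
recovery of the planted intron classes (one-vs-rest, from the measured metrics alone):
     class  n_true  n_predicted  sensitivity  specificity
 antisense      21           21        1.000        1.000
   hotspot      13           14        1.000        0.997
   premrna     176          178        0.966        0.951
    silent      64           67        0.984        0.986
standalone      66           60        0.879        0.993

planted DE introns recovered by intronic DE bins without exon change:
  sensitivity 0.84, specificity 0.82 (31 planted, 83 predicted)
```

Sensitivity/specificity are one-vs-rest per generative class: the
pipeline's measured metrics alone (exon correlation, intron/exon ratios,
junction-calibrated strand class) separate pre-mRNA-like introns from
independently transcribed ones, flag the snoRNA-like hotspots, and find
the planted expression changes that have no exonic counterpart. The other
`examples/*.py` scripts demonstrate each capability in isolation and
print a line explaining what the numbers mean.

A thin CLI mirrors the library:

```bash
intronkit simulate --seed 1 --out data/
intronkit run --dataset data/ --out results/
```

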