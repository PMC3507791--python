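"""Genome-wide differential expression with nested fixed-size bins.

Tiles the toy genome with 100/200/500/1000-bp bins, tests every bin at
every treatment timepoint against the untreated controls (one-tailed paired
t, fold > 2, p < 0.001), merges calls with the smaller-bin-wins rule, and
shows the shuffle-based false-discovery control and the bins that change
without any accompanying exon change.
"""

from intronkit import SimConfig, analyze, simulate

ds = simulate(SimConfig(seed=0, n_transcripts=30))
res = analyze(ds.transcripts, ds.reads, ds.design, ds.exclusion,
              ds.junctions, chrom_sizes=ds.chrom_sizes)

print(f"DE calls before merging: {len(res.de_bins)}; after "
      f"smaller-bin-wins merging: {len(res.de_merged)}")
print("\ncategory breakdown per timepoint/direction:")
cols = ["timepoint", "direction", "total", "pct_exonic", "pct_exon+intron",
        "pct_intronic", "pct_intergenic"]
print(res.de_summary[cols].to_string(index=False))

rep = res.shuffle_report
print(f"\nshuffle control ({rep['n_bins']} expressed {rep['bin_size']}-bp "
      f"bins, {rep['timepoint']} hr vs control):")
print(f"  p<0.001 bins before shuffling: {rep['n_pass_before']}, "
      f"after: {rep['n_pass_after']}, ratio {rep['ratio']:.0f}x")
print("  a large ratio means the planted signal, not multiple testing, "
      "drives the calls (empirical FDR ~ 1/ratio)")

n_all = (res.de_annotated["category"] == "intronic").sum()
n_free = len(res.intronic_no_exon_change)
print(f"\nintronic DE bins: {n_all}; with no same-direction exon change in "
      f"the host gene: {n_free}")
print(res.de_tally_no_exon_change.to_string(index=False))
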