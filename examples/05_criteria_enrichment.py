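"""Six functional-RNA criteria, strand calibration, and enrichment.

Classifies every intron against the six criteria (low exon correlation, low
sibling-intron correlation, high relative density, intron/exon ratio >= 1,
CV no higher than the exons, presence of a DE bin), calibrates sense /
antisense thresholds from junction-spanning reads, and tests whether the
planted snoRNA-like hotspots are enriched among criterion passers with the
hypergeometric upper tail.
"""

import pandas as pd

from intronkit import SimConfig, analyze, simulate

ds = simulate(SimConfig(seed=0, n_transcripts=30))

# the truth's hotspot introns play the role of an external label BED
truth = ds.truth.introns
hot_ids = set(truth.loc[truth["class"] == "hotspot", "intron_id"])
label_rows = [
    {"chrom": r.chrom, "start": r.start, "end": r.end, "name": "snoRNA-like",
     "score": 0, "strand": r.strand}
    for r in ds.introns if r.intron_id in hot_ids]
labels = pd.DataFrame(label_rows)

res = analyze(ds.transcripts, ds.reads, ds.design, ds.exclusion,
              ds.junctions, label_regions=labels,
              chrom_sizes=ds.chrom_sizes)

cal = res.calibration
print(f"junction calibration: mean sense fraction {cal.mu:.1f}% "
      f"+/- {cal.sigma:.1f}% -> sense >= {cal.sense_threshold:.0f}%, "
      f"antisense < {cal.antisense_threshold:.0f}%")
print("strand classes:", res.strand_class.value_counts().to_dict())

print("\nper-criterion enrichment of the snoRNA-like label set")
print("(N tested, M passing, n labeled in N, m labeled passers, "
      "upper-tail p):")
cols = ["criterion", "N", "M", "n", "m", "p", "pct_antisense_or_mixed"]
with pd.option_context("display.float_format", "{:.2e}".format):
    print(res.enrichment[cols].to_string(index=False))
print("\nsmall p: the criterion concentrates known functional RNAs far "
      "beyond chance.")
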