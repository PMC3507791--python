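"""Informative-read filtering, read weighting, and density computation.

Densities are expressed throughout as reads per kb of feature length per
10 million informative reads of the sample.  "Informative" reads are the
uniquely mapped reads left after removing anything overlapping an exclusion
region (rRNA genes and rRNA-like repeats) or the mitochondrial chromosome.

A read that overlaps both exonic and (masked-)intronic bases is counted as
0.5 read in each of the two categories; reads overlapping neither are
intergenic.  Overlap means >=1 shared base.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._intervals import interval_set_by_chrom, overlap_join, overlaps_union
from .annotation import exon_union_by_chrom, intron_union_by_chrom, merged_exons

log = logging.getLogger(__name__)

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
TIMEPOINTS = (0, 3, 6, 12, 24, 48)
DENSITY_SCALE_READS = 1e7  # per 10 M informative reads
DENSITY_SCALE_LENGTH = 1e3  # per 1 kb of feature


def read_bed6(path) -> pd.DataFrame:
    """Load a BED6 file of reads or regions into a DataFrame."""
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            names=BED6_COLUMNS,
            comment="#",
            dtype={"chrom": str, "start": np.int64, "end": np.int64,
                   "name": str, "strand": str},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=BED6_COLUMNS)
        df = df.astype({"start": np.int64, "end": np.int64})
    return df


def write_bed6(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=BED6_COLUMNS)


def read_design(path) -> pd.DataFrame:
    """Study-design table: sample_id, timepoint (hours), animal."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = {"sample_id", "timepoint", "animal"} - set(df.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    return df


@dataclass
class AnnotationIndex:
    """Per-chromosome exon and masked-intron unions, for read weighting."""

    exon_union: dict
    intron_union: dict

    @classmethod
    def build(cls, transcripts, introns):
        return cls(exon_union_by_chrom(transcripts),
                   intron_union_by_chrom(introns))


def filter_informative(reads: pd.DataFrame, exclusion_regions: pd.DataFrame,
                       mito_chrom: str = "chrM"):
    """Remove reads overlapping exclusion regions or the mito chromosome.

    Returns (informative_reads, informative_count).  Any-overlap rule: a
    read sharing a single base with an exclusion region is removed.
    """
    if len(reads) == 0:
        warnings.warn("empty read set: informative count is 0", stacklevel=2)
        return reads, 0
    keep = reads["chrom"].to_numpy() != mito_chrom
    if exclusion_regions is not None and len(exclusion_regions):
        excl = interval_set_by_chrom(exclusion_regions)
        for chrom, (us, ue) in excl.items():
            sel = reads["chrom"].to_numpy() == chrom
            if not sel.any():
                continue
            hit = overlaps_union(
                reads.loc[sel, "start"].to_numpy(),
                reads.loc[sel, "end"].to_numpy(), us, ue)
            keep[sel] &= ~hit
    out = reads.loc[keep].reset_index(drop=True)
    return out, int(len(out))


def assign_read_weights(reads: pd.DataFrame, index: AnnotationIndex) -> pd.DataFrame:
    """Fractional category weights (exonic, intronic, intergenic) per read.

    Exon-only -> (1,0,0); masked-intron-only -> (0,1,0); both -> (0.5,0.5,0);
    neither -> (0,0,1).  Weights always sum to 1.
    """
    n = len(reads)
    in_exon = np.zeros(n, dtype=bool)
    in_intron = np.zeros(n, dtype=bool)
    chroms = reads["chrom"].to_numpy()
    starts = reads["start"].to_numpy()
    ends = reads["end"].to_numpy()
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        if chrom in index.exon_union:
            us, ue = index.exon_union[chrom]
            in_exon[sel] = overlaps_union(starts[sel], ends[sel], us, ue)
        if chrom in index.intron_union:
            us, ue = index.intron_union[chrom]
            in_intron[sel] = overlaps_union(starts[sel], ends[sel], us, ue)
    w_exon = np.where(in_exon, np.where(in_intron, 0.5, 1.0), 0.0)
    w_intron = np.where(in_intron, np.where(in_exon, 0.5, 1.0), 0.0)
    w_intergenic = 1.0 - w_exon - w_intron
    out = reads.copy()
    out["w_exon"] = w_exon
    out["w_intron"] = w_intron
    out["w_intergenic"] = w_intergenic
    return out


# ---------------------------------------------------------------------------
# per-feature counting


def feature_table(introns, transcripts) -> pd.DataFrame:
    """Flatten introns and transcript exon-unions into a feature interval table.

    One row per sub-interval; feature_id repeats for multi-interval features.
    Intron features are the masked sub-intervals; each transcript's exonic
    feature is the union of its exons, treated as one feature spanning the
    entire annotated transcript.
    """
    rows = []
    for rec in introns:
        for s, e in rec.masked_intervals:
            rows.append((rec.intron_id, "intron", rec.chrom, s, e,
                         rec.masked_length))
    for t in transcripts:
        length = t.exon_length()
        for s, e in merged_exons(t):
            rows.append((t.transcript_id, "exon", t.chrom, s, e, length))
    return pd.DataFrame(
        rows, columns=["feature_id", "kind", "chrom", "start", "end", "length"]
    )


def count_feature_reads(features: pd.DataFrame,
                        weighted_reads: pd.DataFrame) -> pd.Series:
    """Weighted read count per feature.

    A read contributes its intronic weight to every intron feature it
    overlaps and its exonic weight to every transcript feature it overlaps;
    a read spanning several sub-intervals of one feature counts once.
    """
    counts = pd.Series(0.0, index=pd.unique(features["feature_id"]))
    for chrom, feats in features.groupby("chrom", sort=False):
        sel = weighted_reads["chrom"].to_numpy() == chrom
        if not sel.any():
            continue
        sub = weighted_reads.loc[sel]
        q_idx, f_idx = overlap_join(
            sub["start"].to_numpy(), sub["end"].to_numpy(),
            feats["start"].to_numpy(), feats["end"].to_numpy())
        if len(q_idx) == 0:
            continue
        hits = pd.DataFrame({
            "read": q_idx,
            "feature_id": feats["feature_id"].to_numpy()[f_idx],
            "kind": feats["kind"].to_numpy()[f_idx],
        }).drop_duplicates()
        w = np.where(
            hits["kind"].to_numpy() == "intron",
            sub["w_intron"].to_numpy()[hits["read"].to_numpy()],
            sub["w_exon"].to_numpy()[hits["read"].to_numpy()],
        )
        add = pd.Series(w).groupby(hits["feature_id"].to_numpy()).sum()
        counts = counts.add(add, fill_value=0.0)
    return counts


@dataclass
class DensityTable:
    """Per-feature x per-sample raw weighted counts and normalized densities.

    density = raw / (length / 1000) / (informative / 1e7)
    """

    raw: pd.DataFrame
    density: pd.DataFrame
    lengths: pd.Series
    informative: pd.Series

    def subset(self, feature_ids):
        return DensityTable(
            self.raw.loc[feature_ids], self.density.loc[feature_ids],
            self.lengths.loc[feature_ids], self.informative)


def compute_density(features: pd.DataFrame, reads_by_sample: dict,
                    informative_counts: dict) -> DensityTable:
    """Build the density table over all samples.

    ``reads_by_sample`` maps sample_id to a weighted read DataFrame (from
    :func:`assign_read_weights`); ``informative_counts`` maps sample_id to
    its informative read count, which must be positive.
    """
    lengths = features.drop_duplicates("feature_id").set_index("feature_id")["length"]
    raw_cols = {}
    for sample_id, reads in reads_by_sample.items():
        inf = informative_counts[sample_id]
        if inf <= 0:
            raise ValueError(f"sample {sample_id}: informative count is 0, "
                             "cannot normalize densities")
        raw_cols[sample_id] = count_feature_reads(features, reads).reindex(
            lengths.index, fill_value=0.0)
    raw = pd.DataFrame(raw_cols)
    inf = pd.Series(informative_counts).reindex(raw.columns).astype(float)
    density = raw.div(lengths / DENSITY_SCALE_LENGTH, axis=0).div(
        inf / DENSITY_SCALE_READS, axis=1)
    return DensityTable(raw, density, lengths, inf)


# ---------------------------------------------------------------------------
# read-distribution accounting


def read_distribution_row(informative: float, exonic: float, intronic: float,
                          intergenic: float) -> dict:
    """Derived percentages for one row of the read-distribution table.

    Given the informative read count and its (weighted) exonic / intronic /
    intergenic components, returns the percentages the summary table prints,
    rounded to 1 decimal place: % non-exonic, % intronic of informative,
    % intronic as a fraction of non-exonic, and % intergenic.
    """
    non_exonic = informative - exonic
    return {
        "pct_non_exonic": round(100.0 * non_exonic / informative, 1),
        "pct_intronic": round(100.0 * intronic / informative, 1),
        "pct_intronic_of_non_exonic": round(100.0 * intronic / non_exonic, 1)
        if non_exonic > 0 else float("nan"),
        "pct_intergenic": round(100.0 * intergenic / informative, 1),
    }


def summarize_distribution(weighted_reads_by_sample: dict, design: pd.DataFrame,
                           extra_region_sets: dict | None = None) -> pd.DataFrame:
    """Read-distribution table per timepoint (animals summed).

    Columns mirror the study's read-accounting layout: informative reads,
    weighted exonic / intronic / intergenic components with the derived
    percentages, plus the count and percentage of informative reads
    overlapping each extra region set (e.g. lincRNA intervals).
    """
    extra_region_sets = extra_region_sets or {}
    extra_unions = {name: interval_set_by_chrom(df)
                    for name, df in extra_region_sets.items()}
    per_sample = []
    for sample_id, reads in weighted_reads_by_sample.items():
        row = {
            "sample_id": sample_id,
            "informative": float(len(reads)),
            "exonic": float(reads["w_exon"].sum()),
            "intronic": float(reads["w_intron"].sum()),
            "intergenic": float(reads["w_intergenic"].sum()),
        }
        for name, union in extra_unions.items():
            hit = np.zeros(len(reads), dtype=bool)
            chroms = reads["chrom"].to_numpy()
            for chrom, (us, ue) in union.items():
                sel = chroms == chrom
                if sel.any():
                    hit[sel] = overlaps_union(
                        reads.loc[sel, "start"].to_numpy(),
                        reads.loc[sel, "end"].to_numpy(), us, ue)
            row[f"overlap_{name}"] = float(hit.sum())
        per_sample.append(row)
    df = pd.DataFrame(per_sample).merge(
        design[["sample_id", "timepoint"]], on="sample_id")
    agg = df.drop(columns="sample_id").groupby("timepoint").sum().reset_index()
    pct = agg.apply(
        lambda r: read_distribution_row(
            r["informative"], r["exonic"], r["intronic"], r["intergenic"]),
        axis=1, result_type="expand")
    out = pd.concat([agg, pct], axis=1)
    for name in extra_unions:
        out[f"pct_{name}"] = (
            100.0 * out[f"overlap_{name}"] / out["informative"]).round(1)
    return out.sort_values("timepoint").reset_index(drop=True)
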