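"""Genomic-bin differential expression with shuffle-based FDR control.

The genome is tiled with non-overlapping bins of several fixed sizes
(default 100/200/500/1000 bp).  For each bin and treatment timepoint, the
bin's read densities in the 7 treated animals are compared to the 7 control
animals with a one-tailed paired Student's t-test (pairing by animal index),
in the direction of the observed fold change.  A bin is differentially
expressed (DE) when the fold change between mean densities exceeds 2x and
p < 0.001.

When one group is all zeros, 0.5 read is added to one animal and 0.5 read
subtracted from another of that group before density and t computation, so
that the test is defined; the group mean stays zero and the fold change
becomes infinite in the appropriate direction.

Calls from different bin sizes are merged with a smaller-bin-wins rule, and
a within-animal shuffle of bin values provides an empirical estimate of the
false discovery rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._intervals import merge_intervals, overlap_join, overlaps_union
from .quantify import DENSITY_SCALE_LENGTH, DENSITY_SCALE_READS, AnnotationIndex

log = logging.getLogger(__name__)

DEFAULT_BIN_SIZES = (100, 200, 500, 1000)


@dataclass
class DEConfig:
    fold_threshold: float = 2.0
    p_threshold: float = 0.001
    zero_adjust: float = 0.5          # reads
    exon_fold_threshold: float = 2.0 ** 0.5   # 1.414
    exon_p_threshold: float = 0.01
    sizes: tuple = DEFAULT_BIN_SIZES
    control_timepoint: int = 0

    def __post_init__(self):
        for name in ("fold_threshold", "p_threshold", "zero_adjust",
                     "exon_fold_threshold", "exon_p_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


# ---------------------------------------------------------------------------
# bin grids and counting


def make_bin_grid(chrom_sizes: dict, sizes=DEFAULT_BIN_SIZES) -> dict:
    """Non-overlapping tilings of every chromosome, one grid per bin size.

    Returns {size: DataFrame(chrom, start, end)} with deterministic row
    order (chromosomes sorted by name, bins left to right); the last bin of
    a chromosome may be short.
    """
    sizes = tuple(sizes)
    if any(s <= 0 for s in sizes) or list(sizes) != sorted(sizes):
        raise ValueError("bin sizes must be positive and ascending")
    grids = {}
    for size in sizes:
        frames = []
        for chrom in sorted(chrom_sizes):
            length = int(chrom_sizes[chrom])
            starts = np.arange(0, length, size, dtype=np.int64)
            ends = np.minimum(starts + size, length)
            frames.append(pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends}))
        grids[size] = (pd.concat(frames, ignore_index=True) if frames
                       else pd.DataFrame(columns=["chrom", "start", "end"]))
    return grids


def count_reads_in_bins(reads_by_sample: dict, grid: pd.DataFrame,
                        size: int) -> pd.DataFrame:
    """Read counts per bin (rows follow the grid) per sample.

    Each read is assigned to the single bin containing its midpoint, which
    keeps counts integral and conserves the total.
    """
    offsets = {}
    cursor = 0
    chrom_nbins = {}
    for chrom, sub in grid.groupby("chrom", sort=False):
        offsets[chrom] = cursor
        chrom_nbins[chrom] = len(sub)
        cursor += len(sub)
    n_bins = cursor
    cols = {}
    for sample_id, reads in reads_by_sample.items():
        vec = np.zeros(n_bins, dtype=np.int64)
        chroms = reads["chrom"].to_numpy()
        mid = (reads["start"].to_numpy() + reads["end"].to_numpy()) // 2
        for chrom, off in offsets.items():
            sel = chroms == chrom
            if not sel.any():
                continue
            idx = mid[sel] // size
            idx = idx[idx < chrom_nbins[chrom]]
            vec[off:off + chrom_nbins[chrom]] += np.bincount(
                idx, minlength=chrom_nbins[chrom])
        cols[sample_id] = vec
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# the paired test


def zero_adjust_counts(counts: np.ndarray, adjust: float = 0.5) -> np.ndarray:
    """Apply the all-zero-group rule to a (n_bins, n_animals) count matrix.

    Rows that are entirely zero get +adjust in the first animal and -adjust
    in the second, leaving the row mean at zero but giving the t-test a
    non-degenerate difference vector.
    """
    counts = np.asarray(counts, dtype=float)
    out = counts.copy()
    allzero = (counts == 0).all(axis=1)
    out[allzero, 0] += adjust
    out[allzero, 1] -= adjust
    return out


def _densities(counts, informative, bin_length):
    scale = (bin_length / DENSITY_SCALE_LENGTH) * (
        np.asarray(informative, dtype=float) / DENSITY_SCALE_READS)
    return np.asarray(counts, dtype=float) / scale


def de_test_matrix(treated_counts, control_counts, informative_treated,
                   informative_control, bin_length, cfg: DEConfig) -> pd.DataFrame:
    """Vectorized paired DE test over a matrix of bins.

    ``treated_counts`` and ``control_counts`` are (n_bins, n_animals) count
    matrices with columns aligned by animal index; ``informative_*`` are the
    per-animal informative read counts used for density normalization.

    Returns a DataFrame with fold (mean treated density / mean control
    density), t, one-tailed p in the observed direction, direction (+1 up,
    -1 down, 0 none), and the DE call combining the fold and p thresholds.
    """
    T = zero_adjust_counts(treated_counts, cfg.zero_adjust)
    C = zero_adjust_counts(control_counts, cfg.zero_adjust)
    both_zero = ((np.asarray(treated_counts) == 0).all(axis=1)
                 & (np.asarray(control_counts) == 0).all(axis=1))
    DT = _densities(T, informative_treated, bin_length)
    DC = _densities(C, informative_control, bin_length)
    n = DT.shape[1]
    diffs = DT - DC
    md = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = md / (sd / np.sqrt(n))
    # sd == 0: identical diffs; md != 0 -> infinitely significant, else no test
    with np.errstate(invalid="ignore"):
        t = np.where(sd == 0, np.where(md == 0, 0.0, np.sign(md) * np.inf), t)
    p = stats.t.sf(np.abs(t), df=n - 1)
    p = np.where((sd == 0) & (md == 0), 1.0, p)
    mt, mc = DT.mean(axis=1), DC.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fold = np.where(mc > 0, mt / mc, np.where(mt > 0, np.inf, 1.0))
    direction = np.sign(md).astype(int)
    up = (direction > 0) & (fold > cfg.fold_threshold) & (p < cfg.p_threshold)
    down = (direction < 0) & (fold < 1.0 / cfg.fold_threshold) & (
        p < cfg.p_threshold)
    out = pd.DataFrame({
        "fold": fold, "t": t, "p": p, "direction": direction,
        "is_de": up | down,
    })
    out.loc[both_zero, ["p", "fold", "direction", "is_de"]] = [1.0, 1.0, 0,
                                                               False]
    return out


def de_test(treated_counts, control_counts, informative_treated,
            informative_control, bin_length, cfg: DEConfig | None = None):
    """Single-bin convenience wrapper: returns (fold, p, direction or None).

    ``direction`` is "up"/"down" when the bin passes both the fold and the
    p-value criterion, otherwise None.
    """
    cfg = cfg or DEConfig()
    res = de_test_matrix(
        np.asarray(treated_counts, float)[None, :],
        np.asarray(control_counts, float)[None, :],
        informative_treated, informative_control, bin_length, cfg).iloc[0]
    direction = None
    if res["is_de"]:
        direction = "up" if res["direction"] > 0 else "down"
    return float(res["fold"]), float(res["p"]), direction


# ---------------------------------------------------------------------------
# genome scan, merging, annotation


def scan_de_bins(bin_counts: dict, grids: dict, design: pd.DataFrame,
                 informative_counts: dict, cfg: DEConfig) -> pd.DataFrame:
    """Run the DE test for every bin size and treatment timepoint.

    ``bin_counts`` maps size -> DataFrame of per-bin counts with one column
    per sample (rows follow the grid of that size).  Returns the DE calls
    (one row per significant bin) across sizes and timepoints.
    """
    design = design.sort_values(["timepoint", "animal"])
    control = design[design["timepoint"] == cfg.control_timepoint]
    if control.empty:
        raise ValueError("no control samples at the control timepoint")
    ctrl_ids = control["sample_id"].tolist()
    results = []
    for size, counts in bin_counts.items():
        grid = grids[size]
        C = counts[ctrl_ids].to_numpy()
        inf_c = [informative_counts[s] for s in ctrl_ids]
        for tp, group in design[design["timepoint"]
                                != cfg.control_timepoint].groupby("timepoint"):
            ids = group["sample_id"].tolist()
            T = counts[ids].to_numpy()
            inf_t = [informative_counts[s] for s in ids]
            res = de_test_matrix(T, C, inf_t, inf_c, size, cfg)
            hits = res.index[res["is_de"]]
            if len(hits) == 0:
                continue
            sub = grid.iloc[hits].reset_index(drop=True)
            sub["size"] = size
            sub["timepoint"] = int(tp)
            sub["direction"] = np.where(
                res.loc[hits, "direction"].to_numpy() > 0, "up", "down")
            sub["fold"] = res.loc[hits, "fold"].to_numpy()
            sub["p"] = res.loc[hits, "p"].to_numpy()
            results.append(sub)
    cols = ["chrom", "start", "end", "size", "timepoint", "direction",
            "fold", "p"]
    if not results:
        return pd.DataFrame(columns=cols)
    return pd.concat(results, ignore_index=True)[cols]


def merge_de_bins(de_bins: pd.DataFrame) -> pd.DataFrame:
    """Smaller-bin-wins merge across sizes.

    Within each (timepoint, direction), any DE bin overlapped by a DE bin of
    a strictly smaller size is dropped; smaller bins always survive.  The
    operation is idempotent.
    """
    if de_bins.empty:
        return de_bins.copy()
    keep_frames = []
    for (tp, direction), sub in de_bins.groupby(["timepoint", "direction"]):
        sizes = sorted(sub["size"].unique())
        for i, size in enumerate(sizes):
            cur = sub[sub["size"] == size]
            if i == 0:
                keep_frames.append(cur)
                continue
            smaller = sub[sub["size"] < size]
            union = {
                chrom: merge_intervals(g["start"].to_numpy(),
                                       g["end"].to_numpy())
                for chrom, g in smaller.groupby("chrom")
            }
            drop = np.zeros(len(cur), dtype=bool)
            for chrom, (us, ue) in union.items():
                sel = cur["chrom"].to_numpy() == chrom
                if sel.any():
                    drop[sel] = overlaps_union(
                        cur["start"].to_numpy()[sel],
                        cur["end"].to_numpy()[sel], us, ue)
            keep_frames.append(cur.loc[~drop])
    out = pd.concat(keep_frames, ignore_index=True)
    return out.sort_values(["timepoint", "direction", "chrom", "start",
                            "size"]).reset_index(drop=True)


def annotate_de_bins(merged: pd.DataFrame, index: AnnotationIndex,
                     extra_sets: dict | None = None) -> pd.DataFrame:
    """Assign each DE bin a mutually exclusive genomic category.

    Categories: exonic / exon+intron / intronic / intergenic, by any-overlap
    of the bin with the exon union and the masked-intron union.  Each extra
    interval set (supplied as {name: union-by-chrom-ready DataFrame with
    chrom/start/end}) adds a non-exclusive boolean overlap column.
    """
    from ._intervals import interval_set_by_chrom

    out = merged.copy()
    n = len(out)
    in_exon = np.zeros(n, dtype=bool)
    in_intron = np.zeros(n, dtype=bool)
    chroms = out["chrom"].to_numpy()
    starts = out["start"].to_numpy()
    ends = out["end"].to_numpy()
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        if chrom in index.exon_union:
            us, ue = index.exon_union[chrom]
            in_exon[sel] = overlaps_union(starts[sel], ends[sel], us, ue)
        if chrom in index.intron_union:
            us, ue = index.intron_union[chrom]
            in_intron[sel] = overlaps_union(starts[sel], ends[sel], us, ue)
    category = np.where(
        in_exon & in_intron, "exon+intron",
        np.where(in_exon, "exonic",
                 np.where(in_intron, "intronic", "intergenic")))
    out["category"] = category
    for name, regions in (extra_sets or {}).items():
        union = interval_set_by_chrom(regions)
        hit = np.zeros(n, dtype=bool)
        for chrom, (us, ue) in union.items():
            sel = chroms == chrom
            if sel.any():
                hit[sel] = overlaps_union(starts[sel], ends[sel], us, ue)
        out[f"overlap_{name}"] = hit
    return out


def de_category_table(annotated: pd.DataFrame) -> pd.DataFrame:
    """Per (timepoint, direction): category counts and percentages of total.

    Percentages are printed to 2 decimal places; the four exclusive
    categories sum to 100%.  Extra-set overlap columns become non-exclusive
    sub-rows.
    """
    extra_cols = [c for c in annotated.columns if c.startswith("overlap_")]
    rows = []
    for (tp, direction), sub in annotated.groupby(["timepoint", "direction"]):
        total = len(sub)
        row = {"timepoint": tp, "direction": direction, "total": total}
        for cat in ("exonic", "exon+intron", "intronic", "intergenic"):
            c = int((sub["category"] == cat).sum())
            row[cat] = c
            row[f"pct_{cat}"] = de_bin_percentage(c, total)
        for col in extra_cols:
            c = int(sub[col].sum())
            row[col] = c
            row[f"pct_{col}"] = de_bin_percentage(c, total)
        rows.append(row)
    return pd.DataFrame(rows)


def de_bin_percentage(count: float, total: float) -> float:
    """A DE-bin table percentage, printed to 2 decimal places."""
    return round(100.0 * count / total, 2) if total else float("nan")


# ---------------------------------------------------------------------------
# shuffle FDR control


def shuffle_control(treated_counts, control_counts, informative_treated,
                    informative_control, bin_length, cfg: DEConfig,
                    seed, n_rounds: int = 1) -> dict:
    """Within-animal shuffle estimate of the false discovery rate.

    The bins are restricted (by the caller or here) to rows with at least
    one non-zero value.  For each round, every animal's column of bin
    values (treated and control alike) is independently permuted with a
    seeded RNG, and the number of bins with one-tailed paired t p below the
    threshold is recounted.  Returns the before-count, the per-round after
    counts, and the before/mean(after) ratio.
    """
    T = np.asarray(treated_counts, dtype=float)
    C = np.asarray(control_counts, dtype=float)
    expressed = (T != 0).any(axis=1) | (C != 0).any(axis=1)
    T, C = T[expressed], C[expressed]
    rng = np.random.default_rng(seed)
    before = int((de_test_matrix(T, C, informative_treated,
                                 informative_control, bin_length, cfg)["p"]
                  < cfg.p_threshold).sum())
    after = []
    for _ in range(n_rounds):
        Ts = np.column_stack([rng.permutation(T[:, j])
                              for j in range(T.shape[1])])
        Cs = np.column_stack([rng.permutation(C[:, j])
                              for j in range(C.shape[1])])
        after.append(int((de_test_matrix(
            Ts, Cs, informative_treated, informative_control, bin_length,
            cfg)["p"] < cfg.p_threshold).sum()))
    mean_after = float(np.mean(after))
    ratio = float("inf") if mean_after == 0 else before / mean_after
    return {"n_bins": int(T.shape[0]), "n_pass_before": before,
            "n_pass_after": after, "ratio": ratio}


# ---------------------------------------------------------------------------
# exon-change filter and tallies


def exon_level_de(exon_counts: pd.DataFrame, exon_transcripts: pd.Series,
                  design: pd.DataFrame, informative_counts: dict,
                  cfg: DEConfig) -> pd.DataFrame:
    """Per-exon DE tests at the relaxed exon thresholds.

    ``exon_counts`` has one row per individual exon (any index), columns per
    sample; ``exon_transcripts`` is an aligned Series giving each exon's
    host transcript.  Returns the (transcript, timepoint, direction) triples
    for which at least one exon is DE at fold > exon_fold_threshold and
    p < exon_p_threshold.
    """
    design = design.sort_values(["timepoint", "animal"])
    ctrl = design[design["timepoint"] == cfg.control_timepoint]
    ctrl_ids = ctrl["sample_id"].tolist()
    C = exon_counts[ctrl_ids].to_numpy()
    inf_c = [informative_counts[s] for s in ctrl_ids]
    rows = []
    exon_cfg = DEConfig(fold_threshold=cfg.exon_fold_threshold,
                        p_threshold=cfg.exon_p_threshold,
                        zero_adjust=cfg.zero_adjust,
                        control_timepoint=cfg.control_timepoint)
    for tp, group in design[design["timepoint"]
                            != cfg.control_timepoint].groupby("timepoint"):
        ids = group["sample_id"].tolist()
        T = exon_counts[ids].to_numpy()
        inf_t = [informative_counts[s] for s in ids]
        # per-row exon length scales treated and control densities by the
        # same factor, so fold / t / p are length-invariant; unit length works
        res = de_test_matrix(T, C, inf_t, inf_c, 1.0, exon_cfg)
        sub = pd.DataFrame({
            "transcript_id": exon_transcripts.to_numpy(),
            "timepoint": int(tp),
            "direction": np.where(res["direction"] > 0, "up", "down"),
            "is_de": res["is_de"].to_numpy(),
        })
        rows.append(sub[sub["is_de"]])
    if not rows:
        return pd.DataFrame(columns=["transcript_id", "timepoint",
                                     "direction"])
    out = pd.concat(rows, ignore_index=True)
    return out[["transcript_id", "timepoint", "direction"]].drop_duplicates()


def map_bins_to_introns(bins: pd.DataFrame, introns) -> pd.DataFrame:
    """Overlap join of bins with masked intron sub-intervals.

    Returns one row per (bin row index, intron_id) overlap.
    """
    sub = pd.DataFrame(
        [(rec.chrom, s, e, rec.intron_id)
         for rec in introns for s, e in rec.masked_intervals],
        columns=["chrom", "start", "end", "intron_id"])
    hits = []
    for chrom, feats in sub.groupby("chrom", sort=False):
        sel = np.flatnonzero(bins["chrom"].to_numpy() == chrom)
        if sel.size == 0:
            continue
        q_idx, f_idx = overlap_join(
            bins["start"].to_numpy()[sel], bins["end"].to_numpy()[sel],
            feats["start"].to_numpy(), feats["end"].to_numpy())
        if len(q_idx):
            hits.append(pd.DataFrame({
                "bin_index": sel[q_idx],
                "intron_id": feats["intron_id"].to_numpy()[f_idx],
            }).drop_duplicates())
    if not hits:
        return pd.DataFrame(columns=["bin_index", "intron_id"])
    return pd.concat(hits, ignore_index=True).drop_duplicates()


def intronic_de_without_exon_change(annotated: pd.DataFrame, introns,
                                    exon_de: pd.DataFrame) -> pd.DataFrame:
    """Intronic DE bins whose host gene shows no exon change.

    An intronic bin at (timepoint, direction) is removed when ANY transcript
    harboring the overlapped intron(s) has at least one exon DE in the same
    direction at the same timepoint (relaxed exon thresholds); an intronic
    up-bin in a gene with only a down-regulated exon is retained.
    """
    intronic = annotated[annotated["category"] == "intronic"].reset_index(
        drop=True)
    if intronic.empty:
        return intronic
    bin_introns = map_bins_to_introns(intronic, introns)
    intron_parents = {rec.intron_id: rec.parent_transcripts for rec in introns}
    de_keys = set(map(tuple, exon_de[["transcript_id", "timepoint",
                                      "direction"]].to_numpy()))
    drop = np.zeros(len(intronic), dtype=bool)
    for bin_idx, group in bin_introns.groupby("bin_index"):
        tp = intronic.loc[bin_idx, "timepoint"]
        direction = intronic.loc[bin_idx, "direction"]
        for intron_id in group["intron_id"]:
            if any((t, tp, direction) in de_keys
                   for t in intron_parents[intron_id]):
                drop[bin_idx] = True
                break
    return intronic.loc[~drop].reset_index(drop=True)


def tally_de_overlap(intronic_bins: pd.DataFrame, introns,
                     transcripts) -> pd.DataFrame:
    """Counts of intronic DE bins and the introns/transcripts/loci they hit.

    One row per (timepoint, direction) plus a "union" row counting features
    hit in ANY timepoint/direction.
    """
    tx_locus = {t.transcript_id: t.locus_id for t in transcripts}
    intron_parents = {rec.intron_id: rec.parent_transcripts for rec in introns}
    bin_introns = map_bins_to_introns(intronic_bins.reset_index(drop=True),
                                      introns)

    def _tally(bin_idx):
        hit_introns = set(
            bin_introns.loc[bin_introns["bin_index"].isin(bin_idx),
                            "intron_id"])
        hit_tx = {t for i in hit_introns for t in intron_parents[i]}
        hit_loci = {tx_locus[t] for t in hit_tx if tx_locus.get(t)}
        return len(hit_introns), len(hit_tx), len(hit_loci)

    rows = []
    idx = intronic_bins.reset_index(drop=True)
    for (tp, direction), sub in idx.groupby(["timepoint", "direction"]):
        n_i, n_t, n_l = _tally(set(sub.index))
        rows.append({"timepoint": tp, "direction": direction,
                     "n_bins": len(sub), "n_introns": n_i,
                     "n_transcripts": n_t, "n_loci": n_l})
    n_i, n_t, n_l = _tally(set(idx.index))
    rows.append({"timepoint": "all", "direction": "any",
                 "n_bins": len(idx), "n_introns": n_i, "n_transcripts": n_t,
                 "n_loci": n_l})
    return pd.DataFrame(rows)


def write_de_bins_bed(de_bins: pd.DataFrame, path) -> None:
    """BED6+: name = size/direction, score = -log10 p (capped at 1000)."""
    with open(path, "w") as fh:
        for _, r in de_bins.iterrows():
            score = 1000.0 if r["p"] <= 0 else min(1000.0, -np.log10(r["p"]))
            fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\t"
                     f"{r['size']}/{r['direction']}\t{score:.1f}\t.\n")
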