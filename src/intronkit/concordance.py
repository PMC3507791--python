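"""Exon/intron concordance statistics over the animal x timepoint design.

Every intron is compared to the exonic density of each transcript that
harbors it: an intron appearing in k annotated isoforms yields k
intron-exon pairs.  The module computes

* the pooled pairwise dataset (every pair x sample a data point) and the
  time-course dataset (42-sample series per pair),
* Spearman rank correlations per pair and their histogram,
* per-intron min/max correlation against sibling introns of the same
  transcript,
* intron abundance ratios (max/min within a transcript; max intron/exon
  ratio over all samples), and
* per-timepoint coefficients of variation across the replicate animals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import DensityTable

log = logging.getLogger(__name__)

RATIO_STRATA = (">10", "2-10", "1-2", ">=1")


def pair_table(introns) -> pd.DataFrame:
    """One row per (intron, parent transcript) combination."""
    rows = [(rec.intron_id, t) for rec in introns for t in rec.parent_transcripts]
    return pd.DataFrame(rows, columns=["intron_id", "transcript_id"])


@dataclass
class PairMatrices:
    """Aligned per-pair density matrices (rows = pairs, cols = samples)."""

    pairs: pd.DataFrame          # intron_id, transcript_id
    intron: np.ndarray           # n_pairs x n_samples densities
    exon: np.ndarray
    samples: pd.DataFrame        # sample_id, timepoint, animal (column order)

    def __len__(self):
        return len(self.pairs)

    def take(self, row_mask):
        return PairMatrices(
            self.pairs.loc[row_mask].reset_index(drop=True),
            self.intron[np.asarray(row_mask)],
            self.exon[np.asarray(row_mask)],
            self.samples,
        )


def pair_matrices(pairs: pd.DataFrame, dens: DensityTable,
                  design: pd.DataFrame) -> PairMatrices:
    """Assemble intron and exon density matrices in (timepoint, animal) order."""
    samples = design.sort_values(["timepoint", "animal"]).reset_index(drop=True)
    sample_ids = samples["sample_id"].tolist()
    intron = dens.density.loc[pairs["intron_id"], sample_ids].to_numpy(float)
    exon = dens.density.loc[pairs["transcript_id"], sample_ids].to_numpy(float)
    return PairMatrices(pairs.reset_index(drop=True), intron, exon, samples)


def _top_half_threshold(values: np.ndarray, top_fraction: float) -> float:
    """Value cutoff keeping the top ``top_fraction`` of points, ties included."""
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    k = int(np.ceil(top_fraction * values.size))
    return float(np.sort(values)[::-1][k - 1])


def build_pairwise_dataset(pm: PairMatrices,
                           top_fraction: float = 0.5) -> pd.DataFrame:
    """The pooled dataset: one row per (pair, sample) data point.

    Points where both exonic and intronic densities are zero are removed;
    the remaining points are ranked by exonic density and the top
    ``top_fraction`` retained (boundary ties all kept).
    """
    n_pairs, n_samples = pm.intron.shape
    exon = pm.exon.ravel()
    intron = pm.intron.ravel()
    keep = ~((exon == 0) & (intron == 0))
    thr = _top_half_threshold(exon[keep], top_fraction)
    keep &= exon >= thr
    pair_idx, sample_idx = np.divmod(np.flatnonzero(keep), n_samples)
    return pd.DataFrame({
        "intron_id": pm.pairs["intron_id"].to_numpy()[pair_idx],
        "transcript_id": pm.pairs["transcript_id"].to_numpy()[pair_idx],
        "sample_id": pm.samples["sample_id"].to_numpy()[sample_idx],
        "exon_density": exon[keep],
        "intron_density": intron[keep],
    })


def build_timecourse_dataset(pm: PairMatrices,
                             top_fraction: float = 0.5) -> PairMatrices:
    """The time-course dataset: whole 42-sample series per pair.

    Pairs that are all-zero in either the exonic or the intronic series are
    removed, then the top ``top_fraction`` of pairs by average exonic
    density is retained (ties at the cutoff all kept).
    """
    nonzero = (pm.exon.sum(axis=1) > 0) & (pm.intron.sum(axis=1) > 0)
    pm = pm.take(nonzero)
    mean_exon = pm.exon.mean(axis=1)
    thr = _top_half_threshold(mean_exon, top_fraction)
    return pm.take(mean_exon >= thr)


# ---------------------------------------------------------------------------
# Spearman machinery


def spearman_rank(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("series must have equal length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant series: Spearman correlation is undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def _rowwise_spearman(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized per-row Spearman; rows with a constant series give NaN."""
    ra = stats.rankdata(a, axis=1)
    rb = stats.rankdata(b, axis=1)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    denom = np.sqrt((ra * ra).sum(axis=1) * (rb * rb).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, (ra * rb).sum(axis=1) / denom, np.nan)


def timecourse_correlation(tc: PairMatrices) -> pd.DataFrame:
    """Per-pair Spearman rho of intron vs exon series across all samples.

    Pairs with a constant series are excluded (rho undefined) and logged.
    """
    rho = _rowwise_spearman(tc.intron, tc.exon)
    out = tc.pairs.copy()
    out["rho"] = rho
    n_excluded = int(np.isnan(rho).sum())
    if n_excluded:
        log.info("timecourse_correlation: %d constant-series pairs excluded",
                 n_excluded)
    return out.dropna(subset=["rho"]).reset_index(drop=True)


def correlation_histogram(rhos) -> pd.DataFrame:
    """Counts and percentages in the narrative rho bins.

    Bins: rho <= 0 (negative or zero), 0 < rho < 0.2 (positive but weak),
    0.2 <= rho <= 0.5 (moderate), rho > 0.5 (relatively strong).
    """
    rhos = np.asarray(rhos, dtype=float)
    total = rhos.size
    counts = {
        "rho<=0": int((rhos <= 0).sum()),
        "0<rho<0.2": int(((rhos > 0) & (rhos < 0.2)).sum()),
        "0.2<=rho<=0.5": int(((rhos >= 0.2) & (rhos <= 0.5)).sum()),
        "rho>0.5": int((rhos > 0.5).sum()),
    }
    df = pd.DataFrame({"bin": list(counts), "count": list(counts.values())})
    df["pct"] = (100.0 * df["count"] / total).round(1)
    return df


def intron_intron_extremes(tc: PairMatrices, rho_exon: pd.DataFrame,
                           top_fraction: float = 0.5,
                           strat_bin_width: float = 0.1) -> pd.DataFrame:
    """Min/max Spearman of each intron against its sibling introns.

    Transcripts are first filtered to the top ``top_fraction`` by maximum
    intronic density in any sample (to avoid spurious low correlations from
    near-silent introns); transcripts with fewer than two introns are
    skipped.  Each intron's extremes are stratified by the bin of its own
    exon correlation (width ``strat_bin_width``, the histogram granularity).
    """
    max_per_pair = tc.intron.max(axis=1)
    tx_max = pd.Series(max_per_pair).groupby(
        tc.pairs["transcript_id"].to_numpy()).max()
    thr = _top_half_threshold(tx_max.to_numpy(), top_fraction)
    kept_tx = set(tx_max.index[tx_max.to_numpy() >= thr])

    rho_lookup = rho_exon.set_index(["intron_id", "transcript_id"])["rho"]
    rows = []
    by_tx = tc.pairs.groupby("transcript_id", sort=False).indices
    for tx, idx in by_tx.items():
        if tx not in kept_tx or len(idx) < 2:
            continue
        series = tc.intron[idx]
        ranks = stats.rankdata(series, axis=1)
        centered = ranks - ranks.mean(axis=1, keepdims=True)
        norms = np.sqrt((centered * centered).sum(axis=1))
        valid = norms > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (centered @ centered.T) / np.outer(norms, norms)
        for i in range(len(idx)):
            if not valid[i]:
                continue
            others = [j for j in range(len(idx)) if j != i and valid[j]]
            if not others:
                continue
            vals = corr[i, others]
            intron_id = tc.pairs["intron_id"].iloc[idx[i]]
            key = (intron_id, tx)
            exon_rho = rho_lookup.get(key, np.nan)
            rows.append({
                "intron_id": intron_id,
                "transcript_id": tx,
                "min_rho": float(vals.min()),
                "max_rho": float(vals.max()),
                "mean_rho": float(vals.mean()),
                "exon_rho": exon_rho,
                "exon_rho_bin": np.nan if np.isnan(exon_rho)
                else np.floor(exon_rho / strat_bin_width) * strat_bin_width,
            })
    return pd.DataFrame(rows, columns=[
        "intron_id", "transcript_id", "min_rho", "max_rho", "mean_rho",
        "exon_rho", "exon_rho_bin"])


# ---------------------------------------------------------------------------
# abundance ratios


@dataclass
class RatioMetrics:
    maxmin: pd.DataFrame        # transcript_id, timepoint, maxmin_ratio
    pair_max_ratio: pd.DataFrame  # intron_id, transcript_id, max_ie_ratio,
    # mean_ie_ratio
    intron_max_ratio: pd.Series   # per unique intron, max over its pairs
    intron_mean_ratio: pd.Series  # per unique intron, max of per-pair means
    pair_rel_min: pd.DataFrame    # intron_id, transcript_id, rel_min_ratio


def intron_ratio_metrics(pm: PairMatrices) -> RatioMetrics:
    """Within-transcript max/min intron ratios and intron/exon ratios.

    ``maxmin``: per transcript (>=2 introns) and timepoint, the ratio of the
    highest to the lowest per-timepoint mean intron density (mean over the
    replicate animals); transcripts whose minimum is zero at a timepoint are
    excluded there.  ``pair_rel_min``: per pair, the intron's per-timepoint
    mean density relative to the transcript's minimum intron density,
    maximized over timepoints (the criterion-3 statistic).
    ``max_ie_ratio``: per pair, the maximum over all samples of intron
    density / exon density (samples with zero exon and zero intron density
    are ignored; zero exon with positive intron gives an infinite ratio);
    ``mean_ie_ratio`` is the average of the defined per-sample ratios.
    """
    tps = pm.samples["timepoint"].to_numpy()
    uniq_tps = np.unique(tps)
    # per-timepoint means over animals
    tp_mean = np.stack([pm.intron[:, tps == t].mean(axis=1) for t in uniq_tps],
                       axis=1)  # n_pairs x n_tp
    rows, rel_rows = [], []
    for tx, idx in pm.pairs.groupby("transcript_id", sort=False).indices.items():
        if len(idx) < 2:
            continue
        sub = tp_mean[idx]          # introns x timepoints
        lo = sub.min(axis=0)
        hi = sub.max(axis=0)
        for j, t in enumerate(uniq_tps):
            if lo[j] <= 0:
                continue
            rows.append({"transcript_id": tx, "timepoint": int(t),
                         "maxmin_ratio": float(hi[j] / lo[j])})
        ok = lo > 0
        if ok.any():
            rel = (sub[:, ok] / lo[ok]).max(axis=1)
            for i, r in zip(idx, rel):
                rel_rows.append({
                    "intron_id": pm.pairs["intron_id"].iloc[i],
                    "transcript_id": tx, "rel_min_ratio": float(r)})
    maxmin = pd.DataFrame(rows, columns=["transcript_id", "timepoint",
                                         "maxmin_ratio"])
    pair_rel_min = pd.DataFrame(rel_rows, columns=["intron_id",
                                                   "transcript_id",
                                                   "rel_min_ratio"])

    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = pm.intron / pm.exon
    ratio[(pm.exon == 0) & (pm.intron == 0)] = np.nan
    ratio[(pm.exon == 0) & (pm.intron > 0)] = np.inf
    with np.errstate(invalid="ignore"):
        max_ratio = np.nanmax(np.where(np.isnan(ratio), -np.inf, ratio), axis=1)
        mean_ratio = np.nanmean(ratio, axis=1)
    max_ratio[np.isneginf(max_ratio)] = np.nan
    pair_max = pm.pairs.copy()
    pair_max["max_ie_ratio"] = max_ratio
    pair_max["mean_ie_ratio"] = mean_ratio
    pair_max = pair_max.dropna(subset=["max_ie_ratio"]).reset_index(drop=True)
    intron_max = pair_max.groupby("intron_id")["max_ie_ratio"].max()
    intron_mean = pair_max.groupby("intron_id")["mean_ie_ratio"].max()
    return RatioMetrics(maxmin, pair_max, intron_max, intron_mean,
                        pair_rel_min)


def ratio_strata_table(intron_max_ratio: pd.Series,
                       annotated_introns: set) -> pd.DataFrame:
    """Stratify introns at >=1x intron/exon ratio by annotation status.

    Strata partition the >=1 group: (10, inf), (2, 10], [1, 2]; the ">=1"
    row is their union.  ``annotated_introns`` is the set of intron ids
    overlapping any known small-RNA annotation.
    """
    r = intron_max_ratio
    masks = {
        ">10": r > 10,
        "2-10": (r > 2) & (r <= 10),
        "1-2": (r >= 1) & (r <= 2),
        ">=1": r >= 1,
    }
    rows = []
    for name in RATIO_STRATA:
        ids = set(r.index[masks[name]])
        total = len(ids)
        annotated = len(ids & annotated_introns)
        un = total - annotated
        rows.append({
            "stratum": name, "total": total, "annotated": annotated,
            "unannotated": un,
            "pct_unannotated": round(100.0 * un / total, 1) if total else np.nan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# coefficient of variation


@dataclass
class CVResult:
    records: pd.DataFrame   # pair x timepoint CVs with retention flag
    intron_flags: pd.Series  # per intron: CV_intron <= CV_exon at >=1 timepoint
    n_analyzed: int          # unique introns in the retained dataset


def coefficient_of_variation(pm: PairMatrices,
                             top_fraction: float = 0.5) -> CVResult:
    """Per-timepoint CV (sample SD / mean, percent) across replicate animals.

    Because CV shrinks with abundance, low-signal combinations are removed
    before flagging: (pair, timepoint) combinations are ranked by average
    intronic density and the top ``top_fraction`` with positive average
    exonic density retained.  An intron is flagged when CV_intron <=
    CV_exon at >=1 retained timepoint; zero-mean features are excluded.
    """
    tps = pm.samples["timepoint"].to_numpy()
    uniq_tps = np.unique(tps)
    frames = []
    for t in uniq_tps:
        ii = pm.intron[:, tps == t]
        ee = pm.exon[:, tps == t]
        mi, me = ii.mean(axis=1), ee.mean(axis=1)
        sdi = ii.std(axis=1, ddof=1)
        sde = ee.std(axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cvi = np.where(mi > 0, 100.0 * sdi / mi, np.nan)
            cve = np.where(me > 0, 100.0 * sde / me, np.nan)
        df = pm.pairs.copy()
        df["timepoint"] = int(t)
        df["mean_intron"] = mi
        df["mean_exon"] = me
        df["cv_intron"] = cvi
        df["cv_exon"] = cve
        frames.append(df)
    rec = pd.concat(frames, ignore_index=True)
    eligible = rec["mean_exon"] > 0
    thr = _top_half_threshold(rec.loc[eligible, "mean_intron"].to_numpy(),
                              top_fraction)
    rec["retained"] = eligible & (rec["mean_intron"] >= thr)
    kept = rec[rec["retained"] & rec["cv_intron"].notna()
               & rec["cv_exon"].notna()]
    flag = (kept["cv_intron"] <= kept["cv_exon"]).groupby(
        kept["intron_id"].to_numpy()).any()
    n_analyzed = kept["intron_id"].nunique()
    return CVResult(rec, flag, n_analyzed)


def cv_flag_fraction(cv: CVResult) -> dict:
    """Tally: how many analyzed introns have CV <= that of their exons."""
    n_flagged = int(cv.intron_flags.sum())
    return {
        "n_analyzed": int(cv.n_analyzed),
        "n_flagged": n_flagged,
        "pct_flagged": round(100.0 * n_flagged / cv.n_analyzed, 1)
        if cv.n_analyzed else float("nan"),
    }
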