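"""Functional-intron criteria, strand classification, and enrichment.

Six criteria flag introns whose RNA behaves like a standalone transcript
rather than a pre-mRNA by-product:

1. correlation with the corresponding exons <= 0,
2. correlation with sibling introns <= -0.3,
3. density >= 10x the minimal intronic density of the transcript,
4. maximum intron/exon density ratio >= 1,
5. coefficient of variation <= that of the exons at >=1 timepoint,
6. presence of a DE bin in the intron at any timepoint.

Each criterion is evaluated on its own eligible subset: an intron with no
value for a metric is excluded from that criterion's denominator.

Strandedness of the RNA in an intron is classified against thresholds
calibrated from reads spanning annotated exon-exon junctions, where any
antisense signal must be artifactual: with mean sense fraction mu and
standard deviation sigma across samples, introns with >= (mu - sigma)%
sense reads are "sense", below the complementary threshold "antisense",
and "sense-antisense" in between.

Enrichment of a label set (e.g. snoRNA-harboring introns) among criterion
passers uses the upper tail of the hypergeometric distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

CRITERION_NAMES = (
    "c1_exon_corr", "c2_sibling_corr", "c3_min_ratio", "c4_ie_ratio",
    "c5_cv", "c6_de_bin",
)
STRAND_CLASSES = ("sense", "sense-antisense", "antisense")


@dataclass
class CriterionSpec:
    """Thresholds of the six criteria (all inclusive, as printed)."""

    c1_exon_corr_max: float = 0.0
    c2_sibling_corr_max: float = -0.3
    c3_min_ratio: float = 10.0
    c4_intron_exon_ratio_min: float = 1.0
    sibling_aggregation: str = "mean"   # mean | min | max over sibling rhos


@dataclass
class StrandCalibration:
    """Sense-fraction thresholds from junction-read calibration."""

    mu: float      # mean % sense junction reads across samples
    sigma: float   # sample SD, %

    @property
    def sense_threshold(self) -> float:
        return self.mu - self.sigma

    @property
    def antisense_threshold(self) -> float:
        return 100.0 - self.sense_threshold

    def __post_init__(self):
        if not 0 <= self.antisense_threshold < self.sense_threshold <= 100:
            raise ValueError(
                f"degenerate calibration: sense threshold "
                f"{self.sense_threshold}, antisense {self.antisense_threshold}")


def junction_calibration(junction_reads_by_sample: dict) -> StrandCalibration:
    """Estimate the artifactual antisense rate from junction-spanning reads.

    ``junction_reads_by_sample`` maps sample_id to a DataFrame with a
    boolean ``sense`` column (read strand matches the junction's transcript
    strand).  Reads spanning an exon-exon junction must come from the
    spliced sense transcript, so their antisense fraction bounds the
    library's spurious second-strand rate.  Returns mu and sigma (sample
    SD) of the per-sample sense percentage.
    """
    fractions = []
    for sample_id, df in junction_reads_by_sample.items():
        if len(df) == 0:
            continue
        fractions.append(100.0 * df["sense"].mean())
    if not fractions:
        raise ValueError("no junction reads in any sample: supply "
                         "calibration thresholds in the configuration")
    mu = float(np.mean(fractions))
    sigma = float(np.std(fractions, ddof=1)) if len(fractions) > 1 else 0.0
    return StrandCalibration(mu, sigma)


def sense_fraction(introns, reads_by_sample: dict) -> pd.Series:
    """Percent of reads in each masked intron on the parents' strand.

    Pools reads over all samples; introns with ambiguous strand ('.') or no
    overlapping reads get NaN (unclassifiable).
    """
    from ._intervals import overlap_join

    sub = pd.DataFrame(
        [(rec.chrom, s, e, rec.intron_id, rec.strand)
         for rec in introns for s, e in rec.masked_intervals
         if rec.strand in "+-"],
        columns=["chrom", "start", "end", "intron_id", "strand"])
    totals = {}
    senses = {}
    for reads in reads_by_sample.values():
        for chrom, feats in sub.groupby("chrom", sort=False):
            sel = np.flatnonzero(reads["chrom"].to_numpy() == chrom)
            if sel.size == 0:
                continue
            q_idx, f_idx = overlap_join(
                reads["start"].to_numpy()[sel], reads["end"].to_numpy()[sel],
                feats["start"].to_numpy(), feats["end"].to_numpy())
            if len(q_idx) == 0:
                continue
            hits = pd.DataFrame({
                "read": sel[q_idx],
                "intron_id": feats["intron_id"].to_numpy()[f_idx],
                "istrand": feats["strand"].to_numpy()[f_idx],
            }).drop_duplicates(["read", "intron_id"])
            rstrand = reads["strand"].to_numpy()[hits["read"].to_numpy()]
            is_sense = rstrand == hits["istrand"].to_numpy()
            grp = hits["intron_id"].to_numpy()
            t = pd.Series(1, index=grp).groupby(level=0).sum()
            s = pd.Series(is_sense.astype(int), index=grp).groupby(level=0).sum()
            for k, v in t.items():
                totals[k] = totals.get(k, 0) + int(v)
            for k, v in s.items():
                senses[k] = senses.get(k, 0) + int(v)
    idx = [rec.intron_id for rec in introns]
    out = pd.Series(np.nan, index=idx, name="sense_pct")
    for k, tot in totals.items():
        out[k] = 100.0 * senses.get(k, 0) / tot
    return out


def classify_strand(sense_pct, calibration: StrandCalibration):
    """Map sense-read percentages to strand classes.

    >= sense_threshold -> "sense"; < antisense_threshold -> "antisense";
    otherwise "sense-antisense".  NaN (no reads) -> "unclassified".
    """
    arr = np.asarray(sense_pct, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    out = np.where(
        np.isnan(arr), "unclassified",
        np.where(arr >= calibration.sense_threshold, "sense",
                 np.where(arr < calibration.antisense_threshold, "antisense",
                          "sense-antisense")))
    if scalar:
        return str(out[0])
    if isinstance(sense_pct, pd.Series):
        return pd.Series(out, index=sense_pct.index, name="strand_class")
    return out


# ---------------------------------------------------------------------------
# criteria


@dataclass
class IntronMetrics:
    """Per-intron inputs to the six criteria; NaN = metric unavailable.

    ``exon_rho``: time-course correlation with the corresponding exons (an
    intron in several transcripts contributes its value per pair; supplied
    here aggregated per intron by minimum, the pair most consistent with
    independence).  ``sibling_rho``: aggregated correlation with the other
    introns of the transcript.  ``rel_min_ratio``: the intron's density
    relative to the transcript's minimum intronic density, maximized over
    timepoints.  ``max_ie_ratio``: maximum intron/exon density ratio over
    all samples.  ``cv_flag`` / ``de_flag``: criterion-5/6 booleans, with
    pandas NA for introns outside the criterion's eligible set.
    """

    table: pd.DataFrame

    REQUIRED = ("exon_rho", "sibling_rho", "rel_min_ratio", "max_ie_ratio",
                "cv_flag", "de_flag")

    def __post_init__(self):
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise ValueError(f"metrics table missing columns {sorted(missing)}")


def apply_criteria(metrics: IntronMetrics,
                   spec: CriterionSpec | None = None) -> pd.DataFrame:
    """Evaluate the six criteria; one boolean (or NA) column per criterion.

    A criterion is NA where its metric is unavailable (the intron is not in
    that criterion's eligible subset).  ``n_criteria`` counts passes over
    evaluable criteria.
    """
    spec = spec or CriterionSpec()
    t = metrics.table
    out = pd.DataFrame(index=t.index)
    out["c1_exon_corr"] = _na_le(t["exon_rho"], spec.c1_exon_corr_max)
    out["c2_sibling_corr"] = _na_le(t["sibling_rho"], spec.c2_sibling_corr_max)
    out["c3_min_ratio"] = _na_ge(t["rel_min_ratio"], spec.c3_min_ratio)
    out["c4_ie_ratio"] = _na_ge(t["max_ie_ratio"],
                                spec.c4_intron_exon_ratio_min)
    out["c5_cv"] = t["cv_flag"].astype("boolean")
    out["c6_de_bin"] = t["de_flag"].astype("boolean")
    out["n_criteria"] = out[list(CRITERION_NAMES)].sum(axis=1).astype(int)
    return out


def _na_le(series, threshold):
    return pd.Series(
        np.where(series.isna(), pd.NA, series.to_numpy(float) <= threshold),
        index=series.index, dtype="boolean")


def _na_ge(series, threshold):
    return pd.Series(
        np.where(series.isna(), pd.NA, series.to_numpy(float) >= threshold),
        index=series.index, dtype="boolean")


def pass_at_least(flags: pd.DataFrame, k: int) -> pd.Series:
    """Introns passing at least k of the six criteria."""
    return flags["n_criteria"] >= k


def criteria_summary(flags: pd.DataFrame, strand_class: pd.Series,
                     label_set: set) -> pd.DataFrame:
    """Per-criterion tally in the layout of the enrichment table.

    For each criterion (and the >=1 / >=2 / >=3 union rows): the number of
    evaluable introns N, passers M, labeled introns n within N, labeled
    passers m, the hypergeometric upper-tail p-value, the strand-class
    composition of the passers, and the fraction with abundant antisense
    transcription (antisense + sense-antisense classes).
    """
    rows = []
    strand_class = strand_class.reindex(flags.index)

    def _row(name, evaluable, passing):
        N = int(evaluable.sum())
        M = int(passing.sum())
        labeled = flags.index.isin(list(label_set))
        n = int((evaluable & labeled).sum())
        m = int((passing & labeled).sum())
        p = hypergeom_tail(N, M, n, m) if M and N else np.nan
        cls = strand_class[passing]
        counts = {c: int((cls == c).sum()) for c in STRAND_CLASSES}
        classified = sum(counts.values())
        anti = counts["antisense"] + counts["sense-antisense"]
        rows.append({
            "criterion": name, "N": N, "M": M, "n": n, "m": m, "p": p,
            **{f"n_{c}": counts[c] for c in STRAND_CLASSES},
            "pct_antisense_or_mixed":
                round(100.0 * anti / classified, 1) if classified else np.nan,
        })

    for name in CRITERION_NAMES:
        col = flags[name]
        _row(name, col.notna(), col.fillna(False).astype(bool))
    any_eval = flags[list(CRITERION_NAMES)].notna().any(axis=1)
    for k in (1, 2, 3):
        _row(f">={k} criteria", any_eval, pass_at_least(flags, k))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# enrichment


@dataclass(frozen=True)
class EnrichmentInput:
    """The (N, M, n, m) quadruple of the hypergeometric tail.

    N: unique introns in the tested dataset; M: introns passing the
    threshold; n: introns of N overlapping the label set; m: passing
    introns overlapping the label set.
    """

    N: int
    M: int
    n: int
    m: int

    def __post_init__(self):
        if not (0 <= self.M <= self.N and 0 <= self.n <= self.N):
            raise ValueError(f"inconsistent enrichment input {self}")
        if self.m > min(self.n, self.M) or self.m < 0:
            raise ValueError(
                f"m={self.m} exceeds min(n={self.n}, M={self.M})")


def hypergeom_tail(N: int, M: int, n: int, m: int) -> float:
    """Upper tail P(X >= m) of Hypergeometric(N, n, M).

    The probability that at least m of the M selected introns are labeled,
    drawing without replacement from N introns of which n are labeled:
    sum_{i=m}^{min(n,M)} C(n,i) C(N-n, M-i) / C(N,M).  Computed through the
    log-space survival function, stable for N up to 1e6 and beyond.
    """
    inp = EnrichmentInput(N, M, n, m)
    if inp.m == 0:
        return 1.0
    # scipy's sf(k) = P(X > k); P(X >= m) = sf(m - 1)
    return float(stats.hypergeom.sf(inp.m - 1, inp.N, inp.n, inp.M))
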