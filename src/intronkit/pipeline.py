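"""End-to-end orchestration: from annotation and reads to summary tables.

:func:`analyze` is the in-memory entry point and returns every intermediate
product; :func:`run_pipeline` is the file-based wrapper that reads a
:class:`PipelineConfig`, runs the stages, and writes the table files
(intron inventory, read-distribution table, density table, concordance
statistics, DE-bin tables, shuffle report, criteria and enrichment tables).
:func:`class_recovery` and :func:`de_recovery` score a pipeline run against
the simulator's ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as ann
from . import concordance as conc
from . import criteria as crit
from . import debins, quantify

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""


@dataclass
class PipelineConfig:
    annotation_path: str = ""
    annotation_format: str = "genepred"   # genepred | bed12
    reads_dir: str = ""
    junctions_dir: str = ""
    design_path: str = ""
    exclusion_path: str = ""
    label_path: str = ""                  # BED of known small-RNA intervals
    output_dir: str = "intronkit_out"
    mito_chrom: str = "chrM"
    min_intron_length: int = ann.DEFAULT_MIN_INTRON_LENGTH
    drop_chrom_pattern: str = "_random"
    shuffle_seed: int = 0
    shuffle_rounds: int = 1
    # fallback strand calibration when no junction reads are available
    calibration_mu: float | None = None
    calibration_sigma: float | None = None
    de: debins.DEConfig = field(default_factory=debins.DEConfig)
    criteria: crit.CriterionSpec = field(default_factory=crit.CriterionSpec)

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        de_cfg = debins.DEConfig(**{
            k: tuple(v) if k == "sizes" else v
            for k, v in raw.pop("debins", {}).items()})
        cr_cfg = crit.CriterionSpec(**raw.pop("criteria", {}))
        return cls(**raw, de=de_cfg, criteria=cr_cfg)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    introns: list
    loci: list
    transcripts: list
    index: quantify.AnnotationIndex
    informative: dict
    distribution: pd.DataFrame
    dens: quantify.DensityTable
    pooled_spearman: float
    rho: pd.DataFrame
    rho_histogram: pd.DataFrame
    sibling: pd.DataFrame
    ratios: conc.RatioMetrics
    cv: conc.CVResult
    de_bins: pd.DataFrame
    de_merged: pd.DataFrame
    de_annotated: pd.DataFrame
    de_summary: pd.DataFrame
    exon_de: pd.DataFrame
    intronic_no_exon_change: pd.DataFrame
    de_tally: pd.DataFrame
    de_tally_no_exon_change: pd.DataFrame
    shuffle_report: dict
    calibration: crit.StrandCalibration | None
    sense_pct: pd.Series
    strand_class: pd.Series
    metrics: crit.IntronMetrics
    flags: pd.DataFrame
    enrichment: pd.DataFrame
    prediction_metrics: pd.DataFrame = None
    # per-intron metrics on the full (unfiltered) pair set, used for class
    # prediction so that low-expressed introns are not left unmeasured


def introns_overlapping(introns, regions: pd.DataFrame) -> set:
    """Intron ids whose masked intervals overlap any region (any-overlap)."""
    from ._intervals import interval_set_by_chrom, overlaps_union

    union = interval_set_by_chrom(regions)
    out = set()
    for rec in introns:
        if rec.chrom not in union:
            continue
        us, ue = union[rec.chrom]
        starts = [s for s, _ in rec.masked_intervals]
        ends = [e for _, e in rec.masked_intervals]
        if overlaps_union(starts, ends, us, ue).any():
            out.add(rec.intron_id)
    return out


def _derive_chrom_sizes(transcripts, reads_by_sample, mito_chrom):
    sizes: dict = {}
    for t in transcripts:
        sizes[t.chrom] = max(sizes.get(t.chrom, 0), t.end)
    for reads in reads_by_sample.values():
        for chrom, end in reads.groupby("chrom")["end"].max().items():
            sizes[chrom] = max(sizes.get(chrom, 0), int(end))
    sizes.pop(mito_chrom, None)
    return {c: s + 1000 for c, s in sizes.items()}


def analyze(transcripts, reads_by_sample: dict, design: pd.DataFrame,
            exclusion: pd.DataFrame | None = None,
            junctions_by_sample: dict | None = None,
            label_regions: pd.DataFrame | None = None,
            extra_region_sets: dict | None = None,
            chrom_sizes: dict | None = None,
            de_cfg: debins.DEConfig | None = None,
            crit_spec: crit.CriterionSpec | None = None,
            min_intron_length: int = ann.DEFAULT_MIN_INTRON_LENGTH,
            mito_chrom: str = "chrM",
            calibration: crit.StrandCalibration | None = None,
            shuffle_seed: int = 0,
            shuffle_rounds: int = 1) -> PipelineResult:
    """Run the full analysis in memory and return every intermediate."""
    de_cfg = de_cfg or debins.DEConfig()
    crit_spec = crit_spec or crit.CriterionSpec()

    log.info("stage introns: %d transcripts", len(transcripts))
    introns = ann.extract_intron_intervals(transcripts, min_intron_length)
    loci = ann.group_loci(transcripts)
    index = quantify.AnnotationIndex.build(transcripts, introns)

    log.info("stage quantify: %d samples", len(reads_by_sample))
    informative, weighted = {}, {}
    for sample_id, reads in reads_by_sample.items():
        filt, n = quantify.filter_informative(reads, exclusion, mito_chrom)
        informative[sample_id] = n
        weighted[sample_id] = quantify.assign_read_weights(filt, index)
    distribution = quantify.summarize_distribution(weighted, design,
                                                   extra_region_sets)
    features = quantify.feature_table(introns, transcripts)
    dens = quantify.compute_density(features, weighted, informative)

    log.info("stage concordance")
    pairs = conc.pair_table(introns)
    pm = conc.pair_matrices(pairs, dens, design)
    pooled = conc.build_pairwise_dataset(pm)
    pooled_spearman = conc.spearman_rank(pooled["exon_density"],
                                         pooled["intron_density"])
    tc = conc.build_timecourse_dataset(pm)
    rho = conc.timecourse_correlation(tc)
    hist = conc.correlation_histogram(rho["rho"])
    sibling = conc.intron_intron_extremes(tc, rho)
    ratios = conc.intron_ratio_metrics(tc)
    cv = conc.coefficient_of_variation(pm)

    log.info("stage debins")
    if chrom_sizes is None:
        chrom_sizes = _derive_chrom_sizes(transcripts, reads_by_sample,
                                          mito_chrom)
    grids = debins.make_bin_grid(chrom_sizes, de_cfg.sizes)
    bin_counts = {
        size: debins.count_reads_in_bins(weighted, grids[size], size)
        for size in de_cfg.sizes}
    de_calls = debins.scan_de_bins(bin_counts, grids, design, informative,
                                   de_cfg)
    merged = debins.merge_de_bins(de_calls)
    annotated = debins.annotate_de_bins(merged, index, extra_region_sets)
    de_summary = debins.de_category_table(annotated)

    # exon-level DE at relaxed thresholds, per individual exon
    exon_rows = [
        (f"{t.transcript_id}__e{i}", "exon", t.chrom, s, e, e - s)
        for t in transcripts for i, (s, e) in enumerate(t.exons)]
    exon_features = pd.DataFrame(exon_rows, columns=[
        "feature_id", "kind", "chrom", "start", "end", "length"])
    exon_counts = pd.DataFrame({
        s: quantify.count_feature_reads(exon_features, w)
        for s, w in weighted.items()})
    exon_tx = pd.Series([fid.rsplit("__e", 1)[0]
                         for fid in exon_counts.index],
                        index=exon_counts.index)
    exon_de = debins.exon_level_de(exon_counts, exon_tx, design, informative,
                                   de_cfg)
    intronic = annotated[annotated["category"] == "intronic"]
    no_exon_change = debins.intronic_de_without_exon_change(
        annotated, introns, exon_de)
    de_tally = debins.tally_de_overlap(intronic, introns, transcripts)
    de_tally_nec = debins.tally_de_overlap(no_exon_change, introns,
                                           transcripts)

    # within-animal shuffle FDR control on the smallest-size bins,
    # first treated timepoint vs control
    smallest = de_cfg.sizes[0]
    dsorted = design.sort_values(["timepoint", "animal"])
    ctrl_ids = dsorted[dsorted["timepoint"]
                       == de_cfg.control_timepoint]["sample_id"].tolist()
    treated_tps = sorted(t for t in dsorted["timepoint"].unique()
                         if t != de_cfg.control_timepoint)
    shuffle_report = {}
    if treated_tps:
        tp = treated_tps[0]
        tr_ids = dsorted[dsorted["timepoint"] == tp]["sample_id"].tolist()
        shuffle_report = debins.shuffle_control(
            bin_counts[smallest][tr_ids].to_numpy(),
            bin_counts[smallest][ctrl_ids].to_numpy(),
            [informative[s] for s in tr_ids],
            [informative[s] for s in ctrl_ids],
            smallest, de_cfg, shuffle_seed, shuffle_rounds)
        shuffle_report["timepoint"] = int(tp)
        shuffle_report["bin_size"] = smallest

    log.info("stage criteria")
    if junctions_by_sample:
        try:
            calibration = crit.junction_calibration(junctions_by_sample)
        except ValueError:
            if calibration is None:
                raise
    if calibration is None:
        raise StageError("no junction reads and no calibration supplied")
    sense_pct = crit.sense_fraction(introns, weighted)
    strand_class = crit.classify_strand(sense_pct, calibration)

    all_ids = pd.Index([rec.intron_id for rec in introns])
    agg = crit_spec.sibling_aggregation
    sib_col = {"mean": "mean_rho", "min": "min_rho", "max": "max_rho"}[agg]
    de_intron_ids = set(
        debins.map_bins_to_introns(intronic.reset_index(drop=True),
                                   introns)["intron_id"])
    metrics_df = pd.DataFrame(index=all_ids)
    metrics_df["exon_rho"] = rho.groupby("intron_id")["rho"].min()
    metrics_df["sibling_rho"] = sibling.groupby("intron_id")[sib_col].min()
    metrics_df["rel_min_ratio"] = ratios.pair_rel_min.groupby(
        "intron_id")["rel_min_ratio"].max()
    metrics_df["max_ie_ratio"] = ratios.intron_max_ratio
    metrics_df["mean_ie_ratio"] = ratios.intron_mean_ratio
    cv_flag = pd.Series(pd.NA, index=all_ids, dtype="boolean")
    cv_flag.loc[cv.intron_flags.index.intersection(all_ids)] = \
        cv.intron_flags.astype(bool)
    metrics_df["cv_flag"] = cv_flag
    metrics_df["de_flag"] = pd.Series(
        all_ids.isin(de_intron_ids), index=all_ids, dtype="boolean")
    metrics = crit.IntronMetrics(metrics_df)
    flags = crit.apply_criteria(metrics, crit_spec)

    # unfiltered metrics (zero-series pairs removed only), for prediction
    nonzero = (pm.exon.sum(axis=1) > 0) & (pm.intron.sum(axis=1) > 0)
    pm_full = pm.take(nonzero)
    rho_full = conc.timecourse_correlation(pm_full)
    ratios_full = conc.intron_ratio_metrics(pm_full)
    pred = pd.DataFrame(index=all_ids)
    pred["exon_rho"] = rho_full.groupby("intron_id")["rho"].max()
    pred["max_ie_ratio"] = ratios_full.intron_max_ratio
    pred["mean_ie_ratio"] = ratios_full.intron_mean_ratio
    label_set = (introns_overlapping(introns, label_regions)
                 if label_regions is not None else set())
    enrichment = crit.criteria_summary(flags, strand_class, label_set)

    return PipelineResult(
        introns=introns, loci=loci, transcripts=transcripts, index=index,
        informative=informative, distribution=distribution, dens=dens,
        pooled_spearman=pooled_spearman, rho=rho, rho_histogram=hist,
        sibling=sibling, ratios=ratios, cv=cv, de_bins=de_calls,
        de_merged=merged, de_annotated=annotated, de_summary=de_summary,
        exon_de=exon_de, intronic_no_exon_change=no_exon_change,
        de_tally=de_tally, de_tally_no_exon_change=de_tally_nec,
        shuffle_report=shuffle_report, calibration=calibration,
        sense_pct=sense_pct, strand_class=strand_class, metrics=metrics,
        flags=flags, enrichment=enrichment, prediction_metrics=pred)


# ---------------------------------------------------------------------------
# file-based runner


def load_inputs(cfg: PipelineConfig):
    reader = (ann.read_genepred if cfg.annotation_format == "genepred"
              else ann.read_bed12)
    transcripts = reader(cfg.annotation_path,
                         drop_chrom_pattern=cfg.drop_chrom_pattern or None)
    design = quantify.read_design(cfg.design_path)
    reads = {
        row["sample_id"]: quantify.read_bed6(
            Path(cfg.reads_dir) / f"{row['sample_id']}.bed")
        for _, row in design.iterrows()}
    junctions = None
    if cfg.junctions_dir:
        from .simulate import junction_sense_table
        junctions = {
            row["sample_id"]: junction_sense_table(
                quantify.read_bed6(
                    Path(cfg.junctions_dir) / f"{row['sample_id']}.bed"),
                transcripts)
            for _, row in design.iterrows()}
    exclusion = (quantify.read_bed6(cfg.exclusion_path)
                 if cfg.exclusion_path else None)
    labels = quantify.read_bed6(cfg.label_path) if cfg.label_path else None
    return transcripts, reads, design, exclusion, junctions, labels


def write_outputs(res: PipelineResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ann.write_introns_bed(res.introns, outdir / "introns.bed")
    ann.write_introns_tsv(res.introns, outdir / "introns.tsv")
    pd.DataFrame([
        {"locus_id": l.locus_id, "chrom": l.span.chrom,
         "start": l.span.start, "end": l.span.end, "strand": l.span.strand,
         "transcripts": ",".join(l.transcript_ids)}
        for l in res.loci]).to_csv(outdir / "loci.tsv", sep="\t", index=False)
    res.distribution.to_csv(outdir / "distribution.tsv", sep="\t",
                            index=False)
    long = (res.dens.density.stack().rename("density").reset_index())
    long.columns = ["feature_id", "sample_id", "density"]
    long["raw"] = res.dens.raw.stack().to_numpy()
    long.to_csv(outdir / "density.tsv", sep="\t", index=False)
    res.rho.to_csv(outdir / "pair_correlations.tsv", sep="\t", index=False)
    res.sibling.to_csv(outdir / "intron_intron.tsv", sep="\t", index=False)
    res.ratios.pair_max_ratio.to_csv(outdir / "ratios.tsv", sep="\t",
                                     index=False)
    res.ratios.maxmin.to_csv(outdir / "maxmin_ratios.tsv", sep="\t",
                             index=False)
    res.cv.records.to_csv(outdir / "cv.tsv", sep="\t", index=False)
    summary = {
        "pooled_spearman": res.pooled_spearman,
        "rho_histogram": res.rho_histogram.to_dict(orient="records"),
        "cv": conc.cv_flag_fraction(res.cv),
    }
    (outdir / "correlation_summary.json").write_text(
        json.dumps(summary, indent=1))
    debins.write_de_bins_bed(res.de_merged, outdir / "de_bins.bed")
    res.de_merged.to_csv(outdir / "de_bins.tsv", sep="\t", index=False)
    res.de_summary.to_csv(outdir / "de_summary.tsv", sep="\t", index=False)
    res.de_tally.to_csv(outdir / "de_tally.tsv", sep="\t", index=False)
    res.de_tally_no_exon_change.to_csv(
        outdir / "de_tally_no_exon_change.tsv", sep="\t", index=False)
    (outdir / "shuffle_report.json").write_text(
        json.dumps(res.shuffle_report, indent=1))
    if res.calibration is not None:
        (outdir / "calibration.json").write_text(json.dumps({
            "mu": res.calibration.mu, "sigma": res.calibration.sigma,
            "sense_threshold": res.calibration.sense_threshold,
            "antisense_threshold": res.calibration.antisense_threshold},
            indent=1))
    crit_out = res.flags.copy()
    crit_out["strand_class"] = res.strand_class
    crit_out["sense_pct"] = res.sense_pct
    crit_out.index.name = "intron_id"
    crit_out.reset_index().to_csv(outdir / "criteria.tsv", sep="\t",
                                  index=False)
    res.enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """File-based end-to-end run: load inputs, analyze, write all tables."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    logging.getLogger("intronkit").addHandler(handler)
    try:
        transcripts, reads, design, exclusion, junctions, labels = \
            load_inputs(cfg)
        calibration = None
        if cfg.calibration_mu is not None:
            calibration = crit.StrandCalibration(
                cfg.calibration_mu, cfg.calibration_sigma or 0.0)
        res = analyze(
            transcripts, reads, design, exclusion, junctions, labels,
            de_cfg=cfg.de, crit_spec=cfg.criteria,
            min_intron_length=cfg.min_intron_length,
            mito_chrom=cfg.mito_chrom, calibration=calibration,
            shuffle_seed=cfg.shuffle_seed,
            shuffle_rounds=cfg.shuffle_rounds)
        write_outputs(res, outdir)
        return res
    finally:
        logging.getLogger("intronkit").removeHandler(handler)


# ---------------------------------------------------------------------------
# recovery scoring against simulated truth


def predict_classes(res: PipelineResult, hotspot_ratio: float = 10.0,
                    rho_boundary: float = 0.35,
                    silent_ratio: float = 0.08) -> pd.Series:
    """Rule-based class prediction from the measured per-intron metrics.

    Uses the unfiltered metrics so every expressed intron is classifiable:
    hotspot when the max intron/exon ratio reaches 10; antisense by the
    junction-calibrated strand class; pre-mRNA vs standalone by whether the
    exon correlation is above or below ``rho_boundary`` (the midpoint
    between the independent-program regime, rho ~ 0, and the shared-noise
    pre-mRNA regime, rho ~ 0.7); silent when the mean intron/exon ratio is
    below ``silent_ratio``, the log-midpoint between the background and
    pre-mRNA abundance regimes once exon-boundary read spill-over into
    introns is accounted for.  Unmeasured introns stay "ambiguous".
    """
    m = res.prediction_metrics
    cls = pd.Series("ambiguous", index=m.index, dtype=object)
    cls[m["mean_ie_ratio"].fillna(0) < silent_ratio] = "silent"
    expressed = m["mean_ie_ratio"] >= silent_ratio
    cls[expressed & (m["exon_rho"] < rho_boundary)] = "standalone"
    cls[expressed & (m["exon_rho"] >= rho_boundary)] = "premrna"
    cls[res.strand_class.reindex(m.index) == "antisense"] = "antisense"
    cls[m["max_ie_ratio"] >= hotspot_ratio] = "hotspot"
    return cls


def class_recovery(res: PipelineResult, truth: pd.DataFrame) -> pd.DataFrame:
    """One-vs-rest sensitivity/specificity per planted intron class."""
    truth = truth.set_index("intron_id")
    pred = predict_classes(res).reindex(truth.index)
    rows = []
    for cls in sorted(truth["class"].unique()):
        pos = truth["class"] == cls
        hit = pred == cls
        tp = int((pos & hit).sum())
        fp = int((~pos & hit).sum())
        rows.append({
            "class": cls, "n_true": int(pos.sum()),
            "n_predicted": int(hit.sum()),
            "sensitivity": tp / pos.sum() if pos.sum() else np.nan,
            "specificity": 1 - fp / (~pos).sum() if (~pos).sum() else np.nan,
        })
    return pd.DataFrame(rows)


def de_recovery(res: PipelineResult, truth: pd.DataFrame) -> dict:
    """Recovery of planted DE introns by intronic DE bins w/o exon change."""
    predicted = set(debins.map_bins_to_introns(
        res.intronic_no_exon_change.reset_index(drop=True),
        res.introns)["intron_id"])
    pos = set(truth.loc[truth["de_direction"].fillna("") != "", "intron_id"])
    neg = set(truth["intron_id"]) - pos
    tp = len(pos & predicted)
    fp = len(neg & predicted)
    return {
        "n_true": len(pos), "n_predicted": len(predicted),
        "sensitivity": tp / len(pos) if pos else float("nan"),
        "specificity": 1 - fp / len(neg) if neg else float("nan"),
    }
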