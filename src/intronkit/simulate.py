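"""Synthetic multi-animal RNA-seq timecourse with per-intron ground truth.

The generator emulates the design of a 7-animal x 6-timepoint inflammation
study on a toy genome: annotated multi-intron transcripts, per-sample BED6
read alignments, junction reads for strand calibration, exclusion regions
(rRNA-like zones and a mitochondrial chromosome analog), and a truth table
labelling every intron with the generative class that produced its RNA:

* ``premrna``   - intron density is a fixed fraction of the exon density
  and shares the exons' temporal profile and animal-to-animal noise (the
  unspliced pre-mRNA / excised-intron by-product model);
* ``standalone`` - an independently transcribed RNA with its own temporal
  profile and noise, optionally carrying a differential-expression spike at
  one timepoint;
* ``hotspot``   - a snoRNA-like producer whose density exceeds the exons'
  by an order of magnitude;
* ``antisense`` - an independent program on the opposite strand;
* ``silent``    - background only.

Counts are negative-binomial (Gamma-Poisson) around the expected density,
with a shared per-(gene, animal) factor linking exons to their pre-mRNA
introns; reads are unspliced fixed-length intervals placed uniformly, so a
fraction naturally straddles exon/intron boundaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import (TranscriptModel, extract_intron_intervals,
                         group_loci, write_transcripts_bed12,
                         write_transcripts_genepred, write_introns_bed,
                         write_introns_tsv)
from .quantify import BED6_COLUMNS, TIMEPOINTS, write_bed6

CLASSES = ("premrna", "standalone", "hotspot", "antisense", "silent")


@dataclass
class SimConfig:
    """Study-design and generative parameters of the simulator.

    Depth-like quantities are expressed as expected reads per feature per
    sample; densities follow from feature lengths and the realized
    informative read count of each sample.
    """

    seed: int = 0
    n_chroms: int = 2
    n_transcripts: int = 60
    isoform_fraction: float = 0.15   # genes that get a 2nd isoform with an
    # extra exon inside one intron (exercises exon masking)
    exons_per_transcript: tuple = (4, 9)    # inclusive range
    exon_length: tuple = (120, 400)
    intron_length: tuple = (700, 2500)
    intergenic_gap: tuple = (1500, 4000)
    timepoints: tuple = TIMEPOINTS
    n_animals: int = 7
    # class mixture over introns
    class_mix: dict = field(default_factory=lambda: {
        "premrna": 0.52, "standalone": 0.16, "hotspot": 0.05,
        "antisense": 0.07, "silent": 0.20})
    noise: str = "nb"                # "nb" or "poisson"
    dispersion: float = 0.05
    mean_exon_reads: float = 250.0   # per transcript per sample, baseline
    between_gene_sigma: float = 0.6  # log-normal spread of gene baselines
    premrna_ratio: float = 0.12      # intron/exon density, pre-mRNA class
    standalone_ratio: float = 0.30
    hotspot_ratio: float = 12.0
    silent_ratio: float = 0.02
    antisense_ratio: float = 0.30
    ratio_sigma: float = 0.3         # log-normal spread of the class ratios
    temporal_sigma_exon: float = 0.25
    temporal_sigma_standalone: float = 0.25
    animal_sigma: float = 0.30       # per-(gene or intron, sample) noise
    sample_scale_sigma: float = 0.10  # library-size variation
    # differential-expression spikes
    de_fraction_standalone: float = 0.5
    de_fold: float = 6.0
    de_timepoint: int = 3
    de_down_fraction: float = 0.5
    exon_de_fraction: float = 0.10   # genes with a real exon-level change
    exon_de_fold: float = 3.0
    # reads
    read_length: int = 35
    contaminant_fraction: float = 0.40  # of uniquely mapped reads
    mito_fraction: float = 0.10         # of contaminants on the chrM analog
    intergenic_fraction: float = 0.20   # of informative reads
    # junction calibration
    junction_sense_mu: float = 0.83
    junction_sense_sigma: float = 0.20
    n_junction_reads: int = 1000
    mito_chrom: str = "chrM"
    rrna_zone_length: int = 5000

    def __post_init__(self):
        probs = np.array([self.class_mix.get(c, 0.0) for c in CLASSES])
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("class_mix proportions must sum to 1")
        if self.intron_length[0] <= self.read_length:
            raise ValueError("introns must be longer than the read length")
        if self.mean_exon_reads <= 0:
            raise ValueError("depth must be positive")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class TruthTable:
    """Ground-truth labels and expectations for every simulated feature."""

    introns: pd.DataFrame          # intron_id, transcript_id, class, de_*
    expected_reads: pd.DataFrame   # feature_id x timepoint deterministic means
    de_events: pd.DataFrame        # feature_id, timepoint, fold, direction


@dataclass
class SimulatedDataset:
    config: SimConfig
    transcripts: list
    introns: list                  # IntronRecord list (full annotation)
    loci: list
    design: pd.DataFrame
    chrom_sizes: dict
    exclusion: pd.DataFrame        # rRNA-like zones, BED-style
    truth: TruthTable
    reads: dict                    # sample_id -> BED6 DataFrame
    junctions: dict                # sample_id -> BED6 + sense DataFrame

    def write(self, outdir):
        outdir = Path(outdir)
        (outdir / "reads").mkdir(parents=True, exist_ok=True)
        (outdir / "junctions").mkdir(exist_ok=True)
        write_transcripts_genepred(self.transcripts,
                                   outdir / "annotation.genePred")
        write_transcripts_bed12(self.transcripts, outdir / "annotation.bed12")
        write_introns_bed(self.introns, outdir / "introns.bed")
        write_introns_tsv(self.introns, outdir / "introns.tsv")
        self.exclusion.to_csv(outdir / "exclude.bed", sep="\t", header=False,
                              index=False, columns=BED6_COLUMNS)
        self.design.to_csv(outdir / "design.tsv", sep="\t", index=False)
        self.truth.introns.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        self.truth.de_events.to_csv(outdir / "de_events.tsv", sep="\t",
                                    index=False)
        pd.DataFrame(sorted(self.chrom_sizes.items()),
                     columns=["chrom", "size"]).to_csv(
            outdir / "chrom.sizes", sep="\t", index=False, header=False)
        for sample_id, df in self.reads.items():
            write_bed6(df, outdir / "reads" / f"{sample_id}.bed")
        for sample_id, df in self.junctions.items():
            write_bed6(df, outdir / "junctions" / f"{sample_id}.bed")
        manifest = {"seed": self.config.seed, "config_hash": self.config.hash()}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))


# ---------------------------------------------------------------------------
# genome and truth


def _make_genes(cfg: SimConfig, rng):
    transcripts, gene_rows = [], []
    cursors = {f"chr{i + 1}": 1000 for i in range(cfg.n_chroms)}
    chrom_names = sorted(cursors)
    intergenic = {c: [(0, 1000)] for c in chrom_names}
    for g in range(cfg.n_transcripts):
        chrom = chrom_names[g % cfg.n_chroms]
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(cfg.exons_per_transcript[0],
                                cfg.exons_per_transcript[1] + 1))
        pos = cursors[chrom]
        exons = []
        for i in range(n_ex):
            length = int(rng.integers(*cfg.exon_length))
            exons.append((pos, pos + length))
            pos += length
            if i < n_ex - 1:
                pos += int(rng.integers(*cfg.intron_length))
        tid = f"tx_{g + 1:04d}"
        primary = TranscriptModel(tid, chrom, strand, tuple(exons))
        transcripts.append(primary)
        extra_exon = None
        if rng.random() < cfg.isoform_fraction and n_ex >= 3:
            gaps = primary.introns()
            gi = len(gaps) // 2
            s, e = gaps[gi]
            if e - s >= 3 * 150:
                mid = (s + e) // 2
                extra_exon = (mid - 75, mid + 75)
                iso_exons = tuple(sorted(exons + [extra_exon]))
                transcripts.append(TranscriptModel(
                    f"{tid}_iso", chrom, strand, iso_exons))
        gene_rows.append({
            "gene_idx": g, "transcript_id": tid, "chrom": chrom,
            "strand": strand, "exons": tuple(exons), "extra_exon": extra_exon,
        })
        gap_end = pos + int(rng.integers(*cfg.intergenic_gap))
        intergenic[chrom].append((pos, gap_end))
        cursors[chrom] = gap_end
    chrom_sizes, exclusion = {}, []
    for chrom in chrom_names:
        zone_start = cursors[chrom] + 1000
        zone_end = zone_start + cfg.rrna_zone_length
        chrom_sizes[chrom] = zone_end + 1000
        intergenic[chrom].append((cursors[chrom], zone_start))
        exclusion.append((chrom, zone_start, zone_end, "rRNA_zone", 0, "."))
    chrom_sizes[cfg.mito_chrom] = 16299
    exclusion = pd.DataFrame(exclusion, columns=BED6_COLUMNS)
    intergenic_df = pd.DataFrame(
        [(c, s, e) for c, ivs in intergenic.items() for s, e in ivs],
        columns=["chrom", "start", "end"])
    return transcripts, gene_rows, chrom_sizes, exclusion, intergenic_df


def simulate_truth(cfg: SimConfig):
    """Generate annotation, ground truth, and the study design.

    Returns a partially filled :class:`SimulatedDataset` (reads empty) plus
    the internal feature table used by :func:`simulate_reads`.
    Deterministic for a fixed config (the seed is part of the config).
    """
    rng = np.random.default_rng(cfg.seed)
    transcripts, gene_rows, chrom_sizes, exclusion, intergenic = \
        _make_genes(cfg, rng)
    introns = extract_intron_intervals(transcripts)
    loci = group_loci(transcripts)
    masked = {rec.intron_id: rec for rec in introns}

    tps = list(cfg.timepoints)
    n_tp = len(tps)
    probs = [cfg.class_mix[c] for c in CLASSES]
    ratio_base = {"premrna": cfg.premrna_ratio,
                  "standalone": cfg.standalone_ratio,
                  "hotspot": cfg.hotspot_ratio,
                  "antisense": cfg.antisense_ratio,
                  "silent": cfg.silent_ratio}

    features = []      # per feature: id, gene, type/class, len, prog strand
    subints = []       # per sub-interval: feature row, chrom, start, end
    truth_rows, de_rows = [], []
    exp_by_feature = {}

    for gene in gene_rows:
        g = gene["gene_idx"]
        base = cfg.mean_exon_reads * float(
            rng.lognormal(0.0, cfg.between_gene_sigma))
        exon_profile = np.exp(rng.normal(0.0, cfg.temporal_sigma_exon,
                                         size=n_tp))
        tid = gene["transcript_id"]
        if rng.random() < cfg.exon_de_fraction:
            j = tps.index(cfg.de_timepoint)
            direction = "up" if rng.random() >= cfg.de_down_fraction else "down"
            f = cfg.exon_de_fold if direction == "up" else 1.0 / cfg.exon_de_fold
            exon_profile[j] *= f
            de_rows.append({"feature_id": tid, "timepoint": cfg.de_timepoint,
                            "fold": cfg.exon_de_fold, "direction": direction,
                            "kind": "exon"})
        exon_ints = list(gene["exons"])
        if gene["extra_exon"]:
            exon_ints = sorted(exon_ints + [gene["extra_exon"]])
        exon_len = sum(e - s for s, e in exon_ints)
        f_idx = len(features)
        features.append({"feature_id": tid, "gene_idx": g, "class": "exon",
                         "length": exon_len, "strand": gene["strand"],
                         "shared": True})
        for s, e in exon_ints:
            subints.append((f_idx, gene["chrom"], s, e))
        exp_by_feature[tid] = base * exon_profile

        gaps = TranscriptModel(tid, gene["chrom"], gene["strand"],
                               gene["exons"]).introns()
        for s, e in gaps:
            intron_id = f"{gene['chrom']}:{s}-{e}"
            rec = masked.get(intron_id)
            if rec is None:
                continue
            cls = CLASSES[int(rng.choice(len(CLASSES), p=probs))]
            ratio = ratio_base[cls] * float(
                rng.lognormal(0.0, cfg.ratio_sigma))
            if cls in ("premrna", "silent"):
                profile = exon_profile.copy()
                shared = True
            else:
                sigma = (cfg.temporal_sigma_standalone
                         if cls in ("standalone", "antisense") else 0.15)
                profile = np.exp(rng.normal(0.0, sigma, size=n_tp))
                shared = False
            de_dir = ""
            if cls == "standalone" and rng.random() < cfg.de_fraction_standalone:
                j = tps.index(cfg.de_timepoint)
                de_dir = ("up" if rng.random() >= cfg.de_down_fraction
                          else "down")
                f = cfg.de_fold if de_dir == "up" else 1.0 / cfg.de_fold
                profile[j] *= f
                de_rows.append({"feature_id": intron_id,
                                "timepoint": cfg.de_timepoint,
                                "fold": cfg.de_fold, "direction": de_dir,
                                "kind": "intron"})
            lam = ratio * base * profile * (rec.masked_length / exon_len)
            f_idx = len(features)
            prog_strand = gene["strand"]
            if cls == "antisense":
                prog_strand = "-" if prog_strand == "+" else "+"
            features.append({"feature_id": intron_id, "gene_idx": g,
                             "class": cls, "length": rec.masked_length,
                             "strand": prog_strand, "shared": shared})
            for ms, me in rec.masked_intervals:
                subints.append((f_idx, rec.chrom, ms, me))
            exp_by_feature[intron_id] = lam
            truth_rows.append({
                "intron_id": intron_id, "transcript_id": tid, "class": cls,
                "expected_ratio": ratio, "de_direction": de_dir,
                "de_fold": cfg.de_fold if de_dir else np.nan,
                "de_timepoint": cfg.de_timepoint if de_dir else -1,
            })

    design = pd.DataFrame([
        {"sample_id": f"t{tp:02d}_a{a}", "timepoint": tp, "animal": a}
        for tp in tps for a in range(1, cfg.n_animals + 1)])
    expected = pd.DataFrame(exp_by_feature).T
    expected.columns = [f"tp{t}" for t in tps]
    expected.index.name = "feature_id"
    truth = TruthTable(pd.DataFrame(truth_rows), expected,
                       pd.DataFrame(de_rows, columns=[
                           "feature_id", "timepoint", "fold", "direction",
                           "kind"]))
    ds = SimulatedDataset(cfg, transcripts, introns, loci, design,
                          chrom_sizes, exclusion, truth, {}, {})
    internals = {"features": pd.DataFrame(features),
                 "subints": pd.DataFrame(
                     subints, columns=["f_idx", "chrom", "start", "end"]),
                 "gene_rows": gene_rows, "intergenic": intergenic}
    return ds, internals


# ---------------------------------------------------------------------------
# reads


def _place_reads(rng, sub_counts, sub_df, strands, p_sense, cfg, chrom_sizes):
    rep = np.repeat(np.arange(len(sub_df)), sub_counts)
    if rep.size == 0:
        return pd.DataFrame(columns=BED6_COLUMNS)
    L = cfg.read_length
    lo = sub_df["start"].to_numpy()[rep] - (L - 1)
    hi = sub_df["end"].to_numpy()[rep]
    starts = rng.integers(lo, hi)
    chroms = sub_df["chrom"].to_numpy()[rep]
    maxpos = np.array([chrom_sizes[c] for c in chroms]) - L
    starts = np.clip(starts, 0, maxpos)
    prog = strands[rep]
    sense = rng.random(rep.size) < p_sense
    flip = {"+": "-", "-": "+", ".": "."}
    strand = np.where(sense, prog, [flip[s] for s in prog])
    return pd.DataFrame({
        "chrom": chroms, "start": starts, "end": starts + L,
        "name": ".", "score": 0, "strand": strand})


def simulate_reads(ds: SimulatedDataset, internals: dict) -> SimulatedDataset:
    """Draw per-sample read sets around the truth expectations (in place)."""
    cfg = ds.config
    rng = np.random.default_rng(cfg.seed + 1)
    features = internals["features"]
    subints = internals["subints"]
    n_feat = len(features)
    gene_of = features["gene_idx"].to_numpy()
    shared = features["shared"].to_numpy()
    feat_len = features["length"].to_numpy(float)
    sub_f = subints["f_idx"].to_numpy()
    sub_len = (subints["end"] - subints["start"]).to_numpy(float)
    frac = sub_len / feat_len[sub_f]
    strands = features["strand"].to_numpy()
    expected = ds.truth.expected_reads.loc[
        features["feature_id"].to_numpy()]
    tps = list(cfg.timepoints)
    n_genes = int(gene_of.max()) + 1

    chrom_names = sorted(c for c in ds.chrom_sizes if c != cfg.mito_chrom)
    zone = {r["chrom"]: (r["start"], r["end"])
            for _, r in ds.exclusion.iterrows()}
    inter_ivs = internals["intergenic"]
    inter_chroms = inter_ivs["chrom"].to_numpy()
    inter_starts = inter_ivs["start"].to_numpy()
    inter_ends = inter_ivs["end"].to_numpy()
    inter_weights = (inter_ends - inter_starts).astype(float)
    inter_weights /= inter_weights.sum()
    junction_pool = [
        (t.chrom, t.exons[i][1], t.strand, t.transcript_id)
        for t in ds.transcripts if len(t.exons) >= 2 and
        not t.transcript_id.endswith("_iso")
        for i in range(len(t.exons) - 1)]

    for _, row in ds.design.iterrows():
        sample_id, tp = row["sample_id"], int(row["timepoint"])
        lam = expected[f"tp{tp}"].to_numpy(float).copy()
        scale = float(rng.lognormal(0.0, cfg.sample_scale_sigma))
        gene_factor = rng.lognormal(0.0, cfg.animal_sigma, size=n_genes)
        own_factor = rng.lognormal(0.0, cfg.animal_sigma, size=n_feat)
        factor = np.where(shared, gene_factor[gene_of], own_factor)
        lam = lam * factor * scale
        if cfg.noise == "nb":
            gamma = rng.gamma(1.0 / cfg.dispersion, cfg.dispersion,
                              size=n_feat)
            lam = lam * gamma
        sub_counts = rng.poisson(lam[sub_f] * frac)
        p_sense = float(np.clip(
            rng.normal(cfg.junction_sense_mu, cfg.junction_sense_sigma),
            0.5, 1.0))
        body = _place_reads(rng, sub_counts, subints, strands[sub_f],
                            p_sense, cfg, ds.chrom_sizes)
        n_feat_reads = len(body)
        # intergenic background: uniform over the gaps between genes
        n_inter = rng.poisson(cfg.intergenic_fraction
                              / (1 - cfg.intergenic_fraction) * n_feat_reads)
        gi = rng.choice(len(inter_ivs), size=n_inter, p=inter_weights)
        ilo = inter_starts[gi]
        ihi = np.maximum(ilo + 1, inter_ends[gi] - cfg.read_length)
        istart = rng.integers(ilo, ihi)
        inter = pd.DataFrame({
            "chrom": inter_chroms[gi], "start": istart,
            "end": istart + cfg.read_length, "name": ".", "score": 0,
            "strand": np.where(rng.random(n_inter) < 0.5, "+", "-")})
        n_informative = n_feat_reads + n_inter
        # contaminants: rRNA-like zones and the chrM analog
        n_cont = rng.poisson(cfg.contaminant_fraction
                             / (1 - cfg.contaminant_fraction) * n_informative)
        n_mito = rng.binomial(n_cont, cfg.mito_fraction)
        mstart = rng.integers(0, ds.chrom_sizes[cfg.mito_chrom]
                              - cfg.read_length, size=n_mito)
        mito = pd.DataFrame({
            "chrom": cfg.mito_chrom, "start": mstart,
            "end": mstart + cfg.read_length, "name": ".", "score": 0,
            "strand": np.where(rng.random(n_mito) < 0.5, "+", "-")})
        n_rrna = n_cont - n_mito
        rchrom = rng.choice(chrom_names, size=n_rrna)
        rlo = np.array([zone[c][0] for c in rchrom])
        rhi = np.array([zone[c][1] for c in rchrom]) - cfg.read_length
        rstart = (rlo + rng.random(n_rrna) * (rhi - rlo)).astype(np.int64)
        rrna = pd.DataFrame({
            "chrom": rchrom, "start": rstart,
            "end": rstart + cfg.read_length, "name": ".", "score": 0,
            "strand": np.where(rng.random(n_rrna) < 0.5, "+", "-")})
        reads = pd.concat([body, inter, mito, rrna], ignore_index=True)
        reads = reads.sort_values(["chrom", "start"],
                                  kind="stable").reset_index(drop=True)
        ds.reads[sample_id] = reads
        # junction reads (kept separate; only their strand tag matters)
        jidx = rng.integers(0, len(junction_pool), size=cfg.n_junction_reads)
        jsense = rng.random(cfg.n_junction_reads) < p_sense
        jrows = []
        for k, si in enumerate(jidx):
            chrom, pos, strand, tid = junction_pool[si]
            s = max(0, pos - cfg.read_length // 2)
            rstrand = strand if jsense[k] else ("-" if strand == "+" else "+")
            jrows.append((chrom, s, s + cfg.read_length, tid, 0, rstrand))
        jdf = pd.DataFrame(jrows, columns=BED6_COLUMNS)
        jdf["sense"] = jsense
        ds.junctions[sample_id] = jdf
    return ds


def simulate(cfg: SimConfig | None = None, **overrides) -> SimulatedDataset:
    """One-call simulation: truth plus reads."""
    if cfg is None:
        cfg = SimConfig(**overrides)
    elif overrides:
        cfg = dataclasses.replace(cfg, **overrides)
    ds, internals = simulate_truth(cfg)
    return simulate_reads(ds, internals)


def junction_sense_table(junctions: pd.DataFrame, transcripts) -> pd.DataFrame:
    """Recompute the sense flag of junction reads from the annotation."""
    strand_of = {t.transcript_id: t.strand for t in transcripts}
    out = junctions.copy()
    out["sense"] = [
        strand_of.get(n) == s
        for n, s in zip(out["name"], out["strand"])]
    return out
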