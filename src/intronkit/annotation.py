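"""Transcript models, exon-masked intron intervals, and locus grouping.

The central object is the *masked intron*: an annotated intron with every
base that overlaps any annotated exon (of any transcript, either strand)
subtracted out.  Introns are deduplicated by their un-masked genomic
coordinates, so an intron shared by several isoforms exists exactly once and
carries every parent transcript.

All coordinates are 0-based half-open (BED convention); genePred input is in
the same convention and is taken as-is.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._intervals import interval_set_by_chrom, merge_intervals, subtract_interval

DEFAULT_MIN_INTRON_LENGTH = 30


class AnnotationError(ValueError):
    """Malformed transcript annotation (unsorted or overlapping exons, ...)."""


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start >= self.end:
            raise AnnotationError(
                f"empty interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self):
        return self.end - self.start


@dataclass
class TranscriptModel:
    """One annotated transcript: an ordered list of disjoint exons."""

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple  # of (start, end) pairs, sorted, pairwise disjoint
    locus_id: str | None = None

    def __post_init__(self):
        self.exons = tuple((int(s), int(e)) for s, e in self.exons)
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: no exons")
        prev_end = -1
        for s, e in self.exons:
            if s >= e:
                raise AnnotationError(f"{self.transcript_id}: empty exon {s}-{e}")
            if s < prev_end:
                raise AnnotationError(
                    f"{self.transcript_id}: exons unsorted or overlapping at {s}"
                )
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    def introns(self):
        """Un-masked introns: the gaps between consecutive exons."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] > self.exons[i][1]
        ]

    def exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class IntronRecord:
    """A unique exon-masked intronic interval.

    ``key`` is the un-masked (chrom, start, end); ``masked_intervals`` is the
    intron minus the union of all exons in the annotation, and
    ``masked_length`` the summed length of those pieces.
    """

    chrom: str
    start: int
    end: int
    strand: str
    masked_intervals: tuple
    parent_transcripts: tuple
    masked_length: int = field(init=False)

    def __post_init__(self):
        self.masked_intervals = tuple(
            (int(s), int(e)) for s, e in self.masked_intervals
        )
        self.masked_length = sum(e - s for s, e in self.masked_intervals)

    @property
    def key(self):
        return (self.chrom, self.start, self.end)

    @property
    def intron_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class LocusGroup:
    locus_id: str
    transcript_ids: tuple
    span: GenomicInterval


# ---------------------------------------------------------------------------
# readers / writers


def read_genepred(path, drop_chrom_pattern: str | None = None):
    """Parse a genePred file (UCSC knownGene column order, no bin column).

    Columns used: name, chrom, strand, txStart, txEnd, cdsStart, cdsEnd,
    exonCount, exonStarts, exonEnds.  Extra trailing columns are ignored.
    """
    pat = re.compile(drop_chrom_pattern) if drop_chrom_pattern else None
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise AnnotationError(f"genePred line with {len(f)} columns")
            name, chrom, strand = f[0], f[1], f[2]
            if pat and pat.search(chrom):
                continue
            starts = [int(x) for x in f[8].rstrip(",").split(",")]
            ends = [int(x) for x in f[9].rstrip(",").split(",")]
            out.append(
                TranscriptModel(name, chrom, strand, tuple(zip(starts, ends)))
            )
    return out


def read_bed12(path, drop_chrom_pattern: str | None = None):
    """Parse BED12 transcript models (blocks become exons)."""
    pat = re.compile(drop_chrom_pattern) if drop_chrom_pattern else None
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise AnnotationError(f"BED12 line with {len(f)} columns")
            chrom, chrom_start, name, strand = f[0], int(f[1]), f[3], f[5]
            if pat and pat.search(chrom):
                continue
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple(
                (chrom_start + o, chrom_start + o + sz)
                for o, sz in zip(offsets, sizes)
            )
            out.append(TranscriptModel(name, chrom, strand, exons))
    return out


def write_transcripts_genepred(transcripts, path):
    with open(path, "w") as fh:
        for t in transcripts:
            starts = ",".join(str(s) for s, _ in t.exons) + ","
            ends = ",".join(str(e) for _, e in t.exons) + ","
            fh.write(
                "\t".join(
                    [
                        t.transcript_id,
                        t.chrom,
                        t.strand,
                        str(t.start),
                        str(t.end),
                        str(t.start),
                        str(t.start),
                        str(len(t.exons)),
                        starts,
                        ends,
                    ]
                )
                + "\n"
            )


def write_transcripts_bed12(transcripts, path):
    with open(path, "w") as fh:
        for t in transcripts:
            sizes = ",".join(str(e - s) for s, e in t.exons) + ","
            offsets = ",".join(str(s - t.start) for s, _ in t.exons) + ","
            fh.write(
                "\t".join(
                    [
                        t.chrom,
                        str(t.start),
                        str(t.end),
                        t.transcript_id,
                        "0",
                        t.strand,
                        str(t.start),
                        str(t.start),
                        "0",
                        str(len(t.exons)),
                        sizes,
                        offsets,
                    ]
                )
                + "\n"
            )


def write_introns_bed(introns, path):
    """BED6, one record per masked sub-interval; name = intron key."""
    with open(path, "w") as fh:
        for rec in introns:
            for s, e in rec.masked_intervals:
                fh.write(
                    f"{rec.chrom}\t{s}\t{e}\t{rec.intron_id}\t0\t{rec.strand}\n"
                )


def write_introns_tsv(introns, path):
    rows = [
        {
            "intron_id": rec.intron_id,
            "chrom": rec.chrom,
            "start": rec.start,
            "end": rec.end,
            "strand": rec.strand,
            "masked_length": rec.masked_length,
            "n_masked_intervals": len(rec.masked_intervals),
            "parents": ",".join(rec.parent_transcripts),
        }
        for rec in introns
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# operations


def exon_union_by_chrom(transcripts):
    """Genome-wide union of all exons, per chromosome (strand-blind)."""
    rows = [
        (t.chrom, s, e) for t in transcripts for s, e in t.exons
    ]
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return interval_set_by_chrom(df)


def extract_intron_intervals(
    transcripts, min_length: int = DEFAULT_MIN_INTRON_LENGTH
):
    """Derive unique exon-masked intron intervals from transcript models.

    An intron is a gap between consecutive exons of one transcript; introns
    with identical (chrom, start, end) collapse to a single record listing
    every parent.  Masking subtracts the union of ALL exons in the input,
    regardless of which transcript or strand they belong to.  Introns whose
    un-masked length is <= ``min_length`` are dropped, as are introns that
    are completely covered by exons elsewhere (masked length 0).
    """
    if min_length < 0:
        raise ValueError("min_length must be >= 0")
    union = exon_union_by_chrom(transcripts)
    by_key: dict = {}
    for t in transcripts:
        for s, e in t.introns():
            if e - s <= min_length:
                continue
            parents, strands = by_key.setdefault((t.chrom, s, e), (set(), set()))
            parents.add(t.transcript_id)
            strands.add(t.strand)
    records = []
    for (chrom, s, e), (parents, strands) in by_key.items():
        us, ue = union.get(chrom, (np.empty(0), np.empty(0)))
        masked = subtract_interval(s, e, us, ue)
        if not masked:
            continue
        strand = strands.pop() if len(strands) == 1 else "."
        records.append(
            IntronRecord(
                chrom, s, e, strand, tuple(masked), tuple(sorted(parents))
            )
        )
    records.sort(key=lambda r: (r.chrom, r.start, r.end))
    return records


def group_loci(transcripts):
    """Group transcripts into loci: same-strand genomic-overlap components.

    Two transcripts belong to the same locus iff they are connected through a
    chain of span overlaps on the same strand; antisense overlap never merges
    loci.  Locus ids are deterministic (sorted by span) and are written back
    onto the transcripts' ``locus_id`` field.
    """
    groups = []
    keyfun = lambda t: (t.chrom, t.strand)  # noqa: E731
    by_cs: dict = {}
    for t in transcripts:
        by_cs.setdefault(keyfun(t), []).append(t)
    for (chrom, strand), members in by_cs.items():
        members.sort(key=lambda t: (t.start, t.end, t.transcript_id))
        current, cur_end = [], -1
        for t in members:
            if current and t.start < cur_end:
                current.append(t)
                cur_end = max(cur_end, t.end)
            else:
                if current:
                    groups.append((chrom, strand, current))
                current, cur_end = [t], t.end
        if current:
            groups.append((chrom, strand, current))
    groups.sort(key=lambda g: (g[0], min(t.start for t in g[2]),
                               max(t.end for t in g[2]), g[1]))
    loci = []
    for i, (chrom, strand, members) in enumerate(groups):
        locus_id = f"locus_{i + 1:05d}"
        span = GenomicInterval(
            chrom,
            min(t.start for t in members),
            max(t.end for t in members),
            strand,
        )
        for t in members:
            t.locus_id = locus_id
        loci.append(
            LocusGroup(
                locus_id,
                tuple(sorted(t.transcript_id for t in members)),
                span,
            )
        )
    return loci


def intron_union_by_chrom(introns):
    """Union of all masked intron sub-intervals, per chromosome."""
    rows = [
        (rec.chrom, s, e) for rec in introns for s, e in rec.masked_intervals
    ]
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return interval_set_by_chrom(df)


def merged_exons(transcript):
    """Sorted disjoint exon union of one transcript (its exonic feature)."""
    s, e = merge_intervals(
        np.array([x for x, _ in transcript.exons]),
        np.array([y for _, y in transcript.exons]),
    )
    return list(zip(s.tolist(), e.tolist()))
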