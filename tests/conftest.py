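import numpy as np
import pandas as pd
import pytest

from intronkit import SimConfig, TranscriptModel, analyze, simulate


@pytest.fixture
def three_exon_transcript():
    return TranscriptModel("t1", "chr1", "+",
                           ((100, 200), (500, 600), (900, 1000)))


@pytest.fixture
def toy_reads():
    """A handful of reads over chr1 plus three on the chrM analog."""
    rows = [
        ("chr1", 120, 155, ".", 0, "+"),   # inside exon 1
        ("chr1", 180, 215, ".", 0, "+"),   # straddles exon/intron boundary
        ("chr1", 300, 335, ".", 0, "-"),   # intron interior
        ("chr1", 2000, 2035, ".", 0, "+"),  # gene desert
        ("chr1", 5005, 5040, ".", 0, "+"),  # inside the rRNA-like region
        ("chr1", 4990, 5010, ".", 0, "-"),  # half-overlaps the rRNA region
        ("chr1", 700, 735, ".", 0, "+"),   # intron interior
        ("chrM", 10, 45, ".", 0, "+"),
        ("chrM", 100, 135, ".", 0, "-"),
        ("chrM", 300, 335, ".", 0, "+"),
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "score", "strand"])


@pytest.fixture
def exclusion_regions():
    return pd.DataFrame([("chr1", 5000, 5100, "rRNA", 0, ".")],
                        columns=["chrom", "start", "end", "name", "score",
                                 "strand"])


def make_design(n_animals=7, timepoints=(0, 3, 6, 12, 24, 48)):
    return pd.DataFrame([
        {"sample_id": f"t{tp:02d}_a{a}", "timepoint": tp, "animal": a}
        for tp in timepoints for a in range(1, n_animals + 1)])


@pytest.fixture(scope="session")
def design42():
    return make_design()


@pytest.fixture(scope="session")
def small_dataset():
    """A fast, reduced simulation for unit-level checks."""
    return simulate(SimConfig(seed=11, n_transcripts=16,
                              mean_exon_reads=120.0, n_junction_reads=300))


@pytest.fixture(scope="session")
def full_run():
    """The reference end-to-end run: default study conditions, seed 1."""
    ds = simulate(SimConfig(seed=1))
    res = analyze(ds.transcripts, ds.reads, ds.design, ds.exclusion,
                  ds.junctions, chrom_sizes=ds.chrom_sizes)
    return ds, res


def rng(seed=0):
    return np.random.default_rng(seed)
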