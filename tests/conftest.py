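import numpy as np
import pandas as pd
import pysam
import pytest

from melopav.simulate import SimParams, simulate_cohort

# ---------------------------------------------------------------------------
# Hand-built BAM fixture. Layout on scaffold s1 (len 10000), interval of
# interest s1:1001-2000 (1-based) = [1000, 2000) 0-based:
#   in1..in3  mapped, MAPQ 30, fully inside the interval
#   edge1     mapped, MAPQ 30, overlaps the interval by exactly 1 bp
#   left1     mapped, MAPQ 30, entirely before the interval
#   mq0       mapped, MAPQ 0, inside the interval (excluded at min_mapq=1)
#   unmapped1 unmapped record
# plus two MAPQ 30 reads on scaffold s2 (len 5000).
# Qualifying reads at min_mapq=1: 4 overlap the interval; 7 genome-wide.
# ---------------------------------------------------------------------------
_READS = [
    # name, ref, 0-based pos, mapq, len
    ("left1", "s1", 200, 30, 100),
    ("edge1", "s1", 901, 30, 100),
    ("in1", "s1", 1100, 30, 100),
    ("mq0", "s1", 1200, 0, 100),
    ("in2", "s1", 1500, 30, 100),
    ("in3", "s1", 1850, 30, 100),
    ("unmapped1", None, None, 0, 100),
    ("s2a", "s2", 1000, 30, 100),
    ("s2b", "s2", 3000, 30, 100),
]

BAM_INTERVAL = ("s1", 1001, 2000)  # 1-based inclusive
BAM_INTERVAL_COUNT = 4
BAM_TOTAL_MAPPED = 7


def build_bam(path, reads=_READS):
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": "s1", "LN": 10000}, {"SN": "s2", "LN": 5000}],
    }
    refs = {"s1": 0, "s2": 1}
    placed = sorted(
        (r for r in reads if r[1] is not None), key=lambda r: (refs[r[1]], r[2])
    )
    unplaced = [r for r in reads if r[1] is None]
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for name, ref, pos, mapq, rlen in placed + unplaced:
            a = pysam.AlignedSegment()
            a.query_name = name
            a.query_sequence = "A" * rlen
            a.query_qualities = pysam.qualitystring_to_array("I" * rlen)
            if ref is None:
                a.is_unmapped = True
            else:
                a.reference_id = refs[ref]
                a.reference_start = pos
                a.mapping_quality = mapq
                a.cigarstring = f"{rlen}M"
            bam.write(a)
    pysam.index(str(path))
    return path


@pytest.fixture(scope="session")
def fixture_bam(tmp_path_factory):
    path = tmp_path_factory.mktemp("bam") / "fixture.bam"
    return build_bam(path)


@pytest.fixture(scope="session")
def small_cohort():
    """Small noise-free synthetic cohort shared by read-only tests."""
    params = SimParams(
        n_genes=2000,
        n_scaffolds=8,
        depth_per_cultivar=13.0,
        base_del_rate=0.01,
        seed=3,
    )
    return simulate_cohort(params)


@pytest.fixture
def toy_counts():
    """5-gene x 3-cultivar count matrix with hand-checkable structure."""
    from melopav.coverage import CountMatrix

    counts = pd.DataFrame(
        {
            "A": [100, 0, 9, 40, 5],
            "B": [100, 95, 9, 100, 40],
            "C": [110, 105, 9, 90, 35],
        },
        index=[f"g{i}" for i in range(5)],
    )
    libs = pd.Series({"A": 1_000_000, "B": 1_000_000, "C": 1_000_000})
    return CountMatrix(counts, libs)


def rng(seed=0):
    return np.random.default_rng(seed)
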