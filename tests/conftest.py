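import numpy as np
import pytest

from regionenrich import GenomicInterval, IntervalSet


@pytest.fixture
def tiny_target() -> IntervalSet:
    return IntervalSet.from_intervals(
        [
            GenomicInterval("chr1", 150, 160, "t1", strand="+"),
            GenomicInterval("chr1", 500, 600, "t2", strand="-"),
            GenomicInterval("chr2", 90, 200, "t3", strand="+"),
        ],
        source_label="tiny_target.bed",
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_set(records, label="set.bed") -> IntervalSet:
    """records: (chrom, start, end[, strand[, score]]) tuples."""
    ivs = []
    for rec in records:
        chrom, start, end = rec[:3]
        strand = rec[3] if len(rec) > 3 else "."
        score = rec[4] if len(rec) > 4 else None
        ivs.append(GenomicInterval(chrom, start, end, score=score, strand=strand))
    return IntervalSet.from_intervals(ivs, source_label=label)


@pytest.fixture
def small_fasta(tmp_path):
    """Two tiny chromosomes with known composition."""
    path = tmp_path / "genome.fa"
    path.write_text(">chrA\nATATGCGCACGTN\n>chrB\nAAAA\n")
    from pyfaidx import Fasta

    return Fasta(str(path))
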