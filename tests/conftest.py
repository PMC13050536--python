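import sys
from pathlib import Path

import numpy as np
import pyBigWig
import pysam
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper

from regulabel.fixtures import generate_dataset, write_dataset


def write_toy_bam(path, chrom, length, reads, read_length=None):
    """Write a sorted+indexed BAM from (start, cigartuples) or start ints."""
    header = {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": chrom, "LN": length}]}
    norm = []
    for r in reads:
        if isinstance(r, tuple):
            start, cig = r
        else:
            start, cig = r, [(0, read_length or 50)]
        norm.append((start, cig))
    norm.sort(key=lambda x: x[0])
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for i, (start, cig) in enumerate(norm):
            qlen = sum(n for op, n in cig if op in (0, 1, 4, 7, 8))
            a = pysam.AlignedSegment()
            a.query_name = f"q{i}"
            a.query_sequence = "A" * qlen
            a.flag = 0
            a.reference_id = 0
            a.reference_start = start
            a.mapping_quality = 60
            a.cigartuples = cig
            bam.write(a)
    pysam.index(str(path))
    return str(path)


def write_toy_bigwig(path, chrom, values):
    """bigWig with explicit per-base values (zeros omitted)."""
    values = np.asarray(values, dtype=float)
    bw = pyBigWig.open(str(path), "w")
    bw.addHeader([(chrom, len(values))])
    change = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate(([0], change)).astype(np.int64)
    ends = np.concatenate((change, [len(values)])).astype(np.int64)
    vals = values[starts]
    keep = vals != 0
    if keep.any():
        bw.addEntries(
            [chrom] * int(keep.sum()),
            starts[keep].tolist(),
            ends=ends[keep].tolist(),
            values=vals[keep].tolist(),
        )
    bw.close()
    return str(path)


@pytest.fixture(scope="session")
def noise_free_dataset(tmp_path_factory):
    """A noise-free planted dataset written to disk, shared by e2e tests."""
    root = tmp_path_factory.mktemp("noise_free_ds")
    ds = generate_dataset(seed=11, noise_level=0.0)
    paths = write_dataset(ds, root)
    return ds, paths
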