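"""Depth-normalised signal quantification.

For each candidate region r and track t (t1=H3K4me1, t2=H3K4me3,
t3=H3K27ac, t4=CTCF) the normalised signal is

    A[r, t] = 1e6 * auc(r ∩ b_t) / auc(genome)_t

where b_t is track t's peak set, auc(.) is the summed per-base read
coverage (area under the coverage curve) over the given bases, and
auc(genome)_t sums over the whole genome — i.e. per-million-of-total
coverage within the region's overlap with the track's peaks. An empty
intersection gives an exact 0, which the rule engine treats as
biologically meaningful absence; no pseudocounts are added anywhere.

``auc_mode="read_count"`` swaps in the read-count interpretation
(number of passing reads overlapping r ∩ b_t; denominator = total
passing reads), kept behind the same interface.
"""

from __future__ import annotations

import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import AlignmentSource
from .intervals import GenomicInterval, intersect_interval_with_set

logger = logging.getLogger(__name__)

#: fixed track order of every signal/rank matrix in the package
TRACKS = ("H3K4me1", "H3K4me3", "H3K27ac", "CTCF")
AUC_MODES = ("area", "read_count")


def _read_blocks(read) -> list:
    """Reference spans consumed by the read (soft-clips excluded)."""
    return read.get_blocks()


def auc(fragments, source: AlignmentSource, mode: str = "area") -> float:
    """Area under the coverage curve restricted to disjoint fragments.

    ``fragments`` is either a GenomicInterval or a (chrom, [(start, end),
    ...]) pair of disjoint spans. Per-base coverage decomposes over
    disjoint fragments, so the total is the per-fragment sum. Returns 0
    for an empty fragment set.
    """
    if mode not in AUC_MODES:
        raise ValueError(f"unknown auc mode {mode!r}")
    if isinstance(fragments, GenomicInterval):
        chrom, spans = fragments.chrom, [(fragments.start, fragments.end)]
    else:
        chrom, spans = fragments
    if not spans:
        return 0.0
    if mode == "read_count":
        seen = set()
        for s, e in spans:
            for read in source.fetch(chrom, s, e):
                seen.add((read.query_name, read.reference_start, read.flag))
        return float(len(seen))
    total = 0
    for s, e in spans:
        for read in source.fetch(chrom, s, e):
            for bs, be in _read_blocks(read):
                lo, hi = max(bs, s), min(be, e)
                if lo < hi:
                    total += hi - lo
    return float(total)


_GENOME_AUC_CACHE: dict[tuple, float] = {}


def genome_auc(source: AlignmentSource, mode: str = "area") -> float:
    """Genome-wide auc: sum of aligned read lengths (or read count).

    Cached per (path, mode, flag filter); errors on an empty source since
    it would become a zero denominator.
    """
    key = (source.path, mode, source.exclude_flags)
    if key in _GENOME_AUC_CACHE:
        return _GENOME_AUC_CACHE[key]
    if mode == "read_count":
        total = float(sum(1 for _ in source.iter_all()))
    else:
        total = float(
            sum(be - bs for read in source.iter_all() for bs, be in _read_blocks(read))
        )
    if total <= 0:
        raise ValueError(f"empty alignment source {source.path}: genome auc is 0")
    _GENOME_AUC_CACHE[key] = total
    return total


@dataclass
class SignalMatrix:
    """R x 4 matrix of normalised signals, rows aligned to a RegionSet."""

    regions: list
    values: np.ndarray  # shape (R, 4), columns in TRACKS order

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(TRACKS):
            raise ValueError("signal matrix must have exactly 4 columns")
        if len(self.regions) != self.values.shape[0]:
            raise ValueError("row count does not match region count")
        if np.any(self.values < 0):
            raise ValueError("negative signal entries")

    def __len__(self) -> int:
        return len(self.regions)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chrom": [r.chrom for r in self.regions],
                "start": [r.start for r in self.regions],
                "end": [r.end for r in self.regions],
            }
        )
        for j, t in enumerate(TRACKS):
            df[t] = self.values[:, j]
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "SignalMatrix":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in ("chrom", "start", "end", *TRACKS) if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        regions = [
            GenomicInterval(c, int(s), int(e))
            for c, s, e in zip(df["chrom"], df["start"], df["end"])
        ]
        return cls(regions=regions, values=df[list(TRACKS)].to_numpy(dtype=float))


def _quantify_chunk(bam_path, exclude_flags, mode, chunk):
    """Worker task: auc for a chunk of (chrom, fragments) jobs.

    Opens its own BAM handle so chunks can run in separate processes;
    per-region sums are independent of chunking, which is what makes the
    result worker-count invariant.
    """
    src = AlignmentSource(bam_path, exclude_flags=exclude_flags)
    try:
        return [auc((chrom, frags), src, mode=mode) for chrom, frags in chunk]
    finally:
        src.close()


def compute_signal_matrix(
    region_set,
    track_peaks: dict,
    track_bams: dict,
    auc_mode: str = "area",
    n_workers: int = 1,
) -> SignalMatrix:
    """Build the R x 4 normalised signal matrix.

    ``track_peaks``/``track_bams`` map each of the four track names to its
    peak list and BAM path. The per-region numerator uses the base-level
    intersection of the region with the track's peaks (possibly several
    disjoint fragments, all summed).
    """
    for t in TRACKS:
        if t not in track_peaks or t not in track_bams:
            raise ValueError(f"missing track configuration: {t}")
    regions = list(region_set)
    values = np.zeros((len(regions), len(TRACKS)), dtype=float)
    for j, t in enumerate(TRACKS):
        jobs = [
            (r.chrom, intersect_interval_with_set(r, track_peaks[t])) for r in regions
        ]
        if not any(frags for _, frags in jobs):
            # no region overlaps any peak of this track: the whole column
            # is a structural 0 and the depth denominator is never needed
            logger.info("track %s: no region/peak overlap, column is 0", t)
            continue
        with AlignmentSource(track_bams[t]) as src:
            denom = genome_auc(src, mode=auc_mode)
            exclude = src.exclude_flags
        if n_workers <= 1 or len(jobs) < 2:
            col = _quantify_chunk(track_bams[t], exclude, auc_mode, jobs)
        else:
            bounds = np.linspace(0, len(jobs), n_workers + 1).astype(int)
            chunks = [jobs[a:b] for a, b in zip(bounds[:-1], bounds[1:]) if b > a]
            with ProcessPoolExecutor(max_workers=n_workers) as pool:
                parts = pool.map(
                    _quantify_chunk,
                    [track_bams[t]] * len(chunks),
                    [exclude] * len(chunks),
                    [auc_mode] * len(chunks),
                    chunks,
                )
                col = [v for part in parts for v in part]
        values[:, j] = 1e6 * np.asarray(col) / denom
        logger.info("quantified %s over %d regions (genome auc %.0f)", t, len(jobs), denom)
    return SignalMatrix(regions=regions, values=values)
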