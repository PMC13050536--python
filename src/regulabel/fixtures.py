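"""Synthetic toy datasets with planted regulatory archetypes.

Generates, on a small toy genome, everything the pipeline consumes —
single-end reads (BAM), per-base coverage (bigWig) and peak calls (BED)
for the four tracks, accessibility peaks, gene annotation, variant
positions — plus the planted truth labels, so every stage is testable
offline.

The model is deliberately minimal: fixed-length single-end reads whose
per-region count is Poisson with mean proportional to the archetype's
track intensity, plus uniform background reads at a configurable rate.
Peak calls are emitted exactly at planted regions with nonzero intensity
for the track (plus optional decoy peaks), so a zero intensity yields an
exactly-zero normalised signal — mirroring how real peak gating produces
structural zeros. Fragment-size, GC and mappability structure of real
libraries is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pyBigWig
import pysam
import yaml

from .classifier import (
    CTCF,
    ENHANCER,
    ENHANCER_CTCF,
    NOT_ASSIGNED,
    PROMOTER,
    PROMOTER_CTCF,
    assign_hybrid_label,
    assign_primary_label,
    rank_row,
)
from .genome_io import GeneRecord
from .intervals import GenomicInterval
from .signal import TRACKS


class DatasetConstructionError(ValueError):
    pass


@dataclass(frozen=True)
class ArchetypeSpec:
    """A planted element class: label, relative track intensities, extent.

    ``profile`` holds relative intensities in track order (H3K4me1,
    H3K4me3, H3K27ac, CTCF). The profile is validated against the rule
    engine at construction: passed noise-free through the rank transform
    and both phases it must reproduce ``label``.
    """

    label: str
    profile: tuple
    width: int = 300
    count: int = 10

    def __post_init__(self) -> None:
        if len(self.profile) != 4 or any(v < 0 for v in self.profile):
            raise DatasetConstructionError(
                f"{self.label}: profile must be 4 non-negative intensities"
            )
        if self.width <= 0 or self.count < 0:
            raise DatasetConstructionError(f"{self.label}: bad width/count")
        signals = np.asarray(self.profile, dtype=float)
        ranks = rank_row(signals)
        got = assign_hybrid_label(signals, ranks, assign_primary_label(signals, ranks))
        if got != self.label:
            raise DatasetConstructionError(
                f"profile {self.profile} classifies as {got!r}, not {self.label!r}"
            )


#: one archetype per class; intensities shaped like the canonical
#: chromatin signatures (promoters H3K4me3-high, enhancers H3K4me1-high,
#: boundary elements CTCF-dominated, hybrids adding CTCF binding)
DEFAULT_ARCHETYPES = (
    ArchetypeSpec(PROMOTER, (1, 10, 6, 0)),
    ArchetypeSpec(ENHANCER, (10, 1, 6, 0)),
    ArchetypeSpec(CTCF, (0, 0, 2, 10)),
    ArchetypeSpec(PROMOTER_CTCF, (0, 8, 5, 9)),
    ArchetypeSpec(ENHANCER_CTCF, (8, 0, 5, 9)),
    ArchetypeSpec(NOT_ASSIGNED, (0, 0, 0, 0)),
)

#: variant with every adjacent nonzero intensity separated >= 5x, for
#: noise-robustness regression tests
SEPARATED_ARCHETYPES = (
    ArchetypeSpec(PROMOTER, (0, 10, 2, 0)),
    ArchetypeSpec(ENHANCER, (10, 0, 2, 0)),
    ArchetypeSpec(CTCF, (0, 0, 2, 10)),
    ArchetypeSpec(PROMOTER_CTCF, (0, 10, 2, 50)),
    ArchetypeSpec(ENHANCER_CTCF, (10, 0, 2, 50)),
    ArchetypeSpec(NOT_ASSIGNED, (0, 0, 0, 0)),
)

GENE_BIOTYPES_CYCLE = ("protein_coding", "miRNA", "lncRNA", "pseudogene")


@dataclass
class SyntheticDataset:
    """In-memory synthetic dataset; ``write`` materialises it on disk."""

    chrom: str
    genome_length: int
    read_length: int
    reads: dict  # track -> sorted int array of read start positions
    track_peaks: dict  # track -> list of GenomicInterval
    accessibility_peaks: list
    genes: list
    variants: pd.DataFrame
    truth: pd.DataFrame  # chrom, start, end, label
    seed: int
    noise_level: float

    def pileup(self, track: str) -> np.ndarray:
        """Per-base read coverage of a track over the toy genome."""
        starts = self.reads[track]
        diff = np.zeros(self.genome_length + self.read_length + 1, dtype=np.int64)
        np.add.at(diff, starts, 1)
        np.add.at(diff, starts + self.read_length, -1)
        return np.cumsum(diff)[: self.genome_length].astype(float)


def generate_dataset(
    archetypes=DEFAULT_ARCHETYPES,
    genome_length: int = 200_000,
    noise_level: float = 0.0,
    seed: int = 0,
    read_length: int = 50,
    reads_per_unit: float = 10.0,
    min_gap: int = 200,
    max_gap: int = 600,
    n_decoy_peaks: int = 0,
    n_genes: int = 8,
    n_variants: int = 50,
    chrom: str = "chrS",
) -> SyntheticDataset:
    """Plant archetype regions on a toy genome and sample reads.

    Deterministic for a fixed seed. Planted regions never overlap; a
    genome too small for the requested instances raises
    DatasetConstructionError. Reads for track t over a planted region
    number Poisson(intensity_t * reads_per_unit); background reads per
    track number Poisson(noise_level * planted reads) and fall uniformly
    over the genome.
    """
    if not 0 <= noise_level <= 1:
        raise DatasetConstructionError("noise_level must be in [0, 1]")
    rng = np.random.default_rng(seed)

    instances = [spec for spec in archetypes for _ in range(spec.count)]
    rng.shuffle(instances)

    margin = max(read_length * 2, 100)
    pos = margin
    planted: list[tuple[GenomicInterval, ArchetypeSpec]] = []
    for spec in instances:
        pos += int(rng.integers(min_gap, max_gap + 1))
        iv = GenomicInterval(chrom, pos, pos + spec.width)
        pos += spec.width
        if pos > genome_length - margin:
            raise DatasetConstructionError(
                f"genome of {genome_length} bp too small for "
                f"{len(instances)} planted regions"
            )
        planted.append((iv, spec))

    reads: dict[str, np.ndarray] = {}
    for j, t in enumerate(TRACKS):
        starts: list[int] = []
        for iv, spec in planted:
            intensity = spec.profile[j]
            if intensity <= 0:
                continue
            n = int(rng.poisson(intensity * reads_per_unit))
            hi = max(iv.start + 1, iv.end - read_length + 1)
            starts.extend(rng.integers(iv.start, hi, size=n).tolist())
        if noise_level > 0:
            n_bg = int(rng.poisson(noise_level * len(starts))) if starts else 0
            starts.extend(
                rng.integers(0, genome_length - read_length + 1, size=n_bg).tolist()
            )
        reads[t] = np.sort(np.asarray(starts, dtype=np.int64))

    occupied = sorted((iv.start, iv.end) for iv, _ in planted)

    def _free(start: int, end: int) -> bool:
        return all(e <= start or end <= s for s, e in occupied)

    track_peaks: dict[str, list] = {t: [] for t in TRACKS}
    for j, t in enumerate(TRACKS):
        track_peaks[t] = [iv for iv, spec in planted if spec.profile[j] > 0]
        for _ in range(n_decoy_peaks):
            # rejection-sample a decoy clear of every planted region
            for _attempt in range(100):
                s = int(rng.integers(0, genome_length - 200))
                if _free(s, s + 200):
                    track_peaks[t].append(GenomicInterval(chrom, s, s + 200))
                    break
        track_peaks[t].sort()

    accessibility_peaks = [iv for iv, _ in planted]

    genes = []
    for i in range(n_genes):
        length = int(rng.integers(800, 3000))
        s = int(rng.integers(0, genome_length - length))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneRecord(
                interval=GenomicInterval(chrom, s, s + length, strand=strand),
                biotype=GENE_BIOTYPES_CYCLE[i % len(GENE_BIOTYPES_CYCLE)],
                name=f"gene{i}",
            )
        )

    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.sort(rng.integers(0, genome_length, size=n_variants)),
            "id": [f"var{i}" for i in range(n_variants)],
        }
    )

    truth = pd.DataFrame(
        sorted(
            ((iv.chrom, iv.start, iv.end, spec.label) for iv, spec in planted),
            key=lambda row: (row[0], row[1], row[2]),
        ),
        columns=["chrom", "start", "end", "label"],
    )

    return SyntheticDataset(
        chrom=chrom,
        genome_length=genome_length,
        read_length=read_length,
        reads=reads,
        track_peaks=track_peaks,
        accessibility_peaks=accessibility_peaks,
        genes=genes,
        variants=variants,
        truth=truth,
        seed=seed,
        noise_level=noise_level,
    )


def _write_bed(intervals, path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def _write_bam(starts, chrom, genome_length, read_length, path) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": genome_length + read_length}],
    }
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for i, s in enumerate(starts):
            a = pysam.AlignedSegment()
            a.query_name = f"r{i}"
            a.query_sequence = "A" * read_length
            a.flag = 0
            a.reference_id = 0
            a.reference_start = int(s)
            a.mapping_quality = 60
            a.cigartuples = [(0, read_length)]
            a.query_qualities = pysam.qualitystring_to_array("I" * read_length)
            bam.write(a)
    pysam.index(str(path))


def _write_bigwig(pileup, chrom, path) -> None:
    """Run-length encode a per-base pileup into a bigWig (zero runs omitted)."""
    bw = pyBigWig.open(str(path), "w")
    bw.addHeader([(chrom, len(pileup))])
    change = np.flatnonzero(np.diff(pileup)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(pileup)]))
    vals = pileup[starts]
    nz = vals > 0
    if nz.any():
        bw.addEntries(
            [chrom] * int(nz.sum()),
            starts[nz].astype(np.int64).tolist(),
            ends=ends[nz].astype(np.int64).tolist(),
            values=vals[nz].astype(float).tolist(),
        )
    bw.close()


def _write_gff3(genes, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, g in enumerate(genes):
            iv = g.interval
            attrs = f"ID=gene:{g.name};Name={g.name};gene_biotype={g.biotype}"
            fh.write(
                f"{iv.chrom}\ttoy\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
            )


def write_dataset(ds: SyntheticDataset, directory) -> dict:
    """Materialise the dataset in the full input layout the pipeline reads.

    Per histone/CTCF track: sorted+indexed BAM, bigWig (equal to the BAM
    pileup at every base), and peak BED; accessibility peaks as BED;
    genes as GFF3; variants as BED; the planted truth as TSV; and a ready
    ``config.yaml`` pointing at everything. Returns the path map.
    """
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict = {"tracks": {}}
    for t in TRACKS:
        bam = directory / f"{t}.bam"
        bw = directory / f"{t}.bw"
        bed = directory / f"{t}.bed"
        _write_bam(ds.reads[t], ds.chrom, ds.genome_length, ds.read_length, bam)
        _write_bigwig(ds.pileup(t), ds.chrom, bw)
        _write_bed(ds.track_peaks[t], bed)
        paths["tracks"][t] = {"bam": str(bam), "bigwig": str(bw), "bed": str(bed)}
    acc = directory / "accessibility.bed"
    _write_bed(ds.accessibility_peaks, acc)
    paths["accessibility_bed"] = str(acc)
    gff = directory / "genes.gff3"
    _write_gff3(ds.genes, gff)
    paths["genes"] = str(gff)
    var = directory / "variants.bed"
    with open(var, "w") as fh:
        for _, v in ds.variants.iterrows():
            fh.write(f"{v['chrom']}\t{v['pos']}\t{v['pos'] + 1}\t{v['id']}\n")
    paths["variants"] = str(var)
    truth = directory / "truth.tsv"
    ds.truth.to_csv(truth, sep="\t", index=False)
    paths["truth"] = str(truth)

    config = {
        "tracks": paths["tracks"],
        "accessibility_bed": str(acc),
        "blacklist_bed": None,
        "genes": {
            "path": str(gff),
            "biotypes": ["protein-coding", "miRNA", "lncRNA"],
        },
        "variants": {"path": str(var), "one_based": False},
        "params": {},
        "outdir": str(directory / "out"),
    }
    cfg_path = directory / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    paths["config"] = str(cfg_path)
    return paths
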