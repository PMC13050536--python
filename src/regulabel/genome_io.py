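"""Readers and writers for the standard formats the pipeline touches.

BED and variant tables are parsed here; bigWig goes through pyBigWig,
BAM through pysam and GFF/GTF through gffutils. Everything is converted
to 0-based half-open coordinates on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
import pyBigWig
import pysam

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

#: canonical biotype vocabulary; anything unrecognised maps to "other"
BIOTYPE_ALIASES = {
    "protein_coding": "protein-coding",
    "protein-coding": "protein-coding",
    "mirna": "miRNA",
    "mi_rna": "miRNA",
    "lncrna": "lncRNA",
    "lnc_rna": "lncRNA",
    "long_noncoding_rna": "lncRNA",
}


@dataclass(frozen=True)
class GeneRecord:
    """A stranded gene span with a normalised biotype."""

    interval: GenomicInterval
    biotype: str
    name: str

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.name!r} lacks a definite strand")


def read_bed(path) -> list:
    """Parse a BED3+ file into GenomicIntervals, preserving file order.

    Coordinates are taken as 0-based half-open. Columns beyond the third
    are kept verbatim in ``extras``; column 6, when present and valid, also
    populates ``strand``. Malformed lines raise with the line number.
    """
    intervals = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 columns")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from exc
            strand = "."
            if len(fields) >= 6 and fields[5] in ("+", "-"):
                strand = fields[5]
            try:
                iv = GenomicInterval(
                    chrom, start, end, strand=strand, extras=tuple(fields[3:])
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            intervals.append(iv)
    return intervals


#: fixed column layout of the annotation BED; documented in the file header
ANNOTATION_COLUMNS = [
    "chrom", "start", "end", "label", "score", "strand",
    "A_H3K4me1", "A_H3K4me3", "A_H3K27ac", "A_CTCF",
    "R_H3K4me1", "R_H3K4me3", "R_H3K27ac", "R_CTCF",
    "activity", "log_distance_tss",
]


def write_annotation_bed(records, path) -> None:
    """Write AnnotationRecords as BED6+.

    Name column carries the regulatory label; score is the row's maximum
    normalised signal rescaled to 0-1000 over the file (0 when all signals
    are zero); strand is always ".". Extra columns: the four normalised
    signals, the four ranks, the enhancer-activity subclass, and
    log10(d+1) distance to the nearest TSS ("NA" when not computed).
    """
    records = list(records)
    max_signal = max((float(np.max(r.signals)) for r in records), default=0.0)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(ANNOTATION_COLUMNS) + "\n")
        for rec in records:
            row_max = float(np.max(rec.signals))
            score = int(round(1000.0 * row_max / max_signal)) if max_signal > 0 else 0
            dist = (
                "NA"
                if rec.log_distance_tss is None or np.isnan(rec.log_distance_tss)
                else f"{rec.log_distance_tss:.6g}"
            )
            fields = [
                rec.region.chrom, str(rec.region.start), str(rec.region.end),
                rec.label, str(score), ".",
                *(f"{v:.10g}" for v in rec.signals),
                *(str(int(v)) for v in rec.ranks),
                rec.activity, dist,
            ]
            fh.write("\t".join(fields) + "\n")


def read_annotation_table(path) -> pd.DataFrame:
    """Round-trip reader for files written by :func:`write_annotation_bed`."""
    df = pd.read_csv(path, sep="\t", comment=None, header=0)
    df.columns = [c.lstrip("#") for c in df.columns]
    return df


def read_gene_annotation(path, biotypes) -> list:
    """Load gene records from GFF3/GTF, keeping the requested biotypes.

    GFF/GTF 1-based inclusive coordinates are converted to 0-based
    half-open. The biotype is taken from the first of ``gene_biotype``,
    ``gene_type`` or ``biotype`` attributes and normalised (e.g.
    ``protein_coding`` -> ``protein-coding``). Strandless records are
    skipped with a warning rather than failing the run.
    """
    biotypes = set(biotypes)
    if not biotypes:
        return []
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        if feat.strand not in ("+", "-"):
            logger.warning("gene %s has no strand; skipped", feat.id)
            continue
        raw = None
        for key in ("gene_biotype", "gene_type", "biotype"):
            if key in feat.attributes:
                raw = feat.attributes[key][0]
                break
        biotype = BIOTYPE_ALIASES.get((raw or "").lower(), raw if raw else "other")
        if biotype not in biotypes:
            continue
        name = feat.attributes.get("Name", [feat.id])[0]
        genes.append(
            GeneRecord(
                interval=GenomicInterval(
                    feat.seqid, feat.start - 1, feat.end, strand=feat.strand
                ),
                biotype=biotype,
                name=name,
            )
        )
    return genes


def read_variants(path, one_based: bool = False) -> pd.DataFrame:
    """Read variant positions from BED3+ or a (chrom, pos, id) TSV.

    ``one_based`` declares the convention of a position-style table
    (e.g. rsID tables); internally everything becomes 0-based. BED input
    uses the start coordinate of each record.
    """
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: fewer than 2 columns")
            chrom = fields[0]
            try:
                pos = int(fields[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer position") from exc
            if one_based:
                pos -= 1
            # BED rows carry an end in column 2 and id in column 3
            if len(fields) >= 3 and fields[2].isdigit():
                ident = fields[3] if len(fields) >= 4 else f"var{lineno}"
            else:
                ident = fields[2] if len(fields) >= 3 else f"var{lineno}"
            if pos < 0:
                raise ValueError(f"{path}:{lineno}: negative position")
            rows.append((chrom, pos, ident))
    return pd.DataFrame(rows, columns=["chrom", "pos", "id"])


class CoverageTrack:
    """Read-only view of a bigWig coverage track.

    Positions outside recorded runs, and whole chromosomes absent from
    the file, read as 0 (one warning per unknown chromosome).
    """

    def __init__(self, path):
        self.path = str(path)
        self._bw = pyBigWig.open(self.path)
        self._warned: set[str] = set()

    def chroms(self) -> dict:
        return dict(self._bw.chroms())

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base coverage over [start, end); out-of-range bases are 0."""
        out = np.zeros(end - start, dtype=float)
        size = self._bw.chroms(chrom)
        if not size:
            if chrom not in self._warned:
                logger.warning("chromosome %s absent from %s; coverage read as 0",
                               chrom, self.path)
                self._warned.add(chrom)
            return out
        lo, hi = max(start, 0), min(end, size)
        if lo >= hi:
            return out
        vals = np.asarray(self._bw.values(chrom, lo, hi), dtype=float)
        if vals.size != hi - lo:  # a track with no entries yields nothing
            return out
        np.nan_to_num(vals, copy=False)
        out[lo - start : hi - start] = vals
        return out

    def close(self) -> None:
        self._bw.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


class AlignmentSource:
    """Sorted, indexed BAM for one assay.

    Duplicate, QC-fail, unmapped, secondary and supplementary reads are
    excluded by default. ``blocks(chrom, start, end)`` yields the
    CIGAR-consumed reference spans of each passing read overlapping the
    window (soft-clips never consume reference bases).
    """

    EXCLUDE_FLAGS = (
        pysam.FUNMAP | pysam.FSECONDARY | pysam.FQCFAIL | pysam.FDUP | pysam.FSUPPLEMENTARY
    )

    def __init__(self, path, exclude_flags: int | None = None):
        self.path = str(path)
        self.exclude_flags = (
            self.EXCLUDE_FLAGS if exclude_flags is None else exclude_flags
        )
        self._af = pysam.AlignmentFile(self.path, "rb")

    def references(self) -> set:
        return set(self._af.references)

    def _passes(self, read) -> bool:
        return not (read.flag & self.exclude_flags)

    def fetch(self, chrom: str, start: int, end: int):
        if chrom not in self._af.references:
            return
        for read in self._af.fetch(chrom, start, end):
            if self._passes(read):
                yield read

    def iter_all(self):
        for read in self._af.fetch():
            if self._passes(read):
                yield read

    def close(self) -> None:
        self._af.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def ensure_bam_index(path) -> None:
    """Index a coordinate-sorted BAM in place when the .bai is missing."""
    p = Path(path)
    if not (p.with_suffix(".bam.bai").exists() or Path(str(p) + ".bai").exists()):
        pysam.index(str(p))
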