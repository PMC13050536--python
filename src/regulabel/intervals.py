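"""Genomic interval primitives.

All coordinates throughout the package are BED-convention: 0-based,
half-open [start, end). 1-based formats (GFF/GTF, 1-based variant tables)
are converted on read and never stored internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span [start, end) on a named chromosome.

    ``extras`` carries opaque trailing BED columns; it never participates
    in equality, ordering or hashing, so two intervals with identical
    coordinates deduplicate regardless of annotation payload.
    """

    chrom: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)
    extras: tuple = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def centre(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def key(self) -> tuple:
        return (self.chrom, self.start, self.end)


def build_interval_trees(intervals) -> dict:
    """Per-chromosome IntervalTree over half-open spans."""
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def remove_blacklisted(regions, blacklist):
    """Drop every region sharing >= 1 bp with any blacklist interval.

    A region touching a blacklist interval only at a shared boundary
    (half-open coordinates) is retained. Order is preserved; an empty
    blacklist is the identity.
    """
    if not blacklist:
        return list(regions)
    trees = build_interval_trees(blacklist)
    kept = []
    for r in regions:
        tree = trees.get(r.chrom)
        if tree is None or not tree.overlaps(r.start, r.end):
            kept.append(r)
    return kept


def intersect_interval_with_set(region: GenomicInterval, others) -> list:
    """Base-level intersection of ``region`` with a set of intervals.

    Overlapping members of ``others`` are unioned first so no base is
    counted twice. Returns disjoint, sorted (start, end) fragments within
    the region; an empty list when nothing overlaps.
    """
    spans = sorted(
        (max(region.start, o.start), min(region.end, o.end))
        for o in others
        if o.chrom == region.chrom and o.start < region.end and region.start < o.end
    )
    merged: list[tuple[int, int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def validate_chrom_namespaces(named_sets: dict) -> None:
    """Hard error on incompatible chromosome naming between inputs.

    Two non-empty inputs that share no chromosome *and* use different
    naming styles (UCSC "chr1" vs Ensembl "1") are treated as a chr1-vs-1
    mismatch and abort: silent zero-signal is the worst failure mode.
    Inputs confined to genuinely different chromosomes of the same style
    are legitimate and pass.
    """

    def style(names: set) -> set:
        return {n.lower().startswith("chr") for n in names}

    items = [(name, s) for name, s in named_sets.items() if s]
    for i, (name_a, a) in enumerate(items):
        for name_b, b in items[i + 1 :]:
            if not (a & b) and not (style(a) & style(b)):
                raise ValueError(
                    f"disjoint chromosome namespaces between {name_a!r} ({sorted(a)[:3]}...) "
                    f"and {name_b!r} ({sorted(b)[:3]}...)"
                )
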