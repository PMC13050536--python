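"""Candidate-region construction and the coverage-difference ordering.

Candidate regulatory elements are anchored at chromatin-accessibility
peaks, optionally unioned with CTCF peaks. "Union" means exact-coordinate
deduplication, never interval merging: overlapping peaks of different
extents stay distinct candidates, because each is quantified
independently downstream and merging would silently change the region
count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import CoverageTrack
from .intervals import GenomicInterval, remove_blacklisted, validate_chrom_namespaces

logger = logging.getLogger(__name__)

MARK_COLUMNS = ("H3K4me1", "H3K4me3")


@dataclass
class RegionSet:
    """Ordered candidate regions with per-region source provenance.

    ``provenance[i]`` is a frozenset drawn from {"accessibility", "ctcf"};
    both members appear when the two inputs contained the exact same
    coordinates.
    """

    regions: list = field(default_factory=list)
    provenance: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [r.chrom for r in self.regions],
                "start": [r.start for r in self.regions],
                "end": [r.end for r in self.regions],
                "source": ["+".join(sorted(p)) for p in self.provenance],
            }
        )


def build_union_regions(
    accessibility_peaks,
    ctcf_peaks,
    blacklist=(),
    anchor_mode: str = "union",
) -> RegionSet:
    """Concatenate accessibility and CTCF peaks into the candidate list.

    Exact duplicates collapse to one region with provenance "both";
    overlapping-but-non-identical peaks are both retained. Regions
    overlapping any blacklist interval (>= 1 bp) are removed outright.
    The canonical order is (chrom, start, end).

    ``anchor_mode`` = "accessibility_only" drops CTCF-only anchors, for
    datasets where every candidate must intersect open chromatin.
    """
    if anchor_mode not in ("union", "accessibility_only"):
        raise ValueError(f"unknown anchor_mode {anchor_mode!r}")
    if ctcf_peaks and accessibility_peaks:
        validate_chrom_namespaces(
            {
                "accessibility peaks": {p.chrom for p in accessibility_peaks},
                "CTCF peaks": {p.chrom for p in ctcf_peaks},
            }
        )

    prov: dict[tuple, set] = {}
    for peak in accessibility_peaks:
        prov.setdefault(peak.key(), set()).add("accessibility")
    if anchor_mode == "union":
        for peak in ctcf_peaks:
            prov.setdefault(peak.key(), set()).add("ctcf")
    else:
        acc_keys = set(prov)
        for peak in ctcf_peaks:
            if peak.key() in acc_keys:
                prov[peak.key()].add("ctcf")

    keys = sorted(prov)
    regions = [GenomicInterval(*k) for k in keys]
    n_before = len(regions)
    kept = remove_blacklisted(regions, blacklist)
    kept_keys = {r.key() for r in kept}
    logger.info(
        "candidate regions: %d unique, %d after blacklist removal",
        n_before, len(kept),
    )
    return RegionSet(
        regions=kept,
        provenance=[frozenset(prov[k]) for k in keys if k in kept_keys],
    )


def compute_coverage_matrix(
    region_set: RegionSet, me1: CoverageTrack, me3: CoverageTrack
) -> pd.DataFrame:
    """Summed per-base bigWig coverage of each region for H3K4me1/H3K4me3.

    This mirrors a bedtools multicov-style quantification over the
    coverage tracks; it feeds only the meta-plot row ordering, never the
    classification.
    """
    if len(region_set) == 0:
        raise ValueError("empty region set")
    rows = []
    for r in region_set:
        rows.append(
            (
                float(me1.values(r.chrom, r.start, r.end).sum()),
                float(me3.values(r.chrom, r.start, r.end).sum()),
            )
        )
    return pd.DataFrame(rows, columns=list(MARK_COLUMNS))


def order_by_mark_difference(cov: pd.DataFrame, region_set: RegionSet) -> np.ndarray:
    """Row permutation by (H3K4me3 - H3K4me1) coverage, descending.

    Ties break by (chrom, start, end) ascending. Used only to order
    meta-plot rows (promoter-like signal on top); classification is
    order-independent.
    """
    diff = cov["H3K4me3"].to_numpy() - cov["H3K4me1"].to_numpy()
    keys = [r.key() for r in region_set]
    idx = sorted(range(len(keys)), key=lambda i: (-diff[i], keys[i]))
    return np.asarray(idx, dtype=int)
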