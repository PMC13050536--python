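"""Downstream analyses over classified regions.

Strand-aware TSS distances, variant-element intersection counts, the
meta-plot coverage matrix around region centres, and the class
distribution summary.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .classifier import ALL_LABELS
from .genome_io import CoverageTrack

logger = logging.getLogger(__name__)


def build_tss_registry(genes) -> pd.DataFrame:
    """One transcription start site per gene, strand-aware.

    Forward-strand genes start transcribing at the interval start;
    reverse-strand genes at the last covered base (end - 1, 0-based).
    Genes are expected pre-filtered to the allowed biotypes.
    """
    rows = []
    for g in genes:
        iv = g.interval
        if iv.strand == "+":
            pos = iv.start
        elif iv.strand == "-":
            pos = iv.end - 1
        else:
            logger.warning("gene %s has no strand; skipped from TSS registry", g.name)
            continue
        rows.append((iv.chrom, pos, iv.strand, g.name))
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "name"])


def log_distance_to_tss(region, registry: pd.DataFrame) -> float:
    """log10(d + 1) where d is the bp gap to the nearest TSS.

    A TSS inside [start, end) gives d = 0 exactly; a TSS g bases beyond
    either edge gives d = g (so d = 9 -> 1.0, d = 999 -> 3.0). NaN when
    the registry has no TSS on the region's chromosome.
    """
    if registry.empty:
        raise ValueError("empty TSS registry")
    pos = registry.loc[registry["chrom"] == region.chrom, "pos"].to_numpy()
    if pos.size == 0:
        return float("nan")
    d = np.maximum.reduce(
        [region.start - pos, pos - (region.end - 1), np.zeros_like(pos)]
    ).min()
    return float(np.log10(d + 1))


def annotate_tss_distances(records, registry: pd.DataFrame) -> None:
    """Fill ``log_distance_tss`` on each AnnotationRecord in place."""
    for rec in records:
        rec.log_distance_tss = log_distance_to_tss(rec.region, registry)


def intersect_variants(variants: pd.DataFrame, records):
    """Assign variants to every containing element (half-open containment).

    Returns ``(summary, per_variant)``:

    * ``summary`` — DataFrame indexed by label with ``n_hits`` (one per
      variant-element pair; a variant inside two overlapping elements
      contributes to both) and ``n_variants`` (distinct variants per
      label), plus an ``unannotated`` row for variants hitting nothing.
    * ``per_variant`` — one row per variant-element pair (or per lone
      variant), with a ``multi_hit`` flag on variants inside more than
      one element.
    """
    trees: dict[str, IntervalTree] = {}
    for i, rec in enumerate(records):
        r = rec.region
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, i)

    rows = []
    pair_counts = {lab: 0 for lab in ALL_LABELS}
    label_variants: dict[str, set] = {lab: set() for lab in ALL_LABELS}
    n_unannotated = 0
    for v_idx, v in variants.iterrows():
        tree = trees.get(v["chrom"])
        hits = sorted(tree[v["pos"]], key=lambda iv: (iv.begin, iv.end, iv.data)) if tree else []
        if not hits:
            n_unannotated += 1
            rows.append((v["id"], v["chrom"], v["pos"], "", -1, -1, "unannotated", False))
            continue
        multi = len(hits) > 1
        for hit in hits:
            rec = records[hit.data]
            pair_counts[rec.label] += 1
            label_variants[rec.label].add(v_idx)
            rows.append(
                (
                    v["id"], v["chrom"], v["pos"],
                    rec.region.chrom, rec.region.start, rec.region.end,
                    rec.label, multi,
                )
            )
    per_variant = pd.DataFrame(
        rows,
        columns=[
            "variant_id", "chrom", "pos",
            "element_chrom", "element_start", "element_end",
            "label", "multi_hit",
        ],
    )
    summary = pd.DataFrame(
        {
            "label": list(ALL_LABELS) + ["unannotated"],
            "n_hits": [pair_counts[lab] for lab in ALL_LABELS] + [n_unannotated],
            "n_variants": [len(label_variants[lab]) for lab in ALL_LABELS]
            + [n_unannotated],
        }
    ).set_index("label")
    return summary, per_variant


def compute_metaplot(
    regions, track: CoverageTrack, flank: int = 2000, bin_width: int = 10
) -> np.ndarray:
    """Binned coverage around each region centre.

    Row i covers [centre_i - flank, centre_i + flank) in ``bin_width``
    bins of mean per-base coverage; bases beyond chromosome edges read 0.
    Rows follow the supplied region order (use the mark-difference
    permutation for the canonical stacked rendering).
    """
    if flank % bin_width != 0:
        raise ValueError("flank must be divisible by bin_width")
    n_bins = 2 * flank // bin_width
    regions = list(regions)
    out = np.zeros((len(regions), n_bins), dtype=float)
    for i, r in enumerate(regions):
        c = r.centre
        vals = track.values(r.chrom, c - flank, c + flank)
        out[i] = vals.reshape(n_bins, bin_width).mean(axis=1)
    return out


def class_distribution(records) -> pd.DataFrame:
    """Count and percentage per regulatory label.

    Percentages are over all regions (Not assigned included) and sum to
    100 within rounding; empty input gives an empty frame.
    """
    records = list(records)
    if not records:
        return pd.DataFrame(columns=["label", "count", "percentage"]).set_index("label")
    counts = {lab: 0 for lab in ALL_LABELS}
    for rec in records:
        counts[rec.label] += 1
    total = len(records)
    df = pd.DataFrame(
        {
            "label": list(ALL_LABELS),
            "count": [counts[lab] for lab in ALL_LABELS],
            "percentage": [100.0 * counts[lab] / total for lab in ALL_LABELS],
        }
    ).set_index("label")
    return df
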