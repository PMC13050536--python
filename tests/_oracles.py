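"""Independent oracles used by the test suite.

Everything here is written from the rule definitions directly, without
importing the implementation's ranking or clause logic, so agreement is
a genuine cross-check and not a tautology.
"""

import numpy as np
import pysam

# track order: t1=H3K4me1, t2=H3K4me3, t3=H3K27ac, t4=CTCF
# tie priority (earlier wins the smaller rank): t2, t1, t4, t3
TIE_PRIORITY = [1, 0, 3, 2]


def oracle_ranks(signals):
    """Selection-style descending ranking with explicit tie handling."""
    remaining = list(range(4))
    ranks = [0] * 4
    for rank in range(1, 5):
        best = None
        for t in sorted(remaining, key=TIE_PRIORITY.index):
            if best is None or signals[t] > signals[best]:
                best = t
        ranks[best] = rank
        remaining.remove(best)
    return ranks


def oracle_label(signals, ranks, hybrid_scope="all"):
    """Clause-by-clause evaluation of the two annotation phases."""
    a1, a2, a3, a4 = signals
    r1, r2, r3, r4 = ranks
    if a1 == a2 == a3 == a4 == 0:
        return "Not assigned"

    enhancer_clauses = [
        r1 == 1 and r2 == 2,
        r1 == 1 and r3 == 2,
        r1 == 2 and r3 == 1,
        r1 == 1 and a2 == 0 and a3 == 0 and a4 == 0,
    ]
    promoter_clauses = [
        r2 == 1 and r1 == 2,
        r2 == 1 and r3 == 2,
        r2 == 2 and r3 == 1,
        r2 == 1 and a1 == 0 and a3 == 0 and a4 == 0,
    ]
    ctcf_clauses = [
        r4 == 1 and r3 == 2,
        r4 == 2 and r3 == 1,
        r4 == 1 and a1 == 0 and a2 == 0 and a3 == 0,
    ]
    if any(enhancer_clauses):
        phase1 = "Enhancer"
    elif any(promoter_clauses):
        phase1 = "Promoter"
    elif any(ctcf_clauses):
        phase1 = "CTCF"
    else:
        phase1 = "Not assigned"

    if hybrid_scope == "phase1_labelled" and phase1 not in ("Enhancer", "Promoter"):
        return phase1

    enh_ctcf = (
        (r4 == 1 and r1 == 2 and a1 != 0 and a4 != 0)
        or (r4 == 2 and r1 == 1 and a1 != 0 and a4 != 0)
        or (a1 != 0 and a2 == 0 and a3 != 0 and a4 != 0)
    )
    prom_ctcf = (
        (r4 == 1 and r2 == 2 and a2 != 0 and a4 != 0)
        or (r4 == 2 and r2 == 1 and a2 != 0 and a4 != 0)
        or (a1 == 0 and a2 != 0 and a3 != 0 and a4 != 0)
    )
    if enh_ctcf and prom_ctcf:
        return "Enhancer/CTCF" if a1 > a2 else "Promoter/CTCF"
    if enh_ctcf:
        return "Enhancer/CTCF"
    if prom_ctcf:
        return "Promoter/CTCF"
    return phase1


def phase1_fired_classes(signals, ranks):
    """Which phase-1 clause sets fire, for the exclusivity check."""
    a1, a2, a3, a4 = signals
    r1, r2, r3, r4 = ranks
    fired = []
    if (
        (r1 == 1 and r2 == 2) or (r1 == 1 and r3 == 2) or (r1 == 2 and r3 == 1)
        or (r1 == 1 and a2 == 0 and a3 == 0 and a4 == 0)
    ):
        fired.append("Enhancer")
    if (
        (r2 == 1 and r1 == 2) or (r2 == 1 and r3 == 2) or (r2 == 2 and r3 == 1)
        or (r2 == 1 and a1 == 0 and a3 == 0 and a4 == 0)
    ):
        fired.append("Promoter")
    if (
        (r4 == 1 and r3 == 2) or (r4 == 2 and r3 == 1)
        or (r4 == 1 and a1 == 0 and a2 == 0 and a3 == 0)
    ):
        fired.append("CTCF")
    return fired


def enumerate_rank_zero_cases():
    """All consistent (signals, ranks) combinations.

    For every zero/nonzero pattern over the four tracks and every
    ordering of the nonzero tracks, build a signal vector with strictly
    decreasing positive values on the nonzero tracks; zeros rank below
    every nonzero value, ordered among themselves by the tie priority.
    Includes all 24 strict-rank permutations (the all-nonzero patterns).
    """
    from itertools import combinations, permutations

    cases = []
    for k in range(5):
        for nonzero in combinations(range(4), k):
            for order in permutations(nonzero):
                signals = [0.0] * 4
                for depth, t in enumerate(order):
                    signals[t] = float(len(order) - depth)
                ranks = [0] * 4
                for depth, t in enumerate(order):
                    ranks[t] = depth + 1
                zeros = [t for t in range(4) if t not in nonzero]
                for j, t in enumerate(sorted(zeros, key=TIE_PRIORITY.index)):
                    ranks[t] = len(order) + 1 + j
                cases.append((signals, ranks))
    return cases


def pileup_from_bam(bam_path, chrom, length):
    """Exhaustive per-base coverage oracle built read-by-read."""
    cov = np.zeros(length, dtype=np.int64)
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        for read in bam.fetch(chrom):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.is_duplicate or read.is_qcfail:
                continue
            for bs, be in read.get_blocks():
                cov[bs : min(be, length)] += 1
    return cov


def oracle_signal_value(cov, region, peaks):
    """1e6 * (coverage inside region-and-peak bases) / (total coverage)."""
    region_mask = np.zeros(len(cov), dtype=bool)
    region_mask[region.start : region.end] = True
    peak_mask = np.zeros(len(cov), dtype=bool)
    for p in peaks:
        if p.chrom == region.chrom:
            peak_mask[p.start : p.end] = True
    total = cov.sum()
    return 1e6 * cov[region_mask & peak_mask].sum() / total
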