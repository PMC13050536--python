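"""TSS distances, variant intersection, meta-plots, class distribution."""

import numpy as np
import pandas as pd
import pytest

from regulabel.classifier import AnnotationRecord
from regulabel.downstream import (
    build_tss_registry,
    class_distribution,
    compute_metaplot,
    intersect_variants,
    log_distance_to_tss,
)
from regulabel.genome_io import CoverageTrack, GeneRecord
from regulabel.intervals import GenomicInterval

from conftest import write_toy_bigwig


def iv(chrom, start, end, strand="."):
    return GenomicInterval(chrom, start, end, strand=strand)


def rec(region, label):
    return AnnotationRecord(
        region=region, signals=np.zeros(4), ranks=np.array([1, 2, 3, 4]),
        label=label, activity="not-applicable",
    )


class TestTSSRegistry:
    def test_strand_aware_positions(self):
        genes = [
            GeneRecord(iv("chr1", 100, 500, "+"), "protein-coding", "fwd"),
            GeneRecord(iv("chr1", 100, 500, "-"), "protein-coding", "rev"),
        ]
        reg = build_tss_registry(genes)
        assert reg.loc[reg["name"] == "fwd", "pos"].item() == 100
        assert reg.loc[reg["name"] == "rev", "pos"].item() == 499

    def test_empty_gene_list(self):
        assert build_tss_registry([]).empty


class TestLogDistance:
    def _registry(self, positions):
        return pd.DataFrame(
            {"chrom": "chr1", "pos": positions, "strand": "+",
             "name": [f"g{i}" for i in range(len(positions))]}
        )

    @pytest.mark.parametrize(
        "region,tss,expected",
        [
            ((100, 200), 150, 0.0),      # TSS inside -> exactly 0
            ((100, 200), 208, 1.0),      # 9 bp beyond the last base -> log10(10)
            ((100, 200), 1198, 3.0),     # 999 bp away -> log10(1000)
            ((100, 200), 91, 1.0),       # 9 bp upstream of start
        ],
    )
    def test_hand_computed_values(self, region, tss, expected):
        got = log_distance_to_tss(iv("chr1", *region), self._registry([tss]))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_nearest_of_many_and_monotonicity(self):
        reg = self._registry([0, 5000])
        d_near = log_distance_to_tss(iv("chr1", 100, 200), reg)
        assert d_near == pytest.approx(np.log10(101))
        gaps = [10, 100, 1000, 10000]
        vals = [
            log_distance_to_tss(iv("chr1", 100, 200), self._registry([199 + g]))
            for g in gaps
        ]
        assert vals == sorted(vals)

    def test_empty_registry_errors_and_missing_chrom_is_nan(self):
        with pytest.raises(ValueError):
            log_distance_to_tss(iv("chr1", 0, 10), pd.DataFrame(columns=["chrom", "pos"]))
        assert np.isnan(log_distance_to_tss(iv("chr9", 0, 10), self._registry([5])))


class TestVariantIntersection:
    def test_containment_and_boundary(self):
        records = [rec(iv("chr1", 100, 200), "Enhancer")]
        variants = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "pos": [150, 200], "id": ["in", "edge"]}
        )
        summary, per_variant = intersect_variants(variants, records)
        assert summary.loc["Enhancer", "n_hits"] == 1
        assert summary.loc["unannotated", "n_hits"] == 1
        assert per_variant.loc[per_variant["variant_id"] == "edge", "label"].item() == "unannotated"

    def test_multi_hit_counted_in_both(self):
        records = [rec(iv("chr1", 100, 300), "Enhancer"), rec(iv("chr1", 200, 400), "Promoter")]
        variants = pd.DataFrame({"chrom": ["chr1"], "pos": [250], "id": ["v"]})
        summary, per_variant = intersect_variants(variants, records)
        assert summary.loc["Enhancer", "n_hits"] == 1
        assert summary.loc["Promoter", "n_hits"] == 1
        assert per_variant["multi_hit"].all()

    def test_random_counts_match_all_pairs_oracle(self):
        rng = np.random.default_rng(5)
        labels = ["Enhancer", "Promoter", "CTCF", "Not assigned"]
        records = []
        for i in range(50):
            s = int(rng.integers(0, 10000))
            records.append(rec(iv("chr1", s, s + int(rng.integers(50, 400))), labels[i % 4]))
        variants = pd.DataFrame(
            {"chrom": "chr1", "pos": rng.integers(0, 11000, 1000),
             "id": [f"v{i}" for i in range(1000)]}
        )
        summary, _ = intersect_variants(variants, records)
        oracle = {lab: 0 for lab in labels}
        unannot = 0
        for pos in variants["pos"]:
            hits = [r for r in records if r.region.start <= pos < r.region.end]
            for r in hits:
                oracle[r.label] += 1
            if not hits:
                unannot += 1
        for lab in labels:
            assert summary.loc[lab, "n_hits"] == oracle[lab]
        assert summary.loc["unannotated", "n_hits"] == unannot
        # totals: per-label hits + unannotated >= number of variants
        assert summary["n_hits"].sum() >= len(variants)


class TestMetaplot:
    def test_constant_and_zero_coverage(self, tmp_path):
        track = CoverageTrack(write_toy_bigwig(tmp_path / "c.bw", "chr1", np.ones(10000)))
        mat = compute_metaplot([iv("chr1", 4000, 4400)], track, flank=2000, bin_width=10)
        assert mat.shape == (1, 400)
        assert np.allclose(mat, 1.0)
        zero = CoverageTrack(write_toy_bigwig(tmp_path / "z.bw", "chr1", np.zeros(10000)))
        assert np.allclose(compute_metaplot([iv("chr1", 4000, 4400)], zero, 2000, 10), 0.0)

    def test_unit_spike_at_centre(self, tmp_path):
        vals = np.zeros(10000)
        vals[5000] = 1.0
        track = CoverageTrack(write_toy_bigwig(tmp_path / "s.bw", "chr1", vals))
        mat = compute_metaplot([iv("chr1", 4900, 5100)], track, flank=2000, bin_width=10)
        centre_bin = 2000 // 10  # first bin of the right flank holds base 5000
        assert mat[0, centre_bin] == pytest.approx(0.1)
        assert mat.sum() == pytest.approx(0.1)

    def test_edge_truncation_reads_zero(self, tmp_path):
        track = CoverageTrack(write_toy_bigwig(tmp_path / "e.bw", "chr1", np.ones(3000)))
        mat = compute_metaplot([iv("chr1", 0, 100)], track, flank=2000, bin_width=10)
        # window [-1950, 2050): the left flank is mostly off-chromosome
        assert mat[0, 0] == 0.0
        assert mat[0, -1] == 1.0

    def test_stacked_identical_regions_identical_rows(self, tmp_path):
        rng = np.random.default_rng(9)
        track = CoverageTrack(
            write_toy_bigwig(tmp_path / "r.bw", "chr1", rng.integers(0, 5, 10000).astype(float))
        )
        regions = [iv("chr1", 4000, 4500)] * 3
        mat = compute_metaplot(regions, track, flank=1000, bin_width=10)
        assert np.array_equal(mat[0], mat[1]) and np.array_equal(mat[1], mat[2])

    def test_indivisible_flank_rejected(self, tmp_path):
        track = CoverageTrack(write_toy_bigwig(tmp_path / "x.bw", "chr1", np.ones(100)))
        with pytest.raises(ValueError):
            compute_metaplot([iv("chr1", 0, 10)], track, flank=25, bin_width=10)


class TestClassDistribution:
    def test_quarter_each(self):
        records = [
            rec(iv("chr1", 0, 10), "Enhancer"),
            rec(iv("chr1", 20, 30), "Promoter"),
            rec(iv("chr1", 40, 50), "CTCF"),
            rec(iv("chr1", 60, 70), "Not assigned"),
        ]
        dist = class_distribution(records)
        for lab in ("Enhancer", "Promoter", "CTCF", "Not assigned"):
            assert dist.loc[lab, "percentage"] == 25.0
        assert dist["percentage"].sum() == pytest.approx(100.0)

    def test_empty(self):
        assert class_distribution([]).empty

    def test_random_tally(self):
        rng = np.random.default_rng(1)
        labels = ["Enhancer", "Promoter", "CTCF", "Enhancer/CTCF", "Promoter/CTCF", "Not assigned"]
        picks = rng.choice(labels, 1000)
        records = [rec(iv("chr1", 10 * i, 10 * i + 5), lab) for i, lab in enumerate(picks)]
        dist = class_distribution(records)
        for lab in labels:
            assert dist.loc[lab, "count"] == int((picks == lab).sum())
        assert dist["percentage"].sum() == pytest.approx(100.0)
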