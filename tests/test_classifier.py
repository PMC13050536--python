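"""Rank transform and the two-phase rule engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from regulabel.classifier import (
    ALL_LABELS,
    CTCF,
    ENHANCER,
    ENHANCER_CTCF,
    NOT_ASSIGNED,
    PROMOTER,
    PROMOTER_CTCF,
    RuleBasedElementClassifier,
    assign_hybrid_label,
    assign_primary_label,
    classify_all,
    classify_enhancer_activity,
    rank_row,
)
from regulabel.intervals import GenomicInterval
from regulabel.signal import SignalMatrix

from _oracles import enumerate_rank_zero_cases, oracle_label, oracle_ranks, phase1_fired_classes


class TestRankRow:
    @pytest.mark.parametrize(
        "signals,expected",
        [
            ([10, 5, 2, 1], [1, 2, 3, 4]),
            ([2, 10, 5, 1], [3, 1, 2, 4]),
            ([5, 5, 0, 0], [2, 1, 4, 3]),  # ties: H3K4me3 beats H3K4me1, CTCF beats H3K27ac
        ],
    )
    def test_examples(self, signals, expected):
        assert rank_row(signals).tolist() == expected

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            rank_row([1, -1, 0, 0])

    def test_all_tie_patterns_match_priority_oracle(self):
        # every assignment of values from {0, 1, 2} covers all tie shapes
        from itertools import product

        for vals in product((0.0, 1.0, 2.0), repeat=4):
            got = rank_row(np.array(vals))
            assert got.tolist() == oracle_ranks(list(vals))
            assert sorted(got.tolist()) == [1, 2, 3, 4]


class TestPrimaryLabel:
    def test_enhancer_rank_clause(self):
        signals = np.array([10.0, 8.0, 1.0, 0.5])
        ranks = rank_row(signals)
        assert (ranks[0], ranks[1]) == (1, 2)
        assert assign_primary_label(signals, ranks) == ENHANCER

    def test_promoter_only_signal_clause(self):
        signals = np.array([0.0, 8.0, 0.0, 0.0])
        assert assign_primary_label(signals, rank_row(signals)) == PROMOTER

    def test_all_zero_row_not_assigned(self):
        signals = np.zeros(4)
        assert assign_primary_label(signals, rank_row(signals)) == NOT_ASSIGNED


class TestHybridLabel:
    def test_ctcf_top_enhancer_second(self):
        signals = np.array([7.0, 0.0, 0.0, 9.0])
        ranks = rank_row(signals)
        primary = assign_primary_label(signals, ranks)
        assert assign_hybrid_label(signals, ranks, primary) == ENHANCER_CTCF

    def test_sign_pattern_promoter_ctcf(self):
        signals = np.array([0.0, 5.0, 3.0, 2.0])
        ranks = rank_row(signals)
        primary = assign_primary_label(signals, ranks)
        assert assign_hybrid_label(signals, ranks, primary) == PROMOTER_CTCF

    def test_no_ctcf_signal_leaves_phase1_label(self):
        signals = np.array([10.0, 8.0, 1.0, 0.0])
        ranks = rank_row(signals)
        primary = assign_primary_label(signals, ranks)
        assert primary == ENHANCER
        assert assign_hybrid_label(signals, ranks, primary) == ENHANCER

    def test_phase1_labelled_scope_skips_ctcf_rows(self):
        # CTCF-dominated row with nonzero H3K4me1: overridden under "all",
        # untouched under "phase1_labelled" because phase 1 called CTCF
        signals = np.array([3.0, 0.0, 4.0, 9.0])
        ranks = rank_row(signals)
        primary = assign_primary_label(signals, ranks)
        assert primary == CTCF
        assert assign_hybrid_label(signals, ranks, primary, "all") == ENHANCER_CTCF
        assert assign_hybrid_label(signals, ranks, primary, "phase1_labelled") == CTCF


class TestEnumerationOracle:
    def test_labels_match_independent_clause_evaluator(self):
        for signals, ranks in enumerate_rank_zero_cases():
            sig = np.asarray(signals)
            got_ranks = rank_row(sig)
            assert got_ranks.tolist() == ranks
            primary = assign_primary_label(sig, got_ranks)
            got = assign_hybrid_label(sig, got_ranks, primary)
            assert got == oracle_label(signals, ranks), (signals, ranks)

    def test_labels_match_oracle_under_restricted_scope(self):
        for signals, ranks in enumerate_rank_zero_cases():
            sig = np.asarray(signals)
            got_ranks = rank_row(sig)
            primary = assign_primary_label(sig, got_ranks)
            got = assign_hybrid_label(sig, got_ranks, primary, "phase1_labelled")
            assert got == oracle_label(signals, ranks, "phase1_labelled")

    def test_phase1_clauses_mutually_exclusive_under_strict_ranks(self):
        from itertools import permutations

        for perm in permutations(range(4)):
            signals = [0.0] * 4
            ranks = [0] * 4
            for depth, t in enumerate(perm):
                signals[t] = float(4 - depth)
                ranks[t] = depth + 1
            fired = phase1_fired_classes(signals, ranks)
            assert len(fired) <= 1, (signals, fired)


class TestProperties:
    @given(
        st.lists(st.integers(min_value=0, max_value=1000), min_size=4, max_size=4),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    @settings(derandomize=True, max_examples=200)
    def test_scale_invariance_of_label(self, signals, k):
        sig = np.asarray(signals, dtype=float)
        scaled = sig * k
        r1, r2 = rank_row(sig), rank_row(scaled)
        assert r1.tolist() == r2.tolist()
        l1 = assign_hybrid_label(sig, r1, assign_primary_label(sig, r1))
        l2 = assign_hybrid_label(scaled, r2, assign_primary_label(scaled, r2))
        assert l1 == l2

    @given(st.lists(st.floats(min_value=0, max_value=1e6, allow_nan=False), min_size=4, max_size=4))
    @settings(derandomize=True, max_examples=200)
    def test_every_row_gets_exactly_one_label(self, signals):
        sig = np.asarray(signals)
        ranks = rank_row(sig)
        label = assign_hybrid_label(sig, ranks, assign_primary_label(sig, ranks))
        assert label in ALL_LABELS


class TestActivity:
    @pytest.mark.parametrize(
        "signals,label,threshold,expected",
        [
            ([1, 0, 0, 0], ENHANCER, 0.0, "inactive"),
            ([1, 0, 5, 0], ENHANCER, 0.0, "active"),
            ([1, 0, 5, 2], ENHANCER_CTCF, 10.0, "inactive"),
            ([0, 9, 5, 0], PROMOTER, 0.0, "not-applicable"),
        ],
    )
    def test_threshold_semantics(self, signals, label, threshold, expected):
        assert classify_enhancer_activity(signals, label, threshold) == expected


class TestClassifyAll:
    ARCHETYPES = {
        ENHANCER: [10, 1, 6, 0],
        PROMOTER: [1, 10, 6, 0],
        CTCF: [0, 0, 2, 10],
        PROMOTER_CTCF: [0, 8, 5, 9],
        ENHANCER_CTCF: [8, 0, 5, 9],
        NOT_ASSIGNED: [0, 0, 0, 0],
    }

    def _matrix(self):
        regions = [GenomicInterval("chr1", 1000 * i, 1000 * i + 300) for i in range(6)]
        values = np.array(list(self.ARCHETYPES.values()), dtype=float)
        return SignalMatrix(regions=regions, values=values), list(self.ARCHETYPES)

    def test_archetype_rows_get_expected_labels(self):
        sm, expected = self._matrix()
        records = classify_all(sm)
        assert [r.label for r in records] == expected

    def test_empty_matrix(self):
        sm = SignalMatrix(regions=[], values=np.zeros((0, 4)))
        assert classify_all(sm) == []

    def test_row_permutation_permutes_output(self):
        sm, _ = self._matrix()
        perm = [3, 0, 5, 1, 4, 2]
        permuted = SignalMatrix(
            regions=[sm.regions[i] for i in perm], values=sm.values[perm]
        )
        base = [r.label for r in classify_all(sm)]
        assert [r.label for r in classify_all(permuted)] == [base[i] for i in perm]


class TestSklearnEstimator:
    def test_fit_predict_transform(self):
        X = np.array(list(TestClassifyAll.ARCHETYPES.values()), dtype=float)
        clf = RuleBasedElementClassifier().fit(X)
        assert clf.n_features_in_ == 4
        assert set(clf.classes_) == set(ALL_LABELS)
        assert clf.predict(X).tolist() == list(TestClassifyAll.ARCHETYPES)
        ranks = clf.transform(X)
        assert ranks.shape == X.shape
        assert all(sorted(row) == [1, 2, 3, 4] for row in ranks.tolist())

    def test_clone_and_params_round_trip(self):
        clf = RuleBasedElementClassifier(activity_threshold=2.5, hybrid_scope="phase1_labelled")
        other = clone(clf)
        assert other.get_params()["activity_threshold"] == 2.5
        other.set_params(hybrid_scope="all")
        assert other.hybrid_scope == "all"

    def test_invalid_inputs_rejected(self):
        clf = RuleBasedElementClassifier()
        with pytest.raises(ValueError):
            clf.fit(np.zeros((2, 3)))
        with pytest.raises(ValueError):
            clf.fit(-np.ones((2, 4)))
        with pytest.raises(ValueError):
            RuleBasedElementClassifier(hybrid_scope="bogus").fit(np.zeros((1, 4)))

    def test_predict_activity(self):
        X = np.array([[10, 1, 6, 0], [10, 1, 0, 0], [1, 10, 6, 0]], dtype=float)
        acts = RuleBasedElementClassifier().fit(X).predict_activity(X)
        assert acts.tolist() == ["active", "inactive", "not-applicable"]
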