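"""The rule engine: rank transform and two-phase regulatory-element labels.

Given the R x 4 normalised signal matrix A (columns t1=H3K4me1,
t2=H3K4me3, t3=H3K27ac, t4=CTCF), each row is rank-transformed in
descending order (rank 1 = strongest track) and labelled in two phases.

Phase 1 (main classes):

    Enhancer  iff (R1=1 ∧ R2=2) ∨ (R1=1 ∧ R3=2) ∨ (R1=2 ∧ R3=1)
                  ∨ (R1=1 ∧ A2=0 ∧ A3=0 ∧ A4=0)
    Promoter  iff (R2=1 ∧ R1=2) ∨ (R2=1 ∧ R3=2) ∨ (R2=2 ∧ R3=1)
                  ∨ (R2=1 ∧ A1=0 ∧ A3=0 ∧ A4=0)
    CTCF      iff (R4=1 ∧ R3=2) ∨ (R4=2 ∧ R3=1)
                  ∨ (R4=1 ∧ A1=0 ∧ A2=0 ∧ A3=0)
    otherwise Not assigned

Phase 2 (hybrid classes, overriding phase 1 when they fire):

    Enhancer/CTCF iff (R4=1 ∧ R1=2 ∧ A1≠0 ∧ A4≠0)
                      ∨ (R4=2 ∧ R1=1 ∧ A1≠0 ∧ A4≠0)
                      ∨ (A1≠0 ∧ A2=0 ∧ A3≠0 ∧ A4≠0)
    Promoter/CTCF iff (R4=1 ∧ R2=2 ∧ A2≠0 ∧ A4≠0)
                      ∨ (R4=2 ∧ R2=1 ∧ A2≠0 ∧ A4≠0)
                      ∨ (A1=0 ∧ A2≠0 ∧ A3≠0 ∧ A4≠0)

Zero tests use exact equality: a normalised signal is 0 only when the
region shares no covered base with the track's peaks, so zeros encode
genuine absence. Enhancer calls are additionally split into active /
inactive by the H3K27ac signal exceeding a threshold (default 0, i.e.
presence/absence).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .signal import TRACKS, SignalMatrix

ENHANCER = "Enhancer"
PROMOTER = "Promoter"
CTCF = "CTCF"
ENHANCER_CTCF = "Enhancer/CTCF"
PROMOTER_CTCF = "Promoter/CTCF"
NOT_ASSIGNED = "Not assigned"

ALL_LABELS = (ENHANCER, PROMOTER, CTCF, ENHANCER_CTCF, PROMOTER_CTCF, NOT_ASSIGNED)

ACTIVE = "active"
INACTIVE = "inactive"
NOT_APPLICABLE = "not-applicable"

#: tie-break priority among equal signals: the earlier track takes the
#: smaller (stronger) rank. Promoter-mark first, acetylation last.
DEFAULT_TIE_BREAK = ("H3K4me3", "H3K4me1", "CTCF", "H3K27ac")

HYBRID_SCOPES = ("all", "phase1_labelled")


def _priority_positions(tie_break_priority) -> tuple:
    if sorted(tie_break_priority) != sorted(TRACKS):
        raise ValueError(
            f"tie_break_priority must be a permutation of {TRACKS}, got {tie_break_priority}"
        )
    order = [TRACKS.index(t) for t in tie_break_priority]
    pos = [0] * 4
    for p, t in enumerate(order):
        pos[t] = p
    return tuple(pos)


def rank_row(signals, tie_break_priority=DEFAULT_TIE_BREAK) -> np.ndarray:
    """Descending ranks of the four signals; rank 1 = largest.

    Ties break by the fixed track priority (default H3K4me3 > H3K4me1 >
    CTCF > H3K27ac): among equal values the higher-priority track takes
    the smaller rank. The result is always a permutation of {1,2,3,4}.
    """
    vals = np.asarray(signals, dtype=float)
    if vals.shape != (4,):
        raise ValueError("rank_row expects exactly 4 signals")
    if np.any(vals < 0):
        raise ValueError("negative signal values violate the signal contract")
    pos = _priority_positions(tie_break_priority)
    order = sorted(range(4), key=lambda t: (-vals[t], pos[t]))
    ranks = np.empty(4, dtype=int)
    for rank0, t in enumerate(order):
        ranks[t] = rank0 + 1
    return ranks


def assign_primary_label(signals, ranks) -> str:
    """Phase-1 label from the clause sets above.

    An all-zero row is forced to Not assigned before clause evaluation:
    its ranks are pure tie-break artifacts, and the "only this track
    nonzero" clauses would otherwise fire vacuously.
    """
    a = np.asarray(signals, dtype=float)
    r = np.asarray(ranks, dtype=int)
    if not np.any(a > 0):
        return NOT_ASSIGNED
    a1, a2, a3, a4 = a
    r1, r2, r3, r4 = r
    if (
        (r1 == 1 and r2 == 2)
        or (r1 == 1 and r3 == 2)
        or (r1 == 2 and r3 == 1)
        or (r1 == 1 and a2 == 0 and a3 == 0 and a4 == 0)
    ):
        return ENHANCER
    if (
        (r2 == 1 and r1 == 2)
        or (r2 == 1 and r3 == 2)
        or (r2 == 2 and r3 == 1)
        or (r2 == 1 and a1 == 0 and a3 == 0 and a4 == 0)
    ):
        return PROMOTER
    if (
        (r4 == 1 and r3 == 2)
        or (r4 == 2 and r3 == 1)
        or (r4 == 1 and a1 == 0 and a2 == 0 and a3 == 0)
    ):
        return CTCF
    return NOT_ASSIGNED


def assign_hybrid_label(signals, ranks, primary: str, hybrid_scope: str = "all") -> str:
    """Phase-2 refinement into Enhancer/CTCF or Promoter/CTCF.

    A firing hybrid clause overrides the phase-1 label; otherwise the
    phase-1 label stands. With ``hybrid_scope="phase1_labelled"`` phase 2
    only examines rows phase 1 called Enhancer or Promoter. Should both
    hybrid clause sets ever fire at once (impossible for the clause sets
    as written, since each requires an opposite zero status of A1/A2 or
    an incompatible rank pattern), the larger of A1 vs A2 decides.
    """
    if hybrid_scope not in HYBRID_SCOPES:
        raise ValueError(f"unknown hybrid_scope {hybrid_scope!r}")
    if hybrid_scope == "phase1_labelled" and primary not in (ENHANCER, PROMOTER):
        return primary
    a = np.asarray(signals, dtype=float)
    r = np.asarray(ranks, dtype=int)
    a1, a2, a3, a4 = a
    r1, r2, r3, r4 = r
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
        return ENHANCER_CTCF if a1 > a2 else PROMOTER_CTCF
    if enh_ctcf:
        return ENHANCER_CTCF
    if prom_ctcf:
        return PROMOTER_CTCF
    return primary


def classify_enhancer_activity(signals, label: str, threshold: float = 0.0) -> str:
    """Active/inactive enhancer subclass from the H3K27ac signal.

    Applies only to Enhancer and Enhancer/CTCF calls: active when the
    normalised H3K27ac signal strictly exceeds ``threshold``. Every other
    label is not-applicable.
    """
    if threshold < 0:
        raise ValueError("activity threshold must be non-negative")
    if label not in (ENHANCER, ENHANCER_CTCF):
        return NOT_APPLICABLE
    a3 = float(np.asarray(signals, dtype=float)[2])
    return ACTIVE if a3 > threshold else INACTIVE


@dataclass
class AnnotationRecord:
    """One classified region: coordinates, signals, ranks, labels."""

    region: object
    signals: np.ndarray
    ranks: np.ndarray
    label: str
    activity: str
    log_distance_tss: Optional[float] = None


class RuleBasedElementClassifier(BaseEstimator, ClassifierMixin):
    """Deterministic rule-based regulatory-element classifier.

    A scikit-learn compatible estimator over an (n_regions, 4) array of
    normalised signals in track order H3K4me1, H3K4me3, H3K27ac, CTCF.
    There are no learned parameters: ``fit`` only validates input and
    records the class set, so the estimator composes with sklearn
    pipelines and model-selection utilities while ``predict`` applies the
    fixed rules.

    Parameters
    ----------
    activity_threshold : float
        H3K27ac level strictly above which an enhancer is called active.
    hybrid_scope : {"all", "phase1_labelled"}
        Whether phase 2 examines every region or only phase-1 enhancer /
        promoter calls.
    tie_break_priority : tuple of 4 track names
        Rank tie-break order (see :func:`rank_row`).
    """

    def __init__(
        self,
        activity_threshold: float = 0.0,
        hybrid_scope: str = "all",
        tie_break_priority: tuple = DEFAULT_TIE_BREAK,
    ):
        self.activity_threshold = activity_threshold
        self.hybrid_scope = hybrid_scope
        self.tie_break_priority = tie_break_priority

    def _validate_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 4:
            raise ValueError("X must be an (n_regions, 4) signal array")
        if np.any(X < 0):
            raise ValueError("signals must be non-negative")
        return X

    def fit(self, X, y=None):
        X = self._validate_X(X)
        _priority_positions(self.tie_break_priority)
        if self.hybrid_scope not in HYBRID_SCOPES:
            raise ValueError(f"unknown hybrid_scope {self.hybrid_scope!r}")
        if self.activity_threshold < 0:
            raise ValueError("activity threshold must be non-negative")
        self.n_features_in_ = 4
        self.classes_ = np.asarray(ALL_LABELS)
        return self

    def transform(self, X) -> np.ndarray:
        """Row-wise descending ranks (the rank matrix R)."""
        X = self._validate_X(X)
        return np.vstack([rank_row(row, self.tie_break_priority) for row in X])

    def predict(self, X) -> np.ndarray:
        X = self._validate_X(X)
        labels = []
        for row in X:
            ranks = rank_row(row, self.tie_break_priority)
            primary = assign_primary_label(row, ranks)
            labels.append(
                assign_hybrid_label(row, ranks, primary, self.hybrid_scope)
            )
        return np.asarray(labels, dtype=object)

    def predict_activity(self, X) -> np.ndarray:
        """Enhancer activity subclass for each row."""
        X = self._validate_X(X)
        labels = self.predict(X)
        return np.asarray(
            [
                classify_enhancer_activity(row, lab, self.activity_threshold)
                for row, lab in zip(X, labels)
            ],
            dtype=object,
        )


def classify_all(
    signal_matrix: SignalMatrix,
    activity_threshold: float = 0.0,
    hybrid_scope: str = "all",
    tie_break_priority: tuple = DEFAULT_TIE_BREAK,
) -> list:
    """Classify every row of a SignalMatrix into AnnotationRecords.

    Rows are independent and processed in order; the output is
    deterministic for identical input.
    """
    clf = RuleBasedElementClassifier(
        activity_threshold=activity_threshold,
        hybrid_scope=hybrid_scope,
        tie_break_priority=tie_break_priority,
    ).fit(np.zeros((1, 4)))
    records = []
    for region, row in zip(signal_matrix.regions, signal_matrix.values):
        ranks = rank_row(row, tie_break_priority)
        primary = assign_primary_label(row, ranks)
        label = assign_hybrid_label(row, ranks, primary, hybrid_scope)
        activity = classify_enhancer_activity(row, label, clf.activity_threshold)
        records.append(
            AnnotationRecord(
                region=region,
                signals=np.asarray(row, dtype=float),
                ranks=ranks,
                label=label,
                activity=activity,
            )
        )
    return records
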