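"""Evaluation schemes: patient-aware and segment-level train/test splitting.

The centerpiece is inter-patient cross-validation: all segments from one
patient form an indivisible group, and patients are assigned to k stratified
folds by a greedy heuristic that, for each group in turn, picks the fold
minimizing the mean (over classes) standard deviation (over folds) of
per-class segment counts.  The heuristic is deliberately greedy — it can
produce suboptimal stratification — but it guarantees the inter-patient
property by construction.  Intra-patient cross-validation (segment-level,
patient-blind), leave-one-patient-out, predefined folds and holdout are also
provided, plus a verifier for the inter-patient invariant.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .segmentation import Segment

logger = logging.getLogger(__name__)


@dataclass
class FoldSplit:
    """A k-way partition of groups (patients) with class-count bookkeeping."""

    k: int
    folds: list[list[str]]  # group ids per fold
    per_fold_class_counts: np.ndarray  # (k, C) ints
    objective: float  # mean-over-classes std-over-folds at the final assignment


@dataclass
class TrainValTest:
    train: np.ndarray  # segment indices
    val: np.ndarray
    test: np.ndarray
    fold_id: int = 0


def stratification_objective(counts: np.ndarray) -> float:
    """mean over classes of the std (over folds) of per-class counts."""
    return float(np.mean(np.std(counts, axis=0)))


def stratified_group_kfold(
    group_class_counts: Mapping[str, np.ndarray],
    k: int,
    order_rule: Optional[Callable[[Mapping[str, np.ndarray]], list[str]]] = None,
) -> FoldSplit:
    """Greedy stratified assignment of groups to k folds.

    Groups are visited in ``order_rule`` order (default: descending total
    segment count, ties by id — large groups placed first is the standard
    greedy-balancing order).  Each group goes to the fold that minimizes the
    stratification objective after tentative placement; ties go to the
    lowest fold index.
    """
    groups = {g: np.asarray(c, dtype=np.int64) for g, c in group_class_counts.items()}
    if k > len(groups):
        raise ValueError(f"k={k} exceeds number of groups ({len(groups)})")
    if k < 2:
        raise ValueError("k must be >= 2")
    C = next(iter(groups.values())).size
    for g, c in groups.items():
        if c.size != C or (c < 0).any() or c.sum() == 0:
            raise ValueError(f"group {g!r}: counts must be non-negative and nonzero")

    if order_rule is None:
        order = sorted(groups, key=lambda g: (-int(groups[g].sum()), g))
    else:
        order = order_rule(groups)

    counts = np.zeros((k, C), dtype=np.int64)
    folds: list[list[str]] = [[] for _ in range(k)]
    for g in order:
        best_f, best_j = 0, np.inf
        for f in range(k):
            counts[f] += groups[g]
            j = stratification_objective(counts)
            counts[f] -= groups[g]
            if j < best_j - 1e-12:
                best_f, best_j = f, j
        counts[best_f] += groups[g]
        folds[best_f].append(g)
    return FoldSplit(k, folds, counts, stratification_objective(counts))


def _segment_class_counts_by_patient(
    segments: Sequence[Segment], n_classes: Optional[int] = None
) -> dict[str, np.ndarray]:
    C = n_classes or (max(s.label for s in segments) + 1)
    out: dict[str, np.ndarray] = {}
    for s in segments:
        out.setdefault(s.patient_id, np.zeros(C, dtype=np.int64))[s.label] += 1
    return out


def inter_patient_cv(
    segments: Sequence[Segment], k: int = 10, n_classes: Optional[int] = None
) -> list[TrainValTest]:
    """Inter-patient k-fold cross-validation.

    Patients are stratified into k folds; for split i the test set is fold i,
    the validation set (for early stopping) fold (i+1) mod k, and the
    remaining folds train.  Each patient appears in exactly one test fold.
    """
    by_patient = _segment_class_counts_by_patient(segments, n_classes)
    if len(by_patient) < k:
        raise ValueError(
            f"only {len(by_patient)} patients for k={k}; "
            "consider the leave-one-patient-out scheme instead"
        )
    fs = stratified_group_kfold(by_patient, k)
    patient_fold = {p: f for f, fold in enumerate(fs.folds) for p in fold}
    seg_fold = np.array([patient_fold[s.patient_id] for s in segments])
    splits = []
    for i in range(k):
        vi = (i + 1) % k
        splits.append(
            TrainValTest(
                train=np.flatnonzero((seg_fold != i) & (seg_fold != vi)),
                val=np.flatnonzero(seg_fold == vi),
                test=np.flatnonzero(seg_fold == i),
                fold_id=i,
            )
        )
    return splits


def intra_patient_cv(
    segments: Sequence[Segment], k: int, seed: int = 0
) -> list[TrainValTest]:
    """Segment-level stratified k-fold, disregarding patients.

    Biased by patient overlap between train and test; provided for
    comparison with the inter-patient schemes.
    """
    y = np.array([s.label for s in segments])
    vals, counts = np.unique(y, return_counts=True)
    for v, c in zip(vals, counts):
        if c < k:
            raise ValueError(f"class {int(v)} has only {int(c)} segments (< k={k})")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    test_folds = [test for _, test in skf.split(np.zeros_like(y), y)]
    splits = []
    for i in range(k):
        vi = (i + 1) % k
        test, val = test_folds[i], test_folds[vi]
        mask = np.ones(y.size, dtype=bool)
        mask[test] = False
        mask[val] = False
        splits.append(TrainValTest(np.flatnonzero(mask), val, test, fold_id=i))
    return splits


def leave_one_patient_out(segments: Sequence[Segment]) -> list[TrainValTest]:
    """One split per patient: that patient's segments are the test set, one
    other patient (round-robin) the validation set, the rest train."""
    pids = sorted({s.patient_id for s in segments})
    if len(pids) < 3:
        raise ValueError("leave-one-patient-out requires at least 3 patients")
    seg_pid = np.array([s.patient_id for s in segments])
    splits = []
    for i, p in enumerate(pids):
        vp = pids[(i + 1) % len(pids)]
        test = np.flatnonzero(seg_pid == p)
        if test.size == 0:
            logger.warning("patient %s has no segments; split skipped", p)
            continue
        val = np.flatnonzero(seg_pid == vp)
        train = np.flatnonzero((seg_pid != p) & (seg_pid != vp))
        splits.append(TrainValTest(train, val, test, fold_id=i))
    return splits


def predefined_folds(
    segments: Sequence[Segment],
    assignment: Mapping[str, int] | Sequence[tuple[str, int]],
    val_fraction: float = 0.1,
    seed: int = 0,
) -> list[TrainValTest]:
    """Honor an externally provided record -> fold assignment exactly.

    A 2-valued assignment is treated as holdout: one train/test split with a
    validation set carved out of the training patients (a ``val_fraction``
    patient-stratified carve-out, since early stopping needs one).
    """
    if not isinstance(assignment, Mapping):
        amap: dict[str, int] = {}
        for rid, f in assignment:
            if rid in amap and amap[rid] != f:
                raise ValueError(f"record {rid!r} assigned to folds {amap[rid]} and {f}")
            amap[rid] = f
    else:
        amap = dict(assignment)
    missing = {s.record_id for s in segments} - set(amap)
    if missing:
        raise ValueError(f"records without fold assignment: {sorted(missing)[:5]} ...")
    fold_ids = sorted(set(amap.values()))
    seg_fold = np.array([amap[s.record_id] for s in segments])

    if len(fold_ids) == 2:  # holdout
        tr_f, te_f = fold_ids
        train_all = np.flatnonzero(seg_fold == tr_f)
        test = np.flatnonzero(seg_fold == te_f)
        train_pids = sorted({segments[i].patient_id for i in train_all})
        rng = np.random.default_rng(seed)
        n_val = max(1, int(round(val_fraction * len(train_pids))))
        val_pids = set(rng.choice(train_pids, size=n_val, replace=False))
        val = np.array([i for i in train_all if segments[i].patient_id in val_pids])
        train = np.array([i for i in train_all if segments[i].patient_id not in val_pids])
        return [TrainValTest(train, val, test, fold_id=0)]

    splits = []
    for i, f in enumerate(fold_ids):
        vf = fold_ids[(i + 1) % len(fold_ids)]
        test = np.flatnonzero(seg_fold == f)
        val = np.flatnonzero(seg_fold == vf)
        train = np.flatnonzero((seg_fold != f) & (seg_fold != vf))
        splits.append(TrainValTest(train, val, test, fold_id=i))
    return splits


def verify_inter_patient(
    split: TrainValTest, segments: Sequence[Segment]
) -> tuple[bool, dict[str, list[str]]]:
    """True iff the patient sets behind train/val/test are pairwise disjoint;
    the report lists offending patients per overlapping pair."""
    pids = {
        part: {segments[i].patient_id for i in idx}
        for part, idx in (("train", split.train), ("val", split.val), ("test", split.test))
    }
    report: dict[str, list[str]] = {}
    for a, b in (("train", "val"), ("train", "test"), ("val", "test")):
        overlap = sorted(pids[a] & pids[b])
        if overlap:
            report[f"{a}/{b}"] = overlap
    return (not report), report


def export_split(fold_split: FoldSplit, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "fold"])
        for f, fold in enumerate(fold_split.folds):
            for p in fold:
                w.writerow([p, f])


def import_split(path) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out[row["patient_id"]] = int(row["fold"])
    return out
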