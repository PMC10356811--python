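"""Evaluation schemes: stratified group k-fold heuristic and its guarantees."""

import numpy as np
import pytest

from ecgbench.segmentation import Segment
from ecgbench.splitting import (
    inter_patient_cv,
    intra_patient_cv,
    leave_one_patient_out,
    predefined_folds,
    stratification_objective,
    stratified_group_kfold,
    verify_inter_patient,
)

from .oracles import brute_force_best_2fold


def _segments(labels_by_patient):
    """Build dummy segments from {patient: [labels]}."""
    segs = []
    for pid, labels in labels_by_patient.items():
        for i, lab in enumerate(labels):
            segs.append(Segment(np.zeros(4), lab, f"{pid}_r", pid, i, "windows2.5s",
                                250.0))
    return segs


class TestStratifiedGroupKFold:
    def test_identical_groups_balance_perfectly(self):
        groups = {f"g{i}": np.array([3, 2]) for i in range(8)}
        fs = stratified_group_kfold(groups, 4)
        assert fs.objective == 0.0
        assert all(len(f) == 2 for f in fs.folds)

    def test_greedy_matches_exhaustive_optimum_on_6_group_instance(self):
        groups = {
            "g0": np.array([10, 0]), "g1": np.array([10, 0]),
            "g2": np.array([0, 10]), "g3": np.array([0, 10]),
            "g4": np.array([5, 5]), "g5": np.array([5, 5]),
        }
        fs = stratified_group_kfold(groups, 2)
        best = brute_force_best_2fold(groups, 3)
        assert fs.objective == pytest.approx(best)

    def test_k_equals_groups_gives_one_group_per_fold(self):
        groups = {f"g{i}": np.array([i + 1, 1]) for i in range(5)}
        fs = stratified_group_kfold(groups, 5)
        assert sorted(len(f) for f in fs.folds) == [1, 1, 1, 1, 1]

    def test_k_larger_than_groups_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            stratified_group_kfold({"a": np.array([1])}, 2)

    def test_counts_bookkeeping_consistent(self):
        rng = np.random.default_rng(0)
        groups = {f"g{i}": rng.integers(0, 20, size=3) + 1 for i in range(13)}
        fs = stratified_group_kfold(groups, 4)
        for f, fold in enumerate(fs.folds):
            expect = sum((groups[g] for g in fold), np.zeros(3, dtype=np.int64))
            assert np.array_equal(fs.per_fold_class_counts[f], expect)

    def test_greedy_beats_random_partitions(self):
        # on random instances the heuristic should be no worse than the
        # median of uniformly random group-preserving partitions
        rng = np.random.default_rng(42)
        wins = 0
        n_instances = 30
        for _ in range(n_instances):
            n_groups = int(rng.integers(8, 15))
            groups = {
                f"g{i}": rng.poisson(8, size=3) + 1 for i in range(n_groups)
            }
            k = 4
            fs = stratified_group_kfold(groups, k)
            mat = np.stack([groups[g] for g in sorted(groups)])
            rand_js = []
            for _ in range(300):
                assign = rng.integers(0, k, size=n_groups)
                counts = np.zeros((k, 3))
                np.add.at(counts, assign, mat)
                rand_js.append(stratification_objective(counts))
            if fs.objective <= np.median(rand_js):
                wins += 1
        assert wins == n_instances


class TestInterPatientCV:
    def test_each_patient_tested_once_and_disjoint(self):
        rng = np.random.default_rng(1)
        segs = _segments({f"p{i}": rng.integers(0, 3, size=20).tolist()
                          for i in range(40)})
        splits = inter_patient_cv(segs, k=10)
        assert len(splits) == 10
        test_patients = []
        for sp in splits:
            ok, report = verify_inter_patient(sp, segs)
            assert ok, report
            test_patients.append({segs[i].patient_id for i in sp.test})
            assert len(sp.train) + len(sp.val) + len(sp.test) == len(segs)
        all_test = set().union(*test_patients)
        assert all_test == {f"p{i}" for i in range(40)}
        assert sum(len(t) for t in test_patients) == 40  # exactly once each

    def test_union_of_test_sets_covers_all_segments(self):
        segs = _segments({f"p{i}": [0, 1, 1] for i in range(12)})
        splits = inter_patient_cv(segs, k=4)
        covered = np.sort(np.concatenate([sp.test for sp in splits]))
        assert np.array_equal(covered, np.arange(len(segs)))

    def test_too_few_patients_advises_lopo(self):
        segs = _segments({"p0": [0, 1], "p1": [0, 1]})
        with pytest.raises(ValueError, match="leave-one-patient-out"):
            inter_patient_cv(segs, k=10)


class TestIntraPatientCV:
    def test_stratified_fold_sizes(self):
        segs = _segments({"p0": [0] * 50 + [1] * 50})
        splits = intra_patient_cv(segs, k=10, seed=0)
        assert len(splits) == 10
        for sp in splits:
            assert len(sp.test) == 10
            labels = [segs[i].label for i in sp.test]
            assert abs(labels.count(0) - 5) <= 1

    def test_seed_reproducibility(self):
        segs = _segments({f"p{i}": [0, 1, 0, 1] for i in range(10)})
        a = intra_patient_cv(segs, k=4, seed=3)
        b = intra_patient_cv(segs, k=4, seed=3)
        for x, y in zip(a, b):
            assert np.array_equal(x.test, y.test) and np.array_equal(x.train, y.train)

    def test_class_smaller_than_k_rejected(self):
        segs = _segments({"p0": [0] * 20 + [1] * 2})
        with pytest.raises(ValueError, match="class 1"):
            intra_patient_cv(segs, k=5)

    def test_multi_segment_patients_violate_inter_patient(self):
        segs = _segments({f"p{i}": [0, 1] * 10 for i in range(5)})
        splits = intra_patient_cv(segs, k=5, seed=0)
        assert any(not verify_inter_patient(sp, segs)[0] for sp in splits)


class TestLeaveOnePatientOut:
    def test_one_split_per_patient_partitioning_segments(self):
        segs = _segments({f"p{i}": [0, 1, i % 2] for i in range(5)})
        splits = leave_one_patient_out(segs)
        assert len(splits) == 5
        covered = np.sort(np.concatenate([sp.test for sp in splits]))
        assert np.array_equal(covered, np.arange(len(segs)))
        for sp in splits:
            ok, _ = verify_inter_patient(sp, segs)
            assert ok

    def test_fewer_than_three_patients_rejected(self):
        segs = _segments({"p0": [0], "p1": [1]})
        with pytest.raises(ValueError, match="3 patients"):
            leave_one_patient_out(segs)


class TestPredefinedFolds:
    def test_assignment_honored_exactly(self):
        segs = _segments({f"p{i}": [0, 1] for i in range(6)})
        assignment = {f"p{i}_r": i % 3 for i in range(6)}
        splits = predefined_folds(segs, assignment)
        assert len(splits) == 3
        for sp in splits:
            test_folds = {assignment[segs[i].record_id] for i in sp.test}
            assert len(test_folds) == 1

    def test_two_valued_assignment_is_holdout_with_val_carveout(self):
        segs = _segments({f"p{i}": [0, 1, 0] for i in range(20)})
        assignment = {f"p{i}_r": (0 if i < 14 else 1) for i in range(20)}
        (sp,) = predefined_folds(segs, assignment, seed=0)
        assert len(sp.val) > 0
        ok, _ = verify_inter_patient(sp, segs)
        assert ok

    def test_unassigned_record_rejected(self):
        segs = _segments({"p0": [0], "p1": [1], "p2": [0]})
        with pytest.raises(ValueError, match="without fold"):
            predefined_folds(segs, {"p0_r": 0, "p1_r": 1})

    def test_contradictory_duplicate_assignment_rejected(self):
        segs = _segments({"p0": [0], "p1": [1]})
        with pytest.raises(ValueError, match="assigned to folds"):
            predefined_folds(segs, [("p0_r", 0), ("p0_r", 1), ("p1_r", 1)])


def test_single_segment_patients_make_intra_and_inter_coincide():
    segs = _segments({f"p{i}": [i % 2] for i in range(12)})
    for sp in intra_patient_cv(segs, k=3, seed=0):
        ok, _ = verify_inter_patient(sp, segs)
        assert ok


def test_determinism_of_inter_patient_cv():
    rng = np.random.default_rng(5)
    segs = _segments({f"p{i}": rng.integers(0, 2, size=8).tolist() for i in range(15)})
    a = inter_patient_cv(segs, k=5)
    b = inter_patient_cv(segs, k=5)
    for x, y in zip(a, b):
        assert np.array_equal(x.test, y.test)
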