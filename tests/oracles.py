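"""Independent brute-force re-implementations used as test oracles.

These deliberately share no code with the package: the window labeler
applies the two labeling rules literally (per-sample coverage counting for
rhythm voting; explicit enumeration of in-window beat classes with the
abnormal-priority rule for form), and the partition oracle enumerates
2-fold group partitions exhaustively.
"""

import itertools

import numpy as np

from ecgbench.annotations import EXCLUDED, map_symbol, resolve_class


def brute_force_window_label(span, beats, episodes, d, task, dataset,
                             class_counts=None):
    start, end = span
    if task.kind == "rhythm":
        per_sample = np.full(end - start, -1, dtype=int)
        earliest = {}
        for ep in episodes:
            code = map_symbol(d, dataset, ep.symbol, "rhythm")
            if code is None:
                continue
            ci = resolve_class(task, code)
            if ci == EXCLUDED:
                continue
            lo, hi = max(start, ep.start), min(end, ep.end)
            if hi > lo:
                per_sample[lo - start : hi - start] = ci
                earliest[ci] = min(earliest.get(ci, ep.start), ep.start)
        covered = per_sample[per_sample >= 0]
        if covered.size == 0:
            return EXCLUDED
        counts = np.bincount(covered, minlength=task.n_classes)
        tied = [c for c in range(task.n_classes) if counts[c] == counts.max()]
        return min(tied, key=lambda c: earliest[c])

    classes = set()
    for b in beats:
        if start <= b.sample_index < end:
            code = map_symbol(d, dataset, b.symbol, "beat")
            if code is not None:
                ci = resolve_class(task, code)
                if ci != EXCLUDED:
                    classes.add(ci)
    if not classes:
        return EXCLUDED
    normal = task.normal_index()
    abnormal = sorted(c for c in classes if c != normal)
    if abnormal:
        if len(abnormal) == 1 or class_counts is None:
            return abnormal[0]
        return min(abnormal, key=lambda c: (class_counts[c], c))
    return normal if normal is not None else EXCLUDED


def enumerate_windows(length, w, s):
    """Every window start by literal enumeration."""
    starts = []
    t = 0
    while t + w <= length:
        starts.append(t)
        t += s
    return starts


def brute_force_best_2fold(groups, fold_size):
    """Exhaustively minimize the stratification objective over all 2-fold
    partitions with ``fold_size`` groups in the first fold."""
    ids = sorted(groups)
    best = np.inf
    for combo in itertools.combinations(ids, fold_size):
        f0 = sum((groups[g] for g in combo), np.zeros_like(groups[ids[0]]))
        f1 = sum((groups[g] for g in ids if g not in combo),
                 np.zeros_like(groups[ids[0]]))
        j = float(np.mean(np.std(np.stack([f0, f1]), axis=0)))
        best = min(best, j)
    return best


def random_annotation_stream(rng, n_classes_hint=3):
    """A random record-length/beat/episode stream with occasional unknown
    symbols, for oracle-equivalence testing (symbols follow the ``synth``
    dictionary conventions)."""
    from ecgbench.io import BeatAnnotation, RhythmEpisode

    L = int(rng.integers(1500, 4000))
    n_cp = int(rng.integers(1, 5))
    cps = np.sort(rng.choice(np.arange(0, L - 1), size=n_cp, replace=False))
    cps[0] = 0
    bounds = list(cps) + [L]
    rhythm_syms = ["N", "AFIB", "ST", "SBR", "XX"]  # XX unknown to the dictionary
    episodes = [
        RhythmEpisode(int(a), int(b), str(rng.choice(rhythm_syms)))
        for a, b in zip(bounds[:-1], bounds[1:])
        if b > a
    ]
    n_beats = int(rng.integers(0, 25))
    pos = np.sort(rng.choice(np.arange(L), size=n_beats, replace=False))
    beat_syms = ["N", "N", "N", "V", "A", "?"]  # ? unknown to the dictionary
    beats = [BeatAnnotation(int(p), str(rng.choice(beat_syms))) for p in pos]
    return L, beats, episodes
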