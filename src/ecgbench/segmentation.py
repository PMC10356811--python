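"""Input-generation techniques and their label-assignment semantics.

Four families of segments are produced from annotated records:

* **heartbeat** segments (``beats0.72s``, ``beats2.4s``): fixed windows
  centered on each annotated R-peak; the short variant covers roughly one
  heartbeat, the long one a beat plus its two neighbours;
* **episode** segments: one variable-length segment per rhythm episode
  (provided for completeness; episode boundaries are unknown in unannotated
  signals, so this is not used in headline experiments);
* **sliding windows** (``windows2.5s``, ``windows10s``): fixed windows at a
  configurable overlap, labeled by voting — for rhythm tasks the class
  covering the largest portion of the window wins; for heartbeat-form tasks
  a single abnormal beat suffices to label the whole window abnormal;
* **full sequence** (``sequence10s``): the entire (recording-level) record
  cropped/zero-padded to a fixed duration.

Window predictions can be folded back to one prediction per recording by
majority voting (:func:`aggregate_predictions`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .annotations import EXCLUDED, LabelDictionary, TaskDefinition, map_symbol, resolve_class
from .io import BeatAnnotation, EcgRecord, RecordingLabel, RhythmEpisode
from .preprocess import fit_length

logger = logging.getLogger(__name__)

TRANSFORM_TAGS = (
    "beats0.72s", "beats2.4s", "windows2.5s", "windows10s", "sequence10s", "episodes",
)


@dataclass
class Segment:
    samples: np.ndarray
    label: int  # class index in the task
    record_id: str
    patient_id: str
    start: int  # sample index at the source fs
    transform_tag: str
    fs: float  # source sampling frequency

    def __post_init__(self) -> None:
        if self.samples.size == 0:
            raise ValueError("empty segment")
        if self.label < 0:
            raise ValueError("segment label must be a valid class index")


@dataclass(frozen=True)
class WindowingParams:
    window_s: float
    overlap_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not self.window_s > 0:
            raise ValueError("window_s must be > 0")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")

    def sizes(self, fs: float) -> tuple[int, int]:
        """(window, stride) in samples; both computed with round()."""
        w = int(round(self.window_s * fs))
        s = int(round(w * (1.0 - self.overlap_fraction)))
        if s < 1:
            raise ValueError("stride rounds to 0 samples")
        return w, s


def window_count(length: int, w: int, s: int) -> int:
    """Closed form: floor((L - w)/s) + 1 windows for L >= w, else 0."""
    if length < w:
        return 0
    return (length - w) // s + 1


# ---------------------------------------------------------------------------
# Heartbeat and episode segmentation
# ---------------------------------------------------------------------------


def segment_beats(
    record: EcgRecord,
    beats: Sequence[BeatAnnotation],
    duration_s: float,
    d: LabelDictionary,
    task: TaskDefinition,
    dataset: str,
    transform_tag: Optional[str] = None,
) -> list[Segment]:
    """One fixed window per annotated beat, centered on the R-peak.

    The window holds ``w = round(duration_s * fs)`` samples starting at
    ``R - w//2``.  Beats whose window would cross either record boundary are
    dropped (padding would fabricate signal inside a morphology window), as
    are beats whose symbol is unknown or maps outside the task.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    w = int(round(duration_s * record.fs))
    tag = transform_tag or f"beats{duration_s:g}s"
    out: list[Segment] = []
    n = record.samples.size
    for b in beats:
        start = b.sample_index - w // 2
        if start < 0 or start + w > n:
            continue
        code = map_symbol(d, dataset, b.symbol, "beat")
        if code is None:
            logger.warning("skipping unknown beat symbol %r (%s)", b.symbol, dataset)
            continue
        ci = resolve_class(task, code)
        if ci == EXCLUDED:
            continue
        out.append(
            Segment(record.samples[start : start + w].copy(), ci,
                    record.record_id, record.patient_id, start, tag, record.fs)
        )
    return out


def segment_episodes(
    record: EcgRecord,
    episodes: Sequence[RhythmEpisode],
    d: LabelDictionary,
    task: TaskDefinition,
    dataset: str,
) -> list[Segment]:
    """One variable-length segment per rhythm episode, labeled from the
    episode symbol; episodes outside the task are dropped."""
    _check_episodes(episodes, record.samples.size)
    out: list[Segment] = []
    for ep in episodes:
        code = map_symbol(d, dataset, ep.symbol, "rhythm")
        if code is None:
            logger.warning("skipping unknown rhythm symbol %r (%s)", ep.symbol, dataset)
            continue
        ci = resolve_class(task, code)
        if ci == EXCLUDED:
            continue
        out.append(
            Segment(record.samples[ep.start : ep.end].copy(), ci,
                    record.record_id, record.patient_id, ep.start, "episodes", record.fs)
        )
    return out


def _check_episodes(episodes: Sequence[RhythmEpisode], n: int) -> None:
    prev_end = 0
    for ep in episodes:
        if not 0 <= ep.start < ep.end <= n:
            raise ValueError(f"episode ({ep.start}, {ep.end}) outside [0, {n}]")
        if ep.start < prev_end:
            raise ValueError("overlapping rhythm episodes")
        prev_end = ep.end


# ---------------------------------------------------------------------------
# Window labeling
# ---------------------------------------------------------------------------


def label_window(
    span: tuple[int, int],
    beats: Sequence[BeatAnnotation],
    episodes: Sequence[RhythmEpisode],
    d: LabelDictionary,
    task: TaskDefinition,
    dataset: str,
    class_counts: Optional[np.ndarray] = None,
) -> int:
    """Assign one task class to the half-open window ``span``.

    Rhythm tasks use coverage voting: the class whose episodes cover the
    largest portion of the window wins; an exact coverage tie goes to the
    class of the earlier-starting contributing episode.  Heartbeat-form
    tasks use the abnormal-priority rule: if at least one in-window beat
    resolves to an abnormal class the window takes that abnormal label (ties
    between distinct abnormal classes go to the globally rarer class per
    ``class_counts``, then lowest index); otherwise normal if any normal
    beat is present.  A window with no resolvable evidence is EXCLUDED.
    """
    start, end = span
    if task.kind == "rhythm":
        coverage = np.zeros(task.n_classes)
        first_start = np.full(task.n_classes, np.iinfo(np.int64).max, dtype=np.int64)
        for ep in episodes:
            ov = min(end, ep.end) - max(start, ep.start)
            if ov <= 0:
                continue
            code = map_symbol(d, dataset, ep.symbol, "rhythm")
            if code is None:
                continue
            ci = resolve_class(task, code)
            if ci == EXCLUDED:
                continue
            coverage[ci] += ov
            first_start[ci] = min(first_start[ci], ep.start)
        if coverage.sum() == 0:
            return EXCLUDED
        best = np.flatnonzero(coverage == coverage.max())
        if best.size == 1:
            return int(best[0])
        return int(best[np.argmin(first_start[best])])

    # form task
    present = np.zeros(task.n_classes, dtype=bool)
    for b in beats:
        if not start <= b.sample_index < end:
            continue
        code = map_symbol(d, dataset, b.symbol, "beat")
        if code is None:
            continue
        ci = resolve_class(task, code)
        if ci != EXCLUDED:
            present[ci] = True
    if not present.any():
        return EXCLUDED
    normal = task.normal_index()
    abnormal = [i for i in np.flatnonzero(present) if i != normal]
    if abnormal:
        if len(abnormal) == 1 or class_counts is None:
            return int(abnormal[0])
        counts = np.asarray(class_counts, dtype=float)[abnormal]
        return int(abnormal[int(np.argmin(counts))])  # rarer class; ties -> lowest index
    return int(normal) if normal is not None else EXCLUDED


def segment_sliding(
    record: EcgRecord,
    beats: Sequence[BeatAnnotation],
    episodes: Sequence[RhythmEpisode],
    params: WindowingParams,
    d: LabelDictionary,
    task: TaskDefinition,
    dataset: str,
    class_counts: Optional[np.ndarray] = None,
    transform_tag: Optional[str] = None,
) -> list[Segment]:
    """Sliding windows over a beat-level record, each labeled by
    :func:`label_window`; EXCLUDED windows are dropped.

    ``class_counts`` (global per-class beat counts over the dataset) feeds
    the rarer-class tie-break of the form rule; when omitted, counts over
    this record's own beats are used.
    """
    w, s = params.sizes(record.fs)
    tag = transform_tag or f"windows{params.window_s:g}s"
    n = record.samples.size
    if class_counts is None and task.kind == "form":
        class_counts = beat_class_counts(beats, d, task, dataset)
    out: list[Segment] = []
    for i in range(window_count(n, w, s)):
        start = i * s
        ci = label_window(
            (start, start + w), beats, episodes, d, task, dataset, class_counts
        )
        if ci == EXCLUDED:
            continue
        out.append(
            Segment(record.samples[start : start + w].copy(), ci,
                    record.record_id, record.patient_id, start, tag, record.fs)
        )
    return out


def beat_class_counts(
    beats: Sequence[BeatAnnotation],
    d: LabelDictionary,
    task: TaskDefinition,
    dataset: str,
) -> np.ndarray:
    counts = np.zeros(task.n_classes, dtype=np.int64)
    for b in beats:
        code = map_symbol(d, dataset, b.symbol, "beat")
        if code is None:
            continue
        ci = resolve_class(task, code)
        if ci != EXCLUDED:
            counts[ci] += 1
    return counts


# ---------------------------------------------------------------------------
# Recording-level segmentation
# ---------------------------------------------------------------------------


def _resolve_recording_label(
    rec_label: RecordingLabel, d: LabelDictionary, task: TaskDefinition, dataset: str
) -> int:
    """First listed label is used for single-label tasks; others logged."""
    code = map_symbol(d, dataset, rec_label.symbols[0], "rhythm")
    if code is None:
        code = map_symbol(d, dataset, rec_label.symbols[0], "beat")
    if code is None:
        logger.warning(
            "record %s: unresolvable label %r, skipping", rec_label.record_id,
            rec_label.symbols[0],
        )
        return EXCLUDED
    return resolve_class(task, code)


def segment_recording_windows(
    record: EcgRecord,
    rec_label: RecordingLabel,
    params: WindowingParams,
    d: LabelDictionary,
    task: TaskDefinition,
    dataset: str,
) -> list[Segment]:
    """Sliding windows over a recording-level record; every window inherits
    the resolved recording label."""
    ci = _resolve_recording_label(rec_label, d, task, dataset)
    if ci == EXCLUDED:
        return []
    w, s = params.sizes(record.fs)
    tag = f"windows{params.window_s:g}s"
    return [
        Segment(record.samples[i * s : i * s + w].copy(), ci,
                record.record_id, record.patient_id, i * s, tag, record.fs)
        for i in range(window_count(record.samples.size, w, s))
    ]


def whole_sequence(
    record: EcgRecord,
    rec_label: RecordingLabel,
    duration_s: float,
    d: LabelDictionary,
    task: TaskDefinition,
    dataset: str,
) -> Optional[Segment]:
    """The full record as one segment, cropped/zero-padded to
    ``round(duration_s * fs)`` samples; None if the label is unresolvable."""
    ci = _resolve_recording_label(rec_label, d, task, dataset)
    if ci == EXCLUDED:
        return None
    target = int(round(duration_s * record.fs))
    return Segment(
        fit_length(record.samples, target), ci, record.record_id,
        record.patient_id, 0, f"sequence{duration_s:g}s", record.fs,
    )


def aggregate_predictions(
    window_preds: Sequence[tuple[str, int]]
) -> dict[str, int]:
    """Majority vote of window predictions per recording; ties go to the
    lowest class index."""
    if not window_preds:
        raise ValueError("no window predictions to aggregate")
    by_rec: dict[str, list[int]] = {}
    for rid, ci in window_preds:
        by_rec.setdefault(rid, []).append(ci)
    out: dict[str, int] = {}
    for rid, labels in by_rec.items():
        vals, counts = np.unique(labels, return_counts=True)
        out[rid] = int(vals[counts == counts.max()].min())
    return out


def export_segment_table(segments: Sequence[Segment], path) -> None:
    """CSV export: record_id, patient_id, start, transform, label."""
    import csv

    with open(path, "w", newline="") as fh:
        wtr = csv.writer(fh)
        wtr.writerow(["record_id", "patient_id", "start", "transform", "label"])
        for seg in segments:
            wtr.writerow([seg.record_id, seg.patient_id, seg.start,
                          seg.transform_tag, seg.label])
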