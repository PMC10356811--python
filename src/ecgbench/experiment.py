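"""Experiment orchestration: dataset x task x transform x model x scheme.

``run_experiment`` executes the full pipeline — open the dataset, unify
labels, segment (with the overlap policy bound to the evaluation scheme),
resample/fit segments to the architecture's input contract, split, then per
fold train with early stopping, predict the test fold (optionally
aggregating window predictions to recordings) and compute metrics.  The test
fold is used for metric computation exclusively.  Per-fold scores are
averaged fold-then-mean; results are persisted as CSV tables plus a JSON run
manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as dio
from .annotations import (
    EXCLUDED,
    LabelDictionary,
    TaskDefinition,
    builtin_task,
    default_label_dictionary,
    load_label_dictionary,
    load_task_definitions,
    map_symbol,
    resolve_class,
)
from .metrics import MetricsReport, compute_metrics
from .models import (
    DEFAULT_INPUT_FS,
    ModelSpec,
    TrainConfig,
    build_model,
    dummy_majority,
    predict,
    train,
)
from .preprocess import fit_length, resample
from .segmentation import (
    Segment,
    WindowingParams,
    aggregate_predictions,
    beat_class_counts,
    segment_beats,
    segment_episodes,
    segment_recording_windows,
    segment_sliding,
    whole_sequence,
)
from .splitting import (
    TrainValTest,
    inter_patient_cv,
    intra_patient_cv,
    leave_one_patient_out,
    predefined_folds,
    stratified_group_kfold,
    verify_inter_patient,
)

logger = logging.getLogger(__name__)

EVAL_SCHEMES = ("inter_cv", "intra_cv", "lopo", "holdout", "predefined")
INTER_PATIENT_SCHEMES = ("inter_cv", "lopo", "holdout")

_DURATION_RE = re.compile(r"^(beats|windows|sequence)([0-9.]+)s$")


def transform_duration(tag: str) -> float:
    if tag == "episodes":
        return 10.0  # variable-length episodes are fitted to a 10 s input
    m = _DURATION_RE.match(tag)
    if not m:
        raise ValueError(f"unknown transform tag {tag!r}")
    return float(m.group(2))


@dataclass
class ExperimentConfig:
    dataset_root: str
    dataset_name: str
    task: str  # built-in task name, or "<file.csv>:<task>"
    transform: str  # Table-1-style tag, e.g. "windows2.5s"
    architecture: str  # cnn|resnet|gruattnet|rtacnn|dummy_mv
    eval_scheme: str = "inter_cv"
    lead: str = "II"
    k: int = 10
    seed: int = 0
    train: TrainConfig = field(default_factory=TrainConfig)
    aggregate_to_recording: bool = False
    overlap_fraction: Optional[float] = None  # None -> bound to the scheme
    input_fs: Optional[float] = None  # None -> the architecture's default
    label_dictionary: Optional[str] = None  # CSV path; None -> packaged default
    predefined_split: Optional[dict[str, int]] = None  # record_id -> fold
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.eval_scheme not in EVAL_SCHEMES:
            raise ValueError(f"unknown eval scheme {self.eval_scheme!r}")
        transform_duration(self.transform)  # validates the tag
        if isinstance(self.train, dict):
            self.train = TrainConfig(**self.train)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class ResultsTable:
    config_summary: str
    fold_reports: list[MetricsReport]
    class_names: list[str]

    @property
    def fold_macro_f1(self) -> list[float]:
        return [r.macro_f1 for r in self.fold_reports]

    @property
    def mean_macro_f1(self) -> float:
        return float(np.mean(self.fold_macro_f1))

    @property
    def sd_macro_f1(self) -> float:
        return float(np.std(self.fold_macro_f1))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.fold_reports:
            row = {"fold": r.fold_id, "macro_f1": r.macro_f1}
            for i, cn in enumerate(self.class_names):
                row[f"f1_{cn}"] = r.f1[i]
                row[f"precision_{cn}"] = r.precision[i]
                row[f"recall_{cn}"] = r.recall[i]
            rows.append(row)
        return pd.DataFrame(rows)

    def summary_frame(self) -> pd.DataFrame:
        df = self.to_frame()
        agg = df.drop(columns="fold").agg(["mean", "std"])
        agg.insert(0, "config", self.config_summary)
        return agg


def _load_task(name: str) -> TaskDefinition:
    if ":" in name:
        path, tname = name.rsplit(":", 1)
        return load_task_definitions(path)[tname]
    return builtin_task(name)


def _overlap_for_scheme(scheme: str) -> float:
    # 50% overlap for inter-patient evaluations; none for intra-patient,
    # avoiding label leakage through overlapping windows across the split.
    return 0.0 if scheme == "intra_cv" else 0.5


def build_segments(
    handle: dio.DatasetHandle,
    d: LabelDictionary,
    task: TaskDefinition,
    transform: str,
    overlap_fraction: float = 0.5,
) -> list[Segment]:
    """Run the configured transform over every record of the dataset."""
    duration = transform_duration(transform)
    segs: list[Segment] = []
    if handle.category == dio.BEAT_LEVEL:
        if transform.startswith("sequence"):
            raise ValueError("sequence input applies to recording-level datasets")
        loaded = [dio.read_record(handle, rid) for rid in handle.record_ids]
        if transform.startswith("beats"):
            for rec, beats, _, _ in loaded:
                segs += segment_beats(rec, beats, duration, d, task, handle.name,
                                      transform_tag=transform)
        elif transform.startswith("windows"):
            counts = None
            if task.kind == "form":
                counts = sum(
                    beat_class_counts(b, d, task, handle.name) for _, b, _, _ in loaded
                )
            params = WindowingParams(duration, overlap_fraction)
            for rec, beats, episodes, _ in loaded:
                segs += segment_sliding(rec, beats, episodes, params, d, task,
                                        handle.name, class_counts=counts,
                                        transform_tag=transform)
        elif transform == "episodes":
            for rec, _, episodes, _ in loaded:
                segs += segment_episodes(rec, episodes, d, task, handle.name)
        return segs

    # recording-level
    if transform.startswith(("beats", "episodes")):
        raise ValueError(
            f"transform {transform!r} requires beat-level annotations; "
            f"dataset {handle.name!r} is recording-level"
        )
    for rid in handle.record_ids:
        rec, _, _, label = dio.read_record(handle, rid)
        assert label is not None
        if transform.startswith("windows"):
            params = WindowingParams(duration, overlap_fraction)
            segs += segment_recording_windows(rec, label, params, d, task, handle.name)
        else:
            seg = whole_sequence(rec, label, duration, d, task, handle.name)
            if seg is not None:
                segs.append(seg)
    return segs


def _prepare_arrays(
    segs: list[Segment], to_fs: float, target_len: int
) -> np.ndarray:
    X = np.empty((len(segs), target_len))
    for i, s in enumerate(segs):
        X[i] = fit_length(resample(s.samples, s.fs, to_fs), target_len)
    return X


def _make_splits(cfg: ExperimentConfig, segs: list[Segment], C: int) -> list[TrainValTest]:
    if cfg.eval_scheme == "inter_cv":
        return inter_patient_cv(segs, k=cfg.k, n_classes=C)
    if cfg.eval_scheme == "intra_cv":
        return intra_patient_cv(segs, k=cfg.k, seed=cfg.seed)
    if cfg.eval_scheme == "lopo":
        return leave_one_patient_out(segs)
    if cfg.eval_scheme == "predefined":
        if cfg.predefined_split is None:
            raise ValueError("predefined scheme requires a record->fold assignment")
        return predefined_folds(segs, cfg.predefined_split, seed=cfg.seed)
    # holdout: one stratified patient split, test = one of 1/k of patients,
    # val carved from the training patients
    counts: dict[str, np.ndarray] = {}
    for s in segs:
        counts.setdefault(s.patient_id, np.zeros(C, dtype=np.int64))[s.label] += 1
    fs = stratified_group_kfold(counts, max(cfg.k, 2))
    pfold = {p: f for f, fold in enumerate(fs.folds) for p in fold}
    sf = np.array([pfold[s.patient_id] for s in segs])
    return [
        TrainValTest(
            train=np.flatnonzero(sf >= 2),
            val=np.flatnonzero(sf == 1),
            test=np.flatnonzero(sf == 0),
            fold_id=0,
        )
    ]


def run_experiment(cfg: ExperimentConfig) -> ResultsTable:
    handle = dio.open_dataset(cfg.dataset_root, cfg.dataset_name, lead=cfg.lead)
    d = (load_label_dictionary(cfg.label_dictionary) if cfg.label_dictionary
         else default_label_dictionary())
    task = _load_task(cfg.task)
    overlap = (cfg.overlap_fraction if cfg.overlap_fraction is not None
               else _overlap_for_scheme(cfg.eval_scheme))
    segs = build_segments(handle, d, task, cfg.transform, overlap)
    if not segs:
        raise ValueError("no segments produced; check transform/task/dataset")
    C = task.n_classes
    y = np.array([s.label for s in segs], dtype=int)

    is_dummy = cfg.architecture == "dummy_mv"
    if is_dummy:
        X = np.zeros((len(segs), 1))
        spec = None
    else:
        net_fs = cfg.input_fs or DEFAULT_INPUT_FS[cfg.architecture]
        input_len = int(round(transform_duration(cfg.transform) * net_fs))
        X = _prepare_arrays(segs, net_fs, input_len)
        spec = ModelSpec(cfg.architecture, net_fs, input_len, C, seed=cfg.seed)

    splits = _make_splits(cfg, segs, C)
    reports: list[MetricsReport] = []
    for split in splits:
        if cfg.eval_scheme in INTER_PATIENT_SCHEMES:
            ok, report = verify_inter_patient(split, segs)
            if not ok:  # hard leakage guard, never a warning
                raise AssertionError(f"inter-patient violation: {report}")
        if is_dummy:
            model = dummy_majority(y[split.train], n_classes=C)
        else:
            fold_spec = dataclasses.replace(spec, seed=cfg.seed + split.fold_id)
            model = build_model(fold_spec)
            train(model, (X[split.train], y[split.train]),
                  (X[split.val], y[split.val]), cfg.train)
        _, pred = predict(model, (X[split.test], y[split.test]))
        truth = y[split.test]
        if cfg.aggregate_to_recording:
            rids = [segs[i].record_id for i in split.test]
            agg_pred = aggregate_predictions(list(zip(rids, pred.tolist())))
            agg_truth = aggregate_predictions(list(zip(rids, truth.tolist())))
            order = sorted(agg_pred)
            pred = np.array([agg_pred[r] for r in order])
            truth = np.array([agg_truth[r] for r in order])
        reports.append(compute_metrics(truth, pred, C, fold_id=split.fold_id))
        logger.info("fold %d: macro F1 = %.4f", split.fold_id, reports[-1].macro_f1)

    summary = (f"{cfg.dataset_name}/{cfg.task}/{cfg.transform}/"
               f"{cfg.architecture}/{cfg.eval_scheme}")
    table = ResultsTable(summary, reports, task.class_names)
    if cfg.out_dir:
        _persist(cfg, table)
    return table


def _persist(cfg: ExperimentConfig, table: ResultsTable) -> None:
    out = Path(cfg.out_dir)
    (out / "results_tables").mkdir(parents=True, exist_ok=True)
    table.to_frame().to_csv(out / "results_tables" / "per_fold.csv", index=False)
    table.summary_frame().to_csv(out / "results_tables" / "summary.csv")
    for r in table.fold_reports:
        np.savetxt(out / "results_tables" / f"confusion_fold{r.fold_id}.csv",
                   r.confusion, fmt="%d", delimiter=",")
    manifest = dataclasses.asdict(cfg)
    manifest["train"] = dataclasses.asdict(cfg.train)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))


def class_distribution_report(
    handle: dio.DatasetHandle,
    d: LabelDictionary,
    task: TaskDefinition,
    plot_path: Optional[str] = None,
) -> pd.DataFrame:
    """Per-class counts of distinct annotated occurrences (beats, episodes
    or recordings, per the dataset category and task kind)."""
    counts = np.zeros(task.n_classes, dtype=np.int64)
    for rid in handle.record_ids:
        _, beats, episodes, label = dio.read_record(handle, rid)
        if handle.category == dio.BEAT_LEVEL:
            items = ([(b.symbol, "beat") for b in beats] if task.kind == "form"
                     else [(e.symbol, "rhythm") for e in episodes])
        else:
            assert label is not None
            items = [(label.symbols[0], "rhythm")]
        for sym, kind in items:
            code = map_symbol(d, handle.name, sym, kind)
            if code is None:
                continue
            ci = resolve_class(task, code)
            if ci != EXCLUDED:
                counts[ci] += 1
    df = pd.DataFrame({"class": task.class_names, "count": counts})
    if plot_path:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 3))
        ax.bar(df["class"], df["count"])
        ax.set_ylabel("annotated occurrences")
        ax.set_title(f"{handle.name}: {task.name}")
        fig.tight_layout()
        fig.savefig(plot_path)
        plt.close(fig)
    return df
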