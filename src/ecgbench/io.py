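"""Dataset reading and on-disk layout.

Both dataset categories are exposed through one abstraction:

* **beat-level** datasets: long records with per-beat annotations (R-peak
  sample index + symbol) and optionally rhythm-change markers that are
  converted at read time to half-open ``[start, end)`` episodes;
* **recording-level** datasets: short (~10 s) records, each carrying one
  diagnostic label (rarely several) in a CSV label table.

The on-disk layout is plain text, one record spread over a JSON header
(``<id>.hdr.json``: patient, sampling frequency, lead names), a whitespace
signal matrix (``<id>.sig.txt``, one column per lead) and an annotation CSV
(``<id>.ann.csv`` with columns ``sample,kind,symbol``; ``kind`` is ``beat``
or ``rhythm``, rhythm rows being change points).  A ``dataset.json`` at the
dataset root enumerates records and patients.  The synthetic generator
writes exactly this layout, so everything here round-trips.

All sample indices are 0-based; episodes are half-open.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

BEAT_LEVEL = "beat_level"
RECORDING_LEVEL = "recording_level"


class DatasetError(ValueError):
    pass


@dataclass
class EcgRecord:
    """One single-lead ECG signal."""

    record_id: str
    patient_id: str
    samples: np.ndarray  # float vector, arbitrary amplitude units
    fs: float  # Hz
    lead_name: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise DatasetError(f"record {self.record_id}: empty or non-1D signal")
        if not self.fs > 0:
            raise DatasetError(f"record {self.record_id}: fs must be > 0")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class BeatAnnotation:
    sample_index: int  # R-peak location
    symbol: str


@dataclass(frozen=True)
class RhythmEpisode:
    start: int  # inclusive
    end: int  # exclusive
    symbol: str


@dataclass(frozen=True)
class RecordingLabel:
    record_id: str
    symbols: tuple[str, ...]  # >= 1 entries; first is primary


@dataclass
class DatasetHandle:
    name: str
    category: str  # BEAT_LEVEL or RECORDING_LEVEL
    root: Path
    chosen_lead: str
    records: list[tuple[str, str]] = field(default_factory=list)  # (record_id, patient_id)

    @property
    def record_ids(self) -> list[str]:
        return [r for r, _ in self.records]

    def patient_of(self, record_id: str) -> str:
        for r, p in self.records:
            if r == record_id:
                return p
        raise DatasetError(f"unknown record {record_id!r} in dataset {self.name!r}")


def open_dataset(root: str | Path, name: str, lead: str = "II") -> DatasetHandle:
    """Open the dataset ``name`` under directory ``root``, selecting ``lead``.

    Raises if the directory is missing/empty or if the requested lead is not
    available (the error lists the available leads).
    """
    ddir = Path(root) / name
    meta_path = ddir / "dataset.json"
    if not meta_path.exists():
        raise DatasetError(f"no dataset.json under {ddir}")
    meta = json.loads(meta_path.read_text())
    if meta.get("category") not in (BEAT_LEVEL, RECORDING_LEVEL):
        raise DatasetError(f"{meta_path}: bad category {meta.get('category')!r}")
    if not meta.get("records"):
        raise DatasetError(f"{meta_path}: dataset has no records")
    leads = meta.get("leads", [])
    if lead not in leads:
        raise DatasetError(
            f"lead {lead!r} not in dataset {name!r}; available leads: {leads}"
        )
    records = [(r["record_id"], r["patient_id"]) for r in meta["records"]]
    seen = set()
    for rid, _ in records:
        if rid in seen:
            raise DatasetError(f"duplicate record id {rid!r}")
        seen.add(rid)
    return DatasetHandle(
        name=meta["name"], category=meta["category"], root=ddir,
        chosen_lead=lead, records=records,
    )


def _read_annotations(
    path: Path, n_samples: int, record_id: str
) -> tuple[list[BeatAnnotation], list[RhythmEpisode]]:
    beats: list[BeatAnnotation] = []
    rhythm_points: list[tuple[int, str]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            try:
                s = int(row["sample"])
                kind = row["kind"]
                sym = row["symbol"]
            except (KeyError, ValueError) as exc:
                raise DatasetError(
                    f"record {record_id}: corrupt annotation row {row!r}"
                ) from exc
            if not 0 <= s < n_samples:
                raise DatasetError(
                    f"record {record_id}: annotation sample {s} outside [0, {n_samples})"
                )
            if kind == "beat":
                beats.append(BeatAnnotation(s, sym))
            elif kind == "rhythm":
                rhythm_points.append((s, sym))
            else:
                raise DatasetError(f"record {record_id}: bad annotation kind {kind!r}")
    beats.sort(key=lambda b: b.sample_index)
    for a, b in zip(beats, beats[1:]):
        if a.sample_index == b.sample_index:
            raise DatasetError(
                f"record {record_id}: duplicate beat annotation at {a.sample_index}"
            )
    # rhythm change points -> half-open episodes, last closed at record end
    rhythm_points.sort(key=lambda t: t[0])
    episodes: list[RhythmEpisode] = []
    for i, (s, sym) in enumerate(rhythm_points):
        end = rhythm_points[i + 1][0] if i + 1 < len(rhythm_points) else n_samples
        if end > s:
            episodes.append(RhythmEpisode(s, end, sym))
    return beats, episodes


def read_record(
    handle: DatasetHandle, record_id: str
) -> tuple[EcgRecord, list[BeatAnnotation], list[RhythmEpisode], Optional[RecordingLabel]]:
    """Read one record with the annotations applicable to its category.

    Beat-level records return sorted beats and validated non-overlapping
    episodes with an empty recording label; recording-level records return a
    populated label and empty beat/episode lists.
    """
    pid = handle.patient_of(record_id)
    hdr = json.loads((handle.root / f"{record_id}.hdr.json").read_text())
    sig = np.loadtxt(handle.root / f"{record_id}.sig.txt", dtype=float, ndmin=2)
    leads = hdr["leads"]
    if handle.chosen_lead not in leads:
        raise DatasetError(
            f"record {record_id}: lead {handle.chosen_lead!r} missing; has {leads}"
        )
    samples = sig[:, leads.index(handle.chosen_lead)]
    rec = EcgRecord(
        record_id=record_id, patient_id=pid, samples=samples,
        fs=float(hdr["fs"]), lead_name=handle.chosen_lead,
    )
    if handle.category == BEAT_LEVEL:
        beats, episodes = _read_annotations(
            handle.root / f"{record_id}.ann.csv", samples.size, record_id
        )
        return rec, beats, episodes, None
    label = _read_recording_label(handle, record_id)
    return rec, [], [], label


def _read_recording_label(handle: DatasetHandle, record_id: str) -> RecordingLabel:
    with open(handle.root / "labels.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            if row["record_id"] == record_id:
                symbols = tuple(s for s in row["labels"].split(";") if s)
                if not symbols:
                    raise DatasetError(f"record {record_id}: empty label list")
                if len(symbols) > 1:
                    logger.info(
                        "record %s carries %d labels; using %r for single-label tasks",
                        record_id, len(symbols), symbols[0],
                    )
                return RecordingLabel(record_id, symbols)
    raise DatasetError(f"record {record_id}: no row in labels.csv")


def patients(handle: DatasetHandle) -> list[str]:
    """All patient ids, in stable first-appearance order."""
    seen: dict[str, None] = {}
    for _, pid in handle.records:
        seen.setdefault(pid)
    return list(seen)


def records_of(handle: DatasetHandle, patient_id: str) -> list[str]:
    rids = [r for r, p in handle.records if p == patient_id]
    if not rids:
        raise DatasetError(f"unknown patient {patient_id!r} in dataset {handle.name!r}")
    return rids


# ---------------------------------------------------------------------------
# Writing (used by the synthetic generator and for export)
# ---------------------------------------------------------------------------


def write_record(
    ddir: Path,
    record_id: str,
    fs: float,
    lead_signals: dict[str, np.ndarray],
    patient_id: str,
    beats: list[BeatAnnotation] | None = None,
    rhythm_points: list[tuple[int, str]] | None = None,
) -> None:
    ddir.mkdir(parents=True, exist_ok=True)
    leads = list(lead_signals)
    n = len(next(iter(lead_signals.values())))
    hdr = {
        "record_id": record_id, "patient_id": patient_id, "fs": fs,
        "n_samples": n, "leads": leads,
    }
    (ddir / f"{record_id}.hdr.json").write_text(json.dumps(hdr, indent=1))
    mat = np.column_stack([np.asarray(lead_signals[l], dtype=float) for l in leads])
    np.savetxt(ddir / f"{record_id}.sig.txt", mat, fmt="%.5f")
    if beats is not None or rhythm_points is not None:
        with open(ddir / f"{record_id}.ann.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["sample", "kind", "symbol"])
            rows = [(b.sample_index, "beat", b.symbol) for b in (beats or [])]
            rows += [(s, "rhythm", sym) for s, sym in (rhythm_points or [])]
            for s, kind, sym in sorted(rows):
                w.writerow([s, kind, sym])


def write_dataset_meta(
    ddir: Path, name: str, category: str, leads: list[str],
    records: list[tuple[str, str]],
) -> None:
    ddir.mkdir(parents=True, exist_ok=True)
    meta = {
        "name": name, "category": category, "leads": leads,
        "records": [{"record_id": r, "patient_id": p} for r, p in records],
    }
    (ddir / "dataset.json").write_text(json.dumps(meta, indent=1))


def write_label_table(ddir: Path, rows: list[tuple[str, str, list[str]]]) -> None:
    """Write the recording-level label table: record_id, patient_id, labels."""
    with open(ddir / "labels.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["record_id", "patient_id", "labels"])
        for rid, pid, labels in rows:
            w.writerow([rid, pid, ";".join(labels)])
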