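"""Label dictionary and task definitions.

Public ECG datasets annotate the same arrhythmia with different raw symbols
(atrial fibrillation appears as ``AFIB`` in some sources and ``AF`` in
others; premature ventricular beats as ``V`` or ``PVC``).  The label
dictionary unifies these into a closed vocabulary of arrhythmia codes, and a
:class:`TaskDefinition` groups unified codes into the ordered target classes
of one classification task (e.g. the AAMI form task N / SVEB / VEB, or the
reduced rhythm task AFIB / SINUS / other).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Final, Iterable, Optional

logger = logging.getLogger(__name__)

#: Closed vocabulary of unified arrhythmia codes.  Beat (form) codes first,
#: then rhythm codes.  ``NOISE`` marks non-diagnostic annotations.
UNIFIED_CODES: Final[frozenset[str]] = frozenset(
    {
        # beat-form codes
        "N", "LBBB", "RBBB", "PAC", "PVC", "FUSION", "PACED", "UNKNOWN",
        # rhythm codes
        "SINUS", "AFIB", "AFL", "STACH", "SBRAD", "SVTA",
        # non-diagnostic
        "NOISE",
    }
)

#: Annotation kinds: a symbol either labels a single beat or a rhythm episode.
KINDS: Final[tuple[str, str]] = ("beat", "rhythm")

#: Sentinel returned by :func:`resolve_class` for codes outside every task
#: class.  Distinct from ``None`` (symbol unknown to the dictionary).
EXCLUDED: Final[int] = -1


class LabelDictionaryError(ValueError):
    """Malformed or inconsistent label-dictionary input."""


@dataclass(frozen=True)
class DictEntry:
    dataset: str
    raw_symbol: str
    unified_code: str
    kind: str


@dataclass
class LabelDictionary:
    """Mapping ``(dataset, raw_symbol, kind) -> unified_code``."""

    entries: list[DictEntry] = field(default_factory=list)
    _index: dict[tuple[str, str, str], str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            for e in self.entries:
                self._add_to_index(e)

    def _add_to_index(self, e: DictEntry) -> None:
        key = (e.dataset, e.raw_symbol, e.kind)
        if key in self._index:
            raise LabelDictionaryError(f"duplicate dictionary key {key!r}")
        if e.kind not in KINDS:
            raise LabelDictionaryError(f"unknown annotation kind {e.kind!r} for {key!r}")
        if e.unified_code not in UNIFIED_CODES:
            raise LabelDictionaryError(
                f"unified code {e.unified_code!r} outside the closed vocabulary"
            )
        self._index[key] = e.unified_code

    def add(self, dataset: str, raw_symbol: str, unified_code: str, kind: str) -> None:
        e = DictEntry(dataset, raw_symbol, unified_code, kind)
        self._add_to_index(e)
        self.entries.append(e)

    def lookup(self, dataset: str, raw_symbol: str, kind: str) -> Optional[str]:
        return self._index.get((dataset, raw_symbol, kind))

    def save(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["dataset", "raw_symbol", "unified_code", "kind"])
            for e in self.entries:
                w.writerow([e.dataset, e.raw_symbol, e.unified_code, e.kind])


def load_label_dictionary(path: str | Path) -> LabelDictionary:
    """Load a label dictionary from CSV.

    The file must have a header row naming the columns
    ``dataset,raw_symbol,unified_code,kind``.  Duplicate
    ``(dataset, raw_symbol, kind)`` keys and codes outside the closed
    vocabulary are rejected.
    """
    path = Path(path)
    d = LabelDictionary()
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise LabelDictionaryError(f"{path}: empty file, header row required")
        expected = ["dataset", "raw_symbol", "unified_code", "kind"]
        if [h.strip() for h in header] != expected:
            raise LabelDictionaryError(
                f"{path}: header must be {','.join(expected)}, got {header!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 4:
                raise LabelDictionaryError(
                    f"{path}:{lineno}: expected 4 fields, got {len(row)}"
                )
            try:
                d.add(*[c.strip() for c in row])
            except LabelDictionaryError as exc:
                raise LabelDictionaryError(f"{path}:{lineno}: {exc}") from exc
    return d


def default_label_dictionary() -> LabelDictionary:
    """The dictionary shipped with the package.

    Covers the synthetic datasets (``synth``) and the standard
    single-character beat-symbol / rhythm-label conventions of the public
    physiological-signal repository (entered under ``mitbih_ar``).
    """
    with resources.as_file(
        resources.files("ecgbench.data") / "label_dictionary.csv"
    ) as p:
        return load_label_dictionary(p)


def map_symbol(
    d: LabelDictionary, dataset: str, raw_symbol: str, kind: str
) -> Optional[str]:
    """Exact-match lookup of a raw annotation symbol.

    Returns the unified code, or ``None`` when the symbol is absent from the
    dictionary (the caller decides whether to skip or fail).
    """
    return d.lookup(dataset, raw_symbol, kind)


# ---------------------------------------------------------------------------
# Task definitions
# ---------------------------------------------------------------------------


@dataclass
class TaskDefinition:
    """An ordered set of target classes over unified codes.

    ``classes`` fixes the label indices ``0..C-1``.  ``other_class`` names a
    class that collects every code not explicitly assigned; without it,
    unassigned codes resolve to :data:`EXCLUDED`.
    """

    name: str
    classes: list[tuple[str, frozenset[str]]]
    kind: str  # "form" or "rhythm"
    other_class: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ValueError(f"task {self.name!r}: at least 2 classes required")
        if self.kind not in ("form", "rhythm"):
            raise ValueError(f"task {self.name!r}: kind must be form or rhythm")
        seen: set[str] = set()
        for cname, codes in self.classes:
            overlap = seen & codes
            if overlap:
                raise ValueError(
                    f"task {self.name!r}: codes {sorted(overlap)} in multiple classes"
                )
            seen |= codes
        names = [c for c, _ in self.classes]
        if self.other_class is not None and self.other_class not in names:
            raise ValueError(
                f"task {self.name!r}: other_class {self.other_class!r} not a class"
            )

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def class_names(self) -> list[str]:
        return [c for c, _ in self.classes]

    def normal_index(self) -> Optional[int]:
        """Index of the class containing the normal-beat code ``N``, if any."""
        for i, (_, codes) in enumerate(self.classes):
            if "N" in codes:
                return i
        return None


def resolve_class(task: TaskDefinition, code: str) -> int:
    """Map a unified code to its class index in ``task``.

    Falls through to the other-class if the task defines one; otherwise
    returns :data:`EXCLUDED`.  Total and deterministic.
    """
    for i, (_, codes) in enumerate(task.classes):
        if code in codes:
            return i
    if task.other_class is not None:
        return task.class_names.index(task.other_class)
    return EXCLUDED


# Built-in tasks.  The AAMI form grouping: SVEB collects supraventricular
# ectopic beats, VEB ventricular ectopic beats, N normal plus bundle-branch
# block; fusion/paced/unknown beats are excluded (overridable via a custom
# task file).
_BUILTIN_TASKS: Final[dict[str, TaskDefinition]] = {}


def _register_builtin() -> None:
    _BUILTIN_TASKS["form"] = TaskDefinition(
        name="form",
        classes=[
            ("N", frozenset({"N", "LBBB", "RBBB"})),
            ("SVEB", frozenset({"PAC"})),
            ("VEB", frozenset({"PVC"})),
        ],
        kind="form",
    )
    _BUILTIN_TASKS["rhythm"] = TaskDefinition(
        name="rhythm",
        classes=[
            ("SINUS", frozenset({"SINUS"})),
            ("STACH", frozenset({"STACH"})),
            ("SBRAD", frozenset({"SBRAD"})),
            ("SVTA", frozenset({"SVTA"})),
            ("AFIB", frozenset({"AFIB"})),
            ("AFL", frozenset({"AFL"})),
        ],
        kind="rhythm",
    )
    _BUILTIN_TASKS["rhythm_reduced"] = TaskDefinition(
        name="rhythm_reduced",
        classes=[
            ("AFIB", frozenset({"AFIB"})),
            ("SINUS", frozenset({"SINUS"})),
            ("OTHER", frozenset()),
        ],
        kind="rhythm",
        other_class="OTHER",
    )


_register_builtin()


def builtin_task(name: str) -> TaskDefinition:
    """Return one of the built-in tasks: ``form``, ``rhythm``, ``rhythm_reduced``."""
    try:
        return _BUILTIN_TASKS[name]
    except KeyError:
        raise KeyError(
            f"unknown task {name!r}; built-ins: {sorted(_BUILTIN_TASKS)}"
        ) from None


def load_task_definitions(path: str | Path) -> dict[str, TaskDefinition]:
    """Load task definitions from CSV.

    Columns ``task,class,member_codes,kind`` with member codes ``;``-separated;
    a row whose member_codes is ``*`` declares that class as the catch-all
    other-class.  Class order within a task follows file order.
    """
    rows: dict[str, list[tuple[str, str, str]]] = {}
    kinds: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"task", "class", "member_codes", "kind"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise LabelDictionaryError(
                f"{path}: header must contain {sorted(required)}"
            )
        for row in reader:
            t = row["task"].strip()
            rows.setdefault(t, []).append(
                (row["class"].strip(), row["member_codes"].strip(), row["kind"].strip())
            )
            kinds[t] = row["kind"].strip()
    tasks: dict[str, TaskDefinition] = {}
    for t, class_rows in rows.items():
        classes: list[tuple[str, frozenset[str]]] = []
        other: Optional[str] = None
        for cname, codes_s, _ in class_rows:
            if codes_s == "*":
                other = cname
                classes.append((cname, frozenset()))
            else:
                codes = frozenset(c for c in codes_s.split(";") if c)
                classes.append((cname, codes))
        tasks[t] = TaskDefinition(name=t, classes=classes, kind=kinds[t], other_class=other)
    return tasks


def skip_unknown(symbols: Iterable[str], d: LabelDictionary, dataset: str, kind: str):
    """Yield (symbol, code) pairs, skipping symbols unknown to the dictionary."""
    for s in symbols:
        code = d.lookup(dataset, s, kind)
        if code is None:
            logger.warning("skipping unknown %s symbol %r in dataset %r", kind, s, dataset)
            continue
        yield s, code
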