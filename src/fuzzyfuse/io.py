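"""Delimited-text score tables, label files, and the ensemble manifest.

Score tables are CSV or TSV (delimiter sniffed) with a header row naming
``sample_id`` followed by one column per class label.  Labels files carry
two columns, ``sample_id`` and ``label``.  The manifest is a JSON or YAML
document listing, per classifier, an identifier, a score-file path and an
accuracy in (0, 1], plus an optional labels path, the positive class label,
and options (currently the accuracy policy: ``manifest`` uses the listed
accuracies, ``out-of-fold`` recomputes them per fold in the CV harness).
Floats are written with 10 significant digits, so write-then-read
round-trips are bit-identical at that precision.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .transform import ProbabilityMatrix, ValidationError

_FLOAT_FMT = "{:.10g}"


class ParseError(ValueError):
    """Raised when an input file violates the table or manifest format."""


@dataclass(frozen=True)
class ClassifierEntry:
    identifier: str
    score_path: Path
    accuracy: float


@dataclass(frozen=True)
class EnsembleManifest:
    """Parsed manifest: classifier entries plus evaluation options."""

    classifiers: tuple
    labels_path: Path | None = None
    positive_class: str = "1"
    options: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.classifiers:
            raise ParseError("manifest lists no classifiers")
        ids = [c.identifier for c in self.classifiers]
        if len(set(ids)) != len(ids):
            raise ParseError(f"duplicate classifier identifiers in manifest: {ids}")
        for c in self.classifiers:
            if not (np.isfinite(c.accuracy) and 0.0 < c.accuracy <= 1.0):
                raise ParseError(
                    f"classifier {c.identifier!r} has invalid accuracy {c.accuracy!r}"
                )

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([c.accuracy for c in self.classifiers])

    @property
    def accuracy_policy(self) -> str:
        return self.options.get("accuracy_policy", "manifest")


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t").delimiter
    except csv.Error:
        return ","


def read_score_table(path: str | Path) -> ProbabilityMatrix:
    """Read and validate one classifier's probability table."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise ParseError(f"{path}: empty file")
    delim = _sniff_delimiter(text.splitlines()[0])
    rows = list(csv.reader(text.splitlines(), delimiter=delim))
    header = rows[0]
    if len(header) < 3 or header[0] != "sample_id":
        raise ParseError(
            f"{path}:1: header must be 'sample_id' followed by >=2 class columns, got {header}"
        )
    class_labels = header[1:]
    sample_ids, values = [], []
    for lineno, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        if len(row) != len(header):
            raise ParseError(f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}")
        sample_ids.append(row[0])
        try:
            values.append([float(x) for x in row[1:]])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric probability: {exc}") from None
    if len(set(sample_ids)) != len(sample_ids):
        raise ParseError(f"{path}: duplicate sample_id values")
    try:
        return ProbabilityMatrix(
            sample_ids=sample_ids, values=np.array(values, dtype=float), class_labels=class_labels
        )
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_score_table(table: ProbabilityMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", *table.class_labels])
        for sid, row in zip(table.sample_ids, table.values):
            writer.writerow([sid, *(_FLOAT_FMT.format(v) for v in row)])


def read_labels(path: str | Path) -> tuple[list, np.ndarray]:
    """Read a two-column sample_id/label file; returns (ids, integer labels)."""
    path = Path(path)
    rows = list(csv.reader(path.read_text(encoding="utf-8").splitlines(),
                           delimiter=_sniff_delimiter(path.read_text(encoding="utf-8").splitlines()[0])))
    if not rows or rows[0][:2] != ["sample_id", "label"]:
        raise ParseError(f"{path}:1: header must be 'sample_id,label'")
    ids, labels = [], []
    for lineno, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        if len(row) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 fields, got {len(row)}")
        ids.append(row[0])
        try:
            labels.append(int(row[1]))
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-integer label {row[1]!r}") from None
    return ids, np.array(labels, dtype=int)


def write_labels(sample_ids: Sequence[str], labels: Sequence[int], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "label"])
        for sid, lab in zip(sample_ids, labels):
            writer.writerow([sid, int(lab)])


def read_manifest(path: str | Path) -> EnsembleManifest:
    """Parse a JSON or YAML ensemble manifest; paths resolve relative to it."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))  # YAML is a JSON superset
    if not isinstance(raw, dict) or "classifiers" not in raw:
        raise ParseError(f"{path}: manifest must be a mapping with a 'classifiers' list")
    base = path.parent
    entries = []
    for i, item in enumerate(raw["classifiers"]):
        try:
            entries.append(
                ClassifierEntry(
                    identifier=str(item["id"]),
                    score_path=base / item["scores"],
                    accuracy=float(item["accuracy"]),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"{path}: classifier entry {i} malformed: {exc}") from None
    labels_path = base / raw["labels"] if raw.get("labels") else None
    return EnsembleManifest(
        classifiers=tuple(entries),
        labels_path=labels_path,
        positive_class=str(raw.get("positive_class", "1")),
        options=dict(raw.get("options", {})),
    )


def load_manifest_tables(manifest: EnsembleManifest) -> list[ProbabilityMatrix]:
    """Read every classifier's score table listed in a manifest."""
    return [read_score_table(entry.score_path) for entry in manifest.classifiers]


def write_metrics_report(report, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.as_dict(), indent=2) + "\n", encoding="utf-8")
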