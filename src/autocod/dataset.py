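"""Numeric training datasets and ARFF / CSV serialization.

The ARFF dialect written here is the minimal classic subset — numeric
attributes, one trailing nominal class attribute declared with the full
class set — and round-trips through standard ARFF readers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["TrainingDataset", "write_arff", "read_arff"]


@dataclass
class TrainingDataset:
    """A feature matrix with nominal labels, ready for classification.

    Rows align with corpus order; ``classes`` is the full declared class
    set (superset of the labels actually present).
    """

    attributes: list[str]
    X: np.ndarray
    labels: list[str]
    classes: tuple[str, ...]
    report_ids: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape != (len(self.labels), len(self.attributes)):
            raise ValueError(
                f"feature matrix shape {self.X.shape} inconsistent with "
                f"{len(self.labels)} rows x {len(self.attributes)} attributes"
            )
        missing = sorted(set(self.labels) - set(self.classes))
        if missing:
            raise ValueError(f"labels not in declared class set: {missing}")

    @property
    def n_reports(self) -> int:
        return len(self.labels)

    @property
    def n_features(self) -> int:
        return len(self.attributes)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.attributes)
        df["class"] = self.labels
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_arff(self, path, relation: str | None = None) -> None:
        write_arff(self, path, relation=relation)


def _quote(name: str) -> str:
    return f"'{name}'" if re.search(r"[\s,{}%']", name) else name


def write_arff(dataset: TrainingDataset, path, relation: str | None = None) -> None:
    relation = relation or dataset.provenance.get("scheme", "autocod")
    lines = [f"@RELATION {_quote(str(relation))}", ""]
    for attr in dataset.attributes:
        lines.append(f"@ATTRIBUTE {_quote(attr)} NUMERIC")
    class_decl = ",".join(dataset.classes)
    lines.append(f"@ATTRIBUTE class {{{class_decl}}}")
    lines.append("")
    lines.append("@DATA")
    for row, label in zip(dataset.X, dataset.labels):
        vals = ",".join(_fmt(v) for v in row)
        lines.append(f"{vals},{label}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _fmt(v: float) -> str:
    if float(v).is_integer():
        return str(int(v))
    return repr(float(v))


def read_arff(path) -> TrainingDataset:
    """Read the numeric-attributes + nominal-class subset of ARFF."""
    attributes: list[str] = []
    classes: tuple[str, ...] | None = None
    rows: list[list[float]] = []
    labels: list[str] = []
    in_data = False
    relation = "autocod"
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        upper = line.upper()
        if in_data:
            parts = [p.strip().strip("'") for p in line.split(",")]
            *vals, label = parts
            if len(vals) != len(attributes):
                raise ValueError(f"{path}: data row with {len(vals)} values, expected {len(attributes)}")
            rows.append([float(v) for v in vals])
            labels.append(label)
        elif upper.startswith("@RELATION"):
            relation = line.split(None, 1)[1].strip().strip("'")
        elif upper.startswith("@ATTRIBUTE"):
            _, name, spec = line.split(None, 2)
            name = name.strip("'")
            spec = spec.strip()
            if spec.startswith("{"):
                classes = tuple(v.strip().strip("'") for v in spec.strip("{}").split(","))
            elif spec.upper() in ("NUMERIC", "REAL", "INTEGER"):
                attributes.append(name)
            else:
                raise ValueError(f"{path}: unsupported attribute type {spec!r}")
        elif upper.startswith("@DATA"):
            in_data = True
    if classes is None:
        raise ValueError(f"{path}: no nominal class attribute found")
    X = np.asarray(rows, dtype=float) if rows else np.zeros((0, len(attributes)))
    return TrainingDataset(
        attributes=attributes,
        X=X,
        labels=labels,
        classes=classes,
        provenance={"scheme": relation},
    )
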