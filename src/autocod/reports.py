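"""Autopsy report containers and corpus I/O.

A report is a labelled bundle of free-text sections.  The demographics map
is carried for bookkeeping only and is guaranteed never to reach any
feature representation downstream.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "SECTION_ORDER",
    "AutopsyReport",
    "load_corpus_jsonl",
    "save_corpus_jsonl",
    "load_corpus_dir",
]

#: Fixed concatenation order for report sections.
SECTION_ORDER: tuple[str, ...] = (
    "external_exam",
    "injury",
    "internal_exam",
    "histopathology",
    "history",
)


@dataclass(frozen=True)
class AutopsyReport:
    """One labelled autopsy report with named free-text sections."""

    report_id: str
    sections: dict[str, str]
    label: str
    demographics: dict | None = None

    def __post_init__(self):
        if not any(v.strip() for v in self.sections.values()):
            raise ValueError(f"report {self.report_id!r}: all sections empty")

    def full_text(self) -> str:
        """Sections concatenated in the fixed order; unknown names follow, sorted."""
        ordered = [self.sections.get(name, "") for name in SECTION_ORDER]
        extras = [self.sections[k] for k in sorted(self.sections) if k not in SECTION_ORDER]
        return " ".join(part for part in ordered + extras if part)


def validate_labels(reports: Sequence[AutopsyReport], class_set: Iterable[str]) -> None:
    allowed = set(class_set)
    bad = sorted({r.label for r in reports} - allowed)
    if bad:
        raise ValueError(f"labels outside the configured class set: {bad}")


def save_corpus_jsonl(reports: Iterable[AutopsyReport], path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for r in reports:
            rec = {
                "report_id": r.report_id,
                "sections": r.sections,
                "label": r.label,
                "demographics": r.demographics or {},
            }
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def load_corpus_jsonl(path) -> list[AutopsyReport]:
    """One JSON object per line: report_id, sections, label, demographics."""
    reports = []
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: malformed JSON line") from exc
            for key in ("report_id", "sections", "label"):
                if key not in rec:
                    raise ValueError(f"{path}:{lineno}: missing field {key!r}")
            reports.append(
                AutopsyReport(
                    report_id=str(rec["report_id"]),
                    sections={k: str(v) for k, v in rec["sections"].items()},
                    label=str(rec["label"]),
                    demographics=rec.get("demographics") or None,
                )
            )
    return reports


def load_corpus_dir(directory, labels_csv) -> list[AutopsyReport]:
    """Load plain-text reports (one .txt per report) with a sidecar label table.

    The label table is CSV with header ``report_id,label``.  Each text file is
    read as a single ``history`` section unless it contains ``== name ==``
    section markers.
    """
    directory = Path(directory)
    labels: dict[str, str] = {}
    with Path(labels_csv).open(encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            labels[row["report_id"]] = row["label"]
    reports = []
    for txt in sorted(directory.glob("*.txt")):
        rid = txt.stem
        if rid not in labels:
            raise ValueError(f"no label for report file {txt.name}")
        text = txt.read_text(encoding="utf-8")
        sections = _parse_sections(text)
        reports.append(AutopsyReport(report_id=rid, sections=sections, label=labels[rid]))
    return reports


def _parse_sections(text: str) -> dict[str, str]:
    sections: dict[str, str] = {}
    current = "history"
    buf: list[str] = []
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith("==") and stripped.endswith("==") and len(stripped) > 4:
            if buf:
                sections[current] = sections.get(current, "") + "\n".join(buf)
                buf = []
            current = stripped.strip("= ").lower().replace(" ", "_")
        else:
            buf.append(line)
    if buf:
        sections[current] = sections.get(current, "") + "\n".join(buf)
    return {k: v for k, v in sections.items() if v.strip()} or {"history": text}
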