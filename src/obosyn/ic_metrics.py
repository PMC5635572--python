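"""Information content of ontology terms from curated disease annotations.

IC(t) = -log10 p(t), where p(t) is the probability that an annotation
record in the curated disease-phenotype table names term t:

    p(t) = (number of records naming t) / (total number of records)

Terms never used in the annotations have no probability estimate and are
classified as *undefined*.  Terms are binned by IC into (0,1), [1,2),
[2,3) and [3,4); because the rarest term in a table of N records has
IC = log10(N), the top bin is open-ended in practice (see docs/methods.md)
but keeps the conventional label.
"""

from __future__ import annotations

import csv
import logging
import math
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationRecord",
    "ICEntry",
    "ICTable",
    "IC_BINS",
    "UNDEFINED_BIN",
    "read_annotations",
    "information_content",
    "ic_bin",
    "bin_ic",
    "write_ic_table",
]

IC_BINS = ["(0,1)", "[1,2)", "[2,3)", "[3,4)"]
UNDEFINED_BIN = "undefined"

_TERM_ID_RE = re.compile(r"^[A-Za-z]+:\S+$")


@dataclass(frozen=True)
class AnnotationRecord:
    disease_id: str
    term_id: str


@dataclass(frozen=True)
class ICEntry:
    count: int
    p: float | None  # None when the term is unannotated
    ic: float | None

    @property
    def defined(self) -> bool:
        return self.ic is not None


@dataclass
class ICTable:
    entries: dict[str, ICEntry]
    total_records: int

    def ic(self, term_id: str) -> float | None:
        e = self.entries.get(term_id)
        return None if e is None else e.ic

    def bin_of(self, term_id: str) -> str:
        return ic_bin(self.ic(term_id))


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Read disease-to-term annotations.

    Accepts either a simple two-column (disease_id, term_id) TSV or the
    HPO phenotype-annotation dialect, where column 1 is the database,
    column 2 the database object id and column 5 the ontology term id.
    Comment lines starting with '#' are skipped.
    """
    out: list[AnnotationRecord] = []
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if len(row) >= 5 and _TERM_ID_RE.match(row[4].strip()):
                out.append(
                    AnnotationRecord(f"{row[0].strip()}:{row[1].strip()}", row[4].strip())
                )
            elif len(row) >= 2 and row[1].strip():
                out.append(AnnotationRecord(row[0].strip(), row[1].strip()))
    return out


def information_content(
    annotations: list[AnnotationRecord], terms: Iterable[str]
) -> ICTable:
    """Per-term probability and IC over a term universe.

    Terms of the universe absent from the annotations get an undefined
    entry; annotation records naming terms outside the universe still
    count toward the denominator and are logged.
    """
    if not annotations:
        raise ValueError("annotation table is empty")
    universe = set(terms)
    counts: Counter[str] = Counter(a.term_id for a in annotations)
    unknown = set(counts) - universe
    if unknown:
        logger.warning(
            "%d annotated term ids are outside the ontology universe "
            "(e.g. %s)",
            len(unknown),
            sorted(unknown)[:3],
        )
    total = len(annotations)
    entries: dict[str, ICEntry] = {}
    for t in universe:
        n = counts.get(t, 0)
        if n == 0:
            entries[t] = ICEntry(count=0, p=None, ic=None)
        else:
            p = n / total
            entries[t] = ICEntry(count=n, p=p, ic=-math.log10(p) + 0.0)
    return ICTable(entries=entries, total_records=total)


def ic_bin(ic: float | None) -> str:
    """Bin label for an IC value; None maps to 'undefined'.

    Boundaries are half-open as printed: 0.999... falls in (0,1) and 1.0
    in [1,2).  An IC of exactly 0 (p = 1) is placed in (0,1) and logged —
    real annotation data never concentrates on a single term.
    """
    if ic is None:
        return UNDEFINED_BIN
    if ic < 0:
        raise ValueError(f"negative information content {ic}")
    if ic == 0.0:
        logger.warning("IC exactly 0 (p=1) binned into (0,1)")
    if ic < 1:
        return IC_BINS[0]
    if ic < 2:
        return IC_BINS[1]
    if ic < 3:
        return IC_BINS[2]
    return IC_BINS[3]


def bin_ic(table: ICTable) -> dict[str, tuple[int, float]]:
    """Counts and percentages per IC bin over the table's term universe.

    Percentages are over the universe size and sum to 100 up to rounding.
    """
    counts = Counter(ic_bin(e.ic) for e in table.entries.values())
    n = len(table.entries)
    out: dict[str, tuple[int, float]] = {}
    for label in IC_BINS + [UNDEFINED_BIN]:
        c = counts.get(label, 0)
        out[label] = (c, 100.0 * c / n if n else 0.0)
    return out


def write_ic_table(table: ICTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["term_id", "count", "p", "ic", "bin"])
        for tid in sorted(table.entries):
            e = table.entries[tid]
            w.writerow(
                [
                    tid,
                    e.count,
                    f"{e.p:.6g}" if e.p is not None else "",
                    f"{e.ic:.4f}" if e.ic is not None else "",
                    ic_bin(e.ic),
                ]
            )
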