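"""Extrinsic evaluation: concept-annotation scoring and retrieval gains.

Two complementary views of what enrichment buys:

* **Concept annotation** — micro-averaged precision/recall/F of a
  recognizer's (document, term) output against a gold standard of expert
  concept annotations; a match is exact (doc_id, term_id) equality.
* **Document retrieval** — per-term counts of documents in which the term
  was recognized, before and after enrichment, stratified by the term's
  information content and by its annotation volume.  The increase rate is
  the percent change relative to the baseline run.

The external concept recognizer is *not* reimplemented; any annotator's
(doc_id, term_id) output can be scored.  A minimal exact-phrase
dictionary matcher (longest match wins, more detailed annotations over
more general ones) is provided so end-to-end runs work on fixtures.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .corpus_filter import CorpusDocument, doc_token_streams
from .ic_metrics import IC_BINS, UNDEFINED_BIN, ICTable
from .obo_io import OntologyModel
from .textnorm import DegeneratePhraseError, normalize_phrase

__all__ = [
    "GoldAnnotation",
    "PRFScores",
    "BandRow",
    "RetrievalReport",
    "VOLUME_BANDS",
    "read_annotation_pairs",
    "write_annotation_pairs",
    "prf_scores",
    "increase_rate",
    "round_half_up",
    "retrieval_increase",
    "dictionary_annotate",
]


@dataclass(frozen=True)
class GoldAnnotation:
    doc_id: str
    term_id: str


def read_annotation_pairs(path: str | Path) -> set[GoldAnnotation]:
    out: set[GoldAnnotation] = set()
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if row[0].strip().lower() == "doc_id":
                continue
            if len(row) >= 2:
                out.add(GoldAnnotation(row[0].strip(), row[1].strip()))
    return out


def write_annotation_pairs(
    pairs: Iterable[GoldAnnotation], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["doc_id", "term_id"])
        for p in sorted(pairs, key=lambda a: (a.doc_id, a.term_id)):
            w.writerow([p.doc_id, p.term_id])


@dataclass(frozen=True)
class PRFScores:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_measure: float


def prf_scores(
    system: Iterable[GoldAnnotation], gold: Iterable[GoldAnnotation]
) -> PRFScores:
    """Micro-averaged precision/recall/F on exact (doc, term) matches.

    An empty system output scores P = R = F = 0 by convention; an empty
    gold standard is an error.
    """
    sys_set = set(system)
    gold_set = set(gold)
    if not gold_set:
        raise ValueError("gold standard is empty")
    tp = len(sys_set & gold_set)
    fp = len(sys_set - gold_set)
    fn = len(gold_set - sys_set)
    p = tp / (tp + fp) if (tp + fp) else 0.0
    r = tp / (tp + fn)
    f = 2 * p * r / (p + r) if (p + r) else 0.0
    return PRFScores(tp=tp, fp=fp, fn=fn, precision=p, recall=r, f_measure=f)


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero (table convention)."""
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def increase_rate(
    baseline: int, enriched: int, denominator: str = "baseline"
) -> float:
    """Percent change in annotated documents.

    The default denominator is the baseline count (134,367 -> 142,041
    gives 5.7, printed as 6); ``denominator="enriched"`` gives the
    alternative convention.  Zero baseline with a nonzero enriched count
    reports 100.
    """
    if denominator not in ("baseline", "enriched"):
        raise ValueError("denominator must be 'baseline' or 'enriched'")
    denom = baseline if denominator == "baseline" else enriched
    if denom == 0:
        return 0.0 if enriched == baseline else 100.0
    return 100.0 * (enriched - baseline) / denom


# annotation-volume bands: documents annotated per term, enriched run
VOLUME_BANDS: list[tuple[str, int, int | None]] = [
    (">1000", 1001, None),
    ("[100-1000)", 100, 1000),
    ("(0-100)", 0, 99),
]


@dataclass
class BandRow:
    ic_bin: str
    band: str
    n_terms: int
    baseline_count: int
    enriched_count: int
    rate: float


@dataclass
class RetrievalReport:
    rows: list[BandRow] = field(default_factory=list)
    bin_totals: list[BandRow] = field(default_factory=list)
    band_totals: list[BandRow] = field(default_factory=list)
    total: BandRow | None = None

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(
                ["ic", "abstracts_per_term", "n_terms", "baseline", "enriched", "increase_rate"]
            )
            for row in self.rows + self.bin_totals + self.band_totals + (
                [self.total] if self.total else []
            ):
                w.writerow(
                    [
                        row.ic_bin,
                        row.band,
                        row.n_terms,
                        row.baseline_count,
                        row.enriched_count,
                        round_half_up(row.rate),
                    ]
                )


def _band_of(n_docs: int) -> str:
    for label, lo, hi in VOLUME_BANDS:
        if n_docs >= lo and (hi is None or n_docs <= hi):
            return label
    return VOLUME_BANDS[-1][0]


def retrieval_increase(
    baseline_docs: Mapping[str, set[str]],
    enriched_docs: Mapping[str, set[str]],
    ic: ICTable,
    denominator: str = "baseline",
) -> RetrievalReport:
    """Stratified document-retrieval comparison of two annotator runs.

    Both runs must cover the same term universe.  Terms are bucketed by
    IC bin and by annotation volume (documents per term in the enriched
    run); each cell counts the union of documents annotated with at least
    one of its terms.
    """
    if set(baseline_docs) != set(enriched_docs):
        raise ValueError("baseline and enriched runs cover different term sets")
    terms = sorted(baseline_docs)
    cell: dict[tuple[str, str], list[str]] = {}
    for t in terms:
        key = (ic.bin_of(t), _band_of(len(enriched_docs[t])))
        cell.setdefault(key, []).append(t)

    def make_row(ic_bin: str, band: str, members: list[str]) -> BandRow:
        base = set().union(*(baseline_docs[t] for t in members)) if members else set()
        enr = set().union(*(enriched_docs[t] for t in members)) if members else set()
        return BandRow(
            ic_bin=ic_bin,
            band=band,
            n_terms=len(members),
            baseline_count=len(base),
            enriched_count=len(enr),
            rate=increase_rate(len(base), len(enr), denominator),
        )

    report = RetrievalReport()
    bins = IC_BINS + [UNDEFINED_BIN]
    for b in bins:
        for band, _, _ in VOLUME_BANDS:
            report.rows.append(make_row(b, band, cell.get((b, band), [])))
        members = [t for t in terms if ic.bin_of(t) == b]
        report.bin_totals.append(make_row(b, "Total", members))
    for band, lo, hi in VOLUME_BANDS:
        members = [t for t in terms if _band_of(len(enriched_docs[t])) == band]
        report.band_totals.append(make_row("Total", band, members))
    report.total = make_row("Total", "Total", terms)
    return report


def dictionary_annotate(
    model: OntologyModel, docs: Sequence[CorpusDocument]
) -> set[GoldAnnotation]:
    """Minimal exact-phrase dictionary matcher for fixtures.

    Scans each document's normalized token stream left to right; at each
    position the longest matching dictionary phrase wins and the scan
    resumes after it (more detailed annotations over more general ones).
    """
    phrase_to_terms: dict[tuple[str, ...], set[str]] = {}
    max_len = 0
    for t in model.non_obsolete():
        for e in t.synonym_entries(include_name=True):
            try:
                tokens = normalize_phrase(e.text).tokens
            except DegeneratePhraseError:
                continue
            phrase_to_terms.setdefault(tokens, set()).add(t.id)
            max_len = max(max_len, len(tokens))

    out: set[GoldAnnotation] = set()
    for doc in docs:
        for stream in doc_token_streams(doc):
            i = 0
            n = len(stream)
            while i < n:
                matched = 0
                for k in range(min(max_len, n - i), 0, -1):
                    terms_here = phrase_to_terms.get(tuple(stream[i : i + k]))
                    if terms_here:
                        for tid in terms_here:
                            out.add(GoldAnnotation(doc.doc_id, tid))
                        matched = k
                        break
                i += matched or 1
    return out
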