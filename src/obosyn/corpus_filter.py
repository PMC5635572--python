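"""Exact-phrase corpus validation of candidate synonyms.

A generated synonym is kept only if its exact phrase occurs in at least
one document of an evidence corpus (title or abstract) — the assumption
being that a term never used in the literature is not a real term.
Occurrences inside longer noun phrases count ("anterior spinal fusion"
matches inside "anterior spinal fusion surgery"), mirroring how a
phrase-indexed search engine behaves.

Document text is normalized like ontology synonyms (lowercase, hyphens
split, whitespace collapsed) except that bracketed content is *kept*:
brackets in running prose are meaningful, unlike the acronym glosses in
ontology labels.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from lxml import etree

from .synonym_generator import CandidateSynonym
from .textnorm import NormalizedPhrase, normalize_phrase

__all__ = [
    "CorpusDocument",
    "FilterOutcome",
    "EmptyCorpusError",
    "doc_token_streams",
    "phrase_occurs",
    "filter_candidates",
    "read_corpus_tsv",
    "write_corpus_tsv",
    "read_medline_xml",
]

_INNER_HYPHEN = re.compile(r"(?<=\w)-(?=\w)")
_WS = re.compile(r"\s+")


class EmptyCorpusError(ValueError):
    """Filtering against an empty corpus would silently discard everything."""


@dataclass(frozen=True)
class CorpusDocument:
    doc_id: str
    title: str
    abstract: str


@dataclass(frozen=True)
class FilterOutcome:
    candidate: CandidateSynonym
    hit_count: int

    @property
    def retained(self) -> bool:
        return self.hit_count >= 1


def _tokenize_prose(text: str) -> tuple[str, ...]:
    t = _INNER_HYPHEN.sub(" ", text.lower())
    t = _WS.sub(" ", t).strip()
    return tuple(t.split(" ")) if t else ()


def doc_token_streams(doc: CorpusDocument) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Normalized token streams of (title, abstract); searched separately
    so a phrase never matches across the field boundary."""
    return _tokenize_prose(doc.title), _tokenize_prose(doc.abstract)


def _occurs_in(tokens: Sequence[str], phrase: tuple[str, ...]) -> bool:
    k = len(phrase)
    if k == 0 or k > len(tokens):
        return False
    return any(tuple(tokens[i : i + k]) == phrase for i in range(len(tokens) - k + 1))


def phrase_occurs(doc: CorpusDocument, phrase: NormalizedPhrase) -> bool:
    """True iff the phrase's token sequence occurs contiguously in the
    title or the abstract."""
    title, abstract = doc_token_streams(doc)
    return _occurs_in(title, phrase.tokens) or _occurs_in(abstract, phrase.tokens)


def count_hits(
    phrase: NormalizedPhrase,
    streams: Iterable[tuple[tuple[str, ...], tuple[str, ...]]],
) -> int:
    """Number of documents (not occurrences) containing the phrase."""
    return sum(
        1
        for title, abstract in streams
        if _occurs_in(title, phrase.tokens) or _occurs_in(abstract, phrase.tokens)
    )


def filter_candidates(
    candidates: list[CandidateSynonym],
    corpus: Sequence[CorpusDocument],
) -> list[FilterOutcome]:
    """One outcome per candidate, order preserved; retained iff the exact
    phrase occurs in at least one document."""
    if not corpus:
        raise EmptyCorpusError("cannot filter candidates against an empty corpus")
    streams = [doc_token_streams(d) for d in corpus]
    out: list[FilterOutcome] = []
    for cand in candidates:
        phrase = normalize_phrase(cand.text)
        hits = count_hits(phrase, streams)
        out.append(FilterOutcome(candidate=cand, hit_count=hits))
    return out


def read_corpus_tsv(path: str | Path) -> list[CorpusDocument]:
    """Read a (doc_id, title, abstract) TSV, with or without a header row."""
    docs: list[CorpusDocument] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for i, row in enumerate(reader):
            if not row or not any(f.strip() for f in row):
                continue
            if i == 0 and [c.strip().lower() for c in row[:3]] == [
                "doc_id",
                "title",
                "abstract",
            ]:
                continue
            if len(row) < 3:
                row = row + [""] * (3 - len(row))
            docs.append(CorpusDocument(row[0], row[1], row[2]))
    return docs


def write_corpus_tsv(docs: Iterable[CorpusDocument], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["doc_id", "title", "abstract"])
        for d in docs:
            w.writerow([d.doc_id, d.title, d.abstract])


def read_medline_xml(path: str | Path) -> list[CorpusDocument]:
    """Read PubMed/MEDLINE XML: PMID, ArticleTitle and AbstractText
    (AbstractText sections concatenated in document order)."""
    tree = etree.parse(str(path))
    docs: list[CorpusDocument] = []
    for art in tree.iter("PubmedArticle", "MedlineCitation"):
        if art.tag == "PubmedArticle":
            cit = art.find("MedlineCitation")
            if cit is None:
                continue
        else:
            if art.getparent() is not None and art.getparent().tag == "PubmedArticle":
                continue  # already handled via the wrapper
            cit = art
        pmid = cit.findtext("PMID", default="").strip()
        title = cit.findtext("Article/ArticleTitle", default="") or ""
        parts = [
            "".join(el.itertext())
            for el in cit.findall("Article/Abstract/AbstractText")
        ]
        if pmid:
            docs.append(CorpusDocument(pmid, title, " ".join(p for p in parts if p)))
    return docs
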