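"""Reading and writing OBO 1.2 flat files and candidate-synonym reports.

Only the tags the enrichment method needs are interpreted: ``id``, ``name``,
``synonym``, ``is_a`` and ``is_obsolete``.  All other tags (``def``,
``xref``, ``comment``, ...) are silently ignored, and non-``[Term]`` stanzas
(``[Typedef]``) are skipped.  The parser is strict about structure: it
reports malformed lines with their line number, rejects duplicate ids,
dangling ``is_a`` references, and cycles among non-obsolete terms.

The preferred name of a term is treated as a synonym of scope EXACT by all
downstream computation; synonym counts throughout the package include term
names for that reason.
"""

from __future__ import annotations

import csv
import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import networkx as nx

from .textnorm import DegeneratePhraseError, normalize_phrase

__all__ = [
    "SynonymScope",
    "SynonymEntry",
    "Term",
    "OntologyModel",
    "OboParseError",
    "OntologyValidationError",
    "parse_obo",
    "parse_obo_text",
    "write_obo",
    "write_enriched_obo",
    "write_candidates",
    "read_candidates",
]


class OboParseError(ValueError):
    """Malformed OBO input; the message names the offending line."""


class OntologyValidationError(ValueError):
    """Structurally invalid ontology (duplicate ids, dangling is_a, cycles)."""


class SynonymScope(enum.Enum):
    """OBO synonym relatedness category.

    UNSPECIFIED marks synonym lines that carry no scope keyword — the
    "synonyms with no relatedness" case.
    """

    EXACT = "EXACT"
    BROAD = "BROAD"
    NARROW = "NARROW"
    RELATED = "RELATED"
    UNSPECIFIED = "UNSPECIFIED"


@dataclass(frozen=True)
class SynonymEntry:
    text: str
    scope: SynonymScope = SynonymScope.UNSPECIFIED

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValueError("synonym text is empty")


@dataclass(frozen=True)
class Term:
    id: str
    name: str
    synonyms: tuple[SynonymEntry, ...] = ()
    parents: tuple[str, ...] = ()
    obsolete: bool = False

    def synonym_entries(self, include_name: bool = True) -> list[SynonymEntry]:
        """All synonym entries; the name leads as an EXACT synonym."""
        out: list[SynonymEntry] = []
        if include_name:
            out.append(SynonymEntry(self.name, SynonymScope.EXACT))
        out.extend(self.synonyms)
        return out


@dataclass
class OntologyModel:
    terms: dict[str, Term] = field(default_factory=dict)
    format_version: str = "1.2"

    def __iter__(self) -> Iterator[Term]:
        return iter(self.terms.values())

    def non_obsolete(self) -> list[Term]:
        return [t for t in self.terms.values() if not t.obsolete]

    @property
    def roots(self) -> list[str]:
        """Non-obsolete terms with no non-obsolete parent, sorted by id."""
        alive = {t.id for t in self.non_obsolete()}
        return sorted(
            t.id
            for t in self.non_obsolete()
            if not any(p in alive for p in t.parents)
        )

    @property
    def categories(self) -> list[str]:
        """Top-level category ids: the children of a unique root, or the
        roots themselves when the ontology is a forest."""
        roots = self.roots
        if len(roots) == 1:
            root = roots[0]
            kids = sorted(
                t.id for t in self.non_obsolete() if root in t.parents
            )
            return kids or roots
        return roots

    def synonym_strings(self, normalized: bool = True) -> set[str]:
        """Global set of synonym strings (term names included) over
        non-obsolete terms; normalized and case-insensitive by default."""
        out: set[str] = set()
        for t in self.non_obsolete():
            for e in t.synonym_entries(include_name=True):
                if normalized:
                    try:
                        out.add(normalize_phrase(e.text).normalized)
                    except DegeneratePhraseError:
                        continue
                else:
                    out.add(e.text)
        return out

    def validate(self) -> None:
        """Check referential integrity and acyclicity of is_a."""
        dangling = [
            (t.id, p)
            for t in self.terms.values()
            for p in t.parents
            if p not in self.terms
        ]
        if dangling:
            refs = ", ".join(f"{t} -> {p}" for t, p in dangling[:20])
            raise OntologyValidationError(
                f"dangling is_a references: {refs}"
            )
        g = nx.DiGraph()
        g.add_nodes_from(t.id for t in self.non_obsolete())
        alive = set(g.nodes)
        for t in self.non_obsolete():
            for p in t.parents:
                if p in alive:
                    g.add_edge(t.id, p)  # child -> parent
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            path = " -> ".join(a for a, _ in cycle) + f" -> {cycle[0][0]}"
            raise OntologyValidationError(f"is_a cycle: {path}")


_SYNONYM_RE = re.compile(r'^"((?:[^"\\]|\\.)*)"\s*(.*)$')
_SCOPE_WORDS = {s.value for s in SynonymScope if s is not SynonymScope.UNSPECIFIED}


def _strip_comment(value: str) -> str:
    """Drop an unquoted trailing ``!`` comment."""
    in_quote = False
    i = 0
    while i < len(value):
        c = value[i]
        if c == "\\" and in_quote:
            i += 2
            continue
        if c == '"':
            in_quote = not in_quote
        elif c == "!" and not in_quote:
            return value[:i].rstrip()
        i += 1
    return value.rstrip()


def _unescape(s: str) -> str:
    return re.sub(r"\\(.)", r"\1", s)


def _escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


def parse_obo_text(text: str, source: str = "<string>") -> OntologyModel:
    """Parse OBO 1.2 flat-file content into an :class:`OntologyModel`."""
    model = OntologyModel()
    in_term = False
    in_other_stanza = False
    cur: dict[str, object] | None = None

    def flush(lineno: int) -> None:
        nonlocal cur
        if cur is None:
            return
        if "id" not in cur:
            raise OboParseError(
                f"{source}: [Term] stanza ending at line {lineno} has no id"
            )
        tid = str(cur["id"])
        if tid in model.terms:
            raise OboParseError(
                f"{source}: duplicate term id {tid} (line {lineno})"
            )
        name = str(cur.get("name", ""))
        if not name:
            raise OboParseError(
                f"{source}: term {tid} has no name (line {lineno})"
            )
        model.terms[tid] = Term(
            id=tid,
            name=name,
            synonyms=tuple(cur.get("synonyms", [])),  # type: ignore[arg-type]
            parents=tuple(cur.get("parents", [])),  # type: ignore[arg-type]
            obsolete=bool(cur.get("obsolete", False)),
        )
        cur = None

    lines = text.splitlines()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("["):
            flush(lineno)
            if line == "[Term]":
                in_term, in_other_stanza = True, False
                cur = {"synonyms": [], "parents": []}
            else:
                in_term, in_other_stanza = False, True
            continue
        if not in_term:
            if in_other_stanza:
                continue
            # header line; remember format-version, ignore the rest
            if line.startswith("format-version:"):
                model.format_version = line.split(":", 1)[1].strip()
            continue
        if ":" not in line:
            raise OboParseError(
                f"{source}: malformed tag line {lineno}: {raw!r}"
            )
        tag, value = line.split(":", 1)
        tag = tag.strip()
        value = _strip_comment(value.strip())
        assert cur is not None
        if tag == "id":
            cur["id"] = value
        elif tag == "name":
            cur["name"] = value
        elif tag == "is_a":
            parent = value.split()[0] if value else ""
            if not parent:
                raise OboParseError(
                    f"{source}: empty is_a value at line {lineno}"
                )
            cur["parents"].append(parent)  # type: ignore[union-attr]
        elif tag == "is_obsolete":
            cur["obsolete"] = value.lower().startswith("true")
        elif tag == "synonym":
            m = _SYNONYM_RE.match(value)
            if not m:
                raise OboParseError(
                    f"{source}: malformed synonym at line {lineno}: {raw!r}"
                )
            syn_text = _unescape(m.group(1))
            rest = m.group(2).split()
            scope = SynonymScope.UNSPECIFIED
            if rest and rest[0] in _SCOPE_WORDS:
                scope = SynonymScope(rest[0])
            if not syn_text.strip():
                raise OboParseError(
                    f"{source}: empty synonym text at line {lineno}"
                )
            cur["synonyms"].append(  # type: ignore[union-attr]
                SynonymEntry(syn_text, scope)
            )
        # any other tag is ignored by design
    flush(len(lines) + 1)
    model.validate()
    return model


def parse_obo(path: str | Path) -> OntologyModel:
    """Read an OBO flat file from disk."""
    p = Path(path)
    return parse_obo_text(p.read_text(encoding="utf-8"), source=str(p))


def _synonym_line(e: SynonymEntry) -> str:
    if e.scope is SynonymScope.UNSPECIFIED:
        return f'synonym: "{_escape(e.text)}" []'
    return f'synonym: "{_escape(e.text)}" {e.scope.value} []'


def _write_stanzas(model: OntologyModel, fh: IO[str]) -> None:
    fh.write(f"format-version: {model.format_version}\n")
    for tid in sorted(model.terms):
        t = model.terms[tid]
        fh.write("\n[Term]\n")
        fh.write(f"id: {t.id}\n")
        fh.write(f"name: {t.name}\n")
        for e in t.synonyms:
            fh.write(_synonym_line(e) + "\n")
        for p in t.parents:
            fh.write(f"is_a: {p}\n")
        if t.obsolete:
            fh.write("is_obsolete: true\n")


def write_obo(model: OntologyModel, path: str | Path) -> None:
    """Serialize a model to OBO; ``parse_obo`` of the output round-trips
    ids, names, parents, synonym texts and scopes exactly."""
    with open(path, "w", encoding="utf-8") as fh:
        _write_stanzas(model, fh)


def write_enriched_obo(
    model: OntologyModel,
    accepted: Iterable["CandidateSynonym"],  # noqa: F821
    path: str | Path,
) -> OntologyModel:
    """Append accepted candidate synonyms to their terms and write OBO.

    Raises on a candidate for an unknown term and on a candidate that
    duplicates an existing synonym of the term (case-insensitive on
    normalized forms).  Returns the enriched model.
    """
    terms = dict(model.terms)
    for cand in accepted:
        if cand.term_id not in terms:
            raise OntologyValidationError(
                f"candidate {cand.text!r} targets unknown term {cand.term_id}"
            )
        t = terms[cand.term_id]
        existing = set()
        for e in t.synonym_entries(include_name=True):
            try:
                existing.add(normalize_phrase(e.text).normalized)
            except DegeneratePhraseError:
                continue
        if normalize_phrase(cand.text).normalized in existing:
            raise OntologyValidationError(
                f"candidate {cand.text!r} duplicates an existing synonym "
                f"of {cand.term_id}"
            )
        terms[cand.term_id] = Term(
            id=t.id,
            name=t.name,
            synonyms=t.synonyms + (SynonymEntry(cand.text, cand.scope),),
            parents=t.parents,
            obsolete=t.obsolete,
        )
    enriched = OntologyModel(terms=terms, format_version=model.format_version)
    write_obo(enriched, path)
    return enriched


_CANDIDATE_COLUMNS = [
    "term_id",
    "term_name",
    "candidate_text",
    "scope",
    "ancestor_term_id",
    "substituted_synonym",
    "overlap_string",
    "corpus_validated",
]


def write_candidates(
    candidates: Iterable["CandidateSynonym"],  # noqa: F821
    path: str | Path,
) -> None:
    """Write a TSV candidate report, one row per candidate, sorted by
    (term_id, candidate_text)."""
    rows = sorted(candidates, key=lambda c: (c.term_id, c.text))
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_CANDIDATE_COLUMNS)
        for c in rows:
            w.writerow(
                [
                    c.term_id,
                    c.term_name,
                    c.text,
                    c.scope.value,
                    c.ancestor_id,
                    c.replacement_text,
                    c.overlap_text,
                    str(bool(c.corpus_validated)).lower()
                    if c.corpus_validated is not None
                    else "",
                ]
            )


def read_candidates(path: str | Path) -> list["CandidateSynonym"]:  # noqa: F821
    """Read a candidate TSV written by :func:`write_candidates`."""
    from .synonym_generator import CandidateSynonym

    out: list[CandidateSynonym] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            validated: bool | None
            raw = (row.get("corpus_validated") or "").strip()
            validated = None if raw == "" else raw == "true"
            out.append(
                CandidateSynonym(
                    term_id=row["term_id"],
                    term_name=row["term_name"],
                    text=row["candidate_text"],
                    scope=SynonymScope(row["scope"]),
                    ancestor_id=row["ancestor_term_id"],
                    replacement_text=row["substituted_synonym"],
                    overlap_text=row["overlap_string"],
                    descendant_text=row["candidate_text"],
                    depth=1,
                    corpus_validated=validated,
                )
            )
    return out
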