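"""Candidate-synonym generation by substitution, with scope inference.

For every lexical overlap, each *other* synonym of the ancestor term is
substituted for the overlapped span of the descendant synonym:

    "sensorineural hearing loss"  +  (hearing loss -> hearing defect)
        -> "sensorineural hearing defect"

The scope of a generated synonym is the weakest (most cautious) of the
three scopes involved — the descendant synonym's, the overlapped ancestor
synonym's and the replacement's — under

    EXACT > NARROW = BROAD > RELATED > UNSPECIFIED

with the incomparable pair NARROW/BROAD meeting at RELATED.  Generated
strings already present in the ontology are separated out (the A/B set
difference accounting); only novel strings are attached to terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .obo_io import OntologyModel, SynonymEntry, SynonymScope
from .overlap_finder import LexicalOverlap
from .textnorm import (
    NormalizedPhrase,
    normalize_phrase,
    occurrence_positions,
    phrase_contains,
)

__all__ = [
    "CandidateSynonym",
    "GenerationResult",
    "scope_meet",
    "infer_scope",
    "substitute",
    "generate_all",
]

_SCOPE_RANK = {
    SynonymScope.EXACT: 3,
    SynonymScope.NARROW: 2,
    SynonymScope.BROAD: 2,
    SynonymScope.RELATED: 1,
    SynonymScope.UNSPECIFIED: 0,
}


def scope_meet(a: SynonymScope, b: SynonymScope) -> SynonymScope:
    """Meet of two scopes: the one making the weaker synonymy claim.

    NARROW and BROAD are incomparable; their meet is RELATED.
    """
    if a is b:
        return a
    ra, rb = _SCOPE_RANK[a], _SCOPE_RANK[b]
    if ra == rb:  # NARROW vs BROAD
        return SynonymScope.RELATED
    return a if ra < rb else b


def infer_scope(
    descendant_scope: SynonymScope,
    ancestor_scope: SynonymScope,
    replacement_scope: SynonymScope,
) -> SynonymScope:
    """Scope of a generated synonym: the meet of all three input scopes.

    Commutative and associative; all-EXACT inputs stay EXACT, a RELATED
    replacement yields RELATED, an UNSPECIFIED input yields UNSPECIFIED.
    """
    return scope_meet(
        scope_meet(descendant_scope, ancestor_scope), replacement_scope
    )


@dataclass(frozen=True)
class CandidateSynonym:
    """A generated synonym attached to a descendant term, with provenance."""

    term_id: str
    term_name: str
    text: str
    scope: SynonymScope
    ancestor_id: str
    replacement_text: str
    overlap_text: str
    descendant_text: str
    depth: int = 1
    corpus_validated: bool | None = None

    @property
    def normalized(self) -> str:
        return normalize_phrase(self.text).normalized


class SubstitutionError(ValueError):
    """Replacement equals the overlapped string — a no-op substitution."""


def substitute(
    overlap: LexicalOverlap,
    replacement: SynonymEntry,
    term_name: str = "",
    depth: int = 1,
) -> CandidateSynonym:
    """Replace the overlapped token span of the descendant synonym with the
    replacement's tokens.

    Candidates are emitted in normalized (lowercase, hyphen-split) form
    except that the leading capital of the descendant surface is kept, so
    "Cortical cataract" + (cataract -> Lens opacities) gives
    "Cortical lens opacities".
    """
    repl = normalize_phrase(replacement.text)
    desc = normalize_phrase(overlap.descendant_synonym.text)
    if repl.normalized == overlap.ancestor_normalized:
        raise SubstitutionError(
            f"replacement {replacement.text!r} equals the overlapped string"
        )
    tokens = (
        desc.tokens[: overlap.start]
        + repl.tokens
        + desc.tokens[overlap.start + overlap.length :]
    )
    text = " ".join(tokens)
    if desc.leading_upper:
        text = text[0].upper() + text[1:]
    scope = infer_scope(
        overlap.descendant_synonym.scope
        if overlap.descendant_synonym.text != term_name
        else SynonymScope.EXACT,
        overlap.ancestor_synonym.scope,
        replacement.scope,
    )
    return CandidateSynonym(
        term_id=overlap.descendant_id,
        term_name=term_name,
        text=text,
        scope=scope,
        ancestor_id=overlap.ancestor_id,
        replacement_text=replacement.text,
        overlap_text=overlap.ancestor_synonym.text,
        descendant_text=overlap.descendant_synonym.text,
        depth=depth,
    )


@dataclass
class GenerationResult:
    """Partition of the generated candidates.

    ``candidates`` is the full multiset A (repetitions included, as in the
    substitution-count accounting); ``existing`` are members of A whose
    normalized string is already an ontology synonym (B ∩ A); ``novel`` is
    the set difference A/B, still with multiplicity.  ``novel_deduplicated``
    collapses novel candidates per (term, normalized string).
    """

    candidates: list[CandidateSynonym] = field(default_factory=list)
    existing: list[CandidateSynonym] = field(default_factory=list)
    novel: list[CandidateSynonym] = field(default_factory=list)

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)

    @property
    def n_unique_strings(self) -> int:
        return len({c.normalized for c in self.candidates})

    def novel_deduplicated(self) -> list[CandidateSynonym]:
        seen: set[tuple[str, str]] = set()
        out: list[CandidateSynonym] = []
        for c in sorted(self.novel, key=lambda c: (c.term_id, c.text, c.depth)):
            key = (c.term_id, c.normalized)
            if key not in seen:
                seen.add(key)
                out.append(c)
        return out

    def attachable(self, model: OntologyModel) -> list[CandidateSynonym]:
        """Novel candidates safe to attach: deduplicated per term, not
        clashing with any synonym of their own term, and not properly
        containing one (the redundancy rule applied to new synonyms)."""
        out: list[CandidateSynonym] = []
        for c in self.novel_deduplicated():
            term = model.terms[c.term_id]
            cand_phrase = normalize_phrase(c.text)
            own: list[NormalizedPhrase] = []
            for e in term.synonym_entries(include_name=True):
                try:
                    own.append(normalize_phrase(e.text))
                except ValueError:
                    continue
            if any(cand_phrase.normalized == p.normalized for p in own):
                continue
            if any(phrase_contains(cand_phrase, p, proper=True) for p in own):
                continue
            out.append(c)
        return out


def _replacements_for(
    model: OntologyModel, ancestor_id: str, overlapped_normalized: str
) -> list[SynonymEntry]:
    out = []
    for e in model.terms[ancestor_id].synonym_entries(include_name=True):
        try:
            norm = normalize_phrase(e.text).normalized
        except ValueError:
            continue
        if norm != overlapped_normalized:
            out.append(e)
    return out


def generate_all(
    model: OntologyModel,
    overlaps: list[LexicalOverlap],
    max_depth: int = 1,
    known_strings: set[str] | None = None,
) -> GenerationResult:
    """Apply substitution to every overlap × eligible replacement.

    At depth > 1, candidates from the previous depth are re-scanned for
    the same overlapped ancestor strings and substituted again; the
    candidate set grows monotonically with depth.  ``known_strings`` is
    the ontology synonym set used for the A/B partition (defaults to the
    model's current global synonym set).
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    known = (
        known_strings if known_strings is not None else model.synonym_strings()
    )

    result = GenerationResult()

    def emit(c: CandidateSynonym) -> None:
        result.candidates.append(c)
        (result.existing if c.normalized in known else result.novel).append(c)

    frontier: list[CandidateSynonym] = []
    for o in overlaps:
        term_name = model.terms[o.descendant_id].name
        for repl in _replacements_for(model, o.ancestor_id, o.ancestor_normalized):
            c = substitute(o, repl, term_name=term_name, depth=1)
            emit(c)
            frontier.append(c)

    # ancestor strings applicable to each descendant term, for re-scanning
    per_term: dict[str, list[tuple[str, SynonymEntry]]] = {}
    if max_depth > 1:
        seen: dict[str, set[str]] = {}
        for o in overlaps:
            key = o.ancestor_normalized
            if key not in seen.setdefault(o.descendant_id, set()):
                seen[o.descendant_id].add(key)
                per_term.setdefault(o.descendant_id, []).append(
                    (o.ancestor_id, o.ancestor_synonym)
                )

    for depth in range(2, max_depth + 1):
        produced: set[tuple[str, str]] = {
            (c.term_id, c.normalized) for c in frontier
        }
        next_frontier: list[CandidateSynonym] = []
        for c in frontier:
            cand_phrase = normalize_phrase(c.text)
            for anc_id, anc_entry in per_term.get(c.term_id, ()):
                anc_phrase = normalize_phrase(anc_entry.text)
                if len(cand_phrase.tokens) <= len(anc_phrase.tokens):
                    continue
                for start in occurrence_positions(cand_phrase, anc_phrase):
                    o = LexicalOverlap(
                        ancestor_id=anc_id,
                        descendant_id=c.term_id,
                        ancestor_synonym=anc_entry,
                        descendant_synonym=SynonymEntry(c.text, c.scope),
                        start=start,
                        length=len(anc_phrase.tokens),
                    )
                    for repl in _replacements_for(
                        model, anc_id, anc_phrase.normalized
                    ):
                        new = substitute(
                            o, repl, term_name=c.term_name, depth=depth
                        )
                        key = (new.term_id, new.normalized)
                        if key in produced:
                            continue
                        produced.add(key)
                        emit(new)
                        next_frontier.append(new)
        frontier = next_frontier
        if not frontier:
            break

    return result
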