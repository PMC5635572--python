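"""Detection of lexical overlaps between hierarchically related terms.

A lexical overlap exists when a synonym of a descendant term properly
contains a synonym of one of its ancestors as a contiguous token
sequence — e.g. "hearing loss" inside "sensorineural hearing loss".
Overlaps are the raw material for synonym substitution: the overlapped
span can be replaced by any other synonym of the ancestor.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

from .hierarchy import ClosurePair, all_closure_pairs
from .obo_io import OntologyModel, SynonymEntry
from .textnorm import (
    DegeneratePhraseError,
    NormalizedPhrase,
    normalize_phrase,
    occurrence_positions,
)

logger = logging.getLogger(__name__)

__all__ = ["LexicalOverlap", "OverlapSummary", "find_overlaps", "unique_overlap_strings"]


@dataclass(frozen=True)
class LexicalOverlap:
    """One occurrence of an ancestor synonym inside a descendant synonym.

    ``start``/``length`` give the overlapped token span in the descendant
    synonym's normalized token coordinates (0-based, half-open).  The same
    string pair at two positions yields two occurrences of one identity.
    """

    ancestor_id: str
    descendant_id: str
    ancestor_synonym: SynonymEntry
    descendant_synonym: SynonymEntry
    start: int
    length: int

    @property
    def ancestor_normalized(self) -> str:
        return normalize_phrase(self.ancestor_synonym.text).normalized

    @property
    def descendant_normalized(self) -> str:
        return normalize_phrase(self.descendant_synonym.text).normalized

    @property
    def identity(self) -> tuple[str, str]:
        """Dedup key: the ordered (ancestor string, descendant string)
        pair on normalized forms."""
        return (self.ancestor_normalized, self.descendant_normalized)


@dataclass
class OverlapSummary:
    """Unique-overlap accounting.

    ``unique_total`` deduplicates occurrences by string-pair identity;
    ``unique_term_pairs`` deduplicates by (ancestor term, descendant term)
    instead — both views are exposed.  The histogram is keyed by the token
    count of the overlapped (ancestor) string.
    """

    unique_total: int
    unique_term_pairs: int
    occurrence_total: int
    tokens_histogram: dict[int, int]


def _normalized_entries(
    model: OntologyModel,
) -> dict[str, list[tuple[SynonymEntry, NormalizedPhrase]]]:
    out: dict[str, list[tuple[SynonymEntry, NormalizedPhrase]]] = {}
    for t in model.non_obsolete():
        pairs: list[tuple[SynonymEntry, NormalizedPhrase]] = []
        seen: set[str] = set()
        for e in t.synonym_entries(include_name=True):
            try:
                p = normalize_phrase(e.text)
            except DegeneratePhraseError:
                logger.warning("term %s: skipping degenerate synonym %r", t.id, e.text)
                continue
            # a synonym textually equal to the name adds nothing
            if p.normalized in seen:
                continue
            seen.add(p.normalized)
            pairs.append((e, p))
        out[t.id] = pairs
    return out


def find_overlaps(
    model: OntologyModel, pairs: set[ClosurePair] | None = None
) -> list[LexicalOverlap]:
    """All lexical overlaps over the hierarchy's transitive closure.

    Expects redundancy removal to have been applied already.  Returns one
    record per containment occurrence, in deterministic order.
    """
    closure = pairs if pairs is not None else all_closure_pairs(model)
    entries = _normalized_entries(model)
    overlaps: list[LexicalOverlap] = []
    for cp in closure:
        for anc_entry, anc_phrase in entries.get(cp.ancestor_id, ()):
            for desc_entry, desc_phrase in entries.get(cp.descendant_id, ()):
                if len(desc_phrase.tokens) <= len(anc_phrase.tokens):
                    continue
                for start in occurrence_positions(desc_phrase, anc_phrase):
                    overlaps.append(
                        LexicalOverlap(
                            ancestor_id=cp.ancestor_id,
                            descendant_id=cp.descendant_id,
                            ancestor_synonym=anc_entry,
                            descendant_synonym=desc_entry,
                            start=start,
                            length=len(anc_phrase.tokens),
                        )
                    )
    overlaps.sort(
        key=lambda o: (
            o.ancestor_id,
            o.descendant_id,
            o.ancestor_synonym.text,
            o.descendant_synonym.text,
            o.start,
        )
    )
    return overlaps


def unique_overlap_strings(overlaps: list[LexicalOverlap]) -> OverlapSummary:
    """Deduplicate overlaps and histogram them by overlapped-string token
    count."""
    identities: set[tuple[str, str]] = set()
    term_pairs: set[tuple[str, str]] = set()
    hist: Counter[int] = Counter()
    for o in overlaps:
        term_pairs.add((o.ancestor_id, o.descendant_id))
        ident = o.identity
        if ident not in identities:
            identities.add(ident)
            hist[o.length] += 1
    return OverlapSummary(
        unique_total=len(identities),
        unique_term_pairs=len(term_pairs),
        occurrence_total=len(overlaps),
        tokens_histogram=dict(sorted(hist.items())),
    )
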