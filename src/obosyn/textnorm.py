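"""Phrase normalization, tokenization and containment semantics.

Every downstream stage (overlap detection, substitution, corpus filtering)
compares phrases through the conventions defined here:

* matching is case-insensitive,
* hyphenated words are broken into their constituent words
  ("criss-cross" -> "criss cross"),
* bracketed spans — usually acronyms or clarifications such as "(tshr)" —
  are removed before tokens are counted,
* containment is *token-sequence* containment, never raw character
  containment, so "art" is not contained in "heart disease".
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .obo_io import SynonymEntry, Term

logger = logging.getLogger(__name__)

__all__ = [
    "DegeneratePhraseError",
    "NormalizedPhrase",
    "normalize_phrase",
    "token_count",
    "phrase_contains",
    "occurrence_positions",
    "remove_redundant_synonyms",
]


class DegeneratePhraseError(ValueError):
    """Raised when a phrase is empty or normalizes to the empty string."""


# a hyphen flanked by word characters is a word separator
_INNER_HYPHEN = re.compile(r"(?<=\w)-(?=\w)")
_WS = re.compile(r"\s+")
_BRACKET_SPANS = (
    re.compile(r"\([^()]*\)"),
    re.compile(r"\[[^\[\]]*\]"),
    re.compile(r"\{[^{}]*\}"),
)
_ANY_BRACKET = re.compile(r"[()\[\]{}]")


@dataclass(frozen=True)
class NormalizedPhrase:
    """A phrase together with its normalized form and token list."""

    surface: str
    normalized: str
    tokens: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def leading_upper(self) -> bool:
        """True when the surface form starts with an uppercase letter."""
        s = self.surface.strip()
        return bool(s) and s[0].isupper()


def _strip_brackets(s: str) -> str:
    """Remove matched (), [], {} spans, innermost first; unmatched brackets
    are kept as literal characters and logged."""
    prev = None
    while prev != s:
        prev = s
        for pat in _BRACKET_SPANS:
            s = pat.sub(" ", s)
    if _ANY_BRACKET.search(s):
        logger.warning("unmatched bracket kept literally in %r", s)
    return s


def normalize_phrase(s: str) -> NormalizedPhrase:
    """Normalize a synonym string.

    Lowercases, removes bracketed spans, splits hyphenated words, and
    collapses whitespace. Raises :class:`DegeneratePhraseError` if the
    input is empty or nothing survives normalization.
    """
    if not s or not s.strip():
        raise DegeneratePhraseError("empty phrase")
    text = _strip_brackets(s)
    text = text.lower()
    text = _INNER_HYPHEN.sub(" ", text)
    text = _WS.sub(" ", text).strip()
    if not text:
        raise DegeneratePhraseError(
            f"phrase {s!r} is empty after normalization"
        )
    return NormalizedPhrase(
        surface=s, normalized=text, tokens=tuple(text.split(" "))
    )


def token_count(p: NormalizedPhrase) -> int:
    """Number of whitespace-delimited tokens, bracketed content excluded."""
    return len(p.tokens)


def occurrence_positions(
    container: NormalizedPhrase, contained: NormalizedPhrase
) -> list[int]:
    """Start indices (in container token coordinates) of every contiguous
    occurrence of ``contained``'s token sequence inside ``container``."""
    big, small = container.tokens, contained.tokens
    k = len(small)
    if k == 0 or k > len(big):
        return []
    return [i for i in range(len(big) - k + 1) if big[i : i + k] == small]


def phrase_contains(
    container: NormalizedPhrase,
    contained: NormalizedPhrase,
    proper: bool = False,
) -> bool:
    """True iff ``contained`` occurs as a contiguous token subsequence of
    ``container``; with ``proper=True`` the container must be strictly
    longer in tokens (equality does not count)."""
    if proper and len(container.tokens) <= len(contained.tokens):
        return False
    return bool(occurrence_positions(container, contained))


def remove_redundant_synonyms(term: "Term") -> tuple["Term", list["SynonymEntry"]]:
    """Drop synonyms that properly contain another synonym of the same term.

    A dictionary matcher that recognizes "congenital hearing loss" also
    recognizes "hearing loss"; the longer string is redundant for concept
    recognition.  The preferred name is never removed.  Returns the pruned
    term and the list of removed synonym entries.
    """
    entries = term.synonym_entries(include_name=True)
    phrases: list[NormalizedPhrase | None] = []
    for e in entries:
        try:
            phrases.append(normalize_phrase(e.text))
        except DegeneratePhraseError:
            logger.warning(
                "term %s: synonym %r normalizes to nothing; kept as-is",
                term.id,
                e.text,
            )
            phrases.append(None)

    removed_texts: set[str] = set()
    # index 0 is the name entry; it is protected
    for i in range(1, len(entries)):
        pi = phrases[i]
        if pi is None:
            continue
        for j, pj in enumerate(phrases):
            if i == j or pj is None:
                continue
            if phrase_contains(pi, pj, proper=True):
                removed_texts.add(entries[i].text)
                break

    kept = tuple(e for e in term.synonyms if e.text not in removed_texts)
    removed = [e for e in term.synonyms if e.text in removed_texts]
    return replace(term, synonyms=kept), removed
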