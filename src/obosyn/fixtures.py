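"""Seeded synthetic ontologies and corpora with exhaustive ground truth.

The generator emulates the genus–differentia naming convention of
phenotype ontologies: a child term's name is often its parent's name (or
one of the parent's synonyms) prefixed by a fresh modifier token, so the
child properly contains the parent as a token subsequence.  Because every
modifier and base token is globally unique, *all* lexical overlaps,
redundant synonyms and closure pairs are exactly the ones planted at
construction — the recorded ground truth is exhaustive and serves as the
oracle for the whole pipeline.

Determinism: identical (seed, parameters) produce byte-identical OBO and
corpus files.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .corpus_filter import CorpusDocument, write_corpus_tsv
from .obo_io import OntologyModel, SynonymEntry, SynonymScope, Term, write_obo
from .textnorm import normalize_phrase

__all__ = [
    "FixtureSpec",
    "PlantedOverlap",
    "OntologyFixture",
    "CorpusFixture",
    "synth_ontology",
    "synth_corpus",
]

_SCOPES = [
    SynonymScope.EXACT,
    SynonymScope.RELATED,
    SynonymScope.NARROW,
    SynonymScope.BROAD,
    SynonymScope.UNSPECIFIED,
]
_SCOPE_WEIGHTS = [0.5, 0.2, 0.1, 0.1, 0.1]


@dataclass(frozen=True)
class FixtureSpec:
    """Structure and rates of a synthetic ontology.

    Defaults mirror the study conditions of a compositional phenotype
    ontology: 1.68 synonyms per term (names included), a high
    genus-differentia rate, and a small redundant-synonym fraction
    (529/18,385 ~ 3%).
    """

    seed: int = 0
    n_roots: int = 2
    depth: int = 3
    branching: int = 2
    genus_differentia_rate: float = 0.7
    synonym_rate: float = 1.68
    redundant_rate: float = 0.03
    multi_parent_rate: float = 0.1
    obsolete_rate: float = 0.0

    def validate(self) -> None:
        if self.n_roots < 1 or self.depth < 1 or self.branching < 0:
            raise ValueError("structure parameters must be positive")
        for name in (
            "genus_differentia_rate",
            "redundant_rate",
            "multi_parent_rate",
            "obsolete_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.synonym_rate < 1.0:
            raise ValueError("synonym_rate counts the name and must be >= 1")


@dataclass(frozen=True)
class PlantedOverlap:
    ancestor_id: str
    descendant_id: str
    ancestor_text: str
    descendant_text: str


@dataclass
class OntologyFixture:
    spec: FixtureSpec
    model: OntologyModel
    obo_text: str
    edges: list[tuple[str, str]]  # (parent, child)
    planted_redundant: list[tuple[str, str]]  # (term_id, synonym text)
    planted_overlaps: list[PlantedOverlap]
    synonyms_including_names: int = 0

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.obo_text, encoding="utf-8")


@dataclass
class _SynRecord:
    text: str
    scope: SynonymScope
    # derivation: None for atomic strings, else the (term_id, text) of the
    # base string this one was built from by modifier prefixing
    base: tuple[str, str] | None
    redundant: bool = False


def _extra_synonym_count(rng: random.Random, rate: float) -> int:
    """Number of extra synonyms beyond the name; expectation rate - 1."""
    mean = rate - 1.0
    whole, frac = int(mean), mean - int(mean)
    return whole + (1 if rng.random() < frac else 0)


def synth_ontology(spec: FixtureSpec) -> OntologyFixture:
    """Build a synthetic ontology and its exhaustive ground truth."""
    spec.validate()
    rng = random.Random(spec.seed)
    counter = iter(range(10**9))

    def fresh(prefix: str) -> str:
        return f"{prefix}{next(counter)}"

    records: dict[str, list[_SynRecord]] = {}
    terms: dict[str, Term] = {}
    edges: list[tuple[str, str]] = []
    planted_redundant: list[tuple[str, str]] = []
    tid_counter = iter(range(1, 10**7))

    def new_id() -> str:
        return f"SYN:{next(tid_counter):07d}"

    def atomic_string() -> str:
        n = 1 + (rng.random() < 0.5)
        return " ".join(fresh("base") for _ in range(n))

    def pick_scope() -> SynonymScope:
        return rng.choices(_SCOPES, weights=_SCOPE_WEIGHTS, k=1)[0]

    def usable_bases(tid: str) -> list[_SynRecord]:
        return [r for r in records[tid] if not r.redundant]

    def build_term(parent_ids: list[str], level: int) -> str:
        tid = new_id()
        recs: list[_SynRecord] = []
        primary = parent_ids[0] if parent_ids else None
        # A compositional term keeps one differentia modifier and tends to
        # reuse it across its synonyms over different parent synonyms
        # ("sensorineural hearing loss" / "sensorineural hearing
        # impairment") — that is what makes many substitution products
        # coincide with strings already in the ontology.
        term_mod: str | None = None
        used: set[tuple[str, str]] = set()

        def comp_synonym() -> _SynRecord:
            nonlocal term_mod
            if term_mod is None:
                term_mod = fresh("mod")
            mod = term_mod if rng.random() < 0.75 else fresh("mod")
            bases = list(usable_bases(primary))
            rng.shuffle(bases)
            for base in bases:
                if (mod, base.text) not in used:
                    used.add((mod, base.text))
                    return _SynRecord(
                        f"{mod} {base.text}", pick_scope(), (primary, base.text)
                    )
            # all combinations taken: force a fresh modifier
            mod = fresh("mod")
            base = bases[0]
            used.add((mod, base.text))
            return _SynRecord(
                f"{mod} {base.text}", pick_scope(), (primary, base.text)
            )

        # name
        if primary is not None and rng.random() < spec.genus_differentia_rate:
            rec = comp_synonym()
            recs.append(_SynRecord(rec.text, SynonymScope.EXACT, rec.base))
        else:
            recs.append(
                _SynRecord(atomic_string().capitalize(), SynonymScope.EXACT, None)
            )
        # extra synonyms
        for _ in range(_extra_synonym_count(rng, spec.synonym_rate)):
            if primary is not None and rng.random() < spec.genus_differentia_rate:
                recs.append(comp_synonym())
            else:
                recs.append(_SynRecord(atomic_string(), pick_scope(), None))
        # planted redundant synonym: contains one of the term's own strings
        if rng.random() < spec.redundant_rate:
            base = rng.choice(recs)
            text = f"{fresh('mod')} {base.text}"
            recs.append(
                _SynRecord(text, pick_scope(), None, redundant=True)
            )
            planted_redundant.append((tid, text))
        records[tid] = recs
        obsolete = rng.random() < spec.obsolete_rate
        terms[tid] = Term(
            id=tid,
            name=recs[0].text,
            synonyms=tuple(SynonymEntry(r.text, r.scope) for r in recs[1:]),
            parents=tuple(parent_ids),
            obsolete=obsolete,
        )
        for p in parent_ids:
            edges.append((p, tid))
        return tid

    # breadth-first construction, one tree per root plus occasional extra
    # parents within the same tree (always to an earlier node: acyclic).
    # Obsolete terms are always leaves, so the pruned is-a graph keeps
    # every planted ancestor chain intact.
    for _root in range(spec.n_roots):
        root_id = build_term([], 0)
        level_nodes = [] if terms[root_id].obsolete else [root_id]
        tree_nodes = list(level_nodes)
        for level in range(1, spec.depth):
            nxt: list[str] = []
            for parent in level_nodes:
                for _ in range(spec.branching):
                    extra: list[str] = []
                    if (
                        len(tree_nodes) > 1
                        and rng.random() < spec.multi_parent_rate
                    ):
                        cand = rng.choice(tree_nodes)
                        if cand != parent:
                            extra = [cand]
                    child = build_term([parent] + extra, level)
                    if not terms[child].obsolete:
                        nxt.append(child)
            tree_nodes.extend(nxt)
            level_nodes = nxt

    model = OntologyModel(terms=terms)
    model.validate()

    # exhaustive planted overlaps: walk each synonym's derivation chain;
    # every base string in the chain belongs to a (strict) ancestor term.
    # With a unique alive root, the top-level categories are its children
    # and the root itself is outside every category sub-DAG, so overlaps
    # anchored at it are not reported.
    alive = {t.id for t in model.non_obsolete()}
    roots = model.roots
    excluded_ancestors = set(roots) if len(roots) == 1 else set()
    overlaps: list[PlantedOverlap] = []
    for tid, recs in records.items():
        if tid not in alive:
            continue
        for r in recs:
            if r.redundant:
                continue  # removed by pruning before overlap detection
            chain = r.base
            desc_text = r.text
            while chain is not None:
                anc_id, anc_text = chain
                if anc_id in alive and anc_id not in excluded_ancestors:
                    overlaps.append(
                        PlantedOverlap(anc_id, tid, anc_text, desc_text)
                    )
                base_rec = next(
                    br for br in records[anc_id] if br.text == anc_text
                )
                chain = base_rec.base

    # serialize deterministically through the standard writer
    import io

    buf = io.StringIO()
    from .obo_io import _write_stanzas  # standard serializer

    _write_stanzas(model, buf)

    n_syn = sum(
        len(t.synonym_entries(include_name=True)) for t in model.non_obsolete()
    )
    return OntologyFixture(
        spec=spec,
        model=model,
        obo_text=buf.getvalue(),
        edges=edges,
        planted_redundant=planted_redundant,
        planted_overlaps=overlaps,
        synonyms_including_names=n_syn,
    )


@dataclass
class CorpusFixture:
    docs: list[CorpusDocument]
    planted: dict[str, set[str]]  # normalized phrase -> doc ids
    tsv_text: str = ""

    def write(self, path: str | Path) -> None:
        write_corpus_tsv(self.docs, path)


def synth_corpus(
    phrases_to_plant: list[str],
    n_docs: int,
    seed: int,
    embed_rate: float = 0.3,
    copies_per_phrase: int = 1,
) -> CorpusFixture:
    """Documents of filler tokens with each phrase inserted verbatim.

    The filler vocabulary is disjoint from all phrase tokens, so a phrase
    occurs in exactly the documents it was planted in.  With probability
    ``embed_rate`` a phrase is planted inside a longer "noun phrase"
    (extra filler tokens attached on both sides) — it still matches, the
    way "anterior spinal fusion" matches inside "anterior spinal fusion
    surgery".
    """
    rng = random.Random(seed)
    phrase_tokens = {
        tok for p in phrases_to_plant for tok in normalize_phrase(p).tokens
    }

    def filler() -> str:
        while True:
            w = f"zz{rng.randrange(10_000)}"
            if w not in phrase_tokens:
                return w

    titles = [
        " ".join(filler() for _ in range(rng.randint(4, 8)))
        for _ in range(n_docs)
    ]
    abstracts = [
        [filler() for _ in range(rng.randint(20, 40))] for _ in range(n_docs)
    ]
    planted: dict[str, set[str]] = {}
    for phrase in phrases_to_plant:
        norm = normalize_phrase(phrase).normalized
        planted.setdefault(norm, set())
        for _ in range(max(1, copies_per_phrase)):
            i = rng.randrange(n_docs)
            words = abstracts[i]
            chunk = phrase
            if rng.random() < embed_rate:
                chunk = f"{filler()} {phrase} {filler()}"
            pos = rng.randint(0, len(words))
            abstracts[i] = words[:pos] + [chunk] + words[pos:]
            planted[norm].add(f"DOC:{i:05d}")

    docs = [
        CorpusDocument(f"DOC:{i:05d}", titles[i], " ".join(abstracts[i]))
        for i in range(n_docs)
    ]
    lines = ["doc_id\ttitle\tabstract"]
    lines += [f"{d.doc_id}\t{d.title}\t{d.abstract}" for d in docs]
    return CorpusFixture(docs=docs, planted=planted, tsv_text="\n".join(lines) + "\n")
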