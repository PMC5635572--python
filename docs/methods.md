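# Methods

## Model and procedure

`obosyn` enriches an OBO ontology with new synonyms in five stages, all
operating on *normalized phrases*: lowercased strings with hyphens
between word characters split into separate tokens, bracketed spans
removed, and whitespace collapsed. Containment is always contiguous
token-subsequence containment, never raw character containment — "art"
is not inside "heart disease". This is a deliberate safety choice for
substitution: character-level matches would splice replacements into
the middle of words.

1. **Redundancy pruning.** A synonym that properly contains another
   synonym of the *same* term is removed: any dictionary matcher that
   recognizes the longer string necessarily recognizes the shorter one,
   so the longer adds no recall and pollutes overlap detection. The
   preferred name is never removed (deleting labels would corrupt the
   ontology); it does, however, participate as containment evidence
   against other synonyms. The rule compares every synonym against the
   full original set, which makes it order-independent and idempotent:
   of {a, a b, a b c} only {a} survives.
2. **Transitive closure.** The is-a graph restricted to non-obsolete
   terms must be a DAG (cycles are a hard error naming one cycle).
   Closure pairs are computed per top-level category — the children of
   a unique root, or the roots themselves in a forest — and
   deduplicated; a term under several categories contributes in each.
   Pairs anchored at a unique global root are therefore out of scope,
   matching the convention that top-level categories, not the ontology
   root, delimit the taxonomies. `min_depth` is the shortest is-a path.
3. **Overlap detection.** For every closure pair and every (ancestor
   synonym, descendant synonym) combination — names included, as EXACT
   synonyms — one overlap record is emitted per occurrence position of
   the ancestor string inside the descendant string. *Unique* overlaps
   deduplicate by the ordered pair of normalized strings; the
   identity's token count is the ancestor (overlapped) string's. The
   per-term-pair count is exposed alongside, since either convention is
   defensible for a published total.
4. **Substitution and scope.** Each overlap × each other synonym of the
   ancestor yields one candidate: the overlapped span replaced by the
   replacement's tokens. Candidates are emitted in normalized form
   except that the descendant surface's leading capital is preserved —
   "Cortical cataract" + (cataract → Lens opacities) gives "Cortical
   lens opacities". (Splicing raw surface fragments instead would
   yield "Cortical Lens opacities"; the lowercase-splice convention is
   what the published example outputs show.) Scope is the meet of the
   descendant synonym's, overlapped synonym's and replacement's scopes
   under EXACT > NARROW = BROAD > RELATED > UNSPECIFIED, with
   NARROW ⊓ BROAD := RELATED for the incomparable pair. "Most
   restrictive" is read as "making the weakest synonymy claim": a
   RELATED replacement can only produce a RELATED synonym, and a
   synonym of unknown relatedness propagates UNSPECIFIED. The meet is
   commutative and associative with EXACT as identity.
5. **Corpus filtering.** A candidate is kept iff its exact phrase
   occurs in the title or abstract of at least one corpus document
   (fields searched separately; hits inside longer noun phrases count,
   the way "anterior spinal fusion" matches inside "anterior spinal
   fusion surgery" in a phrase-indexed search engine). Document prose
   is normalized like synonyms except brackets are kept: parentheses
   in running text are meaningful, unlike acronym glosses in ontology
   labels. Hit counts count documents, not occurrences, mirroring
   search-engine result counts. Filtering an empty corpus is an error
   rather than a silent discard-everything.

### Generation accounting and recursion

`generate_all` reports the candidate multiset A (repetitions included:
the same string generated via two overlaps counts twice), its
intersection with the ontology's global synonym string set B, and the
set difference A/B. B is taken *before* pruning — removed redundant
synonyms are still "strings in the ontology" — while replacements are
drawn from the pruned synonym sets. Attachment additionally
deduplicates per (term, normalized string), rejects clashes with the
candidate's own term, and applies the redundancy rule to new synonyms.

Recursion depth defaults to 1 (single substitutions). At depth d > 1,
depth-(d−1) candidates are re-scanned for the same overlapped ancestor
strings and substituted again; the candidate set grows monotonically
with depth. All published worked examples are single substitutions, so
depth stays an explicit, reported parameter rather than a hidden loop.

## Information content and evaluation

IC(t) = −log₁₀ p(t), with p(t) the fraction of annotation records in a
curated disease–phenotype table that name t (denominator = total
records, the plainest reading of "probability of appearing in the
annotations"; no ancestor propagation by default). Unannotated terms
are *undefined*. Bins are half-open — (0,1), [1,2), [2,3), [3,4),
undefined — and the top bin is open-ended in practice: the rarest term
in a table of N records has IC = log₁₀(N), which exceeds 4 for
N > 10,000, so a literal [3,4) upper bound cannot hold; the label is
kept for table compatibility. IC exactly 0 (p = 1) is binned into
(0,1) and logged; real annotation tables never concentrate on one term.

Concept-annotation scoring is micro-averaged P/R/F on exact
(document, term) pairs; an empty system output scores 0 by convention,
an empty gold standard is an error. The external concept recognizer is
*not* reimplemented — the module scores any annotator's output — but a
minimal exact-phrase dictionary matcher (longest match at each
position wins and the scan resumes after it, so more detailed
annotations suppress more general ones) makes end-to-end fixtures
runnable. Note one consequence: growing the dictionary can *reassign*
a span from a general term to a specific one, so per-term document
sets are supersets after enrichment only when no new synonym shadows
an old match.

Retrieval gain compares per-term annotated-document sets between a
baseline and an enriched run over the terms that received new synonyms
(a substitution product always contains the replacement — an existing
ancestor synonym — as a subsequence, so the all-terms document union
is invariant by construction; the gain is visible only per term). Rows
stratify by IC bin and by annotation volume in the enriched run
(>1000, [100–1000), (0–100) documents per term); each cell counts the
union of its terms' documents. The increase rate is
100·(enriched − baseline)/baseline, rounded half-up for display — the
convention consistent with the published totals (134,367 → 142,041
printed as 6, 9370 → 12,418 as 33, 3055 → 5618 as 84); the
enriched-denominator alternative is available via a parameter. A zero
baseline with nonzero enrichment reports 100.

## Synthetic study conditions

The fixture generator emulates a genus–differentia ontology: a
compositional child's name is a fresh modifier token prefixed to one of
its parent's synonyms, and a compositional term tends to reuse one
differentia modifier across its synonyms over *different* parent
synonyms ("sensorineural hearing loss" / "sensorineural hearing
impairment") — that reuse is exactly what makes many substitution
products coincide with strings already in the ontology (the A∩B
intersection). Because every modifier and base token is globally
unique, the planted ground truth (closure edges, redundant synonyms,
lexical overlaps) is provably exhaustive and serves as the oracle for
the whole pipeline. Defaults, chosen once as study-condition
stand-ins: 1.68 synonyms per term including names (the reported ratio
for the reference ontology), genus-differentia rate 0.7 (high
compositionality with a nontrivial novel fraction at fixture scale),
redundant-synonym rate 0.03 (≈529/18,385), scope mix weighted toward
EXACT, multi-parent rate 0.1, obsolete terms only as leaves so pruned
ancestor chains stay intact.

Synthetic corpora are filler-token documents (vocabulary disjoint from
all planted phrase tokens) with each phrase inserted verbatim,
optionally embedded inside a longer "noun phrase" to exercise the
phrase-index behavior. What these fixtures do **not** model: real word
statistics, morphological variation, stemming/permutation matching of
real recognizers, punctuation-heavy prose, or MEDLINE-scale drift —
passing tests demonstrate the method's combinatorics and bookkeeping,
not recognition performance on clinical text.

The acceptance script (`scripts/acceptance.py`) runs the pipeline on a
3-root, depth-4, branching-3 fixture (120 terms, 300 documents) —
sizes chosen so the whole run completes in seconds while every stage
has non-degenerate counts — planting the 60% shortest novel candidate
strings (shortest-first, so an unplanted phrase can never occur inside
a planted one) plus existing synonyms of 60 terms, so the baseline
dictionary recognizes a realistic share of the corpus. The enriched
run's annotations serve as the evaluation gold standard — by
construction the enriched dictionary is complete for this corpus, so
enriched P/R/F are 1 and the informative number is the baseline gap.

## Numerical and degenerate-input choices

* Phrases that normalize to nothing (empty, all-bracketed) raise a
  degenerate-phrase error at the API boundary and are skipped with a
  warning inside bulk operations.
* Unmatched brackets are kept as literal characters and logged.
* Punctuation other than hyphens and brackets stays attached to tokens,
  preserving exact-phrase fidelity.
* OBO synonym lines without a scope keyword parse as UNSPECIFIED ("no
  relatedness" synonyms); the writer emits UNSPECIFIED synonyms without
  a scope keyword, so parse(write(model)) round-trips texts and scopes
  exactly.
* Deterministic orderings everywhere: overlaps sort by (ancestor,
  descendant, strings, position); candidate reports by (term, text);
  OBO stanzas by id. Identical config + inputs give identical outputs.

## Reproducing published release-level figures

The stage-by-stage statistics of a real release are computed by
`obosyn stats <release.obo>` (or `obosyn.pipeline.release_stats`):
non-obsolete terms, synonyms including names, redundant synonyms
removed, post-pruning count, synonyms per term, unique overlaps, and
the A/B accounting. The archived HPO release 2016-01-13 (`hp.obo`,
~5 MB) is not bundled with the package; place it at
`data/hp-2016-01-13.obo` to run the release-level acceptance test. Each
stat is attributable to one stage, so a divergence from a published
figure isolates the preprocessing convention responsible.

## Known limitations

* The PubMed adapter trusts the E-utilities phrase index; its
  tokenization is not guaranteed to match the local scanner's, and
  counts drift daily (results are cached with the query date).
* Scope inference has no ground truth beyond one published example;
  the restrictiveness ordering is a documented design choice.
* The "unique overlap" identity (string pair vs term pair) is a
  convention; both counts are reported.
* Multi-token overlap positions are substituted one occurrence at a
  time; simultaneous multi-site substitution is out of scope.
* No OWL serialization; only the is_a axis of the ontology is used.
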