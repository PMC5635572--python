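# obosyn

Synonym-substitution enrichment of hierarchical biomedical ontologies,
with exact-phrase corpus validation.

## The problem

Dictionary-based concept recognizers are only as good as the synonym
lists in their ontology. Phenotype ontologies such as the Human
Phenotype Ontology (HPO) name many terms compositionally — a child term
is its parent's name plus a differentia ("sensorineural **hearing
loss**" under "hearing loss") — but the synonym lists rarely cover all
the lexical variants clinicians actually write. `obosyn` exploits that
compositional structure to learn new synonyms automatically:

1. **Prune** synonyms that contain another synonym of the same term as a
   proper token subsequence (redundant for recognition: matching
   "congenital hearing loss" implies matching "hearing loss").
2. **Close** the is-a hierarchy transitively, per top-level category.
3. **Detect lexical overlaps**: pairs of hierarchically related terms
   where a descendant synonym properly contains an ancestor synonym as a
   contiguous token sequence.
4. **Substitute**: replace the overlapped span with each *other* synonym
   of the ancestor — "hearing loss" → "hearing defect" turns
   "sensorineural hearing loss" into "sensorineural hearing defect".
5. **Infer scope** for each generated synonym: the weakest of the three
   scopes involved, under EXACT > NARROW = BROAD > RELATED >
   UNSPECIFIED (NARROW ⊓ BROAD = RELATED).
6. **Validate** candidates by exact-phrase evidence in a document corpus
   (local TSV/MEDLINE XML scanner, or an optional live PubMed
   E-utilities adapter): a candidate never used in the literature is
   ruled out.
7. **Evaluate** the enrichment through information content
   (IC(t) = −log₁₀ p(t) over curated disease annotations),
   concept-annotation precision/recall/F against a gold standard, and
   per-term document-retrieval gains stratified by IC.

Text matching is token-level and case-insensitive; hyphenated words are
split ("criss-cross" → "criss cross") and bracketed clarifications such
as "(tshr)" are dropped from ontology labels before counting tokens.

## Worked example

```python
from obosyn import parse_obo, find_overlaps, generate_all
from obosyn.pipeline import prune_model

model = parse_obo("hearing.obo")          # mini hierarchy around HP:0000365
pruned, removed = prune_model(model)
overlaps = find_overlaps(pruned)
result = generate_all(pruned, overlaps, known_strings=model.synonym_strings())
```

On a five-term extract around *Hearing impairment* (HP:0000365, synonyms
"Hearing loss", "Hearing defect", "Congenital hearing loss") and its
child *Sensorineural hearing impairment* (HP:0000407, synonym
"Sensorineural hearing loss"), this prints:

```
removed: [('HP:0000365', ['Congenital hearing loss'])]
overlap: HP:0000365 'Hearing impairment' in HP:0000407 'Sensorineural hearing impairment'
overlap: HP:0000365 'Hearing loss' in HP:0000407 'Sensorineural hearing loss'
existing HP:0000407  'Sensorineural hearing loss'  scope=EXACT
novel    HP:0000407  'Sensorineural hearing defect'  scope=EXACT
existing HP:0000407  'Sensorineural hearing impairment'  scope=EXACT
novel    HP:0000407  'Sensorineural hearing defect'  scope=EXACT
```

"Congenital hearing loss" is pruned (it contains the sibling synonym
"hearing loss"); two overlaps are found; each substitution of the
remaining ancestor synonyms either regenerates a string the ontology
already has (`existing`, the A∩B intersection) or produces the new
synonym "Sensorineural hearing defect" (`novel`, the A/B set
difference — generated twice, once per overlap, and deduplicated before
attachment).

## Command line

```bash
obosyn synth ontology --seed 4 --out fixture.obo   # seeded synthetic fixture
obosyn enrich --ontology hp.obo --corpus corpus.tsv --out-dir run/
obosyn stats hp.obo                                 # stage-by-stage counts
obosyn ic annotations.tsv --ontology hp.obo --out ic.tsv
obosyn evaluate --system sys.tsv --gold gold.tsv
```

`enrich` writes `candidates.tsv`, `overlaps.tsv`, `enriched.obo`,
`stats.json` and a `manifest.json` that makes every number in the stats
summary re-derivable. Exit codes: 0 success, 2 input error, 3
validation error.

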