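"""End-to-end orchestration: prune -> closure -> overlaps -> generate ->
filter -> scope -> write, with a reproducible run manifest.

Every stage's counts are collected into a stats summary mirroring the
lexical-overlap metrics table (term and synonym counts, redundant
synonyms, unique overlaps) and the generation accounting (candidates A,
intersection B, set difference A/B), so a divergence on real data can be
localized to the stage that produced it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import corpus_filter, obo_io
from .hierarchy import all_closure_pairs
from .obo_io import OntologyModel
from .overlap_finder import find_overlaps, unique_overlap_strings
from .synonym_generator import CandidateSynonym, generate_all
from .textnorm import remove_redundant_synonyms

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "load_config", "prune_model", "run_enrich", "release_stats"]


@dataclass
class RunConfig:
    ontology_path: str
    corpus_path: str | None = None
    out_dir: str = "run"
    max_depth: int = 1
    use_pubmed: bool = False
    email: str = ""
    cache_dir: str | None = None
    seed: int = 0

    @classmethod
    def from_mapping(cls, data: dict[str, str]) -> "RunConfig":
        kwargs: dict[str, object] = {}
        for f in dataclasses.fields(cls):
            if f.name in data:
                raw = data[f.name]
                if f.type in ("int", int):
                    kwargs[f.name] = int(raw)
                elif f.type in ("bool", bool):
                    kwargs[f.name] = str(raw).lower() in ("1", "true", "yes")
                else:
                    kwargs[f.name] = raw
        return cls(**kwargs)  # type: ignore[arg-type]


def load_config(path: str | Path) -> RunConfig:
    """Plain-text key=value config file; '#' starts a comment line."""
    data: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text("utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
        k, v = line.split("=", 1)
        data[k.strip()] = v.strip()
    return RunConfig.from_mapping(data)


def prune_model(model: OntologyModel) -> tuple[OntologyModel, dict[str, list]]:
    """Apply redundancy removal to every non-obsolete term."""
    removed: dict[str, list] = {}
    terms = dict(model.terms)
    for t in model.non_obsolete():
        pruned, dropped = remove_redundant_synonyms(t)
        if dropped:
            removed[t.id] = dropped
            terms[t.id] = pruned
    return OntologyModel(terms=terms, format_version=model.format_version), removed


@dataclass
class RunResult:
    stats: dict = field(default_factory=dict)
    accepted: list[CandidateSynonym] = field(default_factory=list)
    out_dir: Path | None = None


def _scope_split(candidates: list[CandidateSynonym]) -> dict[str, float]:
    n = len(candidates)
    out: dict[str, float] = {}
    for scope in ("EXACT", "NARROW", "BROAD", "RELATED", "UNSPECIFIED"):
        k = sum(1 for c in candidates if c.scope.value == scope)
        out[scope.lower()] = round(100.0 * k / n, 1) if n else 0.0
    return out


def ontology_stage_stats(model: OntologyModel) -> tuple[dict, OntologyModel, list]:
    """Stats for the lexical stages (pruning, closure, overlaps) plus the
    pruned model and the overlap list."""
    stats: dict = {}
    stats["total_terms"] = len(model.terms)
    stats["obsolete_terms"] = sum(1 for t in model if t.obsolete)
    stats["non_obsolete_terms"] = len(model.non_obsolete())
    n_syn = sum(
        len(t.synonym_entries(include_name=True)) for t in model.non_obsolete()
    )
    stats["synonyms_including_names"] = n_syn
    stats["synonyms_per_term"] = (
        round(n_syn / stats["non_obsolete_terms"], 2)
        if stats["non_obsolete_terms"]
        else 0.0
    )

    pruned, removed = prune_model(model)
    stats["redundant_synonyms_removed"] = sum(len(v) for v in removed.values())
    stats["synonyms_after_pruning"] = n_syn - stats["redundant_synonyms_removed"]

    closure = all_closure_pairs(pruned)
    stats["closure_pairs"] = len(closure)

    overlaps = find_overlaps(pruned, pairs=closure)
    summary = unique_overlap_strings(overlaps)
    stats["overlap_occurrences"] = summary.occurrence_total
    stats["unique_lexical_overlaps"] = summary.unique_total
    stats["unique_overlap_term_pairs"] = summary.unique_term_pairs
    stats["overlap_tokens_histogram"] = summary.tokens_histogram
    return stats, pruned, overlaps


def run_enrich(config: RunConfig) -> RunResult:
    """Execute the full enrichment pipeline and write the artifact bundle:
    candidate TSV, overlap TSV, enriched OBO, stats JSON and manifest."""
    if not config.use_pubmed and not config.corpus_path:
        raise ValueError("no corpus: set corpus_path or use_pubmed")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    model = obo_io.parse_obo(config.ontology_path)
    known_strings = model.synonym_strings()
    stats, pruned, overlaps = ontology_stage_stats(model)

    result = generate_all(
        pruned, overlaps, max_depth=config.max_depth, known_strings=known_strings
    )
    stats["max_depth"] = config.max_depth
    stats["candidates_A"] = result.n_candidates
    stats["candidates_A_unique_strings"] = result.n_unique_strings
    stats["existing_B_intersection"] = len(result.existing)
    stats["novel_A_minus_B"] = len(result.novel)
    novel = result.attachable(pruned)
    stats["novel_attachable"] = len(novel)

    # corpus validation
    if config.use_pubmed:
        from .pubmed import PubMedSearcher

        searcher = PubMedSearcher(email=config.email, cache_dir=config.cache_dir)
        accepted = []
        for c in novel:
            hits = searcher.count(c.text)
            c = dataclasses.replace(c, corpus_validated=hits >= 1)
            if c.corpus_validated:
                accepted.append(c)
        validated = accepted
        all_outcomes = None
    elif config.corpus_path:
        corpus = corpus_filter.read_corpus_tsv(config.corpus_path)
        outcomes = corpus_filter.filter_candidates(novel, corpus)
        validated = [
            dataclasses.replace(o.candidate, corpus_validated=True)
            for o in outcomes
            if o.retained
        ]
        all_outcomes = outcomes
    else:
        raise ValueError("no corpus: set corpus_path or use_pubmed")

    stats["retained_after_corpus_filter"] = len(validated)
    stats["retained_unique_terms"] = len({c.term_id for c in validated})
    stats["scope_split_pct"] = _scope_split(validated)

    # artifacts
    reported = list(validated)
    if all_outcomes is not None:
        rejected = [
            dataclasses.replace(o.candidate, corpus_validated=False)
            for o in all_outcomes
            if not o.retained
        ]
        reported += rejected
    obo_io.write_candidates(reported, out_dir / "candidates.tsv")
    _write_overlap_tsv(overlaps, out_dir / "overlaps.tsv")
    obo_io.write_enriched_obo(model, validated, out_dir / "enriched.obo")
    (out_dir / "stats.json").write_text(
        json.dumps(stats, indent=2, sort_keys=True) + "\n", "utf-8"
    )
    (out_dir / "manifest.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=2, sort_keys=True) + "\n",
        "utf-8",
    )
    return RunResult(stats=stats, accepted=validated, out_dir=out_dir)


def _write_overlap_tsv(overlaps, path: Path) -> None:
    import csv

    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            [
                "ancestor_id",
                "descendant_id",
                "ancestor_string",
                "descendant_string",
                "start_token",
                "token_length",
            ]
        )
        for o in overlaps:
            w.writerow(
                [
                    o.ancestor_id,
                    o.descendant_id,
                    o.ancestor_synonym.text,
                    o.descendant_synonym.text,
                    o.start,
                    o.length,
                ]
            )


def release_stats(ontology_path: str | Path, max_depth: int = 1) -> dict:
    """Stage-by-stage statistics of the lexical pipeline on a real
    ontology release (no corpus needed): term/synonym counts, redundancy
    removal, unique overlaps, and the A/B generation accounting.  Used to
    localize which stage diverges when reproducing published numbers.
    """
    model = obo_io.parse_obo(ontology_path)
    known = model.synonym_strings()
    stats, pruned, overlaps = ontology_stage_stats(model)
    result = generate_all(pruned, overlaps, max_depth=max_depth, known_strings=known)
    stats["candidates_A"] = result.n_candidates
    stats["existing_B_intersection"] = len(result.existing)
    stats["novel_A_minus_B"] = len(result.novel)
    return stats
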