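"""The gene-symptom-syndrome combination method.

A syndrome's symptoms are classified into main, Qi-deficiency and
blood-stasis groups, plus *fixed* terms present in every combination.
Each group holds one or more *options*; an option is one term or a small
tuple of terms that always travel together.  Combinations are the
Cartesian product of one option per group, laid out as

    main terms + Qi-deficiency option + fixed terms + blood-stasis option.

Per symptom, the *hit* of a gene is the number of documents in which the
gene and the symptom term co-occur.  A combination's gene set is the union
of per-symptom gene sets over its terms, and the syndrome's core genes are
the intersection of those unions across all combinations ("the genes
existing in each combination").  An intersection-within-combination
reading is available via ``within="intersection"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .errors import TermLookupError, ValidationError
from .io import AbstractRecord
from .ner import GeneDictionary, annotate_corpus, tokenize

Option = tuple[str, ...]
SymptomCombination = tuple[str, ...]
SymptomGeneHits = dict[str, dict[str, int]]


@dataclass(frozen=True)
class SymptomClassification:
    """Symptom grouping of one syndrome.

    ``main``, ``qi_deficiency`` and ``blood_stasis`` are lists of options;
    ``fixed_terms`` join every combination; ``removed_terms`` collects
    symptoms pruned for having no mapped genes.  All term lists must be
    disjoint.
    """

    syndrome_name: str
    main: tuple[Option, ...]
    qi_deficiency: tuple[Option, ...]
    blood_stasis: tuple[Option, ...]
    fixed_terms: Option = ()
    removed_terms: frozenset[str] = frozenset()

    def group_terms(self) -> dict[str, tuple[str, ...]]:
        return {
            "main": tuple(t for opt in self.main for t in opt),
            "qi_deficiency": tuple(t for opt in self.qi_deficiency for t in opt),
            "blood_stasis": tuple(t for opt in self.blood_stasis for t in opt),
            "fixed": self.fixed_terms,
        }

    def all_terms(self) -> tuple[str, ...]:
        return tuple(t for terms in self.group_terms().values() for t in terms)

    def __post_init__(self) -> None:
        groups = self.group_terms()
        seen: set[str] = set()
        for name, terms in groups.items():
            for t in terms:
                if t in seen:
                    raise ValidationError(
                        f"term {t!r} appears in more than one group")
                seen.add(t)
        overlap = self.removed_terms & seen
        if overlap:
            raise ValidationError(
                f"removed terms still present in groups: {sorted(overlap)}")


def _contains_term(tokens: tuple[str, ...], term_tokens: tuple[str, ...]) -> bool:
    """Contiguous case-folded token-subsequence containment."""
    n = len(term_tokens)
    if n == 0 or n > len(tokens):
        return False
    return any(tokens[i:i + n] == term_tokens for i in range(len(tokens) - n + 1))


def count_symptom_gene_hits(corpus: Sequence[AbstractRecord],
                            dictionary: GeneDictionary,
                            symptom_terms: Sequence[str],
                            include_title: bool = True) -> SymptomGeneHits:
    """Document-level co-occurrence counts of symptoms and genes.

    ``hit(s, g)`` is the number of records whose text contains the symptom
    term (case-insensitive contiguous token match) and at least one mention
    of the gene.  Symptoms absent from the corpus keep all-zero rows.
    """
    if not symptom_terms:
        raise ValidationError("symptom term list must be nonempty")
    annotated = annotate_corpus(corpus, dictionary, include_title=include_title)
    term_tokens = {s: tuple(t.text.casefold() for t in tokenize(s))
                   for s in symptom_terms}
    hits: SymptomGeneHits = {s: {} for s in symptom_terms}
    for rec in corpus:
        text = f"{rec.title} {rec.abstract}" if include_title else rec.abstract
        tokens = tuple(t.text.casefold() for t in tokenize(text))
        genes = annotated.genes_in_record(rec.record_id)
        if not genes:
            continue
        for s in symptom_terms:
            if _contains_term(tokens, term_tokens[s]):
                row = hits[s]
                for g in genes:
                    row[g] = row.get(g, 0) + 1
    return hits


def genes_for_symptom(hits: SymptomGeneHits, symptom: str,
                      min_hits: int = 1) -> set[str]:
    """Genes whose hit count for the symptom reaches ``min_hits``."""
    if symptom not in hits:
        raise TermLookupError(f"no hit row for symptom {symptom!r}")
    return {g for g, c in hits[symptom].items() if c >= min_hits}


def unmapped_symptoms(hits: SymptomGeneHits, terms: Sequence[str],
                      min_hits: int = 1) -> set[str]:
    """Symptoms whose gene set is empty (all-zero or absent rows)."""
    out = set()
    for t in terms:
        if t not in hits or not genes_for_symptom(hits, t, min_hits):
            out.add(t)
    return out


def prune_unmapped_symptoms(classification: SymptomClassification,
                            hits: SymptomGeneHits,
                            min_hits: int = 1) -> SymptomClassification:
    """Move symptoms with no mapped genes into ``removed_terms``.

    Options lose their unmapped terms; options emptied entirely are
    dropped.  Emptying a whole variable group (or the main group) is a
    validation error naming the group.
    """
    dead = unmapped_symptoms(hits, classification.all_terms(), min_hits)

    def prune_group(options: tuple[Option, ...], name: str) -> tuple[Option, ...]:
        kept = tuple(opt_kept for opt in options
                     if (opt_kept := tuple(t for t in opt if t not in dead)))
        if options and not kept:
            raise ValidationError(f"pruning emptied the {name!r} symptom group")
        return kept

    fixed = tuple(t for t in classification.fixed_terms if t not in dead)
    return replace(
        classification,
        main=prune_group(classification.main, "main"),
        qi_deficiency=prune_group(classification.qi_deficiency, "qi_deficiency"),
        blood_stasis=prune_group(classification.blood_stasis, "blood_stasis"),
        fixed_terms=fixed,
        removed_terms=classification.removed_terms | frozenset(dead),
    )


def enumerate_combinations(classification: SymptomClassification
                           ) -> list[SymptomCombination]:
    """Cartesian product of one option per group, fixed terms in every row.

    Iteration order: main outermost, then Qi-deficiency, then blood stasis,
    so adjacent combinations differ in the blood-stasis option first.
    Duplicates are removed preserving order.
    """
    for name in ("main", "qi_deficiency", "blood_stasis"):
        if not getattr(classification, name):
            raise ValidationError(f"symptom group {name!r} is empty")
    out: list[SymptomCombination] = []
    seen: set[SymptomCombination] = set()
    for m in classification.main:
        for q in classification.qi_deficiency:
            for b in classification.blood_stasis:
                combo = (*m, *q, *classification.fixed_terms, *b)
                if combo not in seen:
                    seen.add(combo)
                    out.append(combo)
    return out


def core_genes(combinations: Sequence[SymptomCombination],
               hits: SymptomGeneHits, min_hits: int = 1,
               within: str = "union") -> set[str]:
    """Genes present in every combination.

    Within one combination the per-symptom gene sets are combined by
    ``within`` ("union" by default, "intersection" as the strict reading);
    across combinations the result is always the intersection.  An empty
    result is a valid outcome.
    """
    if not combinations:
        raise ValidationError("need at least one symptom combination")
    if within not in ("union", "intersection"):
        raise ValidationError(f"unknown within mode {within!r}")
    result: set[str] | None = None
    for combo in combinations:
        sets = [genes_for_symptom(hits, term, min_hits) for term in combo]
        if within == "union":
            combo_genes = set().union(*sets)
        else:
            combo_genes = set.intersection(*sets) if sets else set()
        result = combo_genes if result is None else result & combo_genes
    return result or set()
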