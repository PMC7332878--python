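"""Integration of the decomposition and combination tracks, plus ORA.

Per syndrome the two tracks each yield a gene set; *matching* them is
exact intersection.  Across two diseases sharing a syndrome, the shared
genes are the intersection of the matched sets — the operational reading
of "treating different diseases with the same method".  An optional
over-representation analysis (hypergeometric upper tail, Benjamini-
Hochberg adjusted) characterizes the resulting gene sets against a
user-supplied GMT collection.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from . import combination as comb
from . import io as zio
from . import network as net
from . import ner
from . import relations as rel
from . import synthetic
from .errors import PipelineStageError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyndromeGeneSet:
    """A gene set attributed to one syndrome and one method."""

    syndrome_name: str
    method: str  # decomposition | combination | matched
    genes: frozenset[str]


def intersect_method_results(decomposition_set: SyndromeGeneSet,
                             combination_set: SyndromeGeneSet
                             ) -> SyndromeGeneSet:
    """Match the two tracks of one syndrome by exact intersection."""
    if decomposition_set.syndrome_name != combination_set.syndrome_name:
        raise ValidationError(
            f"syndrome mismatch: {decomposition_set.syndrome_name!r} vs "
            f"{combination_set.syndrome_name!r}")
    return SyndromeGeneSet(
        syndrome_name=decomposition_set.syndrome_name, method="matched",
        genes=decomposition_set.genes & combination_set.genes)


def shared_across_diseases(set_a: SyndromeGeneSet,
                           set_b: SyndromeGeneSet) -> list[str]:
    """Sorted intersection of two matched gene sets."""
    return sorted(set_a.genes & set_b.genes)


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap: frozenset[str]
    p_value: float
    adjusted_p: float


def enrich(query_genes: Iterable[str],
           gene_set_collection: Mapping[str, set[str]],
           universe: Iterable[str]) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of the query in each gene set.

    P(X >= observed overlap) for overlap between the query and each set
    drawn from the universe; Benjamini-Hochberg adjustment across sets;
    sorted by raw p then name.  The query must be a subset of the
    universe; gene sets are clipped to it.
    """
    universe_set = set(universe)
    query = set(query_genes)
    stray = query - universe_set
    if stray:
        raise ValidationError(f"query genes outside universe: {sorted(stray)}")
    names = sorted(gene_set_collection)
    results: list[tuple[str, frozenset[str], float]] = []
    m = len(universe_set)
    n_query = len(query)
    for name in names:
        members = set(gene_set_collection[name]) & universe_set
        overlap = frozenset(query & members)
        k = len(overlap)
        if not members or not query:
            p = 1.0
        else:
            p = float(hypergeom.sf(k - 1, m, len(members), n_query))
        results.append((name, overlap, min(p, 1.0)))
    if results:
        _, adj, _, _ = multipletests([r[2] for r in results], method="fdr_bh")
    else:
        adj = []
    out = [EnrichmentResult(name, ov, p, float(min(max(a, p), 1.0)))
           for (name, ov, p), a in zip(results, adj)]
    out.sort(key=lambda r: (r.p_value, r.set_name))
    return out


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------

@dataclass
class SyndromeConfig:
    """Inputs of one syndrome: a corpus and a symptom classification."""

    name: str
    corpus: list[zio.AbstractRecord]
    classification: comb.SymptomClassification
    zjw: Mapping[int, float] = field(default_factory=dict)
    # Precomputed symptom-gene hit table (e.g. from an external keyword
    # search or the synthetic symptom generator); when None, hits are
    # counted from the corpus itself.
    hits: comb.SymptomGeneHits | None = None


@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    ``edges_from`` selects whether final network edges come from the MIL
    model's predictions ("model") or directly from flag-positive bags
    ("flags"); ``threshold`` is the prediction decision threshold.
    """

    dictionary: list[zio.GeneEntry]
    knowledge_base: Mapping[zio.GenePairKey, float]
    syndromes: list[SyndromeConfig]
    seed: int = 0
    threshold: float = 0.5
    edges_from: str = "model"
    min_hits: int = 1
    gene_sets: Mapping[str, set[str]] | None = None
    out_dir: Path | None = None


@dataclass
class IntegrationReport:
    """Serializable record of one full run (timings logged, not stored)."""

    config_hash: str
    seed: int
    per_syndrome: dict[str, dict[str, list[str]]]
    shared_genes: list[str]
    enrichment: list[dict]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _config_hash(config: PipelineConfig) -> str:
    payload = {
        "dictionary": [(e.symbol, list(e.synonyms)) for e in config.dictionary],
        "kb": sorted((a, b, s) for (a, b), s in config.knowledge_base.items()),
        "syndromes": [
            {"name": s.name,
             "records": [(r.record_id, r.title, r.abstract) for r in s.corpus],
             "classification": s.classification.syndrome_name,
             "zjw": sorted(s.zjw.items()),
             "hits": (None if s.hits is None else
                      sorted((t, sorted(row.items())) for t, row in s.hits.items()))}
            for s in config.syndromes],
        "seed": config.seed, "threshold": config.threshold,
        "edges_from": config.edges_from, "min_hits": config.min_hits,
    }
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()).hexdigest()


def decomposition_track(corpus: Sequence[zio.AbstractRecord],
                        dictionary: ner.GeneDictionary,
                        knowledge_base: Mapping[zio.GenePairKey, float],
                        seed: int, threshold: float = 0.5,
                        edges_from: str = "model",
                        zjw: Mapping[int, float] | None = None):
    """NER -> bags -> MIL -> network -> communities -> ranking.

    Returns (gene set, ranking table, network, predictions).  Falls back
    to flag edges when the training set is single-class (tiny corpora).
    """
    annotated = ner.annotate_corpus(corpus, dictionary)
    bags = rel.generate_bags(annotated, knowledge_base)
    if not bags:
        return set(), None, None, []
    if edges_from == "flags":
        preds = [rel.RelationPrediction(b.pair, float(b.flag), b.flag,
                                        len(b.instances)) for b in bags]
    else:
        try:
            model = rel.train_mil(bags, seed=seed)
            preds = rel.predict_relations(model, bags, threshold=threshold)
        except ValidationError:
            logger.warning("single-class bags; falling back to flag edges")
            preds = [rel.RelationPrediction(b.pair, float(b.flag), b.flag,
                                            len(b.instances)) for b in bags]
    graph = net.build_network(preds)
    if graph.number_of_nodes() == 0:
        return set(), None, graph, preds
    ranking = net.rank_genes(graph, zjw_map=zjw, seed=seed)
    return set(graph.nodes()), ranking, graph, preds


def combination_track(corpus: Sequence[zio.AbstractRecord],
                      dictionary: ner.GeneDictionary,
                      classification: comb.SymptomClassification,
                      min_hits: int = 1,
                      hits: comb.SymptomGeneHits | None = None):
    """Hits -> pruning -> combinations -> core genes.

    Returns (gene set, pruned classification, combinations, hits).
    """
    if hits is None:
        hits = comb.count_symptom_gene_hits(corpus, dictionary,
                                            classification.all_terms())
    pruned = comb.prune_unmapped_symptoms(classification, hits,
                                          min_hits=min_hits)
    combos = comb.enumerate_combinations(pruned)
    genes = comb.core_genes(combos, hits, min_hits=min_hits)
    return genes, pruned, combos, hits


def run_pipeline(config: PipelineConfig) -> IntegrationReport:
    """Run both tracks per syndrome, match, intersect across syndromes.

    Deterministic given the configuration and seed; every stage failure is
    wrapped in :class:`PipelineStageError` naming the stage.  Intermediate
    artifacts are written under ``config.out_dir`` when set.
    """
    gene_dict = ner.GeneDictionary(config.dictionary)
    per_syndrome: dict[str, dict[str, list[str]]] = {}
    matched_sets: list[SyndromeGeneSet] = []
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    for syn in config.syndromes:
        t0 = time.perf_counter()
        try:
            dec_genes, ranking, graph, preds = decomposition_track(
                syn.corpus, gene_dict, config.knowledge_base,
                seed=config.seed, threshold=config.threshold,
                edges_from=config.edges_from, zjw=syn.zjw)
        except Exception as exc:  # noqa: BLE001 - re-raised typed
            raise PipelineStageError(f"decomposition[{syn.name}]", exc) from exc
        try:
            comb_genes, pruned, combos, hits = combination_track(
                syn.corpus, gene_dict, syn.classification,
                min_hits=config.min_hits, hits=syn.hits)
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError(f"combination[{syn.name}]", exc) from exc
        dec = SyndromeGeneSet(syn.name, "decomposition", frozenset(dec_genes))
        com = SyndromeGeneSet(syn.name, "combination", frozenset(comb_genes))
        matched = intersect_method_results(dec, com)
        matched_sets.append(matched)
        per_syndrome[syn.name] = {
            "decomposition": sorted(dec.genes),
            "combination": sorted(com.genes),
            "matched": sorted(matched.genes),
        }
        logger.info("syndrome %s done in %.2fs (dec=%d comb=%d matched=%d)",
                    syn.name, time.perf_counter() - t0, len(dec.genes),
                    len(com.genes), len(matched.genes))
        if out_dir is not None:
            if ranking is not None:
                ranking.to_csv(out_dir / f"{syn.name}.ranking.csv", index=False)
            if graph is not None and graph.number_of_nodes():
                zio.write_pajek(graph, out_dir / f"{syn.name}.net")
            with open(out_dir / f"{syn.name}.combinations.txt", "w",
                      encoding="utf-8") as fh:
                for i, c in enumerate(combos, start=1):
                    fh.write(f"Combination {i}: " + " + ".join(c) + "\n")

    if len(matched_sets) >= 2:
        shared = shared_across_diseases(matched_sets[0], matched_sets[1])
        for extra in matched_sets[2:]:
            shared = sorted(set(shared) & extra.genes)
    elif matched_sets:
        shared = sorted(matched_sets[0].genes)
    else:
        shared = []

    enrichment_rows: list[dict] = []
    if config.gene_sets and shared:
        universe = sorted(e.symbol for e in config.dictionary)
        try:
            results = enrich(shared, config.gene_sets, universe)
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("enrichment", exc) from exc
        enrichment_rows = [
            {"set_name": r.set_name, "overlap": sorted(r.overlap),
             "p_value": r.p_value, "adjusted_p": r.adjusted_p}
            for r in results]

    report = IntegrationReport(
        config_hash=_config_hash(config), seed=config.seed,
        per_syndrome=per_syndrome, shared_genes=shared,
        enrichment=enrichment_rows)
    if out_dir is not None:
        (out_dir / "report.json").write_text(report.to_json(), encoding="utf-8")
    return report
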