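"""Readers and writers for every external format the pipeline touches.

Formats: MEDLINE-style XML and TSV abstract corpora, TSV gene dictionaries,
TSV knowledge-base edge lists, CSV TCM-to-modern symptom term maps, Pajek
``.net`` graphs, and GMT gene-set collections.

Dialect choices: UTF-8 throughout; TSV without quoting; CSV with RFC-style
quoting; Pajek with 1-based vertex indices and double-quoted labels.  All
readers are total over their declared dialects — any deviation raises a
typed error from :mod:`zhengnet.errors`, never a silent truncation.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
from lxml import etree

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

GenePairKey = tuple[str, str]


def pair_key(a: str, b: str) -> GenePairKey:
    """Canonical (lexicographically sorted) key for an unordered gene pair."""
    if a == b:
        raise ValidationError(f"self-pair is not a valid gene pair: {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class AbstractRecord:
    """One literature abstract.

    ``abstract`` may be empty (some records carry no abstract text) but is
    never absent; ``record_id`` is unique within a corpus.
    """

    record_id: str
    title: str
    abstract: str
    keywords: tuple[str, ...] = ()


@dataclass(frozen=True)
class GeneEntry:
    """A dictionary entry: canonical symbol plus alternative surface forms."""

    symbol: str
    synonyms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValidationError("gene symbol must be nonempty")


# ---------------------------------------------------------------------------
# Abstract corpora
# ---------------------------------------------------------------------------

def read_medline_xml(path: str | Path) -> list[AbstractRecord]:
    """Read a MEDLINE/PubMed-style XML corpus.

    One :class:`AbstractRecord` per ``PubmedArticle`` element.  A missing
    abstract element yields ``abstract=""`` with a logged warning; duplicate
    record identifiers raise :class:`ValidationError`; malformed XML raises
    :class:`ParseError` naming the byte offset.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        offset = getattr(exc, "position", (None, None))
        raise ParseError(f"malformed XML in {path}: {exc.msg}",
                         location=exc.offset if exc.offset else None) from exc
    records: list[AbstractRecord] = []
    seen: set[str] = set()
    for art in tree.iter("PubmedArticle"):
        pmid_el = art.find(".//PMID")
        rid = pmid_el.text.strip() if pmid_el is not None and pmid_el.text else ""
        if not rid:
            raise ValidationError(f"article without PMID in {path}")
        if rid in seen:
            raise ValidationError(f"duplicate record id {rid!r} in {path}")
        seen.add(rid)
        title_el = art.find(".//ArticleTitle")
        title = (title_el.text or "") if title_el is not None else ""
        abst_parts = [t.text or "" for t in art.findall(".//Abstract/AbstractText")]
        if not abst_parts:
            logger.warning("record %s has no abstract; using empty string", rid)
        keywords = tuple(
            (k.text or "").strip() for k in art.findall(".//KeywordList/Keyword")
            if k.text and k.text.strip()
        )
        records.append(AbstractRecord(rid, title, " ".join(abst_parts), keywords))
    return records


def write_medline_xml(records: Iterable[AbstractRecord], path: str | Path) -> None:
    """Write records as MEDLINE-style XML (inverse of :func:`read_medline_xml`)."""
    root = etree.Element("PubmedArticleSet")
    for rec in records:
        art = etree.SubElement(root, "PubmedArticle")
        cit = etree.SubElement(art, "MedlineCitation")
        etree.SubElement(cit, "PMID").text = rec.record_id
        article = etree.SubElement(cit, "Article")
        etree.SubElement(article, "ArticleTitle").text = rec.title
        if rec.abstract:
            abst = etree.SubElement(article, "Abstract")
            etree.SubElement(abst, "AbstractText").text = rec.abstract
        if rec.keywords:
            kwl = etree.SubElement(cit, "KeywordList")
            for kw in rec.keywords:
                etree.SubElement(kwl, "Keyword").text = kw
    etree.ElementTree(root).write(str(path), encoding="utf-8",
                                  xml_declaration=True, pretty_print=True)


def read_corpus_tsv(path: str | Path) -> list[AbstractRecord]:
    """Read a TSV corpus with columns id, title, abstract[, keywords].

    Keywords, when present, are ``|``-separated in the fourth column.
    """
    records: list[AbstractRecord] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"corpus TSV row needs >=3 columns in {path}",
                                 location=lineno)
            rid, title, abstract = parts[0], parts[1], parts[2]
            if rid in seen:
                raise ValidationError(f"duplicate record id {rid!r} in {path}")
            seen.add(rid)
            kws = tuple(k for k in parts[3].split("|") if k) if len(parts) > 3 else ()
            records.append(AbstractRecord(rid, title, abstract, kws))
    return records


def write_corpus_tsv(records: Iterable[AbstractRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f"{rec.record_id}\t{rec.title}\t{rec.abstract}\t"
                     f"{'|'.join(rec.keywords)}\n")


# ---------------------------------------------------------------------------
# Gene dictionary
# ---------------------------------------------------------------------------

def read_gene_dictionary(path: str | Path) -> list[GeneEntry]:
    """Read a TSV gene dictionary: symbol in column 1, synonyms after.

    Case-folded symbol duplicates are a hard error listing the offenders;
    a synonym equal (case-folded) to another entry's symbol is likewise an
    error — silent merging corrupts downstream counts.  A synonym identical
    to its own symbol after case-folding is simply dropped.
    """
    entries: list[GeneEntry] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            symbol = parts[0].strip()
            if not symbol:
                raise ParseError(f"empty symbol in {path}", location=lineno)
            syns = tuple(
                s.strip() for s in parts[1:]
                if s.strip() and s.strip().casefold() != symbol.casefold()
            )
            entries.append(GeneEntry(symbol, syns))
    if not entries:
        raise ValidationError(f"gene dictionary {path} is empty")
    validate_dictionary(entries)
    return entries


def validate_dictionary(entries: Sequence[GeneEntry]) -> None:
    """Check symbol uniqueness and synonym/symbol collisions (case-folded)."""
    by_cf: dict[str, str] = {}
    dups: list[str] = []
    for e in entries:
        cf = e.symbol.casefold()
        if cf in by_cf:
            dups.append(e.symbol)
        by_cf[cf] = e.symbol
    if dups:
        raise ValidationError(f"duplicate symbols after case-folding: {sorted(dups)}")
    for e in entries:
        for syn in e.synonyms:
            cf = syn.casefold()
            if cf in by_cf and by_cf[cf] != e.symbol:
                raise ValidationError(
                    f"synonym {syn!r} of {e.symbol} collides with symbol {by_cf[cf]}")


def write_gene_dictionary(entries: Iterable[GeneEntry], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in entries:
            fh.write("\t".join((e.symbol, *e.synonyms)) + "\n")


# ---------------------------------------------------------------------------
# Knowledge base (gene-gene relation edge list)
# ---------------------------------------------------------------------------

def read_knowledge_base(path: str | Path) -> dict[GenePairKey, float]:
    """Read a TSV edge list (symbol_a, symbol_b[, score]) into unordered pairs.

    Self-pair rows are skipped with a warning; duplicate pairs collapse
    keeping the maximum score; a non-numeric score is a validation error.
    Missing scores default to 1.0.
    """
    kb: dict[GenePairKey, float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"knowledge-base row needs >=2 columns in {path}",
                                 location=lineno)
            a, b = parts[0].strip(), parts[1].strip()
            if a == b:
                logger.warning("skipping self-pair (%s,%s) at line %d", a, b, lineno)
                continue
            if len(parts) > 2 and parts[2].strip():
                try:
                    score = float(parts[2])
                except ValueError as exc:
                    raise ValidationError(
                        f"non-numeric score {parts[2]!r} at line {lineno}") from exc
            else:
                score = 1.0
            key = pair_key(a, b)
            kb[key] = max(score, kb.get(key, float("-inf")))
    return kb


def write_knowledge_base(kb: Mapping[GenePairKey, float], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for (a, b), score in sorted(kb.items()):
            fh.write(f"{a}\t{b}\t{score:g}\n")


# ---------------------------------------------------------------------------
# TCM -> modern symptom term map
# ---------------------------------------------------------------------------

def read_term_map(path: str | Path) -> dict[str, list[str]]:
    """Read a CSV with columns tcm_term, modern_term; group by tcm_term.

    Duplicate identical rows are deduplicated; each source term keeps its
    modern terms in first-seen order.
    """
    mapping: dict[str, list[str]] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise ValidationError(f"term map {path} is empty")
        for row in reader:
            if not row or not any(c.strip() for c in row):
                continue
            if len(row) < 2:
                raise ParseError(f"term-map row needs 2 columns in {path}")
            tcm, modern = row[0].strip(), row[1].strip()
            bucket = mapping.setdefault(tcm, [])
            if modern not in bucket:
                bucket.append(modern)
    return mapping


def write_term_map(mapping: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["tcm_term", "modern_term"])
        for tcm in mapping:
            for modern in mapping[tcm]:
                writer.writerow([tcm, modern])


def lookup_term(mapping: Mapping[str, Sequence[str]], tcm_term: str) -> list[str]:
    """Resolve one source term; unmapped terms raise :class:`TermLookupError`."""
    from .errors import TermLookupError

    if tcm_term not in mapping:
        raise TermLookupError(f"no modern-term mapping for {tcm_term!r}")
    return list(mapping[tcm_term])


# ---------------------------------------------------------------------------
# Pajek .net
# ---------------------------------------------------------------------------
# Written by hand rather than via networkx's pajek module so that the exact
# dialect (1-based indices, quoted labels, *Edges section) and the round-trip
# contract read(write(G)) == G are guaranteed, and so parse errors carry line
# numbers.  Node identity is the gene symbol; the index is file-local only.

def write_pajek(network: nx.Graph, path: str | Path) -> None:
    """Write an undirected graph as a Pajek ``.net`` file.

    Vertices are numbered 1..n in sorted-label order; labels are quoted.
    """
    if network.number_of_nodes() == 0:
        raise ValidationError("cannot write Pajek file for an empty network")
    nodes = sorted(network.nodes(), key=str)
    index = {n: i + 1 for i, n in enumerate(nodes)}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"*Vertices {len(nodes)}\n")
        for n in nodes:
            fh.write(f'{index[n]} "{n}"\n')
        fh.write("*Edges\n")
        for a, b in sorted((pair_key(str(u), str(v)) for u, v in network.edges())):
            fh.write(f"{index[a]} {index[b]}\n")


def read_pajek(path: str | Path) -> nx.Graph:
    """Read a Pajek ``.net`` file written by :func:`write_pajek`.

    Unknown vertex indices in the edge section raise :class:`ParseError`
    with the offending line number.
    """
    graph = nx.Graph()
    labels: dict[int, str] = {}
    section = None
    n_declared = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("%"):
                continue
            low = line.lower()
            if low.startswith("*vertices"):
                try:
                    n_declared = int(line.split()[1])
                except (IndexError, ValueError) as exc:
                    raise ParseError("bad *Vertices header", location=lineno) from exc
                section = "vertices"
                continue
            if low.startswith("*edges") or low.startswith("*arcs"):
                section = "edges"
                continue
            if section == "vertices":
                parts = line.split(None, 1)
                try:
                    idx = int(parts[0])
                except ValueError as exc:
                    raise ParseError("bad vertex index", location=lineno) from exc
                label = parts[1].strip() if len(parts) > 1 else str(idx)
                if label.startswith('"') and label.endswith('"'):
                    label = label[1:-1]
                labels[idx] = label
                graph.add_node(label)
            elif section == "edges":
                parts = line.split()
                try:
                    i, j = int(parts[0]), int(parts[1])
                except (IndexError, ValueError) as exc:
                    raise ParseError("bad edge line", location=lineno) from exc
                if i not in labels or j not in labels:
                    raise ParseError(f"unknown vertex index in edge ({i},{j})",
                                     location=lineno)
                graph.add_edge(labels[i], labels[j])
            else:
                raise ParseError("content before *Vertices header", location=lineno)
    if len(labels) != n_declared:
        raise ParseError(
            f"declared {n_declared} vertices but found {len(labels)} in {path}")
    return graph


# ---------------------------------------------------------------------------
# GMT gene-set collections
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT lines (set name, description, member genes...)."""
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"GMT row needs >=3 columns in {path}",
                                 location=lineno)
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets
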