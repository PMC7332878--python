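"""Dictionary-matching gene named-entity recognition.

Abstracts are segmented into sentences, tokenized with a rule-based English
tokenizer (whitespace + punctuation split, internal hyphens preserved so
symbols like ``IL-10`` or ``HLA-DRB1`` stay one token), and token n-grams
are matched longest-first against the gene dictionary.

Matching is case-insensitive by default.  Short symbols (three characters
or fewer) that collide with common English words — ``INS``, ``MET``,
``AR``, ``CAN`` and the like — are matched exact-case only, via a
configurable exception list, to keep precision high.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io import AbstractRecord, GeneEntry, validate_dictionary

# Sentence-terminal candidates are re-joined when the preceding token is a
# known abbreviation.
_ABBREVIATIONS = frozenset({
    "fig.", "figs.", "e.g.", "i.e.", "al.", "et al.", "etc.", "cf.",
    "dr.", "vs.", "no.", "approx.", "ca.", "ref.", "refs.",
})

# Common English words that double as short gene symbols; these require an
# exact-case match even when matching is otherwise case-insensitive.
_COMMON_WORDS = frozenset({
    "a", "an", "and", "all", "ar", "as", "at", "be", "by", "can", "do",
    "for", "had", "has", "he", "if", "in", "ins", "is", "it", "met", "no",
    "not", "of", "on", "or", "per", "set", "so", "the", "to", "up", "was",
})

_TOKEN_RE = re.compile(r"[A-Za-z0-9_]+(?:[-'/][A-Za-z0-9_]+)*|\S")
_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s|$)")


def split_sentences(text: str) -> list[str]:
    """Split text into sentences on terminal punctuation.

    A terminal mark does not end a sentence when the word it terminates is
    a known abbreviation ("Fig.", "e.g.", "et al.", ...).  Sentences are
    returned stripped of surrounding whitespace and are never empty; their
    in-order concatenation (with the stripped whitespace) reconstructs the
    input.
    """
    if not text.strip():
        return []
    sentences: list[str] = []
    start = 0
    for m in _BOUNDARY_RE.finditer(text):
        end = m.end()
        # word ending at this punctuation, including the punctuation itself
        prefix = text[start:end]
        last_word = prefix.split()[-1].lower() if prefix.split() else ""
        if last_word in _ABBREVIATIONS:
            continue
        # "et al." spans two words
        if last_word == "al." and prefix.lower().rstrip().endswith("et al."):
            continue
        chunk = text[start:end].strip()
        if chunk:
            sentences.append(chunk)
        start = end
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


@dataclass(frozen=True)
class Token:
    text: str
    start: int
    end: int  # half-open


def tokenize(sentence: str) -> list[Token]:
    """Tokenize a sentence into words and punctuation with character offsets.

    Word-internal hyphens, slashes and apostrophes are kept ("IL-10" is one
    token); every other non-space character is its own token.  Offsets are
    half-open, strictly increasing and non-overlapping.
    """
    return [Token(m.group(), m.start(), m.end())
            for m in _TOKEN_RE.finditer(sentence)]


@dataclass(frozen=True)
class GeneMention:
    """One matched dictionary surface within a sentence."""

    record_id: str
    sentence_index: int
    start: int
    end: int
    surface: str
    symbol: str


class GeneDictionary:
    """Surface-form index over gene entries for longest-match-first lookup.

    Multi-token synonyms are supported; lookup keys are token tuples.  The
    exact-case exception list defaults to dictionary surfaces of length
    <= 3 whose case-folded form is a common English word.
    """

    def __init__(self, entries: Sequence[GeneEntry],
                 exact_case_surfaces: Iterable[str] | None = None):
        validate_dictionary(entries)
        self.entries = tuple(entries)
        self.symbols = frozenset(e.symbol for e in entries)
        self._surface_to_symbol: dict[tuple[str, ...], str] = {}
        self._exact_surface_to_symbol: dict[tuple[str, ...], str] = {}
        surfaces: list[str] = []
        for e in entries:
            for surface in (e.symbol, *e.synonyms):
                surfaces.append(surface)
                key = tuple(t.text.casefold() for t in tokenize(surface))
                self._surface_to_symbol[key] = e.symbol
                exact_key = tuple(t.text for t in tokenize(surface))
                self._exact_surface_to_symbol[exact_key] = e.symbol
        if exact_case_surfaces is None:
            exact_case_surfaces = {s for s in surfaces
                                   if len(s) <= 3 and s.casefold() in _COMMON_WORDS}
        self.exact_case = frozenset(exact_case_surfaces)
        self._exact_forms = {tuple(t.text.casefold() for t in tokenize(s)): s
                             for s in self.exact_case}
        self.max_ngram = max(len(k) for k in self._surface_to_symbol)

    def lookup(self, tokens: Sequence[str], case_insensitive: bool = True
               ) -> str | None:
        """Map a token n-gram to its canonical symbol, or None."""
        key = tuple(t.casefold() for t in tokens)
        symbol = self._surface_to_symbol.get(key)
        if symbol is None:
            return None
        exact_form = self._exact_forms.get(key)
        if exact_form is not None:
            # short ambiguous surface: demand exact case regardless of flag
            if " ".join(tokens) != exact_form:
                return None
            return symbol
        if not case_insensitive:
            return self._exact_surface_to_symbol.get(tuple(tokens))
        return symbol


def match_genes(sentence: str, dictionary: GeneDictionary,
                case_insensitive: bool = True, record_id: str = "",
                sentence_index: int = 0) -> list[GeneMention]:
    """Find dictionary gene mentions in one sentence.

    Scans token n-grams longest-first; overlapping candidates resolve to
    the longer match, then the leftmost, so mentions never overlap.
    """
    tokens = tokenize(sentence)
    mentions: list[GeneMention] = []
    i = 0
    while i < len(tokens):
        matched = False
        for n in range(min(dictionary.max_ngram, len(tokens) - i), 0, -1):
            window = tokens[i:i + n]
            symbol = dictionary.lookup([t.text for t in window], case_insensitive)
            if symbol is not None:
                mentions.append(GeneMention(
                    record_id=record_id, sentence_index=sentence_index,
                    start=window[0].start, end=window[-1].end,
                    surface=sentence[window[0].start:window[-1].end],
                    symbol=symbol))
                i += n
                matched = True
                break
        if not matched:
            i += 1
    return mentions


@dataclass
class AnnotatedCorpus:
    """A corpus with per-record sentence lists and gene mentions.

    ``sentences[rid][k]`` is the text that ``mentions`` with that record id
    and ``sentence_index == k`` index into.  Record order is preserved.
    """

    records: list[AbstractRecord]
    sentences: dict[str, list[str]] = field(default_factory=dict)
    mentions: dict[str, list[GeneMention]] = field(default_factory=dict)

    def genes_in_record(self, record_id: str) -> set[str]:
        return {m.symbol for m in self.mentions.get(record_id, ())}


def annotate_corpus(corpus: Sequence[AbstractRecord],
                    dictionary: GeneDictionary,
                    case_insensitive: bool = True,
                    include_title: bool = False) -> AnnotatedCorpus:
    """Run sentence splitting and gene matching over a whole corpus.

    Deterministic and order-preserving.  Titles are excluded by default;
    ``include_title=True`` prepends the title as sentence material.
    """
    annotated = AnnotatedCorpus(records=list(corpus))
    for rec in corpus:
        text = f"{rec.title} {rec.abstract}" if include_title else rec.abstract
        sents = split_sentences(text)
        annotated.sentences[rec.record_id] = sents
        found: list[GeneMention] = []
        for k, sent in enumerate(sents):
            found.extend(match_genes(sent, dictionary, case_insensitive,
                                     record_id=rec.record_id, sentence_index=k))
        annotated.mentions[rec.record_id] = found
    return annotated


def write_mentions_tsv(annotated: AnnotatedCorpus, path) -> None:
    """Write mentions as TSV: record_id, sentence_index, start, end, surface, symbol."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("record_id\tsentence_index\tstart\tend\tsurface\tsymbol\n")
        for rec in annotated.records:
            for m in annotated.mentions.get(rec.record_id, ()):
                fh.write(f"{m.record_id}\t{m.sentence_index}\t{m.start}\t"
                         f"{m.end}\t{m.surface}\t{m.symbol}\n")
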