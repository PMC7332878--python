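import pytest

from zhengnet import ner, relations, synthetic
from zhengnet.io import GeneEntry


@pytest.fixture(scope="session")
def std_bundle():
    """Standard small synthetic bundle shared across tests (read-only)."""
    cfg = synthetic.SyntheticConfig(n_genes=15, n_abstracts=150, seed=42)
    dictionary, kb, corpus, truth, symptoms, hits, term_map = \
        synthetic.gen_bundle(cfg)
    return {
        "config": cfg, "dictionary": dictionary, "kb": kb, "corpus": corpus,
        "truth": truth, "symptoms": symptoms, "hits": hits,
        "term_map": term_map,
    }


@pytest.fixture(scope="session")
def std_annotated(std_bundle):
    gd = ner.GeneDictionary(std_bundle["dictionary"])
    return ner.annotate_corpus(std_bundle["corpus"], gd)


@pytest.fixture
def toy_entries():
    return [
        GeneEntry("BDNF", ("BDNF-1",)),
        GeneEntry("CXCR4", ()),
        GeneEntry("IL-10", ("IL10",)),
        GeneEntry("TRKB", ("TrkB receptor",)),
    ]


@pytest.fixture
def toy_dictionary(toy_entries):
    return ner.GeneDictionary(toy_entries)


@pytest.fixture
def separable_bags():
    """Linearly separable MIL fixture: positives carry a cue verb."""
    def bag(pair, texts, flag):
        instances = []
        for t in texts:
            a0 = t.index(pair[0])
            b0 = t.index(pair[1])
            instances.append(relations.Instance(
                "R1", 0, t, (a0, a0 + len(pair[0])), (b0, b0 + len(pair[1]))))
        return relations.Bag(tuple(sorted(pair)), instances, flag)

    pos = [
        bag(("AAA", "BBB"), ["AAA activates BBB strongly",
                             "AAA and BBB were seen"], 1),
        bag(("CCC", "DDD"), ["CCC inhibits DDD here"], 1),
        bag(("EEE", "FFF"), ["EEE binds FFF tightly"], 1),
    ]
    neg = [
        bag(("AAA", "CCC"), ["AAA and CCC were measured"], 0),
        bag(("BBB", "DDD"), ["BBB appeared near DDD today"], 0),
        bag(("EEE", "GGG"), ["EEE was assayed with GGG"], 0),
    ]
    return pos + neg
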