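"""Symptom-gene hits, pruning, combination enumeration and core genes."""

import numpy as np
import pytest

from zhengnet import combination as comb, datasets, ner
from zhengnet.errors import TermLookupError, ValidationError
from zhengnet.io import AbstractRecord, GeneEntry

ENTRIES = [GeneEntry("BDNF"), GeneEntry("CXCR4"), GeneEntry("AKT1")]


@pytest.fixture
def dictionary():
    return ner.GeneDictionary(ENTRIES)


class TestHits:
    def test_counts_match_exhaustive_record_scan(self, dictionary):
        corpus = [
            AbstractRecord("r1", "", "Dizziness was common. BDNF was high."),
            AbstractRecord("r2", "", "BDNF and dizziness were linked."),
            AbstractRecord("r3", "dizziness study", "BDNF in serum."),
            AbstractRecord("r4", "", "Dizziness without genes."),
            AbstractRecord("r5", "", "BDNF without the symptom."),
        ]
        hits = comb.count_symptom_gene_hits(corpus, dictionary, ["dizziness"])
        # oracle: direct scan over records
        expect = sum(1 for r in corpus
                     if "dizziness" in (r.title + " " + r.abstract).lower()
                     and "BDNF" in r.abstract)
        assert hits["dizziness"]["BDNF"] == expect == 3

    def test_symptom_absent_gives_zero_row(self, dictionary):
        corpus = [AbstractRecord("r1", "", "BDNF only.")]
        hits = comb.count_symptom_gene_hits(corpus, dictionary, ["vertigo"])
        assert not any(hits["vertigo"].values())
        assert comb.unmapped_symptoms(hits, ["vertigo"]) == {"vertigo"}

    def test_gene_absent_gives_zero_column(self, dictionary):
        corpus = [AbstractRecord("r1", "", "Dizziness and BDNF occurred.")]
        hits = comb.count_symptom_gene_hits(corpus, dictionary, ["dizziness"])
        assert hits["dizziness"].get("CXCR4", 0) == 0

    def test_multiword_symptom_token_matching(self, dictionary):
        corpus = [AbstractRecord("r1", "", "Chest pain with BDNF."),
                  AbstractRecord("r2", "", "Chestpain with BDNF.")]
        hits = comb.count_symptom_gene_hits(corpus, dictionary, ["chest pain"])
        assert hits["chest pain"]["BDNF"] == 1  # no substring-in-word match


class TestGenesForSymptom:
    HITS = {"dizziness": {"A": 3, "B": 0, "C": 5}}

    def test_min_hits_filter(self):
        assert comb.genes_for_symptom(self.HITS, "dizziness", 1) == {"A", "C"}
        assert comb.genes_for_symptom(self.HITS, "dizziness", 4) == {"C"}
        assert comb.genes_for_symptom(self.HITS, "dizziness", 6) == set()

    def test_random_table_equals_brute_force_filter(self):
        rng = np.random.default_rng(1)
        hits = {"s": {f"G{i}": int(rng.integers(0, 5)) for i in range(50)}}
        for mh in (1, 2, 3):
            brute = {g for g, c in hits["s"].items() if c >= mh}
            assert comb.genes_for_symptom(hits, "s", mh) == brute

    def test_unknown_symptom_rejected(self):
        with pytest.raises(TermLookupError):
            comb.genes_for_symptom(self.HITS, "nausea")


class TestPruning:
    def test_reference_chd_pruning(self):
        hits = datasets.hits_from_keyword_counts()
        pruned = comb.prune_unmapped_symptoms(datasets.CHD_CLASSIFICATION, hits)
        assert pruned.removed_terms == {"Chest heaviness", "Insomnia",
                                        "Tongue disorder"}
        assert pruned.fixed_terms == ("Palpitation",)

    def test_all_mapped_unchanged(self):
        cls = comb.SymptomClassification(
            "s", main=(("a",),), qi_deficiency=(("b",),), blood_stasis=(("c",),))
        hits = {t: {"G1": 2} for t in "abc"}
        assert comb.prune_unmapped_symptoms(cls, hits) == cls

    def test_group_reduced_but_nonempty_proceeds(self):
        cls = comb.SymptomClassification(
            "s", main=(("a",), ("d",)), qi_deficiency=(("b",),),
            blood_stasis=(("c",),))
        hits = {"a": {"G1": 1}, "b": {"G1": 1}, "c": {"G1": 1}, "d": {}}
        pruned = comb.prune_unmapped_symptoms(cls, hits)
        assert pruned.main == (("a",),)
        assert "d" in pruned.removed_terms

    def test_emptied_group_named_in_error(self):
        cls = comb.SymptomClassification(
            "s", main=(("a",),), qi_deficiency=(("b",),), blood_stasis=(("c",),))
        hits = {"a": {"G1": 1}, "b": {}, "c": {"G1": 1}}
        with pytest.raises(ValidationError, match="qi_deficiency"):
            comb.prune_unmapped_symptoms(cls, hits)


class TestEnumeration:
    def test_reference_chd_ten_combinations(self):
        pruned = comb.prune_unmapped_symptoms(
            datasets.CHD_CLASSIFICATION, datasets.hits_from_keyword_counts())
        combos = comb.enumerate_combinations(pruned)
        expected = [
            ("Chest pain", "Respiratory abnormality", "Palpitation", "Hemiplegia"),
            ("Chest pain", "Respiratory abnormality", "Palpitation", "Ecchymoses"),
            ("Chest pain", "Lassitude", "Palpitation", "Hemiplegia"),
            ("Chest pain", "Lassitude", "Palpitation", "Ecchymoses"),
            ("Chest pain", "Sweating", "Palpitation", "Hemiplegia"),
            ("Chest pain", "Sweating", "Palpitation", "Ecchymoses"),
            ("Chest pain", "Dizziness", "Palpitation", "Hemiplegia"),
            ("Chest pain", "Dizziness", "Palpitation", "Ecchymoses"),
            ("Chest pain", "Typhoid fever", "Palpitation", "Hemiplegia"),
            ("Chest pain", "Typhoid fever", "Palpitation", "Ecchymoses"),
        ]
        assert combos == expected

    def test_reference_stroke_six_combinations(self):
        pruned = comb.prune_unmapped_symptoms(
            datasets.STROKE_CLASSIFICATION, datasets.hits_from_keyword_counts())
        combos = comb.enumerate_combinations(pruned)
        assert len(combos) == 6
        assert combos[0] == ("Hemiplegia", "Stroke", "Respiratory abnormality",
                             "Lassitude", "Constipation", "Xerostomia",
                             "Headache", "Sputum", "Ecchymoses",
                             "Extremity Numbness")
        assert combos[1][-2:] == ("Glossitis", "Irritability")

    def test_single_option_groups(self):
        cls = comb.SymptomClassification(
            "s", main=(("a",),), qi_deficiency=(("b",),), blood_stasis=(("c",),))
        assert comb.enumerate_combinations(cls) == [("a", "b", "c")]

    def test_count_equals_group_product(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            sizes = rng.integers(1, 4, size=3)
            terms = iter(f"t{i}" for i in range(30))
            groups = [tuple((next(terms),) for _ in range(s)) for s in sizes]
            cls = comb.SymptomClassification("s", *groups)
            assert len(comb.enumerate_combinations(cls)) == int(np.prod(sizes))

    def test_empty_group_rejected(self):
        cls = comb.SymptomClassification("s", main=(), qi_deficiency=(("b",),),
                                         blood_stasis=(("c",),))
        with pytest.raises(ValidationError):
            comb.enumerate_combinations(cls)


def _random_hits(rng, n_terms=8, n_genes=20, p_zero=0.4):
    hits = {}
    for i in range(n_terms):
        hits[f"t{i}"] = {f"G{j}": int(rng.integers(0, 3))
                         if rng.random() > p_zero else 0
                         for j in range(n_genes)}
    return hits


class TestCoreGenes:
    def test_single_combination_is_union(self):
        hits = {"a": {"G1": 1}, "b": {"G2": 2}}
        assert comb.core_genes([("a", "b")], hits) == {"G1", "G2"}

    def test_disjoint_unions_empty(self):
        hits = {"a": {"G1": 1}, "b": {"G2": 1}}
        assert comb.core_genes([("a",), ("b",)], hits) == set()

    def test_matches_set_algebra_oracle(self):
        rng = np.random.default_rng(11)
        hits = _random_hits(rng)
        combos = [tuple(rng.choice([f"t{i}" for i in range(8)], size=3,
                                   replace=False)) for _ in range(5)]
        expected = None
        for c in combos:
            u = set()
            for t in c:
                u |= {g for g, n in hits[t].items() if n >= 1}
            expected = u if expected is None else expected & u
        assert comb.core_genes(combos, hits) == expected

    def test_result_subset_of_every_combination_union(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            hits = _random_hits(rng)
            combos = [tuple(rng.choice([f"t{i}" for i in range(8)], size=2,
                                       replace=False)) for _ in range(4)]
            core = comb.core_genes(combos, hits)
            for c in combos:
                union = set().union(*(comb.genes_for_symptom(hits, t)
                                      for t in c))
                assert core <= union

    def test_anti_monotone_in_combinations(self):
        rng = np.random.default_rng(9)
        hits = _random_hits(rng)
        combos = [tuple(rng.choice([f"t{i}" for i in range(8)], size=2,
                                   replace=False)) for _ in range(6)]
        prev = None
        for k in range(1, len(combos) + 1):
            cur = comb.core_genes(combos[:k], hits)
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_pruning_neutrality(self):
        """Dropping a zero-gene symptom from a combination never changes
        the core set (its union contribution is empty)."""
        hits = {"a": {"G1": 1, "G2": 1}, "b": {"G1": 1}, "z": {}}
        with_dead = comb.core_genes([("a", "z"), ("b", "z")], hits)
        without = comb.core_genes([("a",), ("b",)], hits)
        assert with_dead == without

    def test_intersection_within_mode(self):
        hits = {"a": {"G1": 1, "G2": 1}, "b": {"G2": 1}}
        assert comb.core_genes([("a", "b")], hits, within="intersection") == {"G2"}
        with pytest.raises(ValidationError):
            comb.core_genes([("a",)], hits, within="bogus")
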