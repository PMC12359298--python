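"""Apriori mining, association rules and pathway ranking.

The independent oracle for the miner is exhaustive enumeration: an
itemset of size >= 2 is frequent iff its support clears the rule floor
and each member gene clears the gene floor (equivalent to the level-wise
closure by anti-monotonicity); singles need only the gene floor.
"""

from fractions import Fraction
from itertools import chain, combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import crossmir as cm
from conftest import make_db


def exhaustive_frequent(db, min_item_support, min_rule_support):
    """Enumerate all 2^g - 1 itemsets under the two-threshold rule."""
    genes = sorted(db.gene_union())
    n = db.n_transactions
    sup = {}
    for size in range(1, len(genes) + 1):
        for items in combinations(genes, size):
            s = frozenset(items)
            sup[s] = Fraction(
                sum(1 for _, t in db.transactions if s <= t), n)
    frequent_genes = {g for g in genes
                      if sup[frozenset([g])] >= min_item_support}
    out = {}
    for s, value in sup.items():
        if len(s) == 1:
            if s <= frequent_genes and value >= min_item_support:
                out[s] = value
        elif s <= frequent_genes and value >= min_rule_support:
            out[s] = value
    return out


def random_db(rng, max_genes=12, max_tx=10):
    genes = [f"G{i}" for i in range(int(rng.integers(2, max_genes + 1)))]
    n_tx = int(rng.integers(1, max_tx + 1))
    sets = []
    for _ in range(n_tx):
        size = int(rng.integers(1, len(genes) + 1))
        sets.append(frozenset(rng.choice(genes, size=size, replace=False)))
    return make_db(*sets)


class TestSupport:
    def test_hand_counted_small_db(self):
        db = make_db({"A", "B"}, {"A"}, {"A", "B", "C"}, {"C"})
        s = cm.support({"A", "B"}, db)
        assert (s.count, s.support) == (2, Fraction(1, 2))

    def test_universal_gene_has_support_one(self):
        db = make_db({"A", "B"}, {"A"}, {"A", "C"})
        assert cm.support({"A"}, db).support == 1

    def test_matches_brute_force_on_random_dbs(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            db = random_db(rng, max_genes=8, max_tx=8)
            genes = sorted(db.gene_union())
            for size in (1, 2, 3):
                for items in combinations(genes[:6], size):
                    expected = sum(
                        1 for _, t in db.transactions if frozenset(items) <= t)
                    got = cm.support(frozenset(items), db)
                    assert got.count == expected
                    assert got.support == Fraction(expected, db.n_transactions)

    def test_empty_inputs_rejected(self):
        db = make_db({"A"})
        with pytest.raises(cm.ValidationError):
            cm.support(set(), db)
        with pytest.raises(cm.ValidationError):
            cm.support({"A"}, cm.TransactionDB())

    def test_rendering_rounds_half_up_to_four_places(self):
        assert cm.render_support(Fraction(78, 265)) == "0.2943"
        assert cm.render_support(Fraction(1, 8)) == "0.1250"
        assert cm.render_support(Fraction(1, 3)) == "0.3333"


class TestApriori:
    def params(self, item=Fraction(2, 5), rule=Fraction(1, 100)):
        return cm.MiningParams(min_item_support=item, min_rule_support=rule)

    def test_full_cooccurrence_yields_all_subsets(self):
        db = make_db(*[{"g1", "g2", "g3"}] * 5)
        out = cm.apriori(db, self.params())
        assert len(out) == 7  # all non-empty subsets of 3 genes
        assert all(f.support == 1 for f in out)

    def test_impossible_gene_floor_yields_nothing(self):
        db = make_db({"A"}, {"B"})
        out = cm.apriori(db, self.params(item=Fraction(1)))
        assert out == []

    def test_gene_floor_prunes_pairs_of_rare_genes(self):
        # B appears once in 5: below 0.4, so {A,B} must not surface even
        # though its support clears the 0.01 rule floor
        db = make_db({"A", "B"}, {"A"}, {"A"}, {"A"}, {"A"})
        out = cm.apriori(db, self.params())
        assert {tuple(sorted(f.itemset)) for f in out} == {("A",)}

    def test_sorted_by_support_then_size_then_items(self):
        db = make_db({"A", "B"}, {"A", "B"}, {"A", "C"}, {"C", "A"})
        out = cm.apriori(db, self.params(item=Fraction(1, 4)))
        keys = [f.sort_key() for f in out]
        assert keys == sorted(keys)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(25):
            db = random_db(rng)
            item = Fraction(int(rng.integers(1, 6)), 10)
            rule = Fraction(1, 100)
            params = cm.MiningParams(min_item_support=item,
                                     min_rule_support=rule)
            got = {f.itemset: f.support for f in cm.apriori(db, params)}
            assert got == exhaustive_frequent(db, item, rule)

    def test_reported_supports_reverify_via_support_op(self, default_run):
        for d in ("up", "down"):
            dr = default_run.per_direction[d]
            for f in dr.frequent:
                again = cm.support(f.itemset, dr.transactions)
                assert (again.count, again.support) == (f.count, f.support)

    def test_candidate_ceiling_guard(self):
        db = make_db(*[{f"G{i}" for i in range(12)}] * 3)
        params = cm.MiningParams(min_item_support=Fraction(1, 10),
                                 min_rule_support=Fraction(1, 100),
                                 candidate_ceiling=10)
        with pytest.raises(cm.ValidationError):
            cm.apriori(db, params)

    def test_max_itemset_size_truncates_levels(self):
        db = make_db(*[{"A", "B", "C"}] * 4)
        params = cm.MiningParams(min_item_support=Fraction(1, 2),
                                 min_rule_support=Fraction(1, 100),
                                 max_itemset_size=2)
        out = cm.apriori(db, params)
        assert max(len(f.itemset) for f in out) == 2

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.data())
    def test_anti_monotonicity_property(self, data):
        seed = data.draw(st.integers(0, 10**6))
        rng = np.random.default_rng(seed)
        db = random_db(rng, max_genes=8, max_tx=8)
        genes = sorted(db.gene_union())
        small = frozenset(data.draw(st.sets(st.sampled_from(genes),
                                            min_size=1, max_size=3)))
        extra = data.draw(st.sets(st.sampled_from(genes), max_size=3))
        big = small | frozenset(extra)
        assert cm.support(big, db).support <= cm.support(small, db).support


class TestAssociationRules:
    def test_contained_antecedent_gives_confidence_one(self):
        db = make_db({"A", "B"}, {"A", "B"}, {"C"}, {"D"})
        freq = cm.apriori(db, cm.MiningParams(min_item_support=Fraction(1, 4)))
        rules = {(tuple(sorted(r.antecedent)), tuple(sorted(r.consequent))): r
                 for r in cm.association_rules(freq, db)}
        r = rules[(("A",), ("B",))]
        assert r.confidence == 1
        assert r.support == Fraction(1, 2)

    def test_size_three_itemset_emits_six_rules(self):
        db = make_db(*[{"A", "B", "C"}] * 4)
        freq = cm.apriori(db, cm.MiningParams(min_item_support=Fraction(1, 2)))
        rules = cm.association_rules(freq, db)
        triple_rules = [r for r in rules
                        if r.antecedent | r.consequent == {"A", "B", "C"}]
        assert len(triple_rules) == 6

    def test_no_multi_itemsets_no_rules(self):
        db = make_db({"A"}, {"B"})
        freq = cm.apriori(db, cm.MiningParams(min_item_support=Fraction(1, 4)))
        assert cm.association_rules(freq, db) == []

    def test_rule_identity_exact_rationals(self, default_run):
        for d in ("up", "down"):
            dr = default_run.per_direction[d]
            for r in dr.rules[:200]:
                sa = cm.support(r.antecedent, dr.transactions).support
                assert r.confidence * sa == r.support  # exact Fractions


class TestRankPathways:
    def test_two_transaction_hand_case(self):
        db = make_db({"A", "B"}, {"A"}, ids=["P1", "P2"])
        scores = {s.pathway_id: s for s in cm.rank_pathways(db)}
        assert scores["P1"].score == Fraction(3, 4)
        assert scores["P2"].score == 1
        assert scores["P2"].rank == 1

    def test_identical_pathways_tie_by_id(self):
        db = make_db({"A", "B"}, {"A", "B"}, {"A", "B"}, ids=["Z", "M", "A"])
        ranked = cm.rank_pathways(db)
        assert [s.pathway_id for s in ranked] == ["A", "M", "Z"]
        assert len({s.score for s in ranked}) == 1
        assert [s.rank for s in ranked] == [1, 2, 3]

    def test_invariant_under_transaction_permutation(self):
        rng = np.random.default_rng(11)
        db = random_db(rng)
        base = [(s.pathway_id, s.score, s.rank) for s in cm.rank_pathways(db)]
        for _ in range(5):
            order = rng.permutation(len(db.transactions))
            shuffled = cm.TransactionDB(
                transactions=[db.transactions[i] for i in order])
            assert [(s.pathway_id, s.score, s.rank)
                    for s in cm.rank_pathways(shuffled)] == base


class TestMiningParams:
    @pytest.mark.parametrize("item, rule", [
        (Fraction(1, 100), Fraction(1, 10)),  # rule > item
        (0, Fraction(1, 100)),
        (Fraction(11, 10), Fraction(1, 100)),
    ])
    def test_threshold_ordering_enforced(self, item, rule):
        with pytest.raises(cm.ValidationError):
            cm.MiningParams(min_item_support=item, min_rule_support=rule)
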