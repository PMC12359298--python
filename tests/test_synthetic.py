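"""Planted-truth recovery and determinism of the synthetic generators."""

from fractions import Fraction

import pytest

import crossmir as cm
from crossmir.overlap import Direction
from crossmir.synthetic_data import (SyntheticConfig, generate_mti,
                                     generate_pathway_library,
                                     generate_study_tables)


class TestStudyTables:
    def test_planted_shared_counts_recovered(self, default_bundle):
        shared = cm.find_shared_mirnas(default_bundle.table_a,
                                       default_bundle.table_b)
        assert shared.up == default_bundle.study_truth.shared_up
        assert shared.down == default_bundle.study_truth.shared_down
        assert len(shared.up) == 10
        assert len(shared.down) == 11

    def test_conflicting_mirnas_excluded_with_planted_reason(self,
                                                             default_bundle):
        shared = cm.find_shared_mirnas(default_bundle.table_a,
                                       default_bundle.table_b)
        expected = default_bundle.study_truth.conflicting
        assert {m: r.value for m, r in shared.excluded.items()} == expected
        assert len(set(expected.values())) == 2  # both conflict subtypes

    def test_no_conflicts_when_disabled(self):
        cfg = SyntheticConfig(n_conflicting=0, n_specific_a=5, n_specific_b=5)
        ta, tb, truth = generate_study_tables(cfg)
        directions = {}
        for row in ta.rows + tb.rows:
            directions.setdefault(row.mirna_id, set()).add(row.direction)
        assert all(len(d) == 1 for d in directions.values())
        assert truth.conflicting == {}

    def test_same_seed_identical_tables(self):
        cfg = SyntheticConfig(seed=123)
        a1, b1, _ = generate_study_tables(cfg)
        a2, b2, _ = generate_study_tables(SyntheticConfig(seed=123))
        assert a1.rows == a2.rows
        assert b1.rows == b2.rows

    def test_distinct_mirna_totals_match_config(self, default_bundle):
        cfg = SyntheticConfig()
        expected_a = cfg.n_shared_up + cfg.n_shared_down + cfg.n_conflicting \
            + cfg.n_specific_a
        assert len(default_bundle.table_a.mirnas()) == expected_a == 124
        assert len(default_bundle.table_b.mirnas()) == 286


class TestMti:
    def test_absent_mirnas_reported_missing(self, default_bundle):
        shared = cm.find_shared_mirnas(default_bundle.table_a,
                                       default_bundle.table_b)
        targets = cm.collect_targets(
            shared, cm.filter_strong_mti(default_bundle.mti))
        assert targets.missing == default_bundle.mti_truth.absent

    def test_planted_target_counts_recovered(self, default_bundle):
        shared = cm.find_shared_mirnas(default_bundle.table_a,
                                       default_bundle.table_b)
        targets = cm.collect_targets(
            shared, cm.filter_strong_mti(default_bundle.mti))
        assert targets.up_targets == default_bundle.mti_truth.targets_up
        assert targets.down_targets == default_bundle.mti_truth.targets_down

    def test_no_weak_records_makes_filter_identity(self):
        cfg = SyntheticConfig(frac_weak_mti=0.0, absent_mirnas=())
        records, truth = generate_mti(cfg)
        assert cm.filter_strong_mti(records) == records
        assert truth.n_weak == 0

    def test_weak_only_mirna_contributes_zero_targets(self, default_bundle):
        truth = default_bundle.mti_truth
        strong = cm.filter_strong_mti(default_bundle.mti)
        weak_only = {r.mirna_id for r in default_bundle.mti
                     if not r.is_strong} & truth.absent
        assert weak_only  # the generator plants weak-only absences
        for mirna in weak_only:
            assert not any(r.mirna_id == mirna for r in strong)


class TestPathwayLibrary:
    def _db(self, bundle, direction):
        """Transactions straight from the planted library (bypassing
        enrichment): the planted pathway sets for one direction."""
        ids = bundle.pathway_truth.transaction_ids[direction.value]
        return cm.TransactionDB(transactions=[
            (pid, bundle.library.pathways[pid]) for pid in sorted(ids)])

    @pytest.mark.parametrize("direction", [Direction.UP, Direction.DOWN])
    def test_planted_joint_counts_exact(self, default_bundle, direction):
        db = self._db(default_bundle, direction)
        truth = default_bundle.pathway_truth
        n = truth.n_transactions[direction.value]
        assert db.n_transactions == n
        for items, count in truth.planted_counts[direction.value].items():
            got = cm.support(frozenset(items), db)
            assert got.count == count
            assert got.support == Fraction(count, n)

    @pytest.mark.parametrize("direction", [Direction.UP, Direction.DOWN])
    def test_every_planted_subset_count_exact(self, default_bundle, direction):
        db = self._db(default_bundle, direction)
        for items, count in (default_bundle.pathway_truth
                             .subset_counts[direction.value].items()):
            assert cm.support(frozenset(items), db).count == count

    def test_headline_pair_support_magnitude(self, default_bundle):
        db = self._db(default_bundle, Direction.DOWN)
        got = cm.support({"MAP2K1", "MAPK1"}, db)
        assert got.support == Fraction(78, 265)
        assert cm.render_support(got.support) == "0.2943"

    @pytest.mark.parametrize("direction", [Direction.UP, Direction.DOWN])
    def test_filler_genes_capped_below_planted_supports(self, default_bundle,
                                                        direction):
        db = self._db(default_bundle, direction)
        truth = default_bundle.pathway_truth
        planted = set(SyntheticConfig().planted_genes(direction))
        cap = truth.filler_cap_count[direction.value]
        counts = {}
        for _, genes in db.transactions:
            for g in genes - planted:
                counts[g] = counts.get(g, 0) + 1
        assert counts and max(counts.values()) <= cap

    def test_support_one_combo_present_everywhere(self):
        cfg = SyntheticConfig(
            n_pathways_up=0, n_pathways_down=20,
            planted_combos_down=((("GA", "GB"), Fraction(1)),),
            gene_support_floor_down=0.5, n_decoy_pathways=0,
            n_nonsig_pathways=0)
        library, truth = generate_pathway_library(cfg)
        assert truth.planted_counts["down"][("GA", "GB")] == 20
        assert all({"GA", "GB"} <= genes for genes in library.pathways.values()
                   if not genes.isdisjoint({"GA", "GB"}))
        n_with = sum(1 for g in library.pathways.values() if {"GA", "GB"} <= g)
        assert n_with == 20

    def test_inconsistent_planted_supports_rejected(self):
        # a pair planted rarer than its own superset triple is impossible
        cfg = SyntheticConfig(planted_combos_down=(
            (("GA", "GB", "GC"), Fraction(1, 2)),
            (("GA", "GB"), Fraction(1, 4)),
        ))
        with pytest.raises(cm.ValidationError, match="inconsistent"):
            generate_pathway_library(cfg)

    def test_same_seed_identical_library(self):
        l1, _ = generate_pathway_library(SyntheticConfig(seed=5))
        l2, _ = generate_pathway_library(SyntheticConfig(seed=5))
        assert l1.pathways == l2.pathways
        assert list(l1.pathways) == list(l2.pathways)


class TestDrugTable:
    def test_boundary_records_planted_per_gene(self, default_bundle):
        by_gene = {}
        for r in default_bundle.drugs:
            by_gene.setdefault(r.gene, []).append(r)
        for gene, recs in by_gene.items():
            scores = {r.interaction_score for r in recs}
            assert 0.10 in scores
            assert any(s < 0.10 for s in scores)
            assert any(r.interaction_score > 0.10 and not r.approved
                       for r in recs)

    def test_filter_recovers_exact_planted_passing_set(self, default_bundle):
        truth = default_bundle.drug_truth
        out = cm.filter_drugs(default_bundle.drugs, set(truth.passing))
        got = {g: [(r.drug, r.interaction_score) for r in lst]
               for g, lst in out.items()}
        assert got == truth.passing

    def test_empty_gene_list_empty_table(self):
        from crossmir.synthetic_data import generate_drug_table
        records, truth = generate_drug_table(SyntheticConfig(), set())
        assert records == [] and truth.passing == {}


class TestDeterminism:
    def test_full_bundle_reproducible(self):
        b1 = cm.generate_bundle(SyntheticConfig(seed=99))
        b2 = cm.generate_bundle(SyntheticConfig(seed=99))
        assert b1.table_a.rows == b2.table_a.rows
        assert b1.mti == b2.mti
        assert b1.library.pathways == b2.library.pathways
        assert b1.drugs == b2.drugs

    def test_sub_streams_independent(self):
        # changing the drug generator's parameters must not perturb the
        # study tables or the pathway library
        base = cm.generate_bundle(SyntheticConfig(seed=3))
        tweaked = cm.generate_bundle(SyntheticConfig(seed=3,
                                                     n_drugs_per_gene=9))
        assert base.table_a.rows == tweaked.table_a.rows
        assert base.library.pathways == tweaked.library.pathways
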