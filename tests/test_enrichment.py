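"""Venn partition, gene ranking, Fisher and elim over-representation."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from teratoclass import enrichment as en
from teratoclass import synthetic_data as sd


def _enumerate_tail(N, K, n, k):
    """Brute-force hypergeometric upper tail over all tables with fixed margins."""
    total = comb(N, n)
    return sum(
        comb(K, kk) * comb(N - K, n - kk)
        for kk in range(k, min(n, K) + 1)
        if n - kk <= N - K
    ) / total


class TestVennPartition:
    def test_cells_are_disjoint_and_conserve_unions(self):
        rng = np.random.default_rng(4)
        sets = {f"c{i}": set(rng.choice(100, rng.integers(5, 40), replace=False))
                for i in range(6)}
        labels = {f"c{i}": "teratogen" if i < 3 else "non_teratogen" for i in range(6)}
        part = en.venn_partition(sets, labels)
        assert not part.teratogen_only & part.non_teratogen_only
        assert not part.teratogen_only & part.overlap
        assert not part.non_teratogen_only & part.overlap
        union_ter = set().union(*(sets[c] for c in sets if labels[c] == "teratogen"))
        union_non = set().union(*(sets[c] for c in sets if labels[c] == "non_teratogen"))
        assert part.teratogen_only | part.overlap == union_ter
        assert part.non_teratogen_only | part.overlap == union_non

    def test_disjoint_unions_have_empty_overlap(self):
        part = en.venn_partition(
            {"t": {1, 2}, "n": {3, 4}}, {"t": "teratogen", "n": "non_teratogen"}
        )
        assert part.overlap == set()
        assert part.teratogen_only == {1, 2}
        assert part.non_teratogen_only == {3, 4}

    def test_identical_unions_leave_only_cells_empty(self):
        part = en.venn_partition(
            {"t": {1, 2}, "n": {1, 2}}, {"t": "teratogen", "n": "non_teratogen"}
        )
        assert part.overlap == {1, 2}
        assert part.teratogen_only == part.non_teratogen_only == set()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            en.venn_partition({"t": {1}}, {"t": "teratogen"})


def _table(rows):
    df = pd.DataFrame(rows, columns=["probe_id", "log2fc", "significant", "direction"])
    return df.set_index("probe_id")


class TestRankTopGenes:
    def test_more_compounds_outranks_fewer(self):
        tables = {
            f"c{i}": _table([("p1", 1.5, True, "up"), ("p2", 3.0, i < 1, "up" if i < 1 else "none")])
            for i in range(3)
        }
        ranked = en.rank_top_genes(["p1", "p2"], tables, {"p1": "G1", "p2": "G2"})
        assert list(ranked["probe_id"]) == ["p1", "p2"]
        assert ranked.iloc[0]["n_compounds"] == 3

    def test_gene_collapse_keeps_highest_ranked_probe(self):
        tables = {
            "c1": _table([("p1", 2.0, True, "up"), ("p2", 1.2, True, "up")]),
            "c2": _table([("p1", 2.0, True, "up"), ("p2", 1.2, False, "none")]),
        }
        ranked = en.rank_top_genes(["p1", "p2"], tables, {"p1": "G", "p2": "G"})
        assert len(ranked) == 1
        assert ranked.iloc[0]["probe_id"] == "p1"

    def test_tie_broken_by_mean_absolute_fold_change(self):
        # three probes significant in one compound each; |log2fc| decides
        tables = {
            "c1": _table(
                [("pA", 1.1, True, "up"), ("pB", -2.5, True, "down"), ("pC", 1.8, True, "up")]
            )
        }
        ranked = en.rank_top_genes(
            ["pA", "pB", "pC"], tables, {"pA": "GA", "pB": "GB", "pC": "GC"}
        )
        assert list(ranked["probe_id"]) == ["pB", "pC", "pA"]

    def test_suffix_filter_keeps_only_specific_probe_classes(self):
        tables = {
            "c1": _table(
                [
                    ("100_at", 2.0, True, "up"),
                    ("101_a_at", 2.0, True, "up"),
                    ("102_s_at", 2.0, True, "up"),
                    ("103_x_at", 2.0, True, "up"),
                ]
            )
        }
        cell = ["100_at", "101_a_at", "102_s_at", "103_x_at"]
        genes = {p: f"G{p}" for p in cell}
        ranked = en.rank_top_genes(cell, tables, genes, suffix_filter=True)
        assert set(ranked["probe_id"]) == {"100_at", "101_a_at", "102_s_at"}

    def test_unmapped_probe_retained_and_flagged(self):
        tables = {"c1": _table([("p1", 2.0, True, "up")])}
        ranked = en.rank_top_genes(["p1"], tables, {})
        assert ranked.iloc[0]["gene_id"] == "p1"
        assert bool(ranked.iloc[0]["unmapped"])


class TestFisherOverrep:
    def test_small_closed_form(self):
        # universe 4, study 2, term 2, overlap 2: C(2,2)C(2,0)/C(4,2) = 1/6
        p = en.fisher_overrep({"a", "b"}, {"a", "b", "c", "d"}, {"a", "b"})
        assert p == pytest.approx(1 / 6)

    def test_empty_overlap_is_one(self):
        assert en.fisher_overrep(set(), {"a", "b"}, {"a"}) == 1.0
        assert en.fisher_overrep({"b"}, {"a", "b"}, {"a"}) == 1.0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            en.fisher_overrep({"a"}, set(), {"a"})

    def test_matches_full_enumeration_on_random_tables(self):
        rng = np.random.default_rng(12)
        universe = [f"g{i}" for i in range(12)]
        for _ in range(40):
            study = set(rng.choice(universe, rng.integers(1, 8), replace=False))
            term = set(rng.choice(universe, rng.integers(1, 8), replace=False))
            k = len(study & term)
            p = en.fisher_overrep(study, universe, term)
            if k == 0:
                assert p == 1.0
            else:
                assert p == pytest.approx(
                    _enumerate_tail(12, len(term), len(study), k), abs=1e-12
                )


class TestGoElim:
    def _chain(self):
        # R <- A <- B; study genes all sit on the leaf B
        parents = {"R": [], "A": ["R"], "B": ["A"]}
        annotations = {
            "B": {"g0", "g1", "g2", "g3"},
            "A": {"g4", "g5"},
            "R": {"g6", "g7", "g8", "g9"},
        }
        universe = {f"g{i}" for i in range(10)}
        study = {"g0", "g1", "g2", "g3"}
        return en.OntologyDAG(parents, annotations=annotations), study, universe

    def test_chain_elimination_matches_hand_computation(self):
        dag, study, universe = self._chain()
        res = en.go_elim(dag, study, universe, elim_cutoff=0.01).set_index("term_id")
        # leaf: all 4 study genes among its 4 annotated, p = 1/C(10,4) = 1/210
        assert res.at["B", "p_raw"] == pytest.approx(1 / 210)
        # the leaf is significant, so its study genes leave the ancestors'
        # tables: overlap 0, p = 1 for both A and R
        assert res.at["A", "p_raw"] == 1.0
        assert res.at["R", "p_raw"] == 1.0
        assert res.at["A", "count"] == 0

    def test_chain_classic_keeps_parent_signal(self):
        dag, study, universe = self._chain()
        res = en.go_elim(dag, study, universe, method="classic").set_index("term_id")
        # classic parent table: 6 annotated, overlap 4 -> p = 15/210 = 1/14
        assert res.at["A", "p_raw"] == pytest.approx(1 / 14)
        assert res.at["B", "p_raw"] == pytest.approx(1 / 210)

    def test_flat_ontology_equals_classic_fisher(self):
        parents = {"R": []} | {f"L{i}": ["R"] for i in range(4)}
        annotations = {f"L{i}": {f"g{4 * i + j}" for j in range(4)} for i in range(4)}
        dag = en.OntologyDAG(parents, annotations=annotations)
        universe = {f"g{i}" for i in range(16)}
        study = {"g0", "g1", "g2", "g3", "g15"}
        res_elim = en.go_elim(dag, study, universe, elim_cutoff=0.01)
        res_classic = en.go_elim(dag, study, universe, method="classic")
        merged = res_elim.merge(res_classic, on="term_id", suffixes=("_e", "_c"))
        np.testing.assert_allclose(merged["p_raw_e"], merged["p_raw_c"])

    def test_zero_cutoff_disables_elimination(self):
        dag = sd.generate_toy_ontology(seed=7, n_terms=15, n_genes=40)
        universe = dag.annotated_genes()
        study = set(sorted(universe)[:12])
        res_off = en.go_elim(dag, study, universe, elim_cutoff=0.0)
        res_classic = en.go_elim(dag, study, universe, method="classic")
        merged = res_off.merge(res_classic, on="term_id", suffixes=("_e", "_c"))
        np.testing.assert_allclose(merged["p_raw_e"], merged["p_raw_c"])

    def test_elim_never_below_classic(self):
        # eliminated genes can only shrink a term's overlap
        dag = sd.generate_toy_ontology(seed=19, n_terms=20, n_genes=60)
        universe = dag.annotated_genes()
        rng = np.random.default_rng(3)
        study = set(rng.choice(sorted(universe), 20, replace=False))
        res_elim = en.go_elim(dag, study, universe).set_index("term_id")
        res_classic = en.go_elim(dag, study, universe, method="classic").set_index("term_id")
        for term in dag.terms:
            assert res_elim.at[term, "p_raw"] >= res_classic.at[term, "p_raw"] - 1e-12

    def test_bh_preserves_raw_order(self):
        dag = sd.generate_toy_ontology(seed=2, n_terms=12, n_genes=30)
        universe = dag.annotated_genes()
        study = set(sorted(universe)[:10])
        res = en.go_elim(dag, study, universe)
        assert (res["p_raw"].diff().dropna() >= -1e-15).all()
        assert (res["p_fdr"].diff().dropna() >= -1e-15).all()

    def test_cyclic_graph_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            en.OntologyDAG({"A": ["B"], "B": ["A"]})

    def test_multi_root_rejected(self):
        with pytest.raises(ValueError, match="root"):
            en.OntologyDAG({"A": [], "B": []})


class TestPathwayEnrich:
    def test_pathway_equal_to_study_attains_margin_minimum(self):
        universe = {f"g{i}" for i in range(20)}
        study = {"g0", "g1", "g2"}
        res = en.pathway_enrich(study, universe, {"P1": study}).set_index("pathway_id")
        expect = 1 / comb(20, 3)  # all three draws inside the 3-gene pathway
        assert res.at["P1", "p_raw"] == pytest.approx(expect)
        assert res.at["P1", "gene_ratio"] == 1.0

    def test_disjoint_pathway_is_null(self):
        universe = {f"g{i}" for i in range(10)}
        res = en.pathway_enrich({"g0"}, universe, {"P1": {"g5", "g6"}}).set_index(
            "pathway_id"
        )
        assert res.at["P1", "p_raw"] == 1.0
        assert res.at["P1", "gene_ratio"] == 0.0

    def test_gene_ratio_denominator_excludes_unmapped_study_genes(self):
        universe = {f"g{i}" for i in range(10)}
        study = {"g0", "g1", "g9"}  # g9 maps to no pathway
        res = en.pathway_enrich(
            study, universe, {"P1": {"g0", "g1"}, "P2": {"g5"}}
        ).set_index("pathway_id")
        assert res.at["P1", "gene_ratio"] == pytest.approx(1.0)  # 2 of 2 mapped

    def test_empty_pathway_map_rejected(self):
        with pytest.raises(ValueError):
            en.pathway_enrich({"g0"}, {"g0"}, {})


class TestOntologyIO:
    def test_obo_round_trip(self, tmp_path):
        dag = sd.generate_toy_ontology(seed=5, n_terms=8, n_genes=12)
        obo = tmp_path / "toy.obo"
        ann = tmp_path / "ann.tsv"
        dag.write_obo(obo)
        dag.write_annotation_tsv(ann)
        back = en.OntologyDAG.from_obo(obo, annotations_path=ann)
        assert set(back.terms) == set(dag.terms)
        assert back.root == dag.root
        assert back.propagated_annotations() == dag.propagated_annotations()
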