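"""Classical DE baseline, ORA with exact oracles, KO metrics, sweeps."""

import itertools
import math
from math import comb

import numpy as np
import pandas as pd
import pytest

from highedges.evaluation import (
    classical_sweep,
    evaluate_external_table,
    evaluate_ko,
    highedges_sweep,
    induced_subgraph,
    ora,
    select_de_genes,
)
from highedges.pathway_io import (
    InteractionEdge,
    Pathway,
    PathwayCollection,
    build_global_graph,
)


def collection(mapping):
    return PathwayCollection(
        Pathway(pid, pid, set(genes)) for pid, genes in mapping.items()
    )


def hypergeom_upper_tail(overlap, universe, pathway, drawn):
    """Exact oracle: sum of hypergeometric point masses for X >= overlap."""
    total = 0.0
    for x in range(overlap, min(pathway, drawn) + 1):
        total += comb(pathway, x) * comb(universe - pathway, drawn - x) / comb(
            universe, drawn
        )
    return total


class TestSelectDeGenes:
    def test_thresholds_and_universe(self, stats_frame):
        stats = stats_frame({"A": (1.2, 0.001), "B": (0.5, 0.001), "C": (2.0, 0.5)})
        assert select_de_genes(stats, 1.0, 2.0, {"A", "B", "C"}) == ["A"]
        assert select_de_genes(stats, 1.0, 2.0, {"B", "C"}) == []

    def test_zero_cuts_select_all_universe_genes(self, stats_frame):
        stats = stats_frame({"A": (0.1, 0.9), "B": (0.0, 1.0)})
        assert select_de_genes(stats, 0.0, 0.0, {"A", "B"}) == ["A", "B"]

    def test_monotone_in_both_cuts(self, stats_frame):
        rng = np.random.default_rng(6)
        stats = stats_frame(
            {f"g{i}": (float(rng.normal(0, 2)), float(rng.uniform())) for i in range(60)}
        )
        universe = set(stats.index)
        for fc1, fc2 in [(0.0, 0.5), (0.5, 1.0)]:
            for p1, p2 in [(0.0, 0.5), (0.5, 1.5)]:
                loose = set(select_de_genes(stats, fc1, p1, universe))
                tight = set(select_de_genes(stats, fc2, p2, universe))
                assert tight <= loose


class TestInducedSubgraph:
    def graph(self, pairs):
        return build_global_graph(
            [InteractionEdge(a, b, True, "activation", {"P"}) for a, b in pairs]
        )

    def test_singletons_retained(self):
        g = self.graph([("A", "B"), ("C", "D")])
        mech = induced_subgraph(g, ["A", "B", "C"])
        assert len(mech.edges) == 1
        assert {frozenset(c) for c in mech.components} == {
            frozenset({"A", "B"}), frozenset({"C"})
        }

    def test_no_internal_edges_all_singletons(self):
        g = self.graph([("A", "B")])
        mech = induced_subgraph(g, ["A", "C", "D"])
        assert len(mech.edges) == 0
        assert len(mech.components) == 3

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(13)
        genes = [f"g{i}" for i in range(15)]
        pairs = set()
        while len(pairs) < 25:
            a, b = rng.choice(genes, 2, replace=False)
            pairs.add(tuple(sorted((a, b))))
        g = self.graph(sorted(pairs))
        subset = list(rng.choice(genes, 8, replace=False))
        mech = induced_subgraph(g, subset)
        expected = {
            (a, b) for a, b in pairs if a in set(subset) and b in set(subset)
        }
        assert set(map(tuple, mech.edges[["gene_a", "gene_b"]].to_numpy())) == expected


class TestOra:
    def test_full_overlap_closed_form(self):
        universe = {f"u{i}" for i in range(20)}
        pw_genes = set(list(sorted(universe))[:5])
        pathways = collection({"P1": pw_genes})
        out = ora(sorted(pw_genes), pathways, universe)
        assert out.iloc[0].p_value == pytest.approx(1 / comb(20, 5), rel=1e-12)

    def test_overlap_zero_has_p_one(self):
        universe = {f"u{i}" for i in range(10)}
        pathways = collection({"P1": {"u0", "u1"}})
        out = ora(["u5"], pathways, universe)
        assert out.iloc[0].overlap in (0, 1)
        none = ora([], pathways, universe)
        assert none.iloc[0].p_value == pytest.approx(1.0)

    def test_bh_ladder_closed_form(self):
        universe = {f"u{i}" for i in range(40)}
        ordered = sorted(universe)
        # four pathways engineered to give increasing raw p-values
        pathways = collection(
            {f"P{k}": set(ordered[:5 + 3 * k]) for k in range(4)}
        )
        out = ora(ordered[:5], pathways, universe)
        raw = out["p_value"].to_numpy()
        m = len(raw)
        order = np.argsort(raw)
        expected = np.empty(m)
        running = 1.0
        for rank_from_end, idx in enumerate(order[::-1]):
            rank = m - rank_from_end
            running = min(running, raw[idx] * m / rank)
            expected[idx] = running
        np.testing.assert_allclose(out["fdr"], expected, rtol=1e-12)

    def test_bh_flat_example(self):
        # classic ladder: (0.01, 0.02, 0.03, 0.04) over 4 tests -> all 0.04
        from statsmodels.stats.multitest import multipletests

        _, fdr, *_ = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")
        np.testing.assert_allclose(fdr, 0.04)

    def test_exact_enumeration_small_universes(self):
        rng = np.random.default_rng(8)
        for universe_size in (8, 14, 21, 30):
            universe = {f"u{i}" for i in range(universe_size)}
            ordered = sorted(universe)
            for pw_size in (2, universe_size // 3, universe_size - 1):
                pathways = collection({"P": set(ordered[:pw_size])})
                for list_size in (1, universe_size // 2, universe_size):
                    gene_list = list(rng.choice(ordered, list_size, replace=False))
                    out = ora(gene_list, pathways, universe)
                    overlap = len(set(gene_list) & set(ordered[:pw_size]))
                    expected = hypergeom_upper_tail(
                        overlap, universe_size, pw_size, list_size
                    )
                    assert out.iloc[0].p_value == pytest.approx(expected, rel=1e-10)

    def test_empty_universe_is_error(self):
        with pytest.raises(ValueError, match="universe"):
            ora(["A"], collection({"P1": {"A"}}), set())

    def test_single_test_bh_identity(self):
        universe = {f"u{i}" for i in range(12)}
        pathways = collection({"P1": set(sorted(universe)[:4])})
        out = ora(sorted(universe)[:4], pathways, universe)
        assert out.iloc[0].fdr == pytest.approx(out.iloc[0].p_value)


def ora_table(fdrs, positives, pathway_ids=None):
    ids = pathway_ids or [f"P{i}" for i in range(len(fdrs))]
    return pd.DataFrame(
        {"pathway_id": ids, "fdr": fdrs, "list_size": 5}
    ), collection({pid: {"KO" if pid in positives else "x", "y"} for pid in ids})


class TestEvaluateKo:
    def test_mixed_counts(self):
        fdrs = [0.01] * 3 + [0.01, 0.01] + [0.5] * 8
        tab, paths = ora_table(fdrs, positives={"P0", "P1", "P2"})
        res = evaluate_ko(tab, "KO", paths)
        assert res.tpr == 1.0
        assert res.fpr == pytest.approx(0.2)
        assert res.positive_lr == pytest.approx(5.0)

    def test_nothing_significant(self):
        tab, paths = ora_table([0.9] * 6, positives={"P0"})
        res = evaluate_ko(tab, "KO", paths)
        assert (res.tpr, res.fpr, res.positive_lr) == (0.0, 0.0, 0.0)

    def test_alpha_above_one_marks_everything(self):
        tab, paths = ora_table([0.3, 1.0, 0.8], positives={"P1"})
        res = evaluate_ko(tab, "KO", paths, alpha=1.0001)
        assert (res.tpr, res.fpr) == (1.0, 1.0)

    def test_infinite_lr_when_no_false_positive(self):
        tab, paths = ora_table([0.01, 0.9, 0.9], positives={"P0"})
        res = evaluate_ko(tab, "KO", paths)
        assert math.isinf(res.positive_lr)

    def test_ko_outside_all_pathways_is_error(self):
        tab, paths = ora_table([0.1, 0.2], positives=set())
        with pytest.raises(ValueError, match="no ground-truth positives"):
            evaluate_ko(tab, "KO", paths)

    def test_rates_nondecreasing_in_alpha(self):
        rng = np.random.default_rng(31)
        fdrs = rng.uniform(0, 1, 20)
        tab, paths = ora_table(list(fdrs), positives={"P0", "P3", "P7"})
        prev = (0.0, 0.0)
        for alpha in (0.01, 0.05, 0.1, 0.3, 0.7, 1.01):
            res = evaluate_ko(tab, "KO", paths, alpha=alpha)
            assert res.tpr >= prev[0] and res.fpr >= prev[1]
            prev = (res.tpr, res.fpr)

    def test_external_table_adapter(self):
        paths = collection({"P0": {"KO", "a"}, "P1": {"b", "c"}})
        tab = pd.DataFrame({"pathway_id": ["P0", "P1"], "p_value": [0.001, 0.8]})
        res = evaluate_external_table(tab, "KO", paths)
        assert res.tpr == 1.0 and res.fpr == 0.0


class TestSweeps:
    @pytest.fixture()
    def fixture(self, ko_experiment):
        from highedges.diffexpr import moderated_t_test
        from highedges.pathway_io import build_global_graph

        edges, pathways, truth, data = ko_experiment(seed=12)
        stats = moderated_t_test(data)
        graph = build_global_graph(edges)
        return stats, graph, pathways, truth

    def test_single_cell_equals_direct_composition(self, fixture):
        stats, graph, pathways, truth = fixture
        table, best = classical_sweep(
            stats, graph, pathways, truth.ko_gene,
            fc_grid=[1.0], p_grid=[2.0],
        )
        assert len(table) == 1
        universe = pathways.gene_universe() & set(stats.index)
        genes = select_de_genes(stats, 1.0, 2.0, universe)
        direct = evaluate_ko(
            ora(genes, pathways, universe), truth.ko_gene, pathways
        )
        row = table.iloc[0]
        assert (row.tpr, row.fpr) == (direct.tpr, direct.fpr)
        assert row.n_genes == len(genes)

    def test_grid_matches_cell_by_cell_recomputation(self, fixture):
        stats, graph, pathways, truth = fixture
        fc_grid, p_grid = [0.5, 1.0, 2.0], [0.5, 2.0, 4.0]
        table, best = classical_sweep(
            stats, graph, pathways, truth.ko_gene, fc_grid=fc_grid, p_grid=p_grid
        )
        assert len(table) == 9
        universe = pathways.gene_universe() & set(stats.index)
        best_lr, best_key = -1.0, None
        for fc_cut, p_cut in itertools.product(fc_grid, p_grid):
            genes = select_de_genes(stats, fc_cut, p_cut, universe)
            if genes:
                res = evaluate_ko(
                    ora(genes, pathways, universe), truth.ko_gene, pathways
                )
                lr, tpr = res.positive_lr, res.tpr
            else:
                lr = tpr = 0.0
            row = table[(table.fc_cut == fc_cut) & (table.p_cut == p_cut)].iloc[0]
            assert row.positive_lr == pytest.approx(lr)
            if (lr, tpr) > (best_lr, -1):
                best_lr, best_key = lr, (fc_cut, p_cut)
        assert best.positive_lr == pytest.approx(best_lr)

    def test_gene_count_monotone_when_loosening(self, fixture):
        stats, graph, pathways, truth = fixture
        table, _ = classical_sweep(
            stats, graph, pathways, truth.ko_gene,
            fc_grid=[0.5, 1.5], p_grid=[0.5, 3.0],
        )
        loosest = table[(table.fc_cut == 0.5) & (table.p_cut == 0.5)].iloc[0]
        assert (table["n_genes"] <= loosest.n_genes).all()

    def test_highedges_sweep_matches_recomputation(self, fixture):
        from highedges.scoring import score_graph

        stats, graph, pathways, truth = fixture
        scored, _ = score_graph(graph, stats)
        grid = np.linspace(2.0, scored["score"].max(), 5)
        table = highedges_sweep(
            scored, graph, pathways, truth.ko_gene, threshold_grid=grid
        )
        assert table["is_default"].sum() == 1
        universe = pathways.gene_universe() & (
            set(scored["gene_a"]) | set(scored["gene_b"])
        )
        for cutoff in grid:
            keep = scored[scored["score"] >= cutoff]
            genes = sorted((set(keep.gene_a) | set(keep.gene_b)) & universe)
            res = evaluate_ko(
                ora(genes, pathways, universe), truth.ko_gene, pathways
            )
            row = table[np.isclose(table.score_cutoff, cutoff)].iloc[0]
            assert row.tpr == pytest.approx(res.tpr)
            assert row.fpr == pytest.approx(res.fpr)

    def test_extreme_cutoffs(self, fixture):
        from highedges.scoring import score_graph

        stats, graph, pathways, truth = fixture
        scored, _ = score_graph(graph, stats)
        top = scored["score"].max()
        table = highedges_sweep(
            scored, graph, pathways, truth.ko_gene,
            threshold_grid=[scored["score"].min() - 1.0, top],
        )
        low = table.iloc[0]
        assert low.n_edges == len(scored)
        top_row = table[np.isclose(table.score_cutoff, top)].iloc[0]
        n_top = int((scored["score"] >= top).sum())
        assert top_row.n_edges == n_top
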