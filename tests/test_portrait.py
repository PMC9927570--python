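import itertools

import numpy as np
import pytest

from conftest import make_dataset
from nspa.data import MISSING
from nspa.infotheory import all_pairs_information_gain
from nspa.network import EpistasisNetwork, build_network
from nspa.portrait import (
    PairClassProportions,
    build_subject_network,
    class_balance_weight,
    delta_degree_transform,
    edge_sign,
    fit_pair_statistics,
)


def graph_of(edges) -> EpistasisNetwork:
    import networkx as nx

    g = nx.Graph()
    for u, v in edges:
        g.add_edge(u, v, weight=1.0)
    return EpistasisNetwork(g, tau=0.0)


def stats_from_counts(counts: dict, n_case: int, n_control: int, **kw) -> PairClassProportions:
    return PairClassProportions(
        edges=sorted(counts),
        counts={e: np.asarray(c, dtype=np.int64) for e, c in counts.items()},
        n_case=n_case,
        n_control=n_control,
        training_subject_ids=[],
        **kw,
    )


def brute_delta(dataset, stats, nodes):
    """Independent per-subject sign-then-count oracle."""
    out = np.zeros((dataset.n_subjects, len(nodes)), dtype=int)
    for i, sid in enumerate(dataset.subject_ids):
        geno = dict(zip(dataset.variant_ids, dataset.genotypes.codes[i]))
        for u, v in stats.edges:
            s = edge_sign(stats, (u, v), geno[u], geno[v])
            for node in (u, v):
                j = nodes.index(node)
                if s == "+":
                    out[i, j] -= 1
                elif s == "-":
                    out[i, j] += 1
    return out


class TestFit:
    def test_direct_counting(self):
        codes = np.array([[0, 0], [0, 0], [1, 1], [1, 1]])
        ds = make_dataset(codes, [1, 1, 0, 0])
        stats = fit_pair_statistics(ds, graph_of([("rs0", "rs1")]))
        p = stats.proportions(("rs0", "rs1"))
        assert p[0, 0, 1] == 1.0  # all cases carry (0,0)
        assert p[1, 1, 0] == 1.0  # all controls carry (1,1)
        assert p.sum() == pytest.approx(2.0)

    def test_class_normalisation(self, rng):
        codes = rng.integers(0, 3, (30, 3))
        ds = make_dataset(codes, [i % 2 for i in range(30)])
        stats = fit_pair_statistics(ds, graph_of([("rs0", "rs1"), ("rs1", "rs2")]))
        for e in stats.edges:
            p = stats.proportions(e)
            assert p[:, :, 0].sum() == pytest.approx(1.0)
            assert p[:, :, 1].sum() == pytest.approx(1.0)

    def test_unbalanced_cohort_proportions(self, cohort19):
        """Within-class proportions equal raw counts over 10 (cases) and 9 (controls)."""
        stats = fit_pair_statistics(cohort19, graph_of([("rs0", "rs1")]))
        c = stats.counts[("rs0", "rs1")]
        assert c[:, :, 1].sum() == 10 and c[:, :, 0].sum() == 9
        p = stats.proportions(("rs0", "rs1"))
        assert np.allclose(p[:, :, 1], c[:, :, 1] / 10)
        assert np.allclose(p[:, :, 0], c[:, :, 0] / 9)

    def test_single_class_rejected(self):
        ds = make_dataset(np.zeros((3, 2), dtype=int), [1, 1, 1])
        with pytest.raises(Exception):
            fit_pair_statistics(ds, graph_of([("rs0", "rs1")]))

    def test_missing_rows_excluded_per_pair(self):
        codes = np.array([[0, 0, 1], [MISSING, 0, 1], [1, 1, 0], [1, 1, 0]])
        ds = make_dataset(codes, [1, 1, 0, 0])
        stats = fit_pair_statistics(ds, graph_of([("rs0", "rs1"), ("rs1", "rs2")]))
        assert stats.counts[("rs0", "rs1")].sum() == 3  # one subject dropped here
        assert stats.counts[("rs1", "rs2")].sum() == 4  # but not here


class TestEdgeSign:
    def test_case_enriched_is_plus(self):
        c = np.zeros((3, 3, 2), dtype=int)
        c[0, 0] = [1, 2]  # P(case)=0.2 vs P(ctl)=0.1 given totals below
        c[1, 1] = [9, 8]
        stats = stats_from_counts({("u", "v"): c}, 10, 10)
        assert edge_sign(stats, ("u", "v"), 0, 0) == "+"

    def test_control_enriched_is_minus(self):
        c = np.zeros((3, 3, 2), dtype=int)
        c[0, 0] = [3, 0]
        c[1, 1] = [7, 10]
        stats = stats_from_counts({("u", "v"): c}, 10, 10)
        assert edge_sign(stats, ("u", "v"), 0, 0) == "-"

    def test_tie_resolves_to_plus(self):
        c = np.zeros((3, 3, 2), dtype=int)
        c[0, 0] = [3, 3]
        c[1, 1] = [17, 17]
        stats = stats_from_counts({("u", "v"): c}, 20, 20)
        assert edge_sign(stats, ("u", "v"), 0, 0) == "+"

    def test_zero_evidence_absent_by_default(self):
        c = np.zeros((3, 3, 2), dtype=int)
        c[0, 0] = [5, 5]
        stats = stats_from_counts({("u", "v"): c}, 5, 5)
        assert edge_sign(stats, ("u", "v"), 2, 2) == "absent"

    def test_zero_evidence_literal_mode_is_plus(self):
        c = np.zeros((3, 3, 2), dtype=int)
        c[0, 0] = [5, 5]
        stats = stats_from_counts({("u", "v"): c}, 5, 5, zero_evidence="plus")
        assert edge_sign(stats, ("u", "v"), 2, 2) == "+"

    def test_missing_genotype_is_absent(self):
        c = np.ones((3, 3, 2), dtype=int)
        stats = stats_from_counts({("u", "v"): c}, 9, 9)
        assert edge_sign(stats, ("u", "v"), MISSING, 1) == "absent"

    def test_unknown_edge_raises(self):
        stats = stats_from_counts({("u", "v"): np.ones((3, 3, 2), dtype=int)}, 9, 9)
        with pytest.raises(KeyError):
            edge_sign(stats, ("x", "y"), 0, 0)


class TestCountModeEquivalence:
    def test_example_weight(self):
        assert class_balance_weight(10, 9) == pytest.approx(10 / 9)

    def test_balanced_weight_is_one(self):
        assert class_balance_weight(7, 7) == 1.0

    def test_zero_class_rejected(self):
        with pytest.raises(ValueError):
            class_balance_weight(0, 5)

    def test_modes_agree_on_random_tables(self, rng):
        """Proportion and weighted-count comparisons are the same rule."""
        for _ in range(200):
            c = rng.integers(0, 6, (3, 3, 2))
            if c[:, :, 0].sum() == 0 or c[:, :, 1].sum() == 0:
                continue
            stats = stats_from_counts(
                {("u", "v"): c}, int(c[:, :, 1].sum()), int(c[:, :, 0].sum())
            )
            t_prop = stats.sign_table(("u", "v"), mode="proportion")
            t_count = stats.sign_table(("u", "v"), mode="count")
            assert (t_prop == t_count).all()


class TestSubjectNetwork:
    def test_signs_match_per_edge_oracle(self, cohort19):
        edges = [("rs0", "rs1"), ("rs1", "rs2"), ("rs0", "rs2")]
        stats = fit_pair_statistics(cohort19, graph_of(edges))
        for i in range(cohort19.n_subjects):
            geno = dict(zip(cohort19.variant_ids, cohort19.genotypes.codes[i]))
            signed = build_subject_network(geno, graph_of(edges), stats)
            for u, v, s in signed:
                c = stats.counts[(u, v)]
                au, av = geno[u], geno[v]
                if c[au, av].sum() == 0:
                    assert s == "absent"
                else:
                    expect = "+" if c[au, av, 1] / 10 >= c[au, av, 0] / 9 else "-"
                    assert s == expect

    def test_missing_node_makes_edges_absent(self):
        codes = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2], [0, 1, 2]])
        ds = make_dataset(codes, [1, 0, 1, 0])
        edges = [("rs0", "rs1"), ("rs0", "rs2"), ("rs1", "rs2")]
        stats = fit_pair_statistics(ds, graph_of(edges))
        geno = {"rs0": MISSING, "rs1": 1, "rs2": 2}
        signed = dict(((u, v), s) for u, v, s in build_subject_network(geno, graph_of(edges), stats))
        assert signed[("rs0", "rs1")] == "absent"
        assert signed[("rs0", "rs2")] == "absent"
        assert signed[("rs1", "rs2")] != "absent" or stats.counts[("rs1", "rs2")][1, 2].sum() == 0


class TestDeltaDegree:
    def star_stats(self, signs):
        """Star network u0 center with leaves; all subjects' pairs hit cell (0,0)."""
        counts = {}
        for k, s in enumerate(signs):
            c = np.zeros((3, 3, 2), dtype=int)
            # both classes total 2; cell (0,0) enriched for the wanted class
            c[0, 0] = [1, 2] if s == "+" else [2, 1]
            c[2, 2] = [1, 0] if s == "+" else [0, 1]
            counts[("a0", f"b{k}")] = c
        return stats_from_counts(counts, 2, 2)

    def test_mixed_signs_arithmetic(self):
        stats = self.star_stats(["-", "-", "-", "+"])
        ds = make_dataset(np.zeros((2, 5), dtype=int), [1, 0])
        ds.genotypes.variant_ids[:] = ["a0", "b0", "b1", "b2", "b3"]
        net = graph_of(stats.edges)
        tm = delta_degree_transform(ds, net, stats)
        assert tm.values[0, tm.variant_ids.index("a0")] == 2  # 3 minus, 1 plus

    @pytest.mark.parametrize("sign,expect", [("+", -4), ("-", 4)])
    def test_range_endpoints(self, sign, expect):
        stats = self.star_stats([sign] * 4)
        ds = make_dataset(np.zeros((2, 5), dtype=int), [1, 0])
        ds.genotypes.variant_ids[:] = ["a0", "b0", "b1", "b2", "b3"]
        tm = delta_degree_transform(ds, graph_of(stats.edges), stats)
        assert tm.values[0, tm.variant_ids.index("a0")] == expect

    def test_matches_brute_oracle(self, rng):
        codes = rng.integers(0, 3, (25, 5))
        codes[rng.random(codes.shape) < 0.1] = MISSING
        ds = make_dataset(codes, [i % 2 for i in range(25)])
        edges = [("rs0", "rs1"), ("rs1", "rs2"), ("rs2", "rs3"), ("rs0", "rs3"), ("rs3", "rs4")]
        net = graph_of(edges)
        stats = fit_pair_statistics(ds, net)
        tm = delta_degree_transform(ds, net, stats)
        assert (tm.values == brute_delta(ds, stats, tm.variant_ids)).all()

    def test_values_within_degree_bounds(self, rng):
        codes = rng.integers(0, 3, (40, 6))
        ds = make_dataset(codes, [i % 2 for i in range(40)])
        scores = all_pairs_information_gain(ds)
        net = build_network(scores, -1.0)  # complete graph
        stats = fit_pair_statistics(ds, net)
        tm = delta_degree_transform(ds, net, stats)
        for j, v in enumerate(tm.variant_ids):
            assert np.abs(tm.values[:, j]).max() <= net.degree(v)

    def test_isolated_variant_changes_nothing(self, rng):
        codes = rng.integers(0, 3, (30, 4))
        ds = make_dataset(codes, [i % 2 for i in range(30)])
        net = graph_of([("rs0", "rs1")])
        stats = fit_pair_statistics(ds, net)
        base = delta_degree_transform(ds, net, stats)
        wider = make_dataset(np.column_stack([codes, rng.integers(0, 3, 30)]),
                             [i % 2 for i in range(30)])
        again = delta_degree_transform(wider, net, fit_pair_statistics(wider, net))
        assert (base.values == again.values).all()
        assert base.variant_ids == again.variant_ids

    def test_subject_reordering_equivariance(self, rng):
        codes = rng.integers(0, 3, (20, 4))
        y = np.array([i % 2 for i in range(20)])
        ds = make_dataset(codes, y)
        net = graph_of([("rs0", "rs1"), ("rs2", "rs3")])
        stats = fit_pair_statistics(ds, net)
        tm = delta_degree_transform(ds, net, stats)
        perm = rng.permutation(20)
        tm2 = delta_degree_transform(ds.subset_subjects(perm), net, stats)
        assert (tm2.values == tm.values[perm]).all()

    def test_deterministic(self, rng):
        codes = rng.integers(0, 3, (30, 4))
        ds = make_dataset(codes, [i % 2 for i in range(30)])
        net = graph_of([("rs0", "rs1"), ("rs1", "rs2")])
        a = delta_degree_transform(ds, net, fit_pair_statistics(ds, net)).values
        b = delta_degree_transform(ds, net, fit_pair_statistics(ds, net)).values
        assert (a == b).all()
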