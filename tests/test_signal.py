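"""Signal-variation algebra: e_se pairs, effector ASV, pathway ASV."""

import numpy as np
import pytest

from spfa.pathways import find_effectors, upstream_distances
from spfa.signal import (
    CorrelationCache,
    UpstreamLink,
    effector_asv,
    pair_signal_variation,
    pathway_asv,
)

from conftest import make_dataset, make_graph, pearson


def random_dataset(rng, genes, n_per_cond=6):
    vals = {g: (rng.normal(size=n_per_cond), rng.normal(size=n_per_cond)) for g in genes}
    return make_dataset(vals)


class TestPairSignalVariation:
    def test_identical_joint_values_give_zero(self):
        ds = make_dataset({
            "gs": ([1, 2, 3, 4], [1, 2, 3, 4]),
            "ge": ([2, 1, 4, 3], [2, 1, 4, 3]),
        })
        link = pair_signal_variation(ds, "gs", "ge", 1)
        assert link.e_se == pytest.approx(0.0, abs=1e-12)

    def test_maximal_flip_halved_by_distance(self):
        # disease: perfectly correlated; normal: perfectly anti-correlated
        ds = make_dataset({
            "gs": ([1, 2, 3], [1, 2, 3]),
            "ge": ([3, 2, 1], [2, 4, 6]),
        })
        link = pair_signal_variation(ds, "gs", "ge", 2)
        assert link.cor_disease == pytest.approx(1.0)
        assert link.cor_normal == pytest.approx(-1.0)
        assert link.e_se == pytest.approx(1.0)

    def test_matches_textbook_pearson_on_fixture(self):
        gs_d, ge_d = [1, 2, 3, 4], [1, 2, 3, 5]
        gs_n, ge_n = [1, 2, 3, 4], [4, 2, 3, 1]
        ds = make_dataset({"gs": (gs_n, gs_d), "ge": (ge_n, ge_d)})
        link = pair_signal_variation(ds, "gs", "ge", 1)
        expected = abs(pearson(gs_d, ge_d) - pearson(gs_n, ge_n))
        assert link.e_se == pytest.approx(expected, rel=1e-12)
        assert link.cor_disease == pytest.approx(pearson(gs_d, ge_d), rel=1e-12)

    def test_unmeasured_gene_is_degenerate_zero(self):
        ds = make_dataset({"gs": ([1, 2, 3], [1, 2, 3])})
        link = pair_signal_variation(ds, "gs", "missing", 1)
        assert link.degenerate and link.e_se == 0.0

    def test_constant_within_one_condition_is_degenerate(self):
        ds = make_dataset({
            "gs": ([5, 5, 5], [1, 2, 3]),
            "ge": ([1, 2, 3], [3, 1, 2]),
        })
        link = pair_signal_variation(ds, "gs", "ge", 1)
        assert link.degenerate and link.e_se == 0.0
        assert link.cor_normal is None

    def test_distance_below_one_rejected(self):
        ds = make_dataset({"gs": ([1, 2], [1, 2]), "ge": ([1, 2], [1, 2])})
        with pytest.raises(ValueError, match="d_se"):
            pair_signal_variation(ds, "gs", "ge", 0)
        with pytest.raises(ValueError, match="d_se"):
            UpstreamLink("a", "b", 0, None, None, 0.0)

    def test_bound_by_two_over_distance(self, rng):
        ds = random_dataset(rng, ["a", "b"])
        for d in (1, 2, 5):
            link = pair_signal_variation(ds, "a", "b", d)
            assert 0.0 <= link.e_se <= 2.0 / d


class TestEffectorASV:
    def test_single_upstream_equals_single_link(self, rng):
        g = make_graph([("A", "B")])
        ds = random_dataset(rng, ["A", "B"])
        prof = effector_asv(ds, g, "B")
        assert prof.s == 1
        assert prof.asv == pytest.approx(
            pair_signal_variation(ds, "A", "B", 1).e_se
        )

    def test_identical_conditions_zero(self, chain_graph, rng):
        x = {g: rng.normal(size=5) for g in "ABC"}
        ds = make_dataset({g: (x[g], x[g]) for g in "ABC"})
        prof = effector_asv(ds, chain_graph, "C")
        assert prof.asv == pytest.approx(0.0, abs=1e-12)

    def test_four_node_fixture_matches_hand_sum(self, rng):
        # A -> B -> D, C -> D: links to D are (A,2), (B,1), (C,1)
        g = make_graph([("A", "B"), ("B", "D"), ("C", "D")])
        ds = random_dataset(rng, list("ABCD"))
        prof = effector_asv(ds, g, "D")
        expected = sum(
            pair_signal_variation(ds, s, "D", d).e_se
            for s, d in [("A", 2), ("B", 1), ("C", 1)]
        )
        assert prof.s == 3
        assert prof.asv == pytest.approx(expected, rel=1e-12)


class TestPathwayASV:
    def test_no_effectors_flagged_zero(self, rng):
        cyc = make_graph([("A", "B"), ("B", "A")])
        ds = random_dataset(rng, ["A", "B"])
        pasv = pathway_asv(ds, cyc)
        assert pasv.no_effectors and pasv.k == 0 and pasv.asv == 0.0

    def test_additivity_over_disjoint_chains(self, rng):
        g = make_graph([("A", "B"), ("C", "D")])
        ds = random_dataset(rng, list("ABCD"))
        pasv = pathway_asv(ds, g)
        assert pasv.k == 2
        by_eff = {p.g_i: p.asv for p in pasv.profiles}
        assert pasv.asv == pytest.approx(by_eff["B"] + by_eff["D"])

    def test_matches_brute_force_all_pairs_oracle(self, rng):
        g = make_graph([("A", "B"), ("B", "C"), ("A", "C"), ("D", "B")])
        ds = random_dataset(rng, list("ABCD"))
        pasv = pathway_asv(ds, g)
        # oracle: every (ancestor, effector) pair at its shortest distance
        total = 0.0
        for e in find_effectors(g):
            for s, d in upstream_distances(g, e).items():
                total += pair_signal_variation(ds, s, e, d).e_se
        assert pasv.asv == pytest.approx(total, rel=1e-12)

    def test_unmeasured_node_keeps_topology(self, rng):
        """A missing middle gene still relays distance but scores zero itself."""
        g = make_graph([("A", "M"), ("M", "C")])
        ds = random_dataset(rng, ["A", "C"])  # M unmeasured
        pasv = pathway_asv(ds, g)
        link_by_src = {l.g_s: l for l in pasv.profiles[0].links}
        assert link_by_src["M"].degenerate
        assert link_by_src["A"].d_se == 2  # distance still runs through M
        assert pasv.asv == pytest.approx(link_by_src["A"].e_se)


class TestAlgebraicInvariants:
    def test_relay_insertion_halves_pair_score(self, rng):
        ds = random_dataset(rng, ["S", "R", "E"])
        direct = make_graph([("S", "E")])
        relayed = make_graph([("S", "R"), ("R", "E")])
        e1 = {l.g_s: l.e_se for p in pathway_asv(ds, direct).profiles for l in p.links}
        e2 = {l.g_s: l.e_se for p in pathway_asv(ds, relayed).profiles for l in p.links}
        assert e2["S"] == pytest.approx(e1["S"] / 2.0, rel=1e-12)

    def test_condition_swap_symmetry(self, rng):
        for trial in range(50):
            n_vals = rng.normal(size=(2, 5))
            d_vals = rng.normal(size=(2, 5))
            ds = make_dataset({"a": (n_vals[0], d_vals[0]), "b": (n_vals[1], d_vals[1])})
            swapped = make_dataset({"a": (d_vals[0], n_vals[0]), "b": (d_vals[1], n_vals[1])})
            d = int(rng.integers(1, 4))
            assert pair_signal_variation(ds, "a", "b", d).e_se == pytest.approx(
                pair_signal_variation(swapped, "a", "b", d).e_se, rel=1e-10
            )

    def test_positive_scaling_invariance(self, rng):
        for trial in range(50):
            n_vals = rng.normal(size=(2, 5))
            d_vals = rng.normal(size=(2, 5))
            scale = float(rng.uniform(0.01, 100))
            ds = make_dataset({"a": (n_vals[0], d_vals[0]), "b": (n_vals[1], d_vals[1])})
            scaled = make_dataset(
                {"a": (scale * n_vals[0], scale * d_vals[0]), "b": (n_vals[1], d_vals[1])}
            )
            assert pair_signal_variation(ds, "a", "b", 1).e_se == pytest.approx(
                pair_signal_variation(scaled, "a", "b", 1).e_se, abs=1e-10
            )

    def test_three_level_additivity_randomized(self, rng):
        """Pathway ASV == sum over effectors == sum over links, on random
        graphs and data (>= 200 cases including the loops above)."""
        for trial in range(100):
            n = int(rng.integers(3, 7))
            names = [f"g{i}" for i in range(n)]
            edges = {
                (names[a], names[b])
                for a, b in zip(rng.integers(0, n, 10), rng.integers(0, n, 10))
            }
            graph = make_graph(edges, nodes=names)
            ds = random_dataset(rng, names, n_per_cond=4)
            pasv = pathway_asv(ds, graph)
            assert pasv.asv == pytest.approx(sum(p.asv for p in pasv.profiles), rel=1e-12)
            for p in pasv.profiles:
                assert p.asv == pytest.approx(sum(l.e_se for l in p.links), rel=1e-12)
                assert p.s == len(p.links)

    def test_copied_data_gives_zero_everywhere(self, rng):
        names = [f"g{i}" for i in range(5)]
        x = {g: rng.normal(size=6) for g in names}
        ds = make_dataset({g: (x[g], x[g]) for g in names})
        graph = make_graph([(names[0], names[1]), (names[1], names[2]),
                            (names[3], names[2]), (names[2], names[4])])
        assert pathway_asv(ds, graph).asv == pytest.approx(0.0, abs=1e-12)


class TestCorrelationCache:
    def test_cache_matches_numpy_corrcoef(self, rng):
        ds = random_dataset(rng, ["a", "b", "c"])
        cache = CorrelationCache(ds)
        for cond in ("normal", "disease"):
            x = ds.values_for(cond)
            expected = np.corrcoef(x)
            for i in range(3):
                for j in range(3):
                    assert cache.corr(i, j, cond) == pytest.approx(
                        expected[i, j], rel=1e-10
                    )

    def test_vectorized_matches_scalar_route(self, rng):
        ds = random_dataset(rng, ["a", "b", "c", "d"])
        cache = CorrelationCache(ds)
        si = np.array([0, 1, 2, -1])
        ei = np.array([3, 3, 3, 3])
        d = np.array([1, 2, 3, 1])
        vec = cache.pair_variations(si, ei, d)
        for k, (i, j, dd) in enumerate(zip(si, ei, d)):
            if i < 0:
                assert vec[k] == 0.0
                continue
            gs, ge = ds.genes[i], ds.genes[j]
            assert vec[k] == pytest.approx(
                pair_signal_variation(ds, gs, ge, int(dd)).e_se, rel=1e-12
            )
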