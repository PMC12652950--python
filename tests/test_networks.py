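"""PCIT, network assembly, hubs and differential connectivity."""

import numpy as np
import pandas as pd
import pytest

from rewirenet import (
    SimConfig,
    build_group_network,
    cpm,
    differential_connectivity,
    exclusive_hubs,
    find_hubs,
    partial_correlation,
    pcit,
    pcit_reference,
    simulate_counts,
)
from rewirenet.networks import GroupNetwork, _pcit_pairs


def _random_corr(rng, n=30, samples=10):
    return np.corrcoef(rng.standard_normal((n, samples)))


class TestPcit:
    def test_partial_correlation_closed_form(self):
        for r in (-0.9, -0.3, 0.0, 0.5, 0.99):
            assert partial_correlation(r, 0.0, 0.0) == r

    def test_worked_triad_keeps_only_the_direct_edge(self):
        c = np.array([[1.0, 0.9, 0.0], [0.9, 1.0, 0.0], [0.0, 0.0, 1.0]])
        sig = pcit(c)
        assert sig[0, 1] and sig[1, 0]
        assert not sig[0, 2] and not sig[1, 2]

    def test_identity_matrix_yields_no_edges(self):
        assert pcit(np.eye(5)).sum() == 0

    def test_production_equals_bruteforce_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            c = _random_corr(rng)
            assert np.array_equal(pcit(c), pcit_reference(c))

    def test_pair_targeted_equals_full(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            c = _random_corr(rng, n=25, samples=8)
            full = pcit(c)
            iu, ju = np.triu_indices(25, k=1)
            targeted = _pcit_pairs(c, np.column_stack([iu, ju]))
            assert np.array_equal(full[iu, ju], targeted)

    def test_output_symmetric_within_nonzero_support(self):
        rng = np.random.default_rng(12)
        c = _random_corr(rng)
        sig = pcit(c)
        assert np.array_equal(sig, sig.T)
        assert not sig[c == 0.0].any()

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            pcit(np.array([[1.0, 2.0], [2.0, 1.0]]))
        with pytest.raises(ValueError):
            pcit(np.full((4, 4), 1.5))


class TestGroupNetwork:
    @pytest.fixture()
    def logcpm(self, small_sim):
        counts, samples, _, _ = small_sim
        g2 = samples.loc[samples.group == "subfertile", "sample"]
        return cpm(counts, log=True)[g2]

    def test_impossible_threshold_gives_empty_network(self, logcpm, small_sim):
        _, _, tfs, truth = small_sim
        net = build_group_network(logcpm, list(truth.de_genes), tfs, r_cut=1.01)
        assert len(net.edges) == 0

    def test_membership_filter_excludes_outsider_pairs(self):
        # two perfectly correlated genes, neither DEG nor TF
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(
            [base, base * 2, rng.normal(size=5), rng.normal(size=5)],
            index=["a", "b", "c", "d"],
        )
        net = build_group_network(mat, deg_ids=["c"], tf_ids=[])
        pairs = set(map(tuple, net.edges[["gene_a", "gene_b"]].to_numpy()))
        assert ("a", "b") not in pairs

    def test_raising_r_cut_never_adds_edges(self, logcpm, small_sim):
        _, _, tfs, truth = small_sim
        loose = build_group_network(logcpm, list(truth.de_genes), tfs, r_cut=0.95)
        strict = build_group_network(logcpm, list(truth.de_genes), tfs, r_cut=0.99)
        loose_pairs = set(map(tuple, loose.edges[["gene_a", "gene_b"]].to_numpy()))
        strict_pairs = set(map(tuple, strict.edges[["gene_a", "gene_b"]].to_numpy()))
        assert strict_pairs <= loose_pairs

    def test_hub_module_connects_only_in_rewired_group(self):
        wins = 0
        for seed in range(5):
            counts, samples, tfs, truth = simulate_counts(SimConfig(seed=300 + seed))
            lc = cpm(counts, log=True)
            g1 = samples.loc[samples.group == "fertile", "sample"]
            g2 = samples.loc[samples.group == "subfertile", "sample"]
            keep = (lc[g1].var(axis=1) > 0) & (lc[g2].var(axis=1) > 0)
            uni = lc.loc[keep]
            degs = list(truth.de_genes)
            hub = set(truth.hub_module)

            def module_edges(frame):
                net = build_group_network(frame, degs, tfs)
                inside = net.edges["gene_a"].isin(hub) & net.edges["gene_b"].isin(hub)
                return int(inside.sum())

            wins += int(module_edges(uni[g2]) > module_edges(uni[g1]))
        assert wins >= 4


class TestHubs:
    def _net(self, edges):
        frame = pd.DataFrame(edges, columns=["gene_a", "gene_b"])
        frame["r"] = 1.0
        frame["p"] = 0.0
        degree = (
            pd.concat([frame["gene_a"], frame["gene_b"]]).value_counts().sort_index()
        )
        nodes = sorted(set(frame["gene_a"]) | set(frame["gene_b"]))
        return GroupNetwork("g", frame, degree.rename("degree"), nodes)

    def test_star_center_is_unique_hub(self):
        net = self._net([("hub", f"leaf{i:02d}") for i in range(20)])
        hubs, threshold = find_hubs(net)
        assert hubs == ["hub"]
        assert threshold < 20

    def test_uniform_degrees_give_no_hubs(self):
        nodes = [f"n{i}" for i in range(5)]
        edges = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1 :]]
        hubs, _ = find_hubs(self._net(edges))
        assert hubs == []

    def test_empty_network_raises(self):
        net = GroupNetwork("g", pd.DataFrame(columns=["gene_a", "gene_b", "r", "p"]),
                           pd.Series(dtype=float), [])
        with pytest.raises(ValueError):
            find_hubs(net)


class TestExclusiveHubs:
    def test_identical_and_disjoint(self):
        only1, only2, shared = exclusive_hubs({"a", "b"}, {"a", "b"})
        assert only1 == set() and only2 == set() and shared == {"a", "b"}
        only1, only2, shared = exclusive_hubs({"a"}, {"b"})
        assert shared == set()

    def test_reported_hub_partition_arithmetic(self):
        # |A| = 47, |B| = 215, |A & B| = 16 -> 31 and 199 exclusives
        a = {f"x{i}" for i in range(47)}
        b = {f"x{i}" for i in range(31, 31 + 215)}
        only_a, only_b, shared = exclusive_hubs(a, b)
        assert len(shared) == 16
        assert len(only_a) == 31
        assert len(only_b) == 199


class TestDifferentialConnectivity:
    def _nets(self, edges1, edges2, universe):
        def make(edges, label):
            frame = pd.DataFrame(edges, columns=["gene_a", "gene_b"])
            frame["r"] = 1.0
            frame["p"] = 0.0
            degree = (
                pd.concat([frame["gene_a"], frame["gene_b"]])
                .value_counts()
                .sort_index()
                .rename("degree")
            )
            return GroupNetwork(label, frame, degree, universe)

        return make(edges1, "one"), make(edges2, "two")

    def test_identical_networks_are_all_null(self):
        edges = [("a", "b"), ("b", "c")]
        n1, n2 = self._nets(edges, edges, ["a", "b", "c"])
        table = differential_connectivity(n1, n2)
        assert np.allclose(table["dk"], 0.0)
        assert not table["significant"].any()

    def test_missing_top_gene_reaches_the_bound(self):
        n1, n2 = self._nets(
            [("a", "b"), ("a", "c"), ("b", "c")],
            [("b", "c")],
            ["a", "b", "c"],
        )
        table = differential_connectivity(n1, n2)
        assert table.loc["a", "dk"] == pytest.approx(1.0)

    def test_swapping_networks_negates_dk_and_z(self):
        counts, samples, tfs, truth = simulate_counts(SimConfig(seed=77))
        lc = cpm(counts, log=True)
        g1 = samples.loc[samples.group == "fertile", "sample"]
        g2 = samples.loc[samples.group == "subfertile", "sample"]
        keep = (lc[g1].var(axis=1) > 0) & (lc[g2].var(axis=1) > 0)
        uni = lc.loc[keep]
        degs = list(truth.de_genes)
        n1 = build_group_network(uni[g1], degs, tfs, group="fertile")
        n2 = build_group_network(uni[g2], degs, tfs, group="subfertile")
        fwd = differential_connectivity(n1, n2)
        rev = differential_connectivity(n2, n1)
        assert np.allclose(fwd["dk"], -rev["dk"], atol=1e-12)
        assert np.allclose(fwd["dk_z"], -rev["dk_z"], atol=1e-12)

    def test_mismatched_universes_rejected(self):
        n1, n2 = self._nets([("a", "b")], [("a", "b")], ["a", "b"])
        n2.universe = ["a", "b", "c"]
        with pytest.raises(ValueError):
            differential_connectivity(n1, n2)
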