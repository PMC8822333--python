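"""Association matrix, cutoff rule, communities, centrality, summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from neurometab.errors import (
    ConfigurationError,
    EmptyNetworkError,
    InputError,
)
from neurometab.network import (
    AssociationMatrix,
    BipartiteNetwork,
    build_network,
    compute_association_matrix,
    compute_centrality,
    detect_communities,
    modularity_score,
    select_cutoff,
    summarize_clusters,
)


def assoc_from_r(r, p=None):
    r = np.asarray(r, dtype=float)
    return AssociationMatrix(
        r=r,
        p=np.zeros_like(r) if p is None else np.asarray(p, dtype=float),
        n=100,
        voxel_ids=[f"V{i}" for i in range(r.shape[0])],
        metabolite_ids=[f"M{j}" for j in range(r.shape[1])],
    )


class TestAssociation:
    def test_perfect_linear_pairs(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        X = x[:, None]
        M = np.stack([2 * x, x[::-1] * 2], axis=1)
        a = compute_association_matrix(X, M)
        np.testing.assert_allclose(a.r[0], [1.0, -1.0], atol=1e-12)
        assert a.p[0, 0] < 1e-6

    def test_metabolite_equals_voxel_column(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (30, 3))
        a = compute_association_matrix(X, X[:, :1])
        assert a.r[0, 0] == pytest.approx(1.0)

    def test_constant_column_flagged_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (20, 2))
        X[:, 1] = 5.0
        M = rng.normal(0, 1, (20, 2))
        with pytest.warns(UserWarning, match="constant"):
            a = compute_association_matrix(X, M)
        assert np.all(a.r[1] == 0.0) and np.all(a.p[1] == 1.0)

    def test_too_few_subjects(self):
        with pytest.raises(InputError):
            compute_association_matrix(np.ones((3, 2)), np.ones((3, 2)))

    def test_spls_mode_bounded_and_signed(self):
        rng = np.random.default_rng(2)
        z = rng.normal(0, 1, 60)
        X = z[:, None] + rng.normal(0, 0.3, (60, 5))
        M = np.hstack([z[:, None] + rng.normal(0, 0.3, (60, 3)),
                       rng.normal(0, 1, (60, 10))])
        a = compute_association_matrix(X, M, mode="spls")
        assert np.abs(a.r).max() <= 1.0
        # the coupled block carries the strongest associations, positive sign
        assert a.r[:, :3].mean() > 2 * np.abs(a.r[:, 3:]).mean()

    def test_unknown_mode(self):
        with pytest.raises(ConfigurationError):
            compute_association_matrix(np.ones((5, 1)), np.ones((5, 1)), mode="x")


class TestCutoff:
    def test_row_maxima_definition(self):
        a = assoc_from_r([[0.9, 0.2], [0.1, 0.4]])
        assert select_cutoff(a) == pytest.approx(0.4)

    def test_single_pair(self):
        a = assoc_from_r([[0.6]])
        assert select_cutoff(a) == pytest.approx(0.6)

    def test_alpha_masking_and_warning(self):
        r = [[0.9, 0.2], [0.5, 0.3]]
        p = [[0.001, 0.001], [0.9, 0.9]]  # second voxel never passes alpha
        a = assoc_from_r(r, p)
        with pytest.warns(UserWarning, match="no metabolite passing alpha"):
            assert select_cutoff(a) == pytest.approx(0.9)

    def test_cutoff_property_on_random_matrices(self):
        # at the cutoff every voxel keeps >= 1 edge; epsilon above, some voxel
        # loses all of its edges
        rng = np.random.default_rng(3)
        for _ in range(10):
            Z = rng.normal(0, 1, (40, 15))
            M = rng.normal(0, 1, (40, 25))
            a = compute_association_matrix(Z, M)
            a.p[:] = 0.0  # isolate the |r| rule from the alpha rule
            c = select_cutoff(a)
            keep = np.abs(a.r) >= c
            assert keep.any(axis=1).all()
            keep_up = np.abs(a.r) >= c + 1e-9
            assert not keep_up.any(axis=1).all()


class TestBuildNetwork:
    def test_cutoff_one_empty(self):
        a = assoc_from_r([[0.5, 0.2]])
        with pytest.raises(EmptyNetworkError):
            build_network(a, cutoff=1.0)

    def test_edges_and_isolated_metabolite_excluded(self):
        a = assoc_from_r([[0.5, 0.1, 0.1], [0.1, 0.5, 0.1]])
        net = build_network(a, cutoff=0.4)
        assert len(net.edges) == 2
        assert net.metabolites == ["M0", "M1"]  # M2 excluded

    def test_edge_count_monotone_in_cutoff(self):
        rng = np.random.default_rng(4)
        Z = rng.normal(0, 1, (30, 10))
        M = rng.normal(0, 1, (30, 12))
        a = compute_association_matrix(Z, M)
        a.p[:] = 0.0
        counts = []
        for c in [0.05, 0.15, 0.3, 0.5]:
            try:
                counts.append(len(build_network(a, c).edges))
            except EmptyNetworkError:
                counts.append(0)
        assert counts == sorted(counts, reverse=True)

    def test_sign_recorded(self):
        a = assoc_from_r([[0.5, -0.5]])
        net = build_network(a, cutoff=0.4)
        assert sorted(net.edges["sign"]) == [-1, 1]


def biclique_edges(voxels, mets, r=0.8):
    rows = [(v, m, r, 0.0, 1) for v in voxels for m in mets]
    return pd.DataFrame(rows, columns=["voxel", "metabolite", "r", "p", "sign"])


class TestCommunities:
    def test_disconnected_bicliques_found(self):
        edges = pd.concat(
            [
                biclique_edges(["V0", "V1"], ["M0", "M1"]),
                biclique_edges(["V2", "V3"], ["M2", "M3"]),
            ],
            ignore_index=True,
        )
        net = BipartiteNetwork(edges=edges, cutoff=0.5, alpha=0.05)
        cs = detect_communities(net, seed=0)
        groups = {
            frozenset(cs.nodes_in(c)) for c in cs.communities
        }
        assert groups == {
            frozenset({"V0", "V1", "M0", "M1"}),
            frozenset({"V2", "V3", "M2", "M3"}),
        }

    @pytest.mark.parametrize("seed", [0, 1])
    def test_modularity_matches_exhaustive_oracle(self, seed):
        # brute-force all partitions of graphs with <= 8 nodes
        rng = np.random.default_rng(seed)
        voxels = [f"V{i}" for i in range(3)]
        mets = [f"M{j}" for j in range(4)]
        rows = []
        for v in voxels:
            for m in mets:
                if rng.random() < 0.6:
                    rows.append((v, m, rng.uniform(0.3, 0.9), 0.0, 1))
        edges = pd.DataFrame(rows, columns=["voxel", "metabolite", "r", "p", "sign"])
        nodes = sorted(set(edges["voxel"]) | set(edges["metabolite"]))
        net = BipartiteNetwork(edges=edges, cutoff=0.2, alpha=0.05)
        cs = detect_communities(net, seed=0)

        def partitions(items):
            if not items:
                yield []
                return
            first, rest = items[0], items[1:]
            for part in partitions(rest):
                for i in range(len(part)):
                    yield part[:i] + [[first] + part[i]] + part[i + 1:]
                yield [[first]] + part

        best = -np.inf
        for part in partitions(nodes):
            membership = {n: i for i, block in enumerate(part) for n in block}
            best = max(best, modularity_score(edges, membership))
        assert cs.modularity == pytest.approx(best, abs=1e-9)

    def test_seeded_determinism(self, default_run):
        net = default_run.network
        a = detect_communities(net, seed=42)
        b = detect_communities(net, seed=42)
        pd.testing.assert_series_equal(a.membership, b.membership)
        assert a.modularity == b.modularity


class TestCentrality:
    def test_star_graph(self):
        edges = biclique_edges(["V0"], ["M0", "M1", "M2"])
        net = BipartiteNetwork(edges=edges, cutoff=0.5, alpha=0.05)
        cent = compute_centrality(net)
        assert cent["V0"] == pytest.approx(1.0)
        leaves = cent[["M0", "M1", "M2"]]
        assert (leaves < 1).all()
        np.testing.assert_allclose(leaves, leaves.iloc[0])

    def test_complete_bipartite_symmetry(self):
        edges = biclique_edges(["V0", "V1"], ["M0", "M1", "M2"])
        net = BipartiteNetwork(edges=edges, cutoff=0.5, alpha=0.05)
        cent = compute_centrality(net)
        np.testing.assert_allclose(cent[["V0", "V1"]], cent["V0"])
        np.testing.assert_allclose(cent[["M0", "M1", "M2"]], cent["M0"])

    def test_path_matches_power_iteration(self):
        rows = [
            ("V0", "M0", 0.5, 0.0, 1),
            ("V1", "M0", 0.7, 0.0, 1),
            ("V1", "M1", 0.4, 0.0, 1),
        ]
        edges = pd.DataFrame(rows, columns=["voxel", "metabolite", "r", "p", "sign"])
        net = BipartiteNetwork(edges=edges, cutoff=0.2, alpha=0.05)
        cent = compute_centrality(net)
        # independent oracle: dense power iteration
        nodes = ["V0", "V1", "M0", "M1"]
        A = np.zeros((4, 4))
        for v, m, r, _, _ in rows:
            i, j = nodes.index(v), nodes.index(m)
            A[i, j] = A[j, i] = r
        # bipartite adjacency has +/- eigenvalue pairs; shift to converge
        shifted = A + 2.0 * np.eye(4)
        x = np.ones(4)
        for _ in range(500):
            x = shifted @ x
            x /= np.linalg.norm(x)
        x /= x.max()
        for k, name in enumerate(nodes):
            assert cent[name] == pytest.approx(x[k], abs=1e-8)


class TestSummary:
    def _community_set(self):
        edges = pd.concat(
            [
                biclique_edges(["V0", "V1"], ["M0", "M1"]),
                biclique_edges(["V2"], ["M1", "M2"]),
            ],
            ignore_index=True,
        )
        net = BipartiteNetwork(edges=edges, cutoff=0.5, alpha=0.05)
        return detect_communities(net, seed=0)

    def test_edge_linked_counts_shared_metabolite_twice(self):
        cs = self._community_set()
        table = summarize_clusters(cs, mode="edge_linked")
        body = table[table["community"] != "total"]
        assert body["n_voxels"].sum() == 3
        # M1 is linked to voxels of both communities -> counted in both
        assert body["n_metabolites"].sum() == 4
        totals = table[table["community"] == "total"].iloc[0]
        assert totals["n_voxels"] == 3 and totals["n_metabolites"] == 4

    def test_partition_counts_each_node_once(self):
        cs = self._community_set()
        table = summarize_clusters(cs, mode="partition")
        body = table[table["community"] != "total"]
        assert body["n_metabolites"].sum() == 3

    def test_unknown_mode(self):
        with pytest.raises(ConfigurationError):
            summarize_clusters(self._community_set(), mode="bad")
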