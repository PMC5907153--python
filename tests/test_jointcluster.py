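import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from comodule import (
    CoexpressionNetwork,
    ModuleSet,
    SyntheticScenario,
    assemble_C,
    cluster_embedding,
    clustering_objective,
    filter_size,
    find_modules,
    generate_two_layer_sbm,
    remove_dual_isolated,
    select_M,
    single_network_modules,
    spectral_embed,
    split_disconnected,
    union_modules,
)
from conftest import net_from_edges, random_net


def _empty_net(n):
    genes = [f"g{i}" for i in range(n)]
    return CoexpressionNetwork(genes, np.zeros((n, n), dtype=np.int8))


def _clique_net(c, s):
    """c disjoint cliques of size s."""
    n = c * s
    genes = [f"g{i}" for i in range(n)]
    adj = np.zeros((n, n), dtype=np.int8)
    for k in range(c):
        adj[k * s : (k + 1) * s, k * s : (k + 1) * s] = 1
    np.fill_diagonal(adj, 0)
    return CoexpressionNetwork(genes, adj)


class TestRemoveDualIsolated:
    def test_gene_isolated_in_one_network_is_kept(self):
        genes = ["a", "b", "c", "d"]
        na = net_from_edges(genes, [("b", "c")])  # a and d isolated in A
        nb = net_from_edges(genes, [("a", "b"), ("a", "c"), ("a", "d")])
        _, _, kept = remove_dual_isolated(na, nb)
        assert kept == genes  # every gene has a link somewhere

    def test_gene_isolated_in_both_is_removed(self):
        genes = ["a", "b", "c"]
        na = net_from_edges(genes, [("a", "b")])
        nb = net_from_edges(genes, [("a", "b")])
        sa, sb, kept = remove_dual_isolated(na, nb)
        assert kept == ["a", "b"]
        assert sa.n_genes == sb.n_genes == 2

    def test_no_isolated_genes_is_identity(self):
        rng = np.random.default_rng(0)
        na = random_net(10, 0.8, rng)
        nb = random_net(10, 0.8, rng)
        sa, sb, kept = remove_dual_isolated(na, nb)
        assert kept == na.gene_ids
        np.testing.assert_array_equal(sa.adjacency, na.adjacency)


class TestAssembleC:
    def test_beta_zero_spectrum_is_union_of_laplacian_spectra(self):
        rng = np.random.default_rng(1)
        na = random_net(8, 0.4, rng)
        nb = random_net(8, 0.4, rng)
        model = assemble_C(na, nb, beta=0.0)
        got = np.sort(np.linalg.eigvalsh(model.C))
        expected = np.sort(
            np.concatenate(
                [np.linalg.eigvalsh(na.laplacian()), np.linalg.eigvalsh(nb.laplacian())]
            )
        )
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_empty_networks_coupling_only_spectrum(self):
        n = 6
        model = assemble_C(_empty_net(n), _empty_net(n), beta=1.0)
        ev = np.sort(np.linalg.eigvalsh(model.C))
        np.testing.assert_allclose(ev, [-1.0] * n + [1.0] * n, atol=1e-12)

    def test_C_is_symmetric(self):
        rng = np.random.default_rng(2)
        model = assemble_C(random_net(7, 0.5, rng), random_net(7, 0.3, rng), beta=2.5)
        np.testing.assert_array_equal(model.C, model.C.T)

    def test_eigenvalues_bounded_below_by_minus_beta(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(4, 15))
            beta = float(rng.random() * 3)
            model = assemble_C(
                random_net(n, 0.4, rng), random_net(n, 0.4, rng), beta=beta
            )
            assert np.linalg.eigvalsh(model.C).min() >= -beta - 1e-9

    def test_mismatched_gene_index_rejected(self):
        na = _empty_net(3)
        nb = CoexpressionNetwork(["x", "y", "z"], np.zeros((3, 3), dtype=np.int8))
        with pytest.raises(ValueError):
            assemble_C(na, nb)


class TestSpectralEmbed:
    def test_identical_layers_have_symmetric_embedding(self):
        """A1 = A2 with lambda_M(L) < 2*beta: the M smallest eigenvectors are
        all symmetric (v; v), so the two copies of each gene coincide."""
        net = _clique_net(4, 5)
        model = spectral_embed(assemble_C(net, net, beta=1.0), M=4)
        n = model.n
        np.testing.assert_allclose(
            model.embedding[:n], model.embedding[n:], atol=1e-8
        )

    def test_beta_zero_eigenvectors_live_on_one_block(self):
        rng = np.random.default_rng(4)
        na, nb = random_net(8, 0.5, rng), random_net(8, 0.5, rng, prefix="g")
        model = spectral_embed(assemble_C(na, nb, beta=0.0), M=6)
        for j in range(6):
            v = model.embedding[:, j]
            assert min(np.linalg.norm(v[:8]), np.linalg.norm(v[8:])) < 1e-8

    def test_duplicated_cliques_smallest_eigenvalues_at_minus_beta(self):
        net = _clique_net(3, 5)
        model = spectral_embed(assemble_C(net, net, beta=1.0), M=3)
        np.testing.assert_allclose(model.eigenvalues[:3], [-1.0] * 3, atol=1e-9)

    def test_embedding_satisfies_relaxed_constraint(self):
        rng = np.random.default_rng(5)
        model = spectral_embed(
            assemble_C(random_net(10, 0.4, rng), random_net(10, 0.4, rng), 1.0), M=5
        )
        np.testing.assert_allclose(
            model.embedding.T @ model.embedding, 2 * np.eye(5), atol=1e-8
        )

    def test_sign_convention_is_deterministic(self):
        rng = np.random.default_rng(6)
        na, nb = random_net(9, 0.4, rng), random_net(9, 0.4, rng)
        e1 = spectral_embed(assemble_C(na, nb, 1.0), M=4).embedding
        e2 = spectral_embed(assemble_C(na, nb, 1.0), M=4).embedding
        np.testing.assert_array_equal(e1, e2)
        for j in range(4):
            k = int(np.argmax(np.abs(e1[:, j])))
            assert e1[k, j] > 0


class TestSelectM:
    def test_first_big_gap_in_step_spectrum(self):
        ev = np.array([-1.0, -1.0, -1.0, 1.0, 1.0, 1.0, 4.0, 4.0, 4.0, 4.0])
        assert select_M(ev, search_range=(2, 6), factor=3.0) == 3

    def test_uniform_gaps_fall_back_to_argmax_with_warning(self, caplog):
        ev = np.arange(1.0, 11.0)
        with caplog.at_level("WARNING"):
            m = select_M(ev, search_range=(2, 8), factor=3.0)
        assert m == 2  # argmax over equal gaps -> first index
        assert "falling back" in caplog.text

    def test_duplicated_disjoint_cliques_pick_component_count(self):
        for c in (3, 5):
            net = _clique_net(c, 5)
            model = spectral_embed(assemble_C(net, net, beta=1.0), M=2)
            assert select_M(model.eigenvalues, search_range=(2, 10)) == c

    def test_degenerate_spectrum_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            select_M(np.ones(10), search_range=(2, 8))


class TestClusterEmbedding:
    def test_groups_with_distinct_patterns_recovered_exactly(self):
        """Rows sharing a rank pattern within a group, patterns distinct
        across groups: complete linkage recovers the groups exactly."""
        patterns = np.array(
            [[0.1, 0.5, 0.9], [0.9, 0.1, 0.5], [0.5, 0.9, 0.1], [0.9, 0.5, 0.1]]
        )
        rows = np.repeat(patterns, 3, axis=0)  # 12 rows = 2n with n = 6
        model_genes = [f"g{i}" for i in range(6)]
        from comodule.jointcluster import JointModel

        model = JointModel(beta=1.0, gene_ids=model_genes, C=np.zeros((12, 12)))
        model.embedding = rows
        model.M = 4
        model.eigenvalues = np.zeros(12)
        for mode in ("column", "row"):
            ms = cluster_embedding(model, rank_mode=mode)
            labels = np.concatenate([ms.labels_a, ms.labels_b])
            assert adjusted_rand_score(labels, np.repeat(np.arange(4), 3)) == 1.0

    def test_identical_networks_give_identical_per_network_labels(self):
        net = _clique_net(4, 5)
        model = spectral_embed(assemble_C(net, net, beta=1.0), M=4)
        ms = cluster_embedding(model)
        np.testing.assert_array_equal(ms.labels_a, ms.labels_b)

    def test_max_clusters_gives_singletons(self):
        rng = np.random.default_rng(7)
        na, nb = random_net(5, 0.6, rng), random_net(5, 0.4, rng)
        model = spectral_embed(assemble_C(na, nb, 1.0), M=10)
        ms = cluster_embedding(model)
        labels = np.concatenate([ms.labels_a, ms.labels_b])
        assert len(set(labels.tolist())) == 10


class TestModulePostprocessing:
    def test_union_gene_in_both_appears_once(self):
        ms = ModuleSet(
            gene_ids=["a", "b"], labels_a=np.array([1, 1]), labels_b=np.array([1, 1])
        )
        out = union_modules(ms)
        assert out.modules == [["a", "b"]]

    def test_disagreeing_labels_put_gene_in_both_unions(self):
        ms = ModuleSet(
            gene_ids=["a", "b", "c"],
            labels_a=np.array([1, 1, 2]),
            labels_b=np.array([2, 1, 2]),
        )
        out = union_modules(ms)
        assert out.modules == [["a", "b"], ["a", "c"]]
        assert "overlapping unions present" in out.provenance

    def test_identical_labels_reproduce_clusters(self):
        lab = np.array([1, 2, 1, 2])
        ms = ModuleSet(gene_ids=list("abcd"), labels_a=lab, labels_b=lab)
        out = union_modules(ms)
        assert out.modules == [["a", "c"], ["b", "d"]]

    def test_split_into_union_components(self):
        genes = list("abcdefg")
        na = net_from_edges(genes, [("a", "b"), ("b", "c")])
        nb = net_from_edges(genes, [("d", "e")])
        ms = ModuleSet(gene_ids=genes, modules=[["a", "b", "c", "d", "e"], ["f", "g"]])
        out = split_disconnected(ms, na, nb)
        assert [set(m) for m in out.modules] == [
            {"a", "b", "c"},
            {"d", "e"},
            {"f"},
            {"g"},
        ]

    def test_connected_module_unchanged(self):
        genes = list("abc")
        na = net_from_edges(genes, [("a", "b"), ("b", "c")])
        ms = ModuleSet(gene_ids=genes, modules=[["a", "b", "c"]])
        out = split_disconnected(ms, na, na)
        assert out.modules == [["a", "b", "c"]]

    def test_size_filter_inclusive_bounds(self):
        mods = [
            [f"g{i}" for i in range(n)]
            for n in (4, 5, 800, 801)
        ]
        ms = ModuleSet(gene_ids=[f"g{i}" for i in range(801)], modules=mods)
        out = filter_size(ms, 5, 800)
        assert [len(m) for m in out.modules] == [5, 800]

    def test_size_filter_empty_input(self):
        ms = ModuleSet(gene_ids=[], modules=[])
        assert filter_size(ms).modules == []


class TestObjectiveConsistency:
    @staticmethod
    def _brute_force_objective(labels_a, labels_b, net_a, net_b, beta):
        """Direct evaluation of the combined ratio-cut / alignment objective
        from the hard label vectors (cross-network cosine terms only)."""
        total = 0.0
        ms = sorted(set(labels_a.tolist()) | set(labels_b.tolist()))
        for net, lab in ((net_a, labels_a), (net_b, labels_b)):
            L = net.laplacian()
            for m in ms:
                s = (lab == m).astype(float)
                denom = s @ s
                if denom > 0:
                    total += s @ L @ s / denom
        for m in ms:
            sa = (labels_a == m).astype(float)
            sb = (labels_b == m).astype(float)
            na_, nb_ = np.linalg.norm(sa), np.linalg.norm(sb)
            if na_ > 0 and nb_ > 0:
                total -= 2 * beta * (sa @ sb) / (na_ * nb_)
        return total

    def test_trace_matches_brute_force(self):
        rng = np.random.default_rng(8)
        for n in (10, 30, 50):
            na = random_net(n, 0.3, rng)
            nb = random_net(n, 0.3, rng)
            la = rng.integers(1, 4, size=n)
            lb = rng.integers(1, 4, size=n)
            ms = ModuleSet(gene_ids=na.gene_ids, labels_a=la, labels_b=lb)
            beta = 1.3
            got = clustering_objective(ms, na, nb, beta=beta)
            want = self._brute_force_objective(ms.labels_a, ms.labels_b, na, nb, beta)
            assert got == pytest.approx(want, abs=1e-8)


class TestJointRecovery:
    def test_beta_zero_decouples_to_single_network_clustering(self):
        """beta = 0: network-A labels from the joint pipeline equal those of
        single-network spectral clustering of L1 alone (well-separated
        planted instances; equality up to label permutation)."""
        for seed in (1, 2, 3):
            sc = SyntheticScenario(
                n_genes=80,
                module_sizes=[20] * 4,
                layer_intra_p=[(0.7, 0.7)] * 4,
                background_p=0.0,
                rho=[(0.8, 0.8)] * 4,
                seed=seed,
            )
            na, nb, _ = generate_two_layer_sbm(sc)
            sa, sb, _ = remove_dual_isolated(na, nb)
            model = spectral_embed(assemble_C(sa, sb, beta=0.0), M=8)
            joint = cluster_embedding(model)
            single = single_network_modules(sa, M=4)
            assert adjusted_rand_score(joint.labels_a, single) == 1.0

    def test_identical_layers_give_identical_partitions(self):
        sc = SyntheticScenario(
            n_genes=75,
            module_sizes=[25] * 3,
            layer_intra_p=[(0.4, 0.4)] * 3,
            background_p=0.02,
            rho=[(0.8, 0.8)] * 3,
            seed=9,
        )
        na, _, _ = generate_two_layer_sbm(sc)
        mods, model = find_modules(na, na, beta=1.0, M=3)
        labels = cluster_embedding(model)
        np.testing.assert_array_equal(labels.labels_a, labels.labels_b)

    def test_final_modules_respect_size_and_connectivity(self):
        sc = SyntheticScenario(seed=13)
        na, nb, _ = generate_two_layer_sbm(sc)
        mods, _ = find_modules(na, nb, beta=1.0, M=4, min_module_size=5, max_module_size=800)
        union = np.maximum(na.adjacency, nb.adjacency)
        union_net = CoexpressionNetwork(na.gene_ids, union)
        g = union_net.to_graph()
        import networkx as nx

        for m in mods.modules:
            assert 5 <= len(m) <= 800
            assert nx.is_connected(g.subgraph(m))


class TestUnionOverlapResolution:
    def test_non_overlapping_mode_assigns_lower_cluster(self):
        ms = ModuleSet(
            gene_ids=["a", "b", "c"],
            labels_a=np.array([1, 1, 2]),
            labels_b=np.array([2, 1, 2]),
        )
        out = union_modules(ms, allow_overlap=False)
        assert out.modules == [["a", "b"], ["c"]]
        assert "overlapping unions present" not in out.provenance
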