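"""Tests for the weighted co-expression network chain."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg, stats

from ishnet import coexpr as cx
from ishnet.synthetic import CoexprFixtureSpec, gen_coexpr_fixture


def sample_matrix(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return cx.SampleMatrix(values=pd.DataFrame(values, index=genes, columns=samples))


class TestCorrelation:
    def test_duplicate_and_negated_rows(self):
        X = sample_matrix([[1, 2, 3, 4], [1, 2, 3, 4], [-1, -2, -3, -4]])
        c = cx.correlation_matrix(X)
        assert c.iloc[0, 1] == pytest.approx(1.0)
        assert c.iloc[0, 2] == pytest.approx(-1.0)

    def test_matches_pairwise_definition(self, toy_sample_matrix):
        c = cx.correlation_matrix(toy_sample_matrix)
        for a in toy_sample_matrix.genes:
            for b in toy_sample_matrix.genes:
                expected = stats.pearsonr(
                    toy_sample_matrix.values.loc[a], toy_sample_matrix.values.loc[b]
                ).statistic
                assert c.loc[a, b] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_gene_named(self):
        X = sample_matrix([[1, 1, 1, 1], [1, 2, 3, 4]], genes=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            cx.correlation_matrix(X)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            cx.correlation_matrix(sample_matrix([[1, 2], [2, 1]]))


class TestAdjacency:
    def test_powers(self):
        c = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]], index=list("ab"), columns=list("ab"))
        a = cx.adjacency(c, beta=2)
        assert a.loc["a", "b"] == pytest.approx(0.25)
        assert a.loc["a", "a"] == 0.0  # diagonal zeroed

    def test_signed_vs_unsigned_negative_correlation(self):
        c = pd.DataFrame([[1.0, -0.5], [-0.5, 1.0]], index=list("ab"), columns=list("ab"))
        assert cx.adjacency(c, 2).loc["a", "b"] == pytest.approx(0.25)
        assert cx.adjacency(c, 2, signed=True).loc["a", "b"] == pytest.approx(0.0625)

    def test_nonpositive_beta_rejected(self):
        c = pd.DataFrame(np.eye(2), index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError):
            cx.adjacency(c, beta=0)


def brute_force_tom(a: np.ndarray) -> np.ndarray:
    """Triple-loop evaluation of the unsigned topological overlap formula."""
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            k_i = sum(a[i, u] for u in range(n) if u != i)
            k_j = sum(a[j, u] for u in range(n) if u != j)
            out[i, j] = (l_ij + a[i, j]) / (min(k_i, k_j) + 1 - a[i, j])
    return out


class TestTOM:
    def test_two_genes_fully_connected(self):
        a = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=list("ab"), columns=list("ab"))
        t = cx.tom(a)
        assert t.loc["a", "b"] == pytest.approx(1.0)
        assert t.loc["a", "a"] == 1.0

    def test_three_node_hand_value(self):
        a = pd.DataFrame(np.full((3, 3), 0.5) - 0.5 * np.eye(3),
                         index=list("abc"), columns=list("abc"))
        t = cx.tom(a)
        # (0.25 + 0.5) / (1 + 1 - 0.5)
        assert t.loc["a", "b"] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_adjacency(self, seed):
        rng = np.random.default_rng(seed)
        raw = rng.uniform(0, 1, size=(8, 8))
        a = (raw + raw.T) / 2
        np.fill_diagonal(a, 0.0)
        labels = [f"g{i}" for i in range(8)]
        adf = pd.DataFrame(a, index=labels, columns=labels)
        assert np.max(np.abs(cx.tom(adf).to_numpy() - brute_force_tom(a))) < 1e-10

    def test_lower_bound_and_symmetry(self, rng):
        raw = rng.uniform(0, 1, size=(12, 12))
        a = (raw + raw.T) / 2
        np.fill_diagonal(a, 0.0)
        labels = [f"g{i}" for i in range(12)]
        t = cx.tom(pd.DataFrame(a, index=labels, columns=labels)).to_numpy()
        assert np.max(np.abs(t - t.T)) < 1e-12
        k = a.sum(axis=1)
        bound = a / (np.minimum.outer(k, k) + 1 - a)
        off = ~np.eye(12, dtype=bool)
        assert (t[off] >= bound[off] - 1e-12).all()


class TestModuleDetection:
    def test_two_planted_blocks_perfectly_separated(self):
        n = 10
        t = np.zeros((2 * n, 2 * n))
        t[:n, :n] = 0.95
        t[n:, n:] = 0.95
        np.fill_diagonal(t, 1.0)
        labels = [f"g{i:02d}" for i in range(2 * n)]
        part = cx.detect_modules(pd.DataFrame(t, index=labels, columns=labels),
                                 min_size=5)
        assert len(part.module_ids) == 2
        assert (part.labels != cx.UNASSIGNED).all()

    def test_pure_noise_all_unassigned_at_strict_cut(self, rng):
        X = sample_matrix(rng.standard_normal((60, 40)))
        t = cx.tom(cx.adjacency(cx.correlation_matrix(X), 6.0))
        with pytest.warns(UserWarning, match="unassigned"):
            part = cx.detect_modules(t, cut_height=0.2, min_size=5)
        assert (part.labels == cx.UNASSIGNED).all()

    def test_recovery_on_planted_fixture(self):
        from sklearn.metrics import adjusted_rand_score

        X, truth = gen_coexpr_fixture(CoexprFixtureSpec(
            module_sizes=(16, 40), n_noise_genes=100, n_samples=60, rho=0.8, seed=1))
        t = cx.tom(cx.adjacency(cx.correlation_matrix(X), 6.0))
        part = cx.detect_modules(t, X=X)
        assert adjusted_rand_score(truth.values, part.labels.values) >= 0.9

    def test_ids_assigned_by_decreasing_size(self):
        X, _ = gen_coexpr_fixture(CoexprFixtureSpec(
            module_sizes=(16, 40), n_noise_genes=50, n_samples=60, rho=0.8, seed=2))
        t = cx.tom(cx.adjacency(cx.correlation_matrix(X), 6.0))
        part = cx.detect_modules(t, X=X)
        sizes = [len(part.members(m)) for m in part.module_ids]
        assert sizes == sorted(sizes, reverse=True)

    def test_invalid_parameters_rejected(self):
        t = pd.DataFrame(np.eye(4), index=list("abcd"), columns=list("abcd"))
        with pytest.raises(ValueError):
            cx.detect_modules(t, cut_height=1.5)
        with pytest.raises(ValueError):
            cx.detect_modules(t, min_size=1)


class TestEigengene:
    def test_single_gene_module(self, toy_sample_matrix):
        eg = cx.module_eigengene(toy_sample_matrix, ["gA"])
        r = np.corrcoef(toy_sample_matrix.values.loc["gA"], eg.values)[0, 1]
        assert abs(r) == pytest.approx(1.0)
        assert np.linalg.norm(eg.values) == pytest.approx(1.0)

    def test_two_identical_genes(self):
        X = sample_matrix([[1, 2, 3, 4], [1, 2, 3, 4]])
        eg = cx.module_eigengene(X, ["g0", "g1"])
        assert eg.variance_explained == pytest.approx(1.0)
        r = np.corrcoef(X.values.loc["g0"], eg.values)[0, 1]
        assert r == pytest.approx(1.0)

    def test_matches_symmetric_eigendecomposition_oracle(self, rng):
        X = sample_matrix(rng.standard_normal((10, 25)))
        eg = cx.module_eigengene(X, X.genes)
        # oracle: leading eigenvector of the sample-by-sample Gram matrix
        z = ((X.values.T - X.values.mean(axis=1)) / X.values.std(axis=1)).T.to_numpy()
        w, v = linalg.eigh(z.T @ z)
        lead = v[:, -1]
        diff = min(np.abs(eg.values.to_numpy() - lead).max(),
                   np.abs(eg.values.to_numpy() + lead).max())
        assert diff < 1e-8
        assert eg.variance_explained == pytest.approx(w[-1] / w.sum())

    def test_sign_oriented_toward_members(self, rng):
        X = sample_matrix(rng.standard_normal((6, 30)))
        eg = cx.module_eigengene(X, X.genes)
        cors = [np.corrcoef(X.values.loc[g], eg.values)[0, 1] for g in X.genes]
        assert np.mean(cors) >= 0

    def test_absent_member_rejected(self, toy_sample_matrix):
        with pytest.raises(KeyError):
            cx.module_eigengene(toy_sample_matrix, ["nope"])


class TestKME:
    def test_gene_identical_to_eigengene(self):
        X = sample_matrix(np.tile(np.arange(8.0), (3, 1)) * [[1], [2], [-1]])
        eg = cx.module_eigengene(X, X.genes, module=1)
        recs = cx.kme(X, [eg])
        assert all(r.kme == pytest.approx(1.0) for r in recs)

    def test_orthogonal_gene_scores_zero(self):
        e = np.array([1.0, -1.0, 1.0, -1.0])
        g = np.array([1.0, 1.0, -1.0, -1.0])  # orthogonal to e, both centred
        X = sample_matrix(np.vstack([e, g]))
        eg = cx.Eigengene(module=1, values=pd.Series(e / np.linalg.norm(e),
                                                     index=X.values.columns),
                          variance_explained=1.0)
        recs = cx.kme(X, [eg])
        assert recs[1].kme == pytest.approx(0.0, abs=1e-12)

    def test_pvalue_matches_t_distribution_oracle(self, rng):
        X = sample_matrix(rng.standard_normal((5, 10)))
        eg = cx.module_eigengene(X, X.genes, module=1)
        recs = cx.kme(X, [eg])
        n = 10
        for r, gene in zip(recs, X.genes):
            rho = np.corrcoef(X.values.loc[gene], eg.values)[0, 1]
            t = abs(rho) * np.sqrt((n - 2) / (1 - rho**2))
            expected = 2 * stats.t.sf(t, df=n - 2)
            assert r.p_value == pytest.approx(expected, rel=1e-10)


class TestConnectivity:
    def test_star_module(self):
        a = np.zeros((5, 5))
        a[0, 1:] = a[1:, 0] = 1.0
        labels = ["hub", "l1", "l2", "l3", "l4"]
        adf = pd.DataFrame(a, index=labels, columns=labels)
        part = cx.ModulePartition(labels=pd.Series([1] * 5, index=labels),
                                  cut_height=0.5, min_size=2, merge_kme=0.8)
        kim = cx.intramodular_connectivity(adf, part).set_index("gene")["kim"]
        assert kim["hub"] == 4.0
        assert (kim.drop("hub") == 1.0).all()
        hubs = cx.hub_genes(cx.intramodular_connectivity(adf, part), top_k=1)
        assert hubs["gene"].tolist() == ["hub"]

    def test_handshake_identity_and_hand_sums(self, rng):
        raw = rng.uniform(0, 1, size=(5, 5))
        a = (raw + raw.T) / 2
        np.fill_diagonal(a, 0.0)
        labels = [f"g{i}" for i in range(5)]
        adf = pd.DataFrame(a, index=labels, columns=labels)
        modules = pd.Series([1, 1, 1, 2, 2], index=labels)
        part = cx.ModulePartition(labels=modules, cut_height=0.5, min_size=2, merge_kme=0.8)
        kim = cx.intramodular_connectivity(adf, part)
        assert kim.set_index("gene").loc["g0", "kim"] == pytest.approx(a[0, 1] + a[0, 2])
        within = a[:3, :3].sum() / 2 + a[3:, 3:].sum() / 2
        assert kim["kim"].sum() == pytest.approx(2 * within)


class TestBetweenness:
    def _weights(self, edges, nodes):
        w = pd.DataFrame(0.0, index=nodes, columns=nodes)
        for u, v in edges:
            w.loc[u, v] = w.loc[v, u] = 1.0
        return w

    def test_complete_triangle_no_intermediaries(self):
        nodes = list("abc")
        nb, _ = cx.betweenness(self._weights([("a", "b"), ("b", "c"), ("a", "c")], nodes),
                               nodes, edge_threshold=0.5)
        assert (nb["betweenness"] == 0).all()

    def test_path_middle_carries_one_pair(self):
        nodes = list("abc")
        nb, eb = cx.betweenness(self._weights([("a", "b"), ("b", "c")], nodes),
                                nodes, edge_threshold=0.5)
        assert nb.set_index("gene").loc["b", "betweenness"] == 1.0
        # each edge lies on 2 shortest paths (a-b, a-c) resp. (b-c, a-c)
        assert (eb["edge_betweenness"] == 2.0).all()

    def test_star_center_counts_leaf_pairs(self):
        nodes = ["c", "l1", "l2", "l3", "l4"]
        nb, _ = cx.betweenness(self._weights([("c", l) for l in nodes[1:]], nodes),
                               nodes, edge_threshold=0.5)
        assert nb.set_index("gene").loc["c", "betweenness"] == 6.0

    def test_disconnected_graph_allowed(self):
        nodes = list("abcd")
        nb, _ = cx.betweenness(self._weights([("a", "b"), ("c", "d")], nodes),
                               nodes, edge_threshold=0.5)
        assert (nb["betweenness"] == 0).all()

    def test_empty_graph_rejected(self):
        nodes = list("ab")
        with pytest.raises(ValueError):
            cx.betweenness(pd.DataFrame(0.0, index=nodes, columns=nodes), nodes, 0.5)


class TestZsummary:
    def test_identical_data_strong_module_preserved(self):
        X, truth = gen_coexpr_fixture(CoexprFixtureSpec(
            module_sizes=(16,), n_noise_genes=150, n_samples=60, rho=0.8, seed=1))
        part = cx.ModulePartition(labels=truth, cut_height=0.25, min_size=3, merge_kme=0.8)
        reps = cx.zsummary(X, X, part, n_perm=100, seed=1)
        assert len(reps) == 1
        assert reps[0].z_summary > 10

    def test_noise_module_shows_no_preservation(self):
        hits = 0
        for rep in range(50):
            Xr, _ = gen_coexpr_fixture(CoexprFixtureSpec(
                module_sizes=(2,), rho=0.0, n_noise_genes=148, n_samples=60, seed=3000 + rep))
            Xt, _ = gen_coexpr_fixture(CoexprFixtureSpec(
                module_sizes=(2,), rho=0.0, n_noise_genes=148, n_samples=60, seed=4000 + rep))
            rng = np.random.default_rng(rep)
            members = set(rng.choice(Xr.genes, size=12, replace=False))
            labels = pd.Series([1 if g in members else 0 for g in Xr.genes], index=Xr.genes)
            part = cx.ModulePartition(labels=labels, cut_height=0.25, min_size=3, merge_kme=0.8)
            r = cx.zsummary(Xr, Xt, part, n_perm=60, seed=rep)[0]
            hits += abs(r.z_summary) < 2
        assert hits >= 45  # >= 90% of replicates

    def test_bit_identical_under_same_seed(self):
        X, truth = gen_coexpr_fixture(CoexprFixtureSpec(
            module_sizes=(10,), n_noise_genes=60, n_samples=40, rho=0.7, seed=5))
        part = cx.ModulePartition(labels=truth, cut_height=0.25, min_size=3, merge_kme=0.8)
        r1 = cx.zsummary(X, X, part, n_perm=60, seed=9)[0]
        r2 = cx.zsummary(X, X, part, n_perm=60, seed=9)[0]
        assert r1 == r2

    def test_small_module_skipped_with_warning(self):
        X, _ = gen_coexpr_fixture(CoexprFixtureSpec(
            module_sizes=(4,), n_noise_genes=30, n_samples=30, rho=0.5, seed=6))
        labels = pd.Series([1, 1, 0, 0] + [0] * 30, index=X.genes)
        part = cx.ModulePartition(labels=labels, cut_height=0.25, min_size=2, merge_kme=0.8)
        with pytest.warns(UserWarning, match="skipped"):
            assert cx.zsummary(X, X, part, n_perm=50, seed=0) == []

    def test_too_few_permutations_rejected(self):
        X, truth = gen_coexpr_fixture(CoexprFixtureSpec(
            module_sizes=(5,), n_noise_genes=10, n_samples=20, rho=0.5, seed=7))
        part = cx.ModulePartition(labels=truth, cut_height=0.25, min_size=3, merge_kme=0.8)
        with pytest.raises(ValueError):
            cx.zsummary(X, X, part, n_perm=10, seed=0)

    def test_zsummary_is_mean_of_component_zs(self):
        X, truth = gen_coexpr_fixture(CoexprFixtureSpec(
            module_sizes=(10,), n_noise_genes=60, n_samples=40, rho=0.7, seed=8))
        part = cx.ModulePartition(labels=truth, cut_height=0.25, min_size=3, merge_kme=0.8)
        r = cx.zsummary(X, X, part, n_perm=60, seed=2)[0]
        assert r.z_summary == pytest.approx((r.z_density + r.z_connectivity) / 2)
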