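"""Correlations, NNSD/threshold scan, network construction and topology."""
import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.sparse.csgraph import floyd_warshall

import fmen
from fmen.errors import (
    EmptyNetworkError,
    InsufficientSpectrumError,
    InvalidDesignError,
    NoTransitionError,
)


# ---------------------------------------------------------------------------
# correlations


def _nm(data: np.ndarray, groups: list[str]):
    samples = [f"{g}{i}" for i, g in enumerate(groups, start=1)]
    rel = pd.DataFrame(np.asarray(data, dtype=float),
                       index=[f"g{i}" for i in range(np.asarray(data).shape[0])],
                       columns=samples)
    return fmen.NormalizedMatrix(rel, rel > 0, pd.Series(groups, index=samples))


class TestCorrelationMatrix:
    def test_identical_and_opposite_profiles(self):
        base = np.array([1, 2, 3, 4, 5, 6.0])
        data = np.vstack([base, base, 2 * base.mean() - base]) / 100
        nm = _nm(data, ["A"] * 6)
        corr = fmen.correlation_matrix(nm, "A", min_detected_fraction=0.0)
        assert corr.r[0, 1] == pytest.approx(1.0)
        assert corr.r[0, 2] == pytest.approx(-1.0)

    def test_matches_covariance_oracle(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(0.001, 0.01, size=(5, 6))
        nm = _nm(data, ["A"] * 6)
        corr = fmen.correlation_matrix(nm, "A", min_detected_fraction=0.0)
        for i in range(5):
            for j in range(5):
                x, y = data[i], data[j]
                manual = (np.mean(x * y) - x.mean() * y.mean()) / (
                    x.std() * y.std())
                assert corr.r[i, j] == pytest.approx(manual, abs=1e-12)

    def test_zero_variance_gene_excluded_with_warning(self):
        rng = np.random.default_rng(1)
        data = rng.uniform(0.001, 0.01, size=(4, 6))
        data[2] = 0.005
        nm = _nm(data, ["A"] * 6)
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = fmen.correlation_matrix(nm, "A", min_detected_fraction=0.0)
        assert "g2" not in corr.genes
        assert not np.isnan(corr.r).any()

    def test_needs_three_samples(self):
        nm = _nm(np.random.default_rng(2).random((4, 2)), ["A", "A"])
        with pytest.raises(InvalidDesignError):
            fmen.correlation_matrix(nm, "A")

    def test_detection_floor_excludes_patchy_genes(self, small_normalized):
        corr = fmen.correlation_matrix(small_normalized, "HL",
                                       min_detected_fraction=0.5)
        frac = small_normalized.detected[
            small_normalized.sample_ids("HL")].mean(axis=1)
        assert all(frac[g] >= 0.5 for g in corr.genes)


# ---------------------------------------------------------------------------
# NNSD machinery


class TestNNSD:
    def test_unfolded_spacings_have_unit_mean(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            lam = np.cumsum(rng.exponential(1.0, 300))
            s = fmen.unfold_spacings(lam)
            assert s.mean() == pytest.approx(1.0, abs=1e-6)

    def test_block_diagonal_accepted_goe_rejected(self):
        rng = np.random.default_rng(4)
        accept = reject = 0
        n_rep = 25
        for _ in range(n_rep):
            # many independent small blocks -> Poisson
            blocks = []
            for _ in range(40):
                b = rng.standard_normal((8, 8))
                blocks.append((b + b.T) / 2)
            lam = np.concatenate([np.linalg.eigvalsh(b) for b in blocks])
            _, p = fmen.poisson_spacing_gof(fmen.unfold_spacings(lam))
            accept += p > 0.05
            # dense GOE matrix -> Wigner surmise, Poisson rejected
            a = rng.standard_normal((320, 320))
            lam = np.linalg.eigvalsh((a + a.T) / np.sqrt(2))
            _, p = fmen.poisson_spacing_gof(fmen.unfold_spacings(lam))
            reject += p < 0.05
        assert accept >= 0.85 * n_rep
        assert reject >= 0.9 * n_rep

    def test_type_one_error_calibrated(self):
        # Poisson-spaced spectra: rejection rate at alpha=0.05 in (0.01, 0.12)
        rng = np.random.default_rng(5)
        n_rep = 500
        rejections = 0
        for _ in range(n_rep):
            lam = np.cumsum(rng.exponential(1.0, 300))
            _, p = fmen.poisson_spacing_gof(fmen.unfold_spacings(lam))
            rejections += p < 0.05
        assert 0.01 < rejections / n_rep < 0.12

    def test_insufficient_spectrum_raises(self):
        r = np.eye(10)
        with pytest.raises(InsufficientSpectrumError):
            fmen.nnsd_poisson_gof(r, 0.5, min_eigenvalues=100)

    def test_st_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            fmen.nnsd_poisson_gof(np.eye(300), 1.5)


class TestThresholdScan:
    def test_already_poisson_input_selects_first_grid_point(self):
        # a block-diagonal correlation matrix of many independent small
        # blocks is already in the Poisson regime at low thresholds
        rng = np.random.default_rng(6)
        n_blocks, bs = 60, 5
        r = np.zeros((n_blocks * bs, n_blocks * bs))
        for k in range(n_blocks):
            sl = slice(k * bs, (k + 1) * bs)
            x = rng.standard_normal((bs, 8))
            r[sl, sl] = np.corrcoef(x)
        np.fill_diagonal(r, 1.0)
        grid = np.round(np.arange(0.30, 0.46, 0.05), 2)
        res = fmen.rmt_threshold_scan(r, grid=grid, min_eigenvalues=50)
        assert res.st == grid[0]
        assert res.method == "scan"

    def test_no_transition_raises_with_advice(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal((250, 40))
        r = np.corrcoef(a)
        grid = np.round(np.arange(0.01, 0.04, 0.01), 2)  # deep GOE regime
        with pytest.raises(NoTransitionError, match="grid"):
            fmen.rmt_threshold_scan(r, grid=grid, min_eigenvalues=50)

    def test_descending_grid_rejected(self):
        with pytest.raises(ValueError):
            fmen.rmt_threshold_scan(np.eye(5), grid=np.array([0.9, 0.5]))


# ---------------------------------------------------------------------------
# network construction and topology


def _toy_corr(r: np.ndarray, genes=None) -> fmen.CorrelationMatrix:
    genes = genes or [f"g{i}" for i in range(r.shape[0])]
    return fmen.CorrelationMatrix(genes=genes, r=r, group="A", n_samples=6)


class TestBuildNetwork:
    def test_triangle_from_three_correlated_genes(self):
        r = np.full((3, 3), 0.995)
        np.fill_diagonal(r, 1.0)
        g = fmen.build_network(_toy_corr(r), 0.99)
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 3

    def test_empty_network_raises(self):
        r = np.eye(4) + 0.5 - 0.5 * np.eye(4)
        np.fill_diagonal(r, 1.0)
        with pytest.raises(EmptyNetworkError):
            fmen.build_network(_toy_corr(r), 1.0)

    def test_sign_fractions_match_direct_count(self):
        rng = np.random.default_rng(8)
        r = rng.uniform(-1, 1, (20, 20))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        g = fmen.build_network(_toy_corr(r), 0.6)
        topo = fmen.topology_summary(g)
        iu = np.triu_indices(20, 1)
        strong = np.abs(r[iu]) >= 0.6
        n_pos = int((r[iu][strong] > 0).sum())
        n_neg = int((r[iu][strong] < 0).sum())
        assert topo.n_links == n_pos + n_neg
        assert topo.positive_fraction == pytest.approx(n_pos / (n_pos + n_neg))

    def test_raising_threshold_is_monotone_filtration(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((40, 8))
        r = np.corrcoef(x)
        sizes = []
        for st in (0.3, 0.5, 0.7, 0.9):
            try:
                g = fmen.build_network(_toy_corr(r), st)
                sizes.append((g.number_of_nodes(), g.number_of_edges()))
            except EmptyNetworkError:
                sizes.append((0, 0))
        assert sizes == sorted(sizes, reverse=True)


def oracle_hd(g: nx.Graph) -> float:
    nodes = list(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes, weight=None)
    d = floyd_warshall(a, unweighted=True)
    n = len(nodes)
    recip = sum(1.0 / d[i, j] for i in range(n) for j in range(i + 1, n)
                if np.isfinite(d[i, j]) and d[i, j] > 0)
    return (n * (n - 1) / 2) / recip


def oracle_avg_cc(g: nx.Graph) -> float:
    nodes = list(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes, weight=None)
    deg = a.sum(axis=1)
    tri = np.diag(a @ a @ a) / 2
    cc = np.where(deg >= 2, 2 * tri / np.maximum(deg * (deg - 1), 1), 0.0)
    return float(cc.mean())


def oracle_modularity(g: nx.Graph, partition) -> float:
    m = g.number_of_edges()
    q = 0.0
    for comm in partition:
        e_ii = sum(1 for u, v in g.edges if u in comm and v in comm) / m
        a_i = sum(d for n, d in g.degree if n in comm) / (2 * m)
        q += e_ii - a_i ** 2
    return q


class TestTopology:
    def test_triangle(self):
        g = nx.cycle_graph(3)
        t = fmen.topology_summary(g)
        assert t.avg_k == pytest.approx(2.0)
        assert t.harmonic_geodesic_distance == pytest.approx(1.0)
        assert t.avg_clustering == pytest.approx(1.0)

    def test_three_node_path(self):
        g = nx.path_graph(3)
        t = fmen.topology_summary(g)
        assert t.harmonic_geodesic_distance == pytest.approx(3 / 2.5)
        assert t.avg_clustering == pytest.approx(0.0)

    def test_printed_avg_connectivity_identities(self):
        assert fmen.avg_connectivity(2005, 5551) == pytest.approx(5.537, abs=5e-4)
        assert fmen.avg_connectivity(1703, 4667) == pytest.approx(5.481, abs=5e-4)

    def test_avg_k_identity_on_random_graphs(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            g = nx.gnp_random_graph(30, 0.15, seed=int(rng.integers(1 << 30)))
            g.remove_nodes_from(list(nx.isolates(g)))
            if g.number_of_edges() == 0:
                continue
            t = fmen.topology_summary(g)
            assert t.avg_k == 2 * t.n_links / t.n_nodes

    def test_hd_and_cc_match_oracles_on_random_graphs(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            g = nx.gnp_random_graph(25, 0.12, seed=int(rng.integers(1 << 30)))
            g.remove_nodes_from(list(nx.isolates(g)))
            if g.number_of_nodes() < 3:
                continue
            assert fmen.harmonic_geodesic_distance(g) == pytest.approx(
                oracle_hd(g), abs=1e-9)
            assert nx.average_clustering(g, count_zeros=True) == pytest.approx(
                oracle_avg_cc(g), abs=1e-9)

    def test_exact_power_law_gives_r2_one(self):
        # a graph whose degree frequencies are exactly freq(k) = 64 / k^2
        # over k in {1, 2, 4, 8}: one 8-hub, four 4-hubs, sixteen 2-hubs,
        # 56 attached leaves plus 4 leaf-leaf edges (64 degree-1 nodes)
        g = nx.Graph()
        leaf = itertools.count()
        for k, count in ((8, 1), (4, 4), (2, 16)):
            for h in range(count):
                for _ in range(k):
                    g.add_edge(f"hub{k}_{h}", f"leaf{next(leaf)}")
        for _ in range(4):
            g.add_edge(f"leaf{next(leaf)}", f"leaf{next(leaf)}")
        freqs = np.bincount([d for _, d in g.degree()])
        assert list(np.nonzero(freqs)[0]) == [1, 2, 4, 8]
        assert list(freqs[[1, 2, 4, 8]]) == [64, 16, 4, 1]
        assert fmen.power_law_r2(g) == pytest.approx(1.0, abs=1e-12)


class TestModularity:
    def test_two_disconnected_triangles(self):
        g = nx.union(nx.cycle_graph(3), nx.cycle_graph(3, nx.Graph()),
                     rename=("a", "b"))
        partition, q, k = fmen.modularity_partition(g)
        assert k == 2
        assert q == pytest.approx(0.5)
        assert {frozenset(c) for c in partition} == {
            frozenset({"a0", "a1", "a2"}), frozenset({"b0", "b1", "b2"})}

    def test_complete_graph_single_module(self):
        g = nx.complete_graph(6)
        _, q, k = fmen.modularity_partition(g)
        assert k == 1
        assert q == pytest.approx(0.0)

    def test_greedy_q_matches_exhaustive_search(self):
        # two 4-cliques joined by one edge: greedy must find the optimum
        g = nx.union(nx.complete_graph(4), nx.complete_graph(4),
                     rename=("a", "b"))
        g.add_edge("a0", "b0")
        _, q, _ = fmen.modularity_partition(g)

        def partitions(nodes):
            if not nodes:
                yield []
                return
            head, *rest = nodes
            for part in partitions(rest):
                for i in range(len(part)):
                    yield part[:i] + [part[i] | {head}] + part[i + 1:]
                yield part + [{head}]

        best = max(oracle_modularity(g, p) for p in partitions(list(g.nodes)))
        assert q == pytest.approx(best, abs=1e-12)

    def test_q_formula_matches_oracle_on_random_graphs(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            g = nx.gnp_random_graph(20, 0.2, seed=int(rng.integers(1 << 30)))
            g.remove_nodes_from(list(nx.isolates(g)))
            if g.number_of_edges() < 2:
                continue
            partition, q, _ = fmen.modularity_partition(g)
            assert q == pytest.approx(oracle_modularity(g, partition),
                                      abs=1e-12)


class TestHubGenes:
    def test_star_center_is_top_hub(self):
        g = nx.star_graph(6)
        hubs = fmen.hub_genes(g, 1)
        assert hubs.iloc[0]["gene"] == 0
        assert hubs.iloc[0]["degree"] == 6

    def test_ties_broken_lexicographically(self):
        g = nx.Graph([("b", "c"), ("a", "c"), ("a", "b")])
        hubs = fmen.hub_genes(g, 2)
        assert list(hubs["gene"]) == ["a", "b"]

    def test_k_larger_than_network_warns(self):
        g = nx.path_graph(3)
        with pytest.warns(UserWarning):
            hubs = fmen.hub_genes(g, 10)
        assert len(hubs) == 3

    def test_planted_module_members_dominate_hubs(self):
        # one strongly correlated 25-gene block amid unstructured genes:
        # its members should occupy the top-5 degree ranks in most replicates
        wins = 0
        n_rep = 20
        for rep in range(n_rep):
            cat = fmen.generate_catalog(300, seed=60 + rep)
            cfg = fmen.SimulationConfig(
                n_probes=300, richness_fraction={"HL": 1.0, "RAL": 1.0},
                detect_prob=1.0, flip_prob=0.0, category_effect={},
                module_spec=[fmen.ModuleSpec(25, 0.95, "HL")],
                modules_in_core_families=False)
            sm, truth = fmen.simulate_two_lake(cat, cfg, seed=160 + rep)
            nm, _ = fmen.preprocess(sm)
            corr = fmen.correlation_matrix(nm, "HL")
            g = fmen.build_network(corr, 0.9, catalog=cat)
            hubs = fmen.hub_genes(g, 5)
            members = set(truth.modules[0]["probes"])
            wins += sum(h in members for h in hubs["gene"]) >= 4
        assert wins >= 0.9 * n_rep
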