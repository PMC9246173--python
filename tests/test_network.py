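import numpy as np
import pandas as pd
import pytest
from scipy import stats

from locusdissect import network
from locusdissect import synthetic_data as sd


def brute_force_tom(A):
    """Triple-loop TOM for cross-checking the vectorized implementation."""
    A = np.asarray(A, float).copy()
    np.fill_diagonal(A, 0.0)
    m = A.shape[0]
    k = A.sum(axis=1)
    tom = np.eye(m)
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            shared = sum(A[i, u] * A[u, j] for u in range(m) if u != i and u != j)
            tom[i, j] = (shared + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return tom


def exact_hypergeom_tail(overlap, universe, module, hood):
    """P(X >= overlap) by direct combinatorial enumeration."""
    from math import comb

    total = comb(universe, hood)
    return sum(
        comb(module, x) * comb(universe - module, hood - x)
        for x in range(overlap, min(module, hood) + 1)
    ) / total


class TestTom:
    def test_complete_unit_triangle_is_all_ones(self):
        A = np.ones((3, 3))
        assert network.tom_from_adjacency(A) == pytest.approx(np.ones((3, 3)))

    def test_isolated_node_has_zero_overlap(self):
        A = np.ones((4, 4))
        A[3, :] = A[:, 3] = 0.0
        tom = network.tom_from_adjacency(A)
        assert tom[3, :3] == pytest.approx(np.zeros(3))
        assert tom[3, 3] == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_triple_loop_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.uniform(0, 1, size=(10, 10))
        A = (A + A.T) / 2
        assert network.tom_from_adjacency(A) == pytest.approx(brute_force_tom(A), abs=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_entries_in_unit_interval_for_any_unsigned_adjacency(self, seed):
        rng = np.random.default_rng(100 + seed)
        m = int(rng.integers(3, 15))
        A = rng.uniform(0, 1, size=(m, m))
        A = (A + A.T) / 2
        tom = network.tom_from_adjacency(A)
        assert tom.min() >= 0.0 and tom.max() <= 1.0


class TestBuildGraph:
    def test_perfectly_correlated_genes_have_unit_adjacency_at_beta_one(self, rng):
        x = rng.standard_normal(30)
        expr = pd.DataFrame([x, 2 * x + 1], index=["g1", "g2"], columns=[f"s{i}" for i in range(30)])
        graph = network.build_graph(expr, beta=1.0)
        assert graph.adjacency[0, 1] == pytest.approx(1.0)

    def test_zero_variance_gene_excluded(self, rng):
        expr = pd.DataFrame(
            np.vstack([rng.standard_normal((3, 30)), np.ones(30)]),
            index=["g1", "g2", "g3", "flat"],
            columns=[f"s{i}" for i in range(30)],
        )
        graph = network.build_graph(expr)
        assert ("flat", "") not in graph.nodes
        assert len(graph.nodes) == 3

    def test_beta_below_one_rejected(self, rng):
        expr = pd.DataFrame(rng.standard_normal((3, 30)), columns=[f"s{i}" for i in range(30)])
        with pytest.raises(ValueError, match="beta"):
            network.build_graph(expr, beta=0.5)


def planted_module_expression(rng, n_modules=2, module_size=30, n_noise=20, n=300, loading=0.9):
    factors = rng.standard_normal((n_modules, n))
    rows, truth = [], {}
    for m in range(n_modules):
        for j in range(module_size):
            gene = f"mod{m}_g{j}"
            rows.append((gene, loading * factors[m] + np.sqrt(1 - loading**2) * rng.standard_normal(n)))
            truth[gene] = m
    for j in range(n_noise):
        gene = f"noise_{j}"
        rows.append((gene, rng.standard_normal(n)))
        truth[gene] = None
    expr = pd.DataFrame(dict(rows), index=[f"s{i}" for i in range(n)]).T
    return expr, truth


class TestDetectModules:
    def test_planted_factors_recovered(self, rng):
        expr, truth = planted_module_expression(rng)
        graph = network.build_graph(expr)
        modules = network.detect_modules(graph)
        assert len(modules.modules) == 2
        # best label matching: each detected module maps to one planted factor
        agreement = 0
        for members in modules.modules.values():
            genes = [g for g, _ in members]
            planted = [truth[g] for g in genes if truth[g] is not None]
            best = max(planted.count(0), planted.count(1))
            agreement += best
        assert agreement >= 0.9 * 60

    def test_pure_noise_is_all_grey(self, rng):
        expr = pd.DataFrame(
            rng.standard_normal((30, 200)),
            index=[f"g{i}" for i in range(30)],
            columns=[f"s{i}" for i in range(200)],
        )
        graph = network.build_graph(expr)
        modules = network.detect_modules(graph)
        assert modules.modules == {}
        assert len(modules.grey) == 30

    def test_duplicated_gene_lands_in_same_module(self, rng):
        expr, truth = planted_module_expression(rng, n_noise=5)
        expr.loc["dup_of_mod0"] = expr.loc["mod0_g0"] + 1e-6 * rng.standard_normal(expr.shape[1])
        graph = network.build_graph(expr)
        modules = network.detect_modules(graph)
        home = {g for g, _ in modules.modules[
            next(m for m, mem in modules.modules.items() if ("mod0_g0", "") in mem)
        ]}
        assert "dup_of_mod0" in home

    def test_min_size_validation(self, rng):
        expr, _ = planted_module_expression(rng, n_noise=0)
        graph = network.build_graph(expr)
        with pytest.raises(ValueError):
            network.detect_modules(graph, min_size=2)

    def test_eigengene_sign_orientation(self, rng):
        expr, _ = planted_module_expression(rng, n_noise=0)
        graph = network.build_graph(expr)
        modules = network.detect_modules(graph)
        for mod, members in modules.modules.items():
            eig = modules.eigengenes[mod].to_numpy()
            cors = [np.corrcoef(graph.expression.loc[node], eig)[0, 1] for node in members]
            assert np.mean(cors) > 0
            assert modules.eigengenes[mod].std(ddof=0) == pytest.approx(1.0)


class TestModuleTrait:
    def _modules(self, rng):
        expr, _ = planted_module_expression(rng, n_modules=1, module_size=30, n_noise=10)
        graph = network.build_graph(expr)
        return network.detect_modules(graph)

    def test_trait_equal_to_eigengene_gives_r_one(self, rng):
        modules = self._modules(rng)
        traits = modules.eigengenes.rename(columns={"M1": "self"})
        res = network.module_trait(modules, traits)
        assert res.iloc[0]["r"] == pytest.approx(1.0)

    def test_planted_correlation_in_fisher_band(self, rng):
        modules = self._modules(rng)
        eig = modules.eigengenes["M1"].to_numpy()
        n = len(eig)
        trait = 0.5 * eig + np.sqrt(1 - 0.25) * rng.standard_normal(n)
        res = network.module_trait(modules, pd.DataFrame({"t": trait}, index=modules.eigengenes.index))
        # 99% Fisher-z interval around atanh(0.5) at n = 300
        assert 0.38 <= res.iloc[0]["r"] <= 0.61

    def test_independent_trait_has_small_correlation(self):
        small = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            modules = self._modules(rng)
            trait = rng.standard_normal(len(modules.eigengenes))
            res = network.module_trait(modules, pd.DataFrame({"t": trait}, index=modules.eigengenes.index))
            small += abs(res.iloc[0]["r"]) < 0.2
        assert small >= 19


class TestKeyDrivers:
    def test_hypergeometric_tail_worked_example(self):
        # neighborhood 5, module 10, universe 100, overlap 3
        p = float(stats.hypergeom.sf(2, 100, 10, 5))
        assert p == pytest.approx(exact_hypergeom_tail(3, 100, 10, 5), abs=1e-12)
        assert p == pytest.approx(0.0066, abs=5e-4)

    def test_exhaustive_enumeration_small_universe(self):
        for universe in (10, 20, 30):
            for module in (2, 5, universe // 2):
                for hood in (1, 3, universe // 3):
                    for overlap in range(0, min(module, hood) + 1):
                        expected = exact_hypergeom_tail(overlap, universe, module, hood)
                        got = float(stats.hypergeom.sf(overlap - 1, universe, module, hood))
                        assert got == pytest.approx(expected, abs=1e-12)

    def _hub_graph(self, rng, universe=100, module_size=30, wired=24):
        A = rng.uniform(0, 0.1, size=(universe, universe))
        A = (A + A.T) / 2
        hub = universe - 1
        members = list(range(module_size))
        for j in members[:wired]:
            A[hub, j] = A[j, hub] = 0.95
        np.fill_diagonal(A, 0.0)
        nodes = [(f"g{i}", "") for i in range(universe)]
        graph = network.CoexpressionGraph(nodes=nodes, adjacency=A, tom=network.tom_from_adjacency(A), beta=6.0)
        modules = network.ModuleSet(
            modules={"M1": [nodes[i] for i in members]},
            eigengenes=pd.DataFrame(index=pd.Index([], dtype=object)),
        )
        return graph, modules, nodes[hub]

    def test_planted_hub_is_flagged(self):
        flagged = 0
        for seed in range(20):
            rng = np.random.default_rng(2000 + seed)
            graph, modules, hub = self._hub_graph(rng)
            kd = network.key_drivers(graph, modules, tau=0.5)
            row = kd[kd["node"] == hub].iloc[0]
            flagged += bool(row["key_driver"])
        assert flagged >= 18

    def test_zero_overlap_never_flagged(self, rng):
        # hub wired only to nodes outside the module: overlap 0, P = 1
        graph, modules, hub = self._hub_graph(rng, wired=0)
        A = graph.adjacency
        hub_i = graph.nodes.index(hub)
        for j in range(60, 84):
            A[hub_i, j] = A[j, hub_i] = 0.95
        graph = network.CoexpressionGraph(
            nodes=graph.nodes, adjacency=A, tom=network.tom_from_adjacency(A), beta=6.0
        )
        kd = network.key_drivers(graph, modules, tau=0.5)
        row = kd[kd["node"] == hub].iloc[0]
        assert row["overlap"] == 0
        assert row["p"] == pytest.approx(1.0)
        assert not row["key_driver"]

    def test_empty_graph_after_thresholding(self, rng):
        graph, modules, _ = self._hub_graph(rng)
        with pytest.raises(ValueError, match="empty"):
            network.key_drivers(graph, modules, tau=1.01)
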