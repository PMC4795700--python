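from itertools import combinations

import networkx as nx
import numpy as np
import pytest
import sympy as sp
from scipy.integrate import solve_ivp

import gefcycle as gc
from gefcycle.mass_action import rhs_clamped_substrates
from gefcycle.qss import VERTICES, X_GDP, X_GTP, occupancy_basis


def brute_force_in_trees(graph, root):
    """Oracle: filter all 3-edge subsets with networkx reachability."""
    trees = set()
    for subset in combinations(graph.edges, len(graph) - 1):
        sub = nx.DiGraph(list(subset))
        if set(sub.nodes) != set(graph.nodes):
            continue
        if not nx.is_directed_acyclic_graph(sub):
            continue
        if any(sub.out_degree(v) != (0 if v == root else 1) for v in graph.nodes):
            continue
        if all(nx.has_path(sub, v, root) for v in graph.nodes if v != root):
            trees.add(tuple(sorted(subset)))
    return trees


def matrix_tree_count(graph, root):
    """Oracle: number of in-trees to root via the directed matrix-tree theorem."""
    nodes = [v for v in graph.nodes if v != root] + [root]
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    lap = np.zeros((n, n))
    for u, v in graph.edges:
        lap[idx[u], idx[u]] += 1.0
        lap[idx[u], idx[v]] -= 1.0
    return round(np.linalg.det(lap[:-1, :-1]))


class TestGraph:
    def test_structure(self, fixture_bundle):
        p, pools, *_ = fixture_bundle
        g = gc.build_gef_graph(p, pools)
        assert g.number_of_nodes() == 4
        assert g.number_of_edges() == 8
        assert all(g.in_degree(v) == 2 and g.out_degree(v) == 2 for v in g)
        assert nx.is_strongly_connected(g)

    def test_irreversible_stays_strongly_connected(self, fixture_bundle):
        p, pools, *_ = fixture_bundle
        g = gc.build_gef_graph(gc.make_irreversible(p), pools)
        g.remove_edge("E.G_GTP", "E.G")  # the disabled k7 step
        assert nx.is_strongly_connected(g)


class TestSpanningTrees:
    def test_four_trees_per_root_sixteen_total(self, fixture_bundle):
        p, pools, *_ = fixture_bundle
        g = gc.build_gef_graph(p, pools)
        total = 0
        for root in VERTICES:
            trees = gc.enumerate_spanning_trees(g, root)
            assert len(trees) == 4
            assert len(set(trees)) == 4
            assert len(trees) == matrix_tree_count(g, root)
            total += len(trees)
        assert total == 16

    def test_matches_brute_force_oracle(self, fixture_bundle):
        p, pools, *_ = fixture_bundle
        g = gc.build_gef_graph(p, pools)
        for root in VERTICES:
            assert set(gc.enumerate_spanning_trees(g, root)) == brute_force_in_trees(g, root)

    def test_two_vertex_graph(self):
        g = nx.DiGraph()
        g.add_edge("a", "b", label=sp.Integer(2))
        g.add_edge("b", "a", label=sp.Integer(3))
        assert gc.enumerate_spanning_trees(g, "a") == [(("b", "a"),)]
        assert gc.enumerate_spanning_trees(g, "b") == [(("a", "b"),)]

    def test_unreachable_root_empty(self):
        g = nx.DiGraph()
        g.add_edge("a", "b", label=sp.Integer(1))
        g.add_edge("c", "b", label=sp.Integer(1))
        assert gc.enumerate_spanning_trees(g, "c") == []


class TestOccupancyBasis:
    def test_uniform_for_unit_labels(self):
        p = gc.KineticParameters(1, 1, 1, 1, 1, 1, 1, 1)
        pools = gc.NucleotidePools(gdp=1.0, gtp=1.0)
        g = gc.build_gef_graph(p, pools)
        rho = occupancy_basis(g)
        subs = {X_GDP: 1.0, X_GTP: 1.0}
        vals = [float(rho[v].subs(subs)) for v in VERTICES]
        assert np.allclose(vals, vals[0])
        occ = gc.occupancies(rho, 1.0, 1.0, e0=0.4)
        assert all(v == pytest.approx(0.1) for v in occ.values())

    def test_occupancies_sum_to_e0(self):
        p, pools, totals = gc.sample_params(5)
        rho = occupancy_basis(gc.build_gef_graph(p, pools))
        occ = gc.occupancies(rho, 2.0, 3.0, e0=totals.e0)
        assert sum(occ.values()) == pytest.approx(totals.e0, rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_clamped_substrate_ode(self, seed):
        # with free G protein clamped, the enzyme subsystem relaxes to the
        # spanning-tree distribution
        p, pools, totals = gc.sample_params(seed, log_range=(0.1, 10.0))
        g_gdp, g_gtp = 3.0, 5.0
        sol = solve_ivp(
            lambda t, y: rhs_clamped_substrates(y, g_gdp, g_gtp, p, pools),
            (0, 1e4),
            [totals.e0, 0, 0, 0],
            rtol=1e-12, atol=1e-14, method="LSODA",
        )
        ode = dict(zip(VERTICES, sol.y[:, -1]))
        rho = occupancy_basis(gc.build_gef_graph(p, pools))
        occ = gc.occupancies(rho, g_gdp, g_gtp, totals.e0)
        for v in VERTICES:
            assert occ[v] == pytest.approx(ode[v], rel=1e-6)

    def test_basis_canonical_under_edge_order(self, fixture_bundle):
        p, pools, *_ = fixture_bundle
        g = gc.build_gef_graph(p, pools)
        rev = nx.DiGraph()
        rev.add_nodes_from(reversed(list(g.nodes)))
        for u, v in reversed(list(g.edges)):
            rev.add_edge(u, v, label=g.edges[u, v]["label"])
        r1, r2 = occupancy_basis(g), occupancy_basis(rev)
        for v in VERTICES:
            assert sp.expand(r1[v] - r2[v]) == 0


def closed_form_summary(p, pools):
    """Independently hand-derived constants for the 4-cycle (oracle)."""
    k, d, t = p, pools.gdp, pools.gtp
    K0 = k.k6 * k.k8 * t * (k.k2 + k.k3) + k.k2 * k.k4 * d * (k.k6 + k.k7)
    K1 = k.k1 * ((k.k6 + k.k3) * k.k8 * t + (k.k4 * d + k.k3) * (k.k6 + k.k7))
    K2 = k.k5 * ((k.k8 * t + k.k7) * (k.k2 + k.k3) + k.k4 * d * (k.k2 + k.k7))
    K1d = k.k1 * (k.k6 * k.k8 * t + k.k4 * d * (k.k6 + k.k7))
    K2d = k.k4 * k.k5 * k.k7 * d
    K1t = k.k1 * k.k3 * k.k8 * t
    K2t = k.k5 * (k.k8 * t * (k.k2 + k.k3) + k.k2 * k.k4 * d)
    K1g = k.k1 * k.k3 * (k.k6 + k.k7)
    K2g = k.k5 * k.k7 * (k.k2 + k.k3)
    return dict(K0=K0, K1=K1, K2=K2, K1d=K1d, K2d=K2d, K1t=K1t, K2t=K2t,
                K1g=K1g, K2g=K2g)


class TestSummaryParams:
    @pytest.mark.parametrize("seed", [0, 3, 8])
    def test_against_hand_derived_forms(self, seed):
        p, pools, _ = gc.sample_params(seed)
        s = gc.summary_params(p, pools)
        oracle = closed_form_summary(p, pools)
        for name, val in oracle.items():
            assert getattr(s, name) == pytest.approx(val, rel=1e-9), name

    def test_numerator_vanishes_at_kappa_ratio(self, fixture_bundle):
        p, pools, _, _ = fixture_bundle
        s = gc.summary_params(p, pools)
        g_gtp = 2.0
        assert gc.qss_rhs(s.kappa * g_gtp, g_gtp, 0.1, s, gc.GTPaseSpec(mode="none")) == pytest.approx(0.0, abs=1e-12)

    def test_michaelis_menten_reduction(self, fixture_bundle):
        # with no active G protein and no hydrolysis the reduced rate is
        # kfwd*x*e0/(K0 + K1*x)
        p, pools, _, _ = fixture_bundle
        s = gc.summary_params(p, pools)
        x, e0 = 1.7, 0.1
        assert gc.qss_rhs(x, 0.0, e0, s, gc.GTPaseSpec(mode="none")) == pytest.approx(
            s.kfwd * x * e0 / (s.K0 + s.K1 * x), rel=1e-12
        )

    def test_linear_in_e0(self, fixture_bundle):
        p, pools, _, _ = fixture_bundle
        s = gc.summary_params(p, pools)
        none = gc.GTPaseSpec(mode="none")
        assert gc.qss_rhs(1.0, 2.0, 0.2, s, none) == pytest.approx(
            2 * gc.qss_rhs(1.0, 2.0, 0.1, s, none), rel=1e-12
        )

    def test_homogeneity_in_rates(self, fixture_bundle):
        p, pools, _, _ = fixture_bundle
        c = 2.5
        scaled = gc.KineticParameters(*(c * p.as_array()))
        s1, s2 = gc.summary_params(p, pools), gc.summary_params(scaled, pools)
        assert s2.kfwd == pytest.approx(c**4 * s1.kfwd, rel=1e-9)
        assert s2.kappa == pytest.approx(s1.kappa, rel=1e-12)
        assert s2.K0 == pytest.approx(c**3 * s1.K0, rel=1e-9)

    def test_kappa_hat(self, fixture_bundle):
        p, pools, _, spec = fixture_bundle
        s = gc.summary_params(p, pools, spec)
        assert s.kappa_hat == pytest.approx(s.kfwd / spec.kase)
        with pytest.raises(ZeroDivisionError):
            gc.summary_params(p, pools, gc.GTPaseSpec(mode="intrinsic", kase=0.0))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_reduced_rate_matches_clamped_qss_flux(self, seed):
        # at the clamped-substrate enzyme QSS, the net production of free
        # g_gtp from the full model equals the reduced-model rate
        p, pools, totals = gc.sample_params(seed, log_range=(0.1, 10.0))
        s = gc.summary_params(p, pools)
        g_gdp, g_gtp = 4.0, 2.0
        rho = gc.occupancy_basis(gc.build_gef_graph(p, pools))
        occ = gc.occupancies(rho, g_gdp, g_gtp, totals.e0)
        e = occ["E"]
        full_rate = -p.k5 * e * g_gtp + p.k6 * occ["E.G_GTP"]
        red_rate = gc.qss_rhs(g_gdp, g_gtp, totals.e0, s, gc.GTPaseSpec(mode="none"))
        assert red_rate == pytest.approx(full_rate, rel=1e-9)


class TestReducedTrajectory:
    def test_tracks_full_model_when_enzyme_scarce(self, fixture_bundle):
        p, pools, _, _ = fixture_bundle
        e0, g0 = 0.1, 10.0
        s = gc.summary_params(p, pools)
        none = gc.GTPaseSpec(mode="none")

        y0 = np.array([e0, 0, 0, 0, g0, 0.0])
        t_eval = np.linspace(0, 20, 50)
        full = gc.simulate(p, pools, none, y0, (0, 20), t_eval=t_eval)

        def red(t, y):
            g_gtp = y[0]
            return [gc.qss_rhs(g0 - g_gtp, g_gtp, e0, s, none)]

        reduced = solve_ivp(red, (0, 20), [0.0], t_eval=t_eval,
                            rtol=1e-10, atol=1e-13, method="LSODA")
        # the reduction neglects O(e0) of complex-bound G protein, so the
        # expected accuracy is O(e0/g0) of the trajectory scale
        err = np.abs(reduced.y[0] - full.y[5])
        assert np.max(err) / np.max(full.y[5]) < 0.012
        late = t_eval > 10.0
        rel = err[late] / np.abs(full.y[5][late])
        assert np.max(rel) < 0.02
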