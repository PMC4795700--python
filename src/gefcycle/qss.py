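"""Quasi-steady-state reduction via the directed spanning-tree construction.

The four enzyme species form a cycle graph traversed in both directions.
Steady-state occupancies of the enzyme complexes are proportional to the
basis vector rho, where rho_i sums, over all directed spanning trees
rooted at vertex i (edges oriented toward the root), the product of the
tree's edge labels.  Collecting coefficients of the free substrate
concentrations in the rho polynomials yields the summary constants of the
one-equation reduced model

    d[G_GTP]/dt = kfwd*([G_GDP] - kappa*[G_GTP])*e0
                  / (K0 + K1*[G_GDP] + K2*[G_GTP])  -  f_GTPase

The engine is generic over labelled digraphs; the public surface is the
GEF cycle.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import sympy as sp

from . import parameters as pm
from .parameters import GTPaseSpec, KineticParameters, NucleotidePools

__all__ = [
    "VERTICES",
    "X_GDP",
    "X_GTP",
    "build_gef_graph",
    "enumerate_spanning_trees",
    "occupancy_basis",
    "occupancies",
    "SummaryParameters",
    "summary_params",
    "qss_rhs",
]

#: vertex names of the enzyme-complex graph, in occupancy order
VERTICES = ("E", "E.G_GDP", "E.G_GTP", "E.G")

#: symbols for the free substrate concentrations (the only symbolic labels)
X_GDP, X_GTP = sp.symbols("x_gdp x_gtp", nonnegative=True)


def build_gef_graph(params: KineticParameters, pools: NucleotidePools) -> nx.DiGraph:
    """The 4-vertex, 8-edge labelled digraph of the exchange mechanism.

    Bimolecular steps carry their free-partner concentration in the
    label: the substrate pools [G_GDP], [G_GTP] stay symbolic, the
    buffered nucleotide pools enter as numbers.
    """
    k = params
    g = nx.DiGraph()
    g.add_nodes_from(VERTICES)
    edges = [
        ("E", "E.G_GDP", sp.Float(k.k1) * X_GDP),
        ("E.G_GDP", "E", sp.Float(k.k2)),
        ("E.G_GDP", "E.G", sp.Float(k.k3)),
        ("E.G", "E.G_GDP", sp.Float(k.k4 * pools.gdp)),
        ("E", "E.G_GTP", sp.Float(k.k5) * X_GTP),
        ("E.G_GTP", "E", sp.Float(k.k6)),
        ("E.G_GTP", "E.G", sp.Float(k.k7)),
        ("E.G", "E.G_GTP", sp.Float(k.k8 * pools.gtp)),
    ]
    for u, v, label in edges:
        g.add_edge(u, v, label=label)
    return g


def enumerate_spanning_trees(graph: nx.DiGraph, root) -> list[tuple]:
    """All directed spanning trees oriented toward ``root``.

    Brute force over (n-1)-edge subsets: a subset is a rooted in-tree iff
    every non-root vertex has exactly one outgoing edge, the root none,
    and the subset is cycle-free (then every vertex reaches the root).
    Returns each tree as a sorted tuple of (u, v) edges.
    """
    nodes = list(graph.nodes)
    n = len(nodes)
    trees = []
    for subset in combinations(graph.edges, n - 1):
        out_deg = {v: 0 for v in nodes}
        for u, _ in subset:
            out_deg[u] += 1
        if out_deg[root] != 0:
            continue
        if any(out_deg[v] != 1 for v in nodes if v != root):
            continue
        # functional graph with no cycles => all chains terminate at root
        succ = {u: v for u, v in subset}
        ok = True
        for start in nodes:
            seen = set()
            v = start
            while v != root:
                if v in seen:
                    ok = False
                    break
                seen.add(v)
                v = succ[v]
            if not ok:
                break
        if ok:
            trees.append(tuple(sorted(subset)))
    return trees


def occupancy_basis(graph: nx.DiGraph) -> dict:
    """The basis polynomial rho_i for each vertex.

    rho_i = sum over trees rooted at i of the product of edge labels.
    Strictly positive for strictly positive rates.
    """
    rho = {}
    for root in graph.nodes:
        total = sp.Integer(0)
        for tree in enumerate_spanning_trees(graph, root):
            prod = sp.Integer(1)
            for u, v in tree:
                prod *= graph.edges[u, v]["label"]
            total += prod
        rho[root] = sp.expand(total)
    if all(r == 0 for r in rho.values()):
        raise ValueError("degenerate rates: all spanning-tree weights vanish")
    return rho


def occupancies(
    rho: dict, g_gdp: float, g_gtp: float, e0: float
) -> dict:
    """Numeric enzyme-complex concentrations X_i = rho_i/sum(rho) * e0."""
    subs = {X_GDP: g_gdp, X_GTP: g_gtp}
    vals = {v: float(rho[v].subs(subs)) for v in rho}
    total = sum(vals.values())
    if total <= 0:
        raise ValueError("degenerate occupancy basis: sum(rho) <= 0")
    return {v: vals[v] / total * e0 for v in vals}


@dataclass(frozen=True)
class SummaryParameters:
    """Constants of the reduced model and the occupancy equations.

    K0, K1, K2 form the shared denominator K0 + K1*[G_GDP] + K2*[G_GTP];
    (K1d, K2d), (K1t, K2t), (K1g, K2g) are the numerator pairs for the
    E.G_GDP, E.G_GTP and E.G occupancies.  kfwd is the product of the
    forward kinetic rates (with the buffered GTP pool absorbed), kappa
    the backward/forward ratio, Ks = K0/(K1*kappa + K2), and kappa_hat =
    kfwd/kase when intrinsic hydrolysis is active (else None).
    """

    K0: float
    K1: float
    K2: float
    K1d: float
    K2d: float
    K1t: float
    K2t: float
    K1g: float
    K2g: float
    kfwd: float
    kappa: float
    Ks: float
    kappa_hat: float | None = None


def _coeffs(poly: sp.Expr) -> tuple[float, float, float]:
    """Split a rho polynomial into (constant, coeff of x_gdp, coeff of x_gtp)."""
    p = sp.Poly(poly, X_GDP, X_GTP)
    c0 = float(p.coeff_monomial(1))
    c1 = float(p.coeff_monomial(X_GDP))
    c2 = float(p.coeff_monomial(X_GTP))
    if sp.expand(poly - (c0 + c1 * X_GDP + c2 * X_GTP)) != 0:
        raise ValueError("rho polynomial is not affine in the substrate symbols")
    return c0, c1, c2


def summary_params(
    params: KineticParameters,
    pools: NucleotidePools,
    spec: GTPaseSpec | None = None,
) -> SummaryParameters:
    """Extract the summary constants from the spanning-tree basis."""
    graph = build_gef_graph(params, pools)
    rho = occupancy_basis(graph)
    K0, c1e, c2e = _coeffs(rho["E"])
    if c1e != 0 or c2e != 0:
        raise ValueError("free-enzyme basis element should be substrate-free")
    K1d, K2d = _coeffs(rho["E.G_GDP"])[1:]
    K1t, K2t = _coeffs(rho["E.G_GTP"])[1:]
    K1g, K2g = _coeffs(rho["E.G"])[1:]
    K1 = K1d + K1t + K1g
    K2 = K2d + K2t + K2g
    kfwd = params.k1 * params.k3 * params.k6 * params.k8 * pools.gtp
    kap = pm.kappa(params, pools)
    Ks = K0 / (K1 * kap + K2)
    kappa_hat = None
    if spec is not None and spec.mode == "intrinsic":
        if spec.kase == 0:
            raise ZeroDivisionError("kappa_hat undefined: intrinsic mode with kase = 0")
        kappa_hat = kfwd / spec.kase
    return SummaryParameters(
        K0=K0, K1=K1, K2=K2,
        K1d=K1d, K2d=K2d, K1t=K1t, K2t=K2t, K1g=K1g, K2g=K2g,
        kfwd=kfwd, kappa=kap, Ks=Ks, kappa_hat=kappa_hat,
    )


def qss_rhs(
    g_gdp: float,
    g_gtp: float,
    e0: float,
    summary: SummaryParameters,
    spec: GTPaseSpec,
) -> float:
    """d[G_GTP]/dt of the reduced one-variable model (uM/s).

    Valid as an approximation to the full model only when e0 << g0.
    """
    from .mass_action import gtpase_flux

    denom = summary.K0 + summary.K1 * g_gdp + summary.K2 * g_gtp
    if denom == 0:
        raise ZeroDivisionError("degenerate summary constants: zero denominator")
    exchange = summary.kfwd * (g_gdp - summary.kappa * g_gtp) * e0 / denom
    return exchange - gtpase_flux(g_gtp, spec)
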