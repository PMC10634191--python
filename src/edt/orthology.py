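"""Orthology-variant graphs of a relaxed scenario.

Four notions are supported: weak/strict quasi-orthology (reconciliation
condition only) and weak/strict orthology (additionally requiring an
HGT-free connecting path), plus the symmetrized Fitch graph joining leaf
pairs separated by at least one HGT edge.  All graphs carry sigma as
vertex coloring for uniform I/O; the weak quasi-orthology graph need not
be properly colored.
"""

from __future__ import annotations

from itertools import combinations

from edt.scenario import Scenario, hgt_edges
from edt.divergence import ColoredGraph

__all__ = ["quasi_orthology", "orthology", "fitch_graph"]


def _hgt_free_components(s: Scenario) -> dict[str, int]:
    """Component index of each gene-tree vertex in T minus its HGT edges.

    Two leaves are joined by an HGT-free path iff they share a component.
    """
    lam = hgt_edges(s)
    comp: dict[str, int] = {}
    idx = 0
    for v in s.T.preorder():
        p = s.T.parent(v)
        if p is None or lam[(p, v)] == 1:
            idx += 1
            comp[v] = idx
        else:
            comp[v] = comp[p]
    return comp


def _lca_condition(s: Scenario, x: str, y: str, strict: bool) -> bool:
    m = s.mu[s.T.lca((x, y))]
    if strict:
        return m == s.S.lca((s.sigma[x], s.sigma[y]))
    return not isinstance(m, tuple) and m in s.S.inner_vertices


def quasi_orthology(s: Scenario, strict: bool = False) -> ColoredGraph:
    """Weak: xy is an edge iff mu(lca_T(x,y)) is an inner species vertex.
    Strict: iff mu(lca_T(x,y)) equals lca_S(sigma(x), sigma(y))."""
    leaves = sorted(s.T.leaves)
    edges = [
        (x, y)
        for x, y in combinations(leaves, 2)
        if _lca_condition(s, x, y, strict)
    ]
    return ColoredGraph.make(leaves, edges, {x: s.sigma[x] for x in leaves})


def orthology(s: Scenario, strict: bool = False) -> ColoredGraph:
    """As :func:`quasi_orthology`, additionally requiring that the path
    between x and y in T contains no HGT edge."""
    comp = _hgt_free_components(s)
    leaves = sorted(s.T.leaves)
    edges = [
        (x, y)
        for x, y in combinations(leaves, 2)
        if comp[x] == comp[y] and _lca_condition(s, x, y, strict)
    ]
    return ColoredGraph.make(leaves, edges, {x: s.sigma[x] for x in leaves})


def fitch_graph(s: Scenario) -> ColoredGraph:
    """Symmetrized Fitch graph: xy is an edge iff the T-path between x and
    y contains an HGT edge."""
    comp = _hgt_free_components(s)
    leaves = sorted(s.T.leaves)
    edges = [
        (x, y) for x, y in combinations(leaves, 2) if comp[x] != comp[y]
    ]
    return ColoredGraph.make(leaves, edges, {x: s.sigma[x] for x in leaves})
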