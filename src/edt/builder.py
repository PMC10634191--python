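"""Construction of a relaxed (or restricted) scenario explaining a valid
graph 3-partition.

The gene tree and its reconciliation are grown top-down by a recursive
decomposition of the leaf set guided by three auxiliary graphs H1, H2, H3
and the species tree.  With ``restricted=True`` the choice of the species
child for the H2-component vertices follows the modified rule that makes
the output additionally satisfy S4-S6.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from typing import Iterable, Optional

from edt.trees import (
    InputError,
    Number,
    PlantedTree,
    assign_time_map,
    fresh_label,
)
from edt.scenario import Scenario
from edt.divergence import (
    ColoredGraph,
    GraphThreePartition,
    is_cograph,
    is_properly_colored,
)
from edt.triples import TripleSystem, agrees, mixed_tree, species_triples

__all__ = [
    "AuxiliaryGraphs",
    "BuildInputError",
    "auxiliary_graphs",
    "epsilon",
    "classify_input",
    "build_scenario",
    "build_scenario_with_trace",
    "TraceEntry",
]

# explainability conditions in their reporting order
CONDITIONS = (
    "partition",
    "proper_coloring_ldt",
    "proper_coloring_edt",
    "cograph_ldt",
    "cograph_pdt",
    "triples_inconsistent",
)


class BuildInputError(InputError):
    """The 3-partition is not a valid input; names the failed condition."""

    def __init__(self, condition: str, detail: str = ""):
        super().__init__(f"invalid input: {condition}" + (f" ({detail})" if detail else ""))
        self.condition = condition


def classify_input(
    g: GraphThreePartition,
) -> tuple[Optional[str], TripleSystem, Optional[PlantedTree]]:
    """Evaluate the explainability conditions in order.

    Returns (failed_condition_or_None, species triple system, species tree
    agreeing with the system or None if inconsistent).
    """
    sys_s = species_triples(g)
    if g.partition_violations():
        return "partition", sys_s, None
    if not is_properly_colored(g.ldt):
        return "proper_coloring_ldt", sys_s, None
    if not is_properly_colored(g.edt):
        return "proper_coloring_edt", sys_s, None
    if not is_cograph(g.ldt)[0]:
        return "cograph_ldt", sys_s, None
    if not is_cograph(g.pdt)[0]:
        return "cograph_pdt", sys_s, None
    tree = mixed_tree(sys_s.required, sys_s.forbidden, sys_s.labels)
    if tree is None:
        return "triples_inconsistent", sys_s, None
    return None, sys_s, tree


@dataclass
class AuxiliaryGraphs:
    """The three auxiliary graphs of one recursion step, on the current
    leaf subset L'.  H2 refines H1, H3 refines H2 and has clique
    components."""

    h1_edges: frozenset
    h2_edges: frozenset
    h3_edges: frozenset
    components_h1: list[frozenset]
    components_h2: list[frozenset]
    components_h3: list[frozenset]


def _components(verts: Iterable[str], edges: Iterable[frozenset]) -> list[frozenset]:
    adj: dict[str, set] = {v: set() for v in verts}
    for e in edges:
        u, v = tuple(e)
        adj[u].add(v)
        adj[v].add(u)
    seen: set = set()
    comps = []
    for v in sorted(adj):
        if v in seen:
            continue
        comp = {v}
        stack = [v]
        seen.add(v)
        while stack:
            w = stack.pop()
            for x in adj[w]:
                if x not in seen:
                    seen.add(x)
                    comp.add(x)
                    stack.append(x)
        comps.append(frozenset(comp))
    # deterministic: order components by smallest contained label
    comps.sort(key=lambda c: min(c))
    return comps


def auxiliary_graphs(
    g: GraphThreePartition, subset: Iterable[str], u_s: str, S: PlantedTree
) -> AuxiliaryGraphs:
    """Auxiliary graphs H1, H2, H3 on L' for an inner species vertex u_S.

    H1 joins the LDT and EDT edges within L'.  H2 keeps the LDT edges and
    only those EDT edges whose colors diverge strictly below u_S.  H3
    joins x, y lying in one H2 component whose colors descend from a
    common child of u_S.
    """
    lp = sorted(set(subset))
    sig = g.sigma
    sub_colors = {sig[x] for x in lp}
    if not sub_colors <= S.subtree_leaves(u_s):
        raise InputError(
            f"recursion invariant broken: sigma(L') not below {u_s!r}"
        )
    if S.is_leaf(u_s):
        raise InputError("auxiliary graphs are defined for inner species vertices")
    h1, h2 = set(), set()
    below: dict[frozenset, bool] = {}
    for x, y in combinations(lp, 2):
        e = frozenset((x, y))
        lca_below = S.lca((sig[x], sig[y])) != u_s
        if e in g.ldt.edges:
            h1.add(e)
            h2.add(e)
        elif e in g.edt.edges:
            h1.add(e)
            if lca_below:
                h2.add(e)
        below[e] = lca_below
    comps2 = _components(lp, h2)
    comp_of = {}
    for c in comps2:
        for x in c:
            comp_of[x] = c
    h3 = {
        frozenset((x, y))
        for x, y in combinations(lp, 2)
        if comp_of[x] is comp_of[y] and below[frozenset((x, y))]
    }
    return AuxiliaryGraphs(
        frozenset(h1),
        frozenset(h2),
        frozenset(h3),
        _components(lp, h1),
        comps2,
        _components(lp, h3),
    )


def epsilon(S: PlantedTree, tau_s: dict[str, Number]) -> Number:
    """One third of the minimum edge duration of the dated species tree
    (planted edge included); small enough that all nested stamp
    assignments of the builder remain time-consistent."""
    d_min = None
    for u, v in S.edges():
        d = tau_s[u] - tau_s[v]
        if d <= 0:
            raise InputError(f"degenerate (non-increasing) edge {u}->{v}")
        if d_min is None or d < d_min:
            d_min = d
    if d_min is None:
        raise InputError("species tree has no edges")
    if isinstance(d_min, (int, Fraction)):
        return Fraction(d_min, 3)
    return d_min / 3


@dataclass
class TraceEntry:
    """One vertex creation event of the recursion (before suppression)."""

    kind: str  # 'local_root' | 'h1' | 'h2' | 'leaf'
    vertex: str
    time: Number
    mu: object
    subset: tuple
    u_s: str


def build_scenario_with_trace(
    g: GraphThreePartition,
    restricted: bool = False,
    species_tree: Optional[PlantedTree] = None,
    tau_s: Optional[dict[str, Number]] = None,
    scale: Number = 3,
) -> tuple[Scenario, list[TraceEntry]]:
    """As :func:`build_scenario` but also returns the creation trace."""
    if not g.vertices:
        raise InputError("cannot build a scenario for an empty vertex set")
    failed, sys_s, built_tree = classify_input(g)
    if failed is not None:
        raise BuildInputError(failed)
    if species_tree is not None:
        S = species_tree if species_tree.is_planted else species_tree.plant()
        colors = frozenset(g.sigma.values())
        if not colors <= S.leaves:
            raise InputError("supplied species tree misses colors of the input")
        if not agrees(S, sys_s):
            raise InputError(
                "supplied species tree does not agree with the species triples"
            )
    else:
        S = built_tree
    if tau_s is None:
        tau_s = assign_time_map(S, scale=scale)
    eps = epsilon(S, tau_s)

    sig = g.sigma
    children: dict[str, list] = {}
    mu: dict[str, object] = {}
    tau_t: dict[str, Number] = {}
    trace: list[TraceEntry] = []
    counter = [0]
    taken = set(g.vertices)

    def new_vertex() -> str:
        counter[0] += 1
        lbl = f"t{counter[0]}"
        while lbl in taken:
            counter[0] += 1
            lbl = f"t{counter[0]}"
        taken.add(lbl)
        return lbl

    def record(kind, vertex, time, m, subset, u_s):
        trace.append(TraceEntry(kind, vertex, time, m, tuple(sorted(subset)), u_s))

    def build_gene_tree(lp: frozenset, u_s: str) -> str:
        # local root rho', mapped to the species edge above u_S
        rho = new_vertex()
        children[rho] = []
        tau_t[rho] = tau_s[u_s] + eps
        mu[rho] = (S.parent(u_s), u_s)
        record("local_root", rho, tau_t[rho], mu[rho], lp, u_s)
        if S.is_leaf(u_s):
            for x in sorted(lp):
                children[rho].append(x)
                children[x] = []
                tau_t[x] = tau_s[u_s]
                mu[x] = sig[x]
                record("leaf", x, tau_t[x], mu[x], lp, u_s)
            return rho
        aux = auxiliary_graphs(g, lp, u_s, S)
        for comp1 in aux.components_h1:
            u_i = new_vertex()
            children[rho].append(u_i)
            children[u_i] = []
            tau_t[u_i] = tau_s[u_s]
            mu[u_i] = u_s
            record("h1", u_i, tau_t[u_i], mu[u_i], comp1, u_s)
            comps2 = [c for c in aux.components_h2 if c <= comp1]
            # restricted choice rule: with two or more H2 components inside
            # this H1 component, pin the species-child choice of the two
            # components holding the endpoints of one H1-minus-H2 edge so
            # that the created vertex is witnessed by an lca-matching pair.
            pinned: dict[frozenset, str] = {}
            if restricted and len(comps2) >= 2:
                cross = sorted(
                    tuple(sorted(e))
                    for e in aux.h1_edges - aux.h2_edges
                    if e <= comp1
                )
                x, y = cross[0]
                comp_of = {v: c for c in comps2 for v in c}
                pinned[comp_of[x]] = _child_above(S, u_s, sig[x])
                pinned[comp_of[y]] = _child_above(S, u_s, sig[y])
            for comp2 in comps2:
                v_j = new_vertex()
                children[u_i].append(v_j)
                children[v_j] = []
                v_star = pinned.get(comp2) or _default_child_choice(S, u_s, comp2, sig)
                tau_t[v_j] = tau_s[u_s] - eps
                mu[v_j] = (u_s, v_star)
                record("h2", v_j, tau_t[v_j], mu[v_j], comp2, u_s)
                for comp3 in (c for c in aux.components_h3 if c <= comp2):
                    v_s = _child_above(S, u_s, sig[min(comp3)])
                    # recursion invariant: all colors of the H3 component descend from v_S
                    assert {sig[v] for v in comp3} <= S.subtree_leaves(v_s)
                    sub_root = build_gene_tree(comp3, v_s)
                    children[v_j].append(sub_root)
        return rho

    top = build_gene_tree(frozenset(g.vertices), S.root)
    planted = fresh_label("0T", taken)
    children[planted] = [top]
    tau_t[planted] = tau_s[S.planted_root]
    mu[planted] = S.planted_root

    # suppress inner vertices with a single child (keep planted root, leaves)
    def suppress() -> bool:
        for v, cs in list(children.items()):
            if v == planted or not cs or len(cs) >= 2:
                continue
            # splice v out: its only child takes its place at the parent
            for p, pcs in children.items():
                if v in pcs:
                    pcs[pcs.index(v)] = cs[0]
                    break
            del children[v]
            del tau_t[v]
            del mu[v]
            return True
        return False

    while suppress():
        pass

    root = children[planted][0]
    T = PlantedTree(
        {v: tuple(cs) for v, cs in children.items()},
        root=root,
        planted_root=planted,
    )
    scenario = Scenario(
        T=T,
        S=S,
        sigma={x: sig[x] for x in T.leaves},
        mu=mu,
        tau_T=tau_t,
        tau_S=dict(tau_s),
    )
    return scenario, trace


def _child_above(S: PlantedTree, u_s: str, color: str) -> str:
    """The child of u_S on the path toward the species leaf *color*."""
    for c in S.children(u_s):
        if color in S.subtree_leaves(c):
            return c
    raise InputError(f"color {color!r} not below {u_s!r}")


def _default_child_choice(
    S: PlantedTree, u_s: str, comp: frozenset, sig
) -> str:
    """Default v*_S: among the children of u_S whose subtree meets the
    colors of the component, the one with the smallest leaf label."""
    candidates = []
    colors = {sig[x] for x in comp}
    for c in S.children(u_s):
        if colors & S.subtree_leaves(c):
            candidates.append(c)
    return min(candidates, key=lambda c: min(S.subtree_leaves(c)))


def build_scenario(
    g: GraphThreePartition,
    restricted: bool = False,
    species_tree: Optional[PlantedTree] = None,
    tau_s: Optional[dict[str, Number]] = None,
    scale: Number = 3,
) -> Scenario:
    """Construct a relaxed scenario explaining the 3-partition *g*.

    Raises :class:`BuildInputError` naming the first failed explainability
    condition when *g* is not a valid input.  With ``restricted=True`` the
    output additionally satisfies S4-S6.  A species tree agreeing with the
    species triple system may be supplied and is used unchanged; its time
    map defaults to leaves at 0 and ``scale * height`` at inner vertices.
    """
    scenario, _ = build_scenario_with_trace(
        g, restricted=restricted, species_tree=species_tree, tau_s=tau_s, scale=scale
    )
    return scenario
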