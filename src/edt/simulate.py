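"""Synthetic scenario generator and canonical worked-example fixtures.

The generator grows a gene tree top-down inside a dated species tree:
lineages pass through speciation vertices (mapped onto them), duplicate
inside species edges, or transfer a copy to a contemporaneous
incomparable species edge.  All stamps are exact rationals; with
jittering enabled (default) the non-speciation stamps avoid every inner
species stamp, so generated scenarios are generic by construction.  Any
valid-scenario generator would do as a test bed; this one is merely
deterministic per seed and sound.
"""

from __future__ import annotations

import random
from fractions import Fraction
from typing import Optional, Union

from edt.trees import InputError, PlantedTree, fresh_label, tree_from_nested
from edt.scenario import Scenario
from edt.divergence import ColoredGraph, GraphThreePartition

__all__ = ["random_scenario", "fixture", "FIXTURE_NAMES"]

_JITTER_DENOM = 9973
_DESCEND_PROB = 0.9


def _species_labels(n: int) -> list[str]:
    """A, B, ..., Z, AA, AB, ... spreadsheet-style labels."""
    out = []
    for i in range(n):
        k = i
        lbl = ""
        while True:
            lbl = chr(ord("A") + k % 26) + lbl
            k = k // 26 - 1
            if k < 0:
                break
        out.append(lbl)
    return out


def _random_species_tree(
    n: int, binary_only: bool, rng: random.Random
) -> PlantedTree:
    labels = _species_labels(n)
    if n == 1:
        return tree_from_nested(labels[0], planted=True, label_prefix="sv")
    subtrees: list = list(labels)
    while len(subtrees) > 1:
        k = 2
        if not binary_only and len(subtrees) >= 3 and rng.random() < 0.3:
            k = 3
        picks = rng.sample(range(len(subtrees)), k)
        merged = tuple(subtrees[i] for i in sorted(picks))
        subtrees = [t for i, t in enumerate(subtrees) if i not in picks]
        subtrees.append(merged)
    return tree_from_nested(subtrees[0], planted=True, label_prefix="sv")


def _random_species_times(S: PlantedTree, rng: random.Random) -> dict:
    tau: dict = {}
    used: set = set()
    for v in S.postorder():
        cs = S.children(v)
        if not cs:
            tau[v] = 0
        else:
            t = max(tau[c] for c in cs) + rng.randint(1, 4)
            while t in used:
                t += 1
            used.add(t)
            tau[v] = t
    return tau


def random_scenario(
    n_species: int,
    n_genes: int,
    transfer_prob: float = 0.2,
    dup_prob: float = 0.2,
    binary_only: bool = False,
    hgt_free: bool = False,
    seed: int = 0,
    jitter: bool = True,
) -> Scenario:
    """Generate a valid relaxed scenario, deterministic per seed.

    *n_genes* bounds the number of gene leaves (a lineage budget); the
    realized leaf count depends on how the branching process unfolds.
    ``hgt_free`` forces the transfer probability to zero; ``binary_only``
    yields binary species and gene trees.
    """
    if n_species < 1 or n_genes < 1:
        raise InputError("n_species and n_genes must be >= 1")
    if not (0 <= transfer_prob <= 1 and 0 <= dup_prob <= 1):
        raise InputError("probabilities must lie in [0, 1]")
    if transfer_prob + dup_prob > 1:
        raise InputError("transfer_prob + dup_prob must not exceed 1")
    if hgt_free:
        transfer_prob = 0.0
    rng = random.Random(seed)
    S = _random_species_tree(n_species, binary_only, rng)
    tau_s = _random_species_times(S, rng)
    inner_stamps = {tau_s[v] for v in S.inner_vertices}
    s_edges = list(S.edges())

    children: dict[str, list] = {}
    mu: dict[str, object] = {}
    tau_t: dict[str, object] = {}
    sigma: dict[str, str] = {}
    counters = {"v": 0, "g": 0}
    budget = [n_genes - 1]

    def new_label(kind: str) -> str:
        counters[kind] += 1
        return f"{kind}{counters[kind]}"

    def pick_time(lo, hi):
        span = hi - lo
        if not jitter:
            return lo + Fraction(span, 2)
        while True:
            t = lo + span * Fraction(rng.randint(1, _JITTER_DENOM - 1), _JITTER_DENOM)
            if t not in inner_stamps:
                return t

    def grow(edge: tuple, t_hi) -> str:
        u, v = edge
        lo = tau_s[v]
        if budget[0] > 0:
            r = rng.random()
            if r < dup_prob:
                t = pick_time(lo, t_hi)
                budget[0] -= 1
                node = new_label("v")
                mu[node] = edge
                tau_t[node] = t
                children[node] = [grow(edge, t), grow(edge, t)]
                return node
            if r < dup_prob + transfer_prob:
                t = pick_time(lo, t_hi)
                recipients = [
                    f
                    for f in s_edges
                    if not S.comparable_ext(f, edge)
                    and tau_s[f[1]] < t < tau_s[f[0]]
                ]
                if recipients:
                    budget[0] -= 1
                    f = recipients[rng.randrange(len(recipients))]
                    node = new_label("v")
                    mu[node] = edge
                    tau_t[node] = t
                    children[node] = [grow(edge, t), grow(f, t)]
                    return node
                # no contemporaneous incomparable edge: transfer skipped
        if S.is_leaf(v):
            x = new_label("g")
            sigma[x] = v
            mu[x] = v
            tau_t[x] = tau_s[v]
            children[x] = []
            return x
        kids = S.children(v)
        chosen = [w for w in kids if rng.random() < _DESCEND_PROB]
        if not chosen:
            chosen = [kids[rng.randrange(len(kids))]]
        if len(chosen) - 1 > budget[0]:
            chosen = chosen[: budget[0] + 1]
        budget[0] -= len(chosen) - 1
        node = new_label("v")
        mu[node] = v
        tau_t[node] = tau_s[v]
        children[node] = [grow((v, w), tau_s[v]) for w in chosen]
        return node

    top = grow((S.planted_root, S.root), tau_s[S.planted_root])
    planted = fresh_label("0T", set(children))
    children[planted] = [top]
    mu[planted] = S.planted_root
    tau_t[planted] = tau_s[S.planted_root]

    # suppress pass-through vertices with a single child
    changed = True
    while changed:
        changed = False
        for v, cs in list(children.items()):
            if v == planted or not cs or len(cs) >= 2:
                continue
            for p, pcs in children.items():
                if v in pcs:
                    pcs[pcs.index(v)] = cs[0]
                    break
            del children[v], tau_t[v], mu[v]
            changed = True
            break

    T = PlantedTree(
        {v: tuple(cs) for v, cs in children.items()},
        root=children[planted][0],
        planted_root=planted,
    )
    return Scenario(T=T, S=S, sigma=sigma, mu=mu, tau_T=tau_t, tau_S=tau_s)


# -- canonical fixtures --------------------------------------------------------

FIXTURE_NAMES = (
    "star_example",
    "c4_example",
    "fig9_partition",
    "p4_partition",
    "c6_partition",
    "edt_obstruction",
)


def _star_example() -> Scenario:
    S = tree_from_nested((("X", "Y"), "Z"), planted=True, label_prefix="sv")
    T = tree_from_nested(("x", "y", "z"), planted=True, label_prefix="gv")
    xy = S.lca(("X", "Y"))
    tau_s = {"X": 0, "Y": 0, "Z": 0, xy: 3, S.root: 6, S.planted_root: 9}
    tau_t = {"x": 0, "y": 0, "z": 0, T.root: 6, T.planted_root: 9}
    mu = {
        "x": "X",
        "y": "Y",
        "z": "Z",
        T.root: S.root,
        T.planted_root: S.planted_root,
    }
    return Scenario(
        T=T, S=S, sigma={"x": "X", "y": "Y", "z": "Z"}, mu=mu, tau_T=tau_t, tau_S=tau_s
    )


def _c4_example() -> Scenario:
    S = tree_from_nested(("A", "B"), planted=True, label_prefix="sv")
    T = tree_from_nested((("a1", "a2"), ("b1", "b2")), planted=True, label_prefix="gv")
    la = T.lca(("a1", "a2"))
    lb = T.lca(("b1", "b2"))
    sigma = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    tau_s = {"A": 0, "B": 0, S.root: 3, S.planted_root: 6}
    tau_t = {
        "a1": 0,
        "a2": 0,
        "b1": 0,
        "b2": 0,
        la: Fraction(3, 2),
        lb: Fraction(3, 2),
        T.root: 3,
        T.planted_root: 6,
    }
    mu = {
        "a1": "A",
        "a2": "A",
        "b1": "B",
        "b2": "B",
        la: (S.root, "A"),
        lb: (S.root, "B"),
        T.root: S.root,
        T.planted_root: S.planted_root,
    }
    return Scenario(T=T, S=S, sigma=sigma, mu=mu, tau_T=tau_t, tau_S=tau_s)


def _fig9_partition() -> GraphThreePartition:
    sigma = {"a": "A", "a'": "A", "b": "B", "b'": "B"}
    return GraphThreePartition.from_classes(
        sigma.keys(),
        sigma,
        ldt_edges=[("a", "b"), ("a'", "b'")],
        edt_edges=[("a", "b'"), ("a'", "b")],
        pdt_edges=[("a", "a'"), ("b", "b'")],
    )


def _p4_partition() -> GraphThreePartition:
    # EDT graph = induced P4 a-b-c-b' on three colors (inner color repeat)
    sigma = {"a": "A", "b": "B", "c": "C", "b'": "B"}
    return GraphThreePartition.from_classes(
        sigma.keys(),
        sigma,
        ldt_edges=[("a", "b'")],
        edt_edges=[("a", "b"), ("b", "c"), ("c", "b'")],
        pdt_edges=[("a", "c"), ("b", "b'")],
    )


def _c6_partition() -> GraphThreePartition:
    # EDT graph = induced C6 (contains induced P5s) on six distinct colors
    verts = ["a", "b", "c", "d", "e", "f"]
    sigma = {v: v.upper() for v in verts}
    cycle = [
        ("a", "b"),
        ("b", "c"),
        ("c", "d"),
        ("d", "e"),
        ("e", "f"),
        ("f", "a"),
    ]
    diagonals = [("a", "d"), ("b", "e"), ("c", "f")]
    return GraphThreePartition.from_classes(
        verts, sigma, ldt_edges=diagonals, edt_edges=cycle, pdt_edges=None
    )


def _edt_obstruction() -> ColoredGraph:
    # properly colored cograph that is not an EDT graph: the main component
    # forces a species triple among AC|B, AD|B, CD|A for every assignment
    # of the free pairs, while three P3 components forbid all three
    sigma = {
        "a": "A",
        "b": "B",
        "c": "C",
        "d": "D",
        "a1": "A",
        "c1": "C",
        "b1": "B",
        "a2": "A",
        "d2": "D",
        "b2": "B",
        "d3": "D",
        "c3": "C",
        "a3": "A",
    }
    edges = [
        ("a", "b"),
        ("b", "c"),
        ("b", "d"),
        ("c", "d"),
        ("a1", "c1"),
        ("c1", "b1"),
        ("a2", "d2"),
        ("d2", "b2"),
        ("d3", "c3"),
        ("c3", "a3"),
    ]
    return ColoredGraph.make(sigma.keys(), edges, sigma)


def fixture(
    name: str,
) -> Union[Scenario, GraphThreePartition, ColoredGraph]:
    """Canonical worked-example instances used throughout the test suite."""
    builders = {
        "star_example": _star_example,
        "c4_example": _c4_example,
        "fig9_partition": _fig9_partition,
        "p4_partition": _p4_partition,
        "c6_partition": _c6_partition,
        "edt_obstruction": _edt_obstruction,
    }
    if name not in builders:
        raise InputError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
    return builders[name]()
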