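"""Rooted-triple systems read off a graph 3-partition, and tree building
from required plus forbidden triples.

``aho_build`` is the classic BUILD recursion on the Aho graph.
``mixed_tree`` solves the mixed-triples problem restricted to trees: find
a (possibly non-binary) tree displaying every required triple and none of
the forbidden ones.  Any agreeing tree is acceptable downstream, so the
implementation is deterministic but otherwise free in its tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional

from edt.trees import InputError, PlantedTree, RootedTriple, tree_from_nested
from edt.divergence import GraphThreePartition

__all__ = [
    "TripleSystem",
    "gene_triples",
    "species_triples",
    "aho_build",
    "mixed_tree",
    "agrees",
    "enumerate_trees",
    "read_triples_text",
    "write_triples_text",
]


@dataclass(frozen=True)
class TripleSystem:
    """Required triples R and forbidden triples F over a label set."""

    required: frozenset  # of RootedTriple
    forbidden: frozenset  # of RootedTriple
    labels: frozenset

    def __post_init__(self):
        for t in self.required | self.forbidden:
            if not t.leaves <= self.labels:
                raise InputError(f"triple {t} uses labels outside the system")

    @property
    def contradictory(self) -> frozenset:
        """Triples present in both R and F (detected, not forbidden)."""
        return self.required & self.forbidden


def gene_triples(g: GraphThreePartition) -> TripleSystem:
    """Informative/forbidden triples on the gene leaves L.

    R contains xy|z when (a) xy in G< and xz, yz not in G<, or (b) xz and
    yz in G> and xy not in G>.  F contains xz|y and yz|x when xz, yz in G=
    and xy not in G=.
    """
    required: set = set()
    forbidden: set = set()
    lt, eq, gt = g.ldt.edges, g.edt.edges, g.pdt.edges
    for a, b, c in combinations(sorted(g.vertices), 3):
        for x, y, z in ((a, b, c), (a, c, b), (b, c, a)):
            xy, xz, yz = (
                frozenset((x, y)),
                frozenset((x, z)),
                frozenset((y, z)),
            )
            if xy in lt and xz not in lt and yz not in lt:
                required.add(RootedTriple(x, y, z))
            if xz in gt and yz in gt and xy not in gt:
                required.add(RootedTriple(x, y, z))
            if xz in eq and yz in eq and xy not in eq:
                forbidden.add(RootedTriple(x, z, y))
                forbidden.add(RootedTriple(y, z, x))
    return TripleSystem(frozenset(required), frozenset(forbidden), g.vertices)


def species_triples(g: GraphThreePartition) -> TripleSystem:
    """Informative/forbidden triples on the colors sigma(L).

    R contains XY|Z (colors pairwise distinct) when (a') xz, yz in G< and
    xy not in G<, or (b') xy in G> and xz, yz not in G>.  F contains XZ|Y
    and YZ|X when xz, yz in G= and xy not in G=.
    """
    required: set = set()
    forbidden: set = set()
    sig = g.sigma
    lt, eq, gt = g.ldt.edges, g.edt.edges, g.pdt.edges
    for a, b, c in combinations(sorted(g.vertices), 3):
        if len({sig[a], sig[b], sig[c]}) != 3:
            continue
        for x, y, z in ((a, b, c), (a, c, b), (b, c, a)):
            X, Y, Z = sig[x], sig[y], sig[z]
            xy, xz, yz = (
                frozenset((x, y)),
                frozenset((x, z)),
                frozenset((y, z)),
            )
            if xz in lt and yz in lt and xy not in lt:
                required.add(RootedTriple(X, Y, Z))
            if xy in gt and xz not in gt and yz not in gt:
                required.add(RootedTriple(X, Y, Z))
            if xz in eq and yz in eq and xy not in eq:
                forbidden.add(RootedTriple(X, Z, Y))
                forbidden.add(RootedTriple(Y, Z, X))
    return TripleSystem(
        frozenset(required), frozenset(forbidden), frozenset(sig.values())
    )


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, x, y):
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            # deterministic: smaller label wins as representative
            if ry < rx:
                rx, ry = ry, rx
            self.parent[ry] = rx
            return True
        return False


def aho_build(
    required: Iterable[RootedTriple], labels: Iterable[str]
) -> Optional[PlantedTree]:
    """BUILD: a planted tree on *labels* displaying all of R, or None iff R
    is inconsistent."""
    labels = sorted(set(labels))
    triples = list(required)
    for t in triples:
        if not t.leaves <= set(labels):
            raise InputError(f"triple {t} uses labels outside the label set")

    def rec(ls: list, ts: list):
        if len(ls) == 1:
            return ls[0]
        uf = _UnionFind(ls)
        for t in ts:
            uf.union(t.a, t.b)
        blocks: dict[str, list] = {}
        for x in ls:
            blocks.setdefault(uf.find(x), []).append(x)
        if len(blocks) == 1:
            return None
        kids = []
        for root in sorted(blocks):
            block = sorted(blocks[root])
            bset = set(block)
            sub = [t for t in ts if t.leaves <= bset]
            child = rec(block, sub)
            if child is None:
                return None
            kids.append(child)
        return tuple(kids)

    nested = rec(labels, triples)
    if nested is None:
        return None
    return tree_from_nested(nested, planted=True, label_prefix="s")


def mixed_tree(
    required: Iterable[RootedTriple],
    forbidden: Iterable[RootedTriple],
    labels: Iterable[str],
) -> Optional[PlantedTree]:
    """A planted tree on *labels* that displays every triple of R and none
    of F, or None iff no such tree exists.

    Recursion: the children blocks of the current vertex are the finest
    partition that (i) keeps the two grouped leaves of every required
    triple together (Aho components) and (ii) is closed under the rule
    that whenever the pair of a forbidden triple xy|z ends up in one
    block, z is pulled into that block too (otherwise the triple would be
    displayed at this vertex).
    """
    labels = sorted(set(labels))
    req = list(required)
    forb = list(forbidden)
    for t in req + forb:
        if not t.leaves <= set(labels):
            raise InputError(f"triple {t} uses labels outside the label set")

    def rec(ls: list, rs: list, fs: list):
        if len(ls) == 1:
            return ls[0]
        uf = _UnionFind(ls)
        for t in rs:
            uf.union(t.a, t.b)
        changed = True
        while changed:
            changed = False
            for t in sorted(fs):
                if uf.find(t.a) == uf.find(t.b) and uf.find(t.outgroup) != uf.find(t.a):
                    uf.union(t.a, t.outgroup)
                    changed = True
        blocks: dict[str, list] = {}
        for x in ls:
            blocks.setdefault(uf.find(x), []).append(x)
        if len(blocks) == 1:
            return None
        kids = []
        for root in sorted(blocks):
            block = sorted(blocks[root])
            bset = set(block)
            child = rec(
                block,
                [t for t in rs if t.leaves <= bset],
                [t for t in fs if t.leaves <= bset],
            )
            if child is None:
                return None
            kids.append(child)
        return tuple(kids)

    nested = rec(labels, req, forb)
    if nested is None:
        return None
    return tree_from_nested(nested, planted=True, label_prefix="s")


def agrees(tree: PlantedTree, system: TripleSystem) -> bool:
    """True iff the tree displays every required and no forbidden triple."""
    if not system.labels <= tree.leaves:
        raise InputError("triple-system labels are not a subset of the tree leaves")
    return all(tree.displays(t) for t in system.required) and not any(
        tree.displays(t) for t in system.forbidden
    )


def enumerate_trees(labels: Iterable[str]):
    """Yield every rooted multifurcating phylogenetic tree topology on the
    given labels as nested tuples.  Exponential; intended as a brute-force
    oracle for <= 7 labels."""
    labels = sorted(set(labels))

    def partitions(items):
        if len(items) == 1:
            yield [items]
            return
        first, rest = items[0], items[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [[first] + part[i]] + part[i + 1 :]
            yield [[first]] + part

    def rec(items):
        if len(items) == 1:
            yield items[0]
            return
        for part in partitions(items):
            if len(part) < 2:
                continue
            choices = [list(rec(block)) for block in part]

            def combine(i, acc):
                if i == len(choices):
                    yield tuple(acc)
                    return
                for c in choices[i]:
                    yield from combine(i + 1, acc + [c])

            yield from combine(0, [])

    yield from rec(labels)


# -- text format ---------------------------------------------------------------


def write_triples_text(system: TripleSystem, path) -> None:
    """One triple per line ``x,y|z``; forbidden triples prefixed with '!'."""
    with open(path, "w") as fh:
        for t in sorted(system.required):
            fh.write(f"{t.a},{t.b}|{t.outgroup}\n")
        for t in sorted(system.forbidden):
            fh.write(f"!{t.a},{t.b}|{t.outgroup}\n")


def read_triples_text(path, labels: Optional[Iterable[str]] = None) -> TripleSystem:
    required, forbidden = set(), set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            target = required
            if line.startswith("!"):
                target = forbidden
                line = line[1:]
            try:
                pair, z = line.split("|")
                x, y = pair.split(",")
            except ValueError as e:
                raise InputError(f"{path}:{lineno}: expected 'x,y|z'") from e
            target.add(RootedTriple(x.strip(), y.strip(), z.strip()))
    lbls = set(labels) if labels is not None else set()
    for t in required | forbidden:
        lbls |= t.leaves
    return TripleSystem(frozenset(required), frozenset(forbidden), frozenset(lbls))
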