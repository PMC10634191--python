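"""EDT/LDT/PDT graph 3-partitions and their structural theory.

The 3-partition of a scenario classifies every unordered pair of gene
leaves by comparing the stamp of their gene-tree lca with the stamp of
the species-tree lca of their colors: later (LDT, ``<``), equal (EDT,
``=``) or prior (PDT, ``>``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

from edt.trees import InputError
from edt.scenario import DEFAULT_TOL, Scenario, time_eq, time_lt

__all__ = [
    "ColoredGraph",
    "GraphThreePartition",
    "divergence_partition",
    "restrict_partition",
    "is_properly_colored",
    "is_cograph",
    "find_induced_p4",
    "structural_report",
    "StructuralReport",
    "read_colored_graph_tsv",
    "write_colored_graph_tsv",
    "read_partition_tsv",
    "write_partition_tsv",
]


def _norm_edge(u: str, v: str) -> frozenset:
    if u == v:
        raise InputError(f"self-loop {u!r}")
    return frozenset((u, v))


@dataclass(frozen=True)
class ColoredGraph:
    """Undirected simple graph with a vertex coloring."""

    vertices: frozenset
    edges: frozenset  # of frozenset pairs
    sigma: Mapping[str, str] = field(hash=False)

    @classmethod
    def make(
        cls,
        vertices: Iterable[str],
        edges: Iterable[Sequence[str]],
        sigma: Mapping[str, str],
    ) -> "ColoredGraph":
        vs = frozenset(vertices)
        es = frozenset(_norm_edge(*e) for e in edges)
        for e in es:
            if not e <= vs:
                raise InputError(f"edge {set(e)} over undeclared vertices")
        missing = vs - set(sigma)
        if missing:
            raise InputError(f"vertices without a color: {sorted(missing)}")
        return cls(vs, es, dict(sigma))

    def has_edge(self, u: str, v: str) -> bool:
        return frozenset((u, v)) in self.edges

    def adjacency(self) -> dict[str, set]:
        adj: dict[str, set] = {v: set() for v in self.vertices}
        for e in self.edges:
            u, v = tuple(e)
            adj[u].add(v)
            adj[v].add(u)
        return adj

    def induced(self, subset: Iterable[str]) -> "ColoredGraph":
        sub = frozenset(subset)
        if not sub <= self.vertices:
            raise InputError("induced subgraph on non-vertices")
        return ColoredGraph(
            sub,
            frozenset(e for e in self.edges if e <= sub),
            {v: self.sigma[v] for v in sub},
        )

    def complement(self) -> "ColoredGraph":
        es = frozenset(
            frozenset(p)
            for p in combinations(sorted(self.vertices), 2)
            if frozenset(p) not in self.edges
        )
        return ColoredGraph(self.vertices, es, dict(self.sigma))

    def components(self) -> list[frozenset]:
        adj = self.adjacency()
        seen: set = set()
        comps = []
        for v in sorted(self.vertices):
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
        return comps


@dataclass(frozen=True)
class GraphThreePartition:
    """Edge-disjoint colored graphs (G<, G=, G>) covering the complete graph
    on a common vertex set."""

    ldt: ColoredGraph
    edt: ColoredGraph
    pdt: ColoredGraph

    def __post_init__(self):
        violations = self.partition_violations()
        if violations:
            raise InputError("not a graph 3-partition: " + "; ".join(violations))

    def partition_violations(self) -> list[str]:
        out = []
        if not (self.ldt.vertices == self.edt.vertices == self.pdt.vertices):
            out.append("vertex sets differ")
            return out
        if not (dict(self.ldt.sigma) == dict(self.edt.sigma) == dict(self.pdt.sigma)):
            out.append("colorings differ")
        n_pairs = len(self.ldt.vertices) * (len(self.ldt.vertices) - 1) // 2
        union = self.ldt.edges | self.edt.edges | self.pdt.edges
        total = len(self.ldt.edges) + len(self.edt.edges) + len(self.pdt.edges)
        if total != len(union):
            out.append("edge sets overlap")
        if len(union) != n_pairs:
            out.append("some pair is not covered")
        return out

    @property
    def vertices(self) -> frozenset:
        return self.ldt.vertices

    @property
    def sigma(self) -> Mapping[str, str]:
        return self.ldt.sigma

    def classify(self, u: str, v: str) -> str:
        e = frozenset((u, v))
        if e in self.ldt.edges:
            return "LT"
        if e in self.edt.edges:
            return "EQ"
        return "GT"

    @classmethod
    def from_classes(
        cls,
        vertices: Iterable[str],
        sigma: Mapping[str, str],
        ldt_edges: Iterable = (),
        edt_edges: Iterable = (),
        pdt_edges: Optional[Iterable] = None,
    ) -> "GraphThreePartition":
        """Build a partition; if *pdt_edges* is None all remaining pairs go
        to the PDT graph."""
        vs = frozenset(vertices)
        lt = frozenset(_norm_edge(*e) for e in ldt_edges)
        eq = frozenset(_norm_edge(*e) for e in edt_edges)
        if pdt_edges is None:
            gt = frozenset(
                frozenset(p)
                for p in combinations(sorted(vs), 2)
                if frozenset(p) not in lt and frozenset(p) not in eq
            )
        else:
            gt = frozenset(_norm_edge(*e) for e in pdt_edges)
        return cls(
            ColoredGraph.make(vs, lt, sigma),
            ColoredGraph.make(vs, eq, sigma),
            ColoredGraph.make(vs, gt, sigma),
        )


def divergence_partition(s: Scenario, tol: float = DEFAULT_TOL) -> GraphThreePartition:
    """The 3-partition (G<, G=, G>) of a valid relaxed scenario."""
    leaves = sorted(s.T.leaves)
    lt, eq, gt = [], [], []
    for x, y in combinations(leaves, 2):
        tg = s.tau_T[s.T.lca((x, y))]
        ts = s.tau_S[s.S.lca((s.sigma[x], s.sigma[y]))]
        if time_eq(tg, ts, tol):
            eq.append((x, y))
        elif time_lt(tg, ts, tol):
            lt.append((x, y))
        else:
            gt.append((x, y))
    sigma = {x: s.sigma[x] for x in leaves}
    return GraphThreePartition.from_classes(leaves, sigma, lt, eq, gt)


def restrict_partition(
    g: GraphThreePartition, subset: Iterable[str]
) -> GraphThreePartition:
    sub = frozenset(subset)
    return GraphThreePartition(
        g.ldt.induced(sub), g.edt.induced(sub), g.pdt.induced(sub)
    )


def is_properly_colored(g: ColoredGraph) -> bool:
    """True iff no edge joins two vertices of the same color."""
    return all(len({g.sigma[v] for v in e}) == 2 for e in g.edges)


def find_induced_p4(
    adj: Mapping[str, set], verts: Iterable[str]
) -> Optional[tuple[str, str, str, str]]:
    """Brute-force search for an induced path a-b-c-d within *verts*."""
    vset = set(verts)
    for b in sorted(vset):
        for c in sorted(adj[b] & vset):
            for a in sorted((adj[b] - adj[c]) & vset - {c}):
                for d in sorted((adj[c] - adj[b]) & vset - {a, b}):
                    if d not in adj[a]:
                        return (a, b, c, d)
    return None


def _cograph_decompose(adj: Mapping[str, set], verts: frozenset) -> bool:
    """Cotree decomposition test: a graph on >= 2 vertices is a cograph iff
    it or its complement is disconnected, recursively."""
    if len(verts) <= 1:
        return True
    comps = _components(adj, verts)
    if len(comps) == 1:
        comps = _co_components(adj, verts)
        if len(comps) == 1:
            return False
    return all(_cograph_decompose(adj, c) for c in comps)


def _components(adj, verts: frozenset) -> list[frozenset]:
    seen: set = set()
    comps = []
    for v in verts:
        if v in seen:
            continue
        comp = {v}
        stack = [v]
        seen.add(v)
        while stack:
            w = stack.pop()
            for x in adj[w] & verts:
                if x not in seen:
                    seen.add(x)
                    comp.add(x)
                    stack.append(x)
        comps.append(frozenset(comp))
    return comps


def _co_components(adj, verts: frozenset) -> list[frozenset]:
    seen: set = set()
    comps = []
    for v in verts:
        if v in seen:
            continue
        comp = {v}
        stack = [v]
        seen.add(v)
        while stack:
            w = stack.pop()
            for x in verts - adj[w] - {w}:
                if x not in seen:
                    seen.add(x)
                    comp.add(x)
                    stack.append(x)
        comps.append(frozenset(comp))
    return comps


def is_cograph(g: ColoredGraph) -> tuple[bool, Optional[tuple[str, str, str, str]]]:
    """Cograph test; on failure also returns one induced P4 as certificate."""
    adj = g.adjacency()
    if _cograph_decompose(adj, g.vertices):
        return True, None
    cert = find_induced_p4(adj, g.vertices)
    assert cert is not None
    return False, cert


def _longest_induced_path(adj: Mapping[str, set], verts: frozenset) -> int:
    """Number of vertices on a longest induced path (exhaustive search)."""
    best = 1 if verts else 0
    order = sorted(verts)

    def extend(path: list, banned: set):
        nonlocal best
        best = max(best, len(path))
        last = path[-1]
        for w in sorted(adj[last] & verts):
            if w in banned:
                continue
            # w must not be adjacent to any earlier path vertex
            if any(w in adj[p] for p in path[:-1]):
                continue
            extend(path + [w], banned | {w})

    for v in order:
        extend([v], {v})
    return best


def has_induced_path(g: ColoredGraph, k: int) -> bool:
    """True iff the graph contains an induced path on *k* vertices."""
    adj = g.adjacency()
    verts = g.vertices
    found = [False]

    def extend(path: list, banned: set):
        if found[0]:
            return
        if len(path) == k:
            found[0] = True
            return
        last = path[-1]
        for w in sorted(adj[last] & verts):
            if w in banned or any(w in adj[p] for p in path[:-1]):
                continue
            extend(path + [w], banned | {w})

    for v in sorted(verts):
        extend([v], {v})
        if found[0]:
            return True
    return False


def _has_hole(adj: Mapping[str, set], verts: frozenset, lengths: Iterable[int]) -> bool:
    """Exhaustive induced-cycle search via subset enumeration; intended for
    small graphs only."""

    def is_hole(sub: tuple) -> bool:
        degs = {v: len(adj[v] & set(sub)) for v in sub}
        if any(d != 2 for d in degs.values()):
            return False
        # connected 2-regular graph on the subset = single cycle
        start = sub[0]
        seen = {start}
        stack = [start]
        while stack:
            w = stack.pop()
            for x in adj[w] & set(sub):
                if x not in seen:
                    seen.add(x)
                    stack.append(x)
        return len(seen) == len(sub)

    vs = sorted(verts)
    for ell in lengths:
        if ell > len(vs):
            break
        for sub in combinations(vs, ell):
            if is_hole(sub):
                return True
    return False


def has_odd_hole(g: ColoredGraph) -> bool:
    """Induced odd cycle of length >= 5 (exhaustive; small graphs only)."""
    n = len(g.vertices)
    return _has_hole(g.adjacency(), g.vertices, range(5, n + 1, 2))


@dataclass
class StructuralReport:
    ldt_cograph: bool
    pdt_cograph: bool
    edt_cograph: bool
    proper_colorings: dict[str, bool]
    rainbow_triangles: list[tuple[str, str, str]]
    longest_induced_path_in_edt: Optional[int]  # None = not computed
    edt_odd_hole_free: Optional[bool]  # None = not computed
    not_computed: list[str] = field(default_factory=list)


def structural_report(
    g: GraphThreePartition,
    max_path_vertices: int = 14,
    max_hole_vertices: int = 11,
) -> StructuralReport:
    """Diagnostic report on a 3-partition.

    A rainbow triangle is a vertex triple with one edge in each of the
    three graphs.  The induced-path and odd-hole statistics are computed
    exhaustively and therefore guarded by explicit size limits; when a
    guard trips the field is None and listed in ``not_computed`` (never
    silently truncated).
    """
    rainbow = []
    for a, b, c in combinations(sorted(g.vertices), 3):
        classes = {g.classify(a, b), g.classify(a, c), g.classify(b, c)}
        if len(classes) == 3:
            rainbow.append((a, b, c))
    n = len(g.vertices)
    not_computed = []
    if n <= max_path_vertices:
        lip = _longest_induced_path(g.edt.adjacency(), g.edt.vertices)
    else:
        lip = None
        not_computed.append("longest_induced_path_in_edt")
    if n <= max_hole_vertices:
        ohf = not has_odd_hole(g.edt)
    else:
        ohf = None
        not_computed.append("edt_odd_hole_free")
    return StructuralReport(
        ldt_cograph=is_cograph(g.ldt)[0],
        pdt_cograph=is_cograph(g.pdt)[0],
        edt_cograph=is_cograph(g.edt)[0],
        proper_colorings={
            "ldt": is_properly_colored(g.ldt),
            "edt": is_properly_colored(g.edt),
            "pdt": is_properly_colored(g.pdt),
        },
        rainbow_triangles=rainbow,
        longest_induced_path_in_edt=lip,
        edt_odd_hole_free=ohf,
        not_computed=not_computed,
    )


# -- TSV I/O -------------------------------------------------------------------

_CLASSES = ("LT", "EQ", "GT")


def write_colored_graph_tsv(g: ColoredGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("#colors\n")
        for v in sorted(g.vertices):
            fh.write(f"#{v}\t{g.sigma[v]}\n")
        for e in sorted(g.edges, key=sorted):
            u, v = sorted(e)
            fh.write(f"{u}\t{v}\n")


def _read_tsv_body(path):
    sigma: dict[str, str] = {}
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if line.strip() == "#colors":
                    continue
                parts = line[1:].split("\t")
                if len(parts) != 2:
                    raise InputError(f"{path}:{lineno}: bad color line {line!r}")
                sigma[parts[0]] = parts[1]
                continue
            rows.append((lineno, line.split("\t")))
    return sigma, rows


def read_colored_graph_tsv(path) -> ColoredGraph:
    """Colored graph TSV: '#colors' header block mapping vertex to color,
    then one edge per line ``u<TAB>v``."""
    sigma, rows = _read_tsv_body(path)
    edges = []
    for lineno, parts in rows:
        if len(parts) != 2:
            raise InputError(f"{path}:{lineno}: expected 'u<TAB>v'")
        edges.append(tuple(parts))
    return ColoredGraph.make(sigma.keys(), edges, sigma)


def write_partition_tsv(g: GraphThreePartition, path) -> None:
    with open(path, "w") as fh:
        fh.write("#colors\n")
        for v in sorted(g.vertices):
            fh.write(f"#{v}\t{g.sigma[v]}\n")
        for u, v in combinations(sorted(g.vertices), 2):
            fh.write(f"{u}\t{v}\t{g.classify(u, v)}\n")


def read_partition_tsv(path) -> GraphThreePartition:
    """3-partition TSV: all pairs with class ``u<TAB>v<TAB>{LT|EQ|GT}``;
    missing pairs are rejected (the partition must be total)."""
    sigma, rows = _read_tsv_body(path)
    classes: dict[frozenset, str] = {}
    for lineno, parts in rows:
        if len(parts) != 3 or parts[2] not in _CLASSES:
            raise InputError(f"{path}:{lineno}: expected 'u<TAB>v<TAB>{{LT|EQ|GT}}'")
        u, v, cls = parts
        e = _norm_edge(u, v)
        if e in classes:
            raise InputError(f"{path}:{lineno}: duplicate pair {u},{v}")
        classes[e] = cls
    vs = sorted(sigma)
    missing = [
        (u, v)
        for u, v in combinations(vs, 2)
        if frozenset((u, v)) not in classes
    ]
    if missing:
        raise InputError(f"{path}: pairs without a class: {missing[:5]}")
    lt = [tuple(e) for e, c in classes.items() if c == "LT"]
    eq = [tuple(e) for e, c in classes.items() if c == "EQ"]
    gt = [tuple(e) for e, c in classes.items() if c == "GT"]
    return GraphThreePartition.from_classes(vs, sigma, lt, eq, gt)
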