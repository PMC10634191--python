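"""Planted phylogenetic trees: ancestor order, lca, restriction, triples,
time maps and Newick I/O.

A *planted* tree carries an extra degree-1 root above the conventional
root; it hosts events that predate the first divergence.  Vertices are
opaque string labels; leaf labels are user data, internal labels are
synthetic (``v<k>`` in preorder) unless supplied explicitly.

Edge orientation convention: an edge ``(u, v)`` always means ``v`` is the
child of ``u``.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Callable, Iterable, Iterator, Mapping, Optional, Sequence, Union

Number = Union[int, float, Fraction]
Edge = tuple[str, str]
Place = Union[str, Edge]  # a vertex or an oriented edge of a tree

__all__ = [
    "InputError",
    "NewickError",
    "PlantedTree",
    "RootedTriple",
    "FanTriple",
    "read_newick",
    "write_newick",
    "assign_time_map",
    "fresh_label",
]


class InputError(ValueError):
    """Raised on invalid user-supplied input (unknown labels, bad sets...)."""


class NewickError(ValueError):
    """Malformed Newick string; carries the 0-based offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


def fresh_label(base: str, used) -> str:
    """Return ``base`` or ``base_1``, ``base_2``, ... not contained in *used*."""
    if base not in used:
        return base
    k = 1
    while f"{base}_{k}" in used:
        k += 1
    return f"{base}_{k}"


class PlantedTree:
    """Rooted (optionally planted) phylogenetic tree.

    Invariants: the planted root, if present, has exactly one child; every
    other non-leaf vertex has at least two children; the parent relation is
    acyclic and connects every vertex to the (planted) root; labels are
    unique.
    """

    __slots__ = (
        "_children",
        "_parent",
        "planted_root",
        "root",
        "_leaves",
        "_depth",
        "_subtree_leaves",
    )

    def __init__(
        self,
        children: Mapping[str, Sequence[str]],
        root: str,
        planted_root: Optional[str] = None,
    ):
        self._children: dict[str, tuple[str, ...]] = {
            v: tuple(cs) for v, cs in children.items()
        }
        self.root = root
        self.planted_root = planted_root
        self._parent: dict[str, Optional[str]] = {}
        top = planted_root if planted_root is not None else root
        self._parent[top] = None
        # walk down from the top, checking connectivity/acyclicity
        seen = {top}
        stack = [top]
        order = []
        while stack:
            v = stack.pop()
            order.append(v)
            for c in self._children.get(v, ()):
                if c in seen:
                    raise InputError(f"vertex {c!r} reachable twice (cycle or reuse)")
                seen.add(c)
                self._parent[c] = v
                stack.append(c)
        all_mentioned = set(self._children)
        for cs in self._children.values():
            all_mentioned.update(cs)
        if planted_root is not None:
            all_mentioned.add(planted_root)
        all_mentioned.add(root)
        if all_mentioned - seen:
            raise InputError(
                f"vertices not connected to the root: {sorted(all_mentioned - seen)}"
            )
        if planted_root is not None:
            if len(self._children.get(planted_root, ())) != 1:
                raise InputError("planted root must have exactly one child")
            if self._children[planted_root][0] != root:
                raise InputError("root must be the unique child of the planted root")
        leaves = []
        for v in seen:
            cs = self._children.get(v, ())
            if not cs:
                leaves.append(v)
            elif len(cs) < 2 and v != planted_root:
                raise InputError(f"non-leaf vertex {v!r} has a single child")
        self._leaves = frozenset(leaves)
        self._depth: dict[str, int] = {}
        d = 0
        self._depth[top] = 0
        for v in order:
            if v != top:
                self._depth[v] = self._depth[self._parent[v]] + 1
        self._subtree_leaves: dict[str, frozenset] = {}

    # -- basic accessors ---------------------------------------------------

    @property
    def is_planted(self) -> bool:
        return self.planted_root is not None

    @property
    def vertices(self) -> frozenset:
        return frozenset(self._parent)

    @property
    def leaves(self) -> frozenset:
        return self._leaves

    @property
    def inner_vertices(self) -> frozenset:
        """V0: all vertices except leaves and the planted root."""
        out = set(self._parent) - self._leaves
        if self.planted_root is not None:
            out.discard(self.planted_root)
        return frozenset(out)

    def children(self, v: str) -> tuple[str, ...]:
        return self._children.get(v, ())

    def parent(self, v: str) -> Optional[str]:
        return self._parent[v]

    def is_leaf(self, v: str) -> bool:
        return v in self._leaves

    def depth(self, v: str) -> int:
        return self._depth[v]

    def edges(self) -> Iterator[Edge]:
        """Oriented edges (parent, child), including the planted edge."""
        for v, p in self._parent.items():
            if p is not None:
                yield (p, v)

    def preorder(self) -> Iterator[str]:
        stack = [self.planted_root if self.is_planted else self.root]
        while stack:
            v = stack.pop()
            yield v
            stack.extend(reversed(self._children.get(v, ())))

    def postorder(self) -> Iterator[str]:
        out = list(self.preorder())
        return reversed(out)

    def subtree_leaves(self, v: str) -> frozenset:
        """Leaf set L(T(v)) of the subtree rooted at v (cached)."""
        cached = self._subtree_leaves.get(v)
        if cached is not None:
            return cached
        for w in self.postorder():
            if w in self._subtree_leaves:
                continue
            cs = self._children.get(w, ())
            if not cs:
                self._subtree_leaves[w] = frozenset((w,))
            else:
                acc = frozenset()
                for c in cs:
                    acc |= self._subtree_leaves[c]
                self._subtree_leaves[w] = acc
        return self._subtree_leaves[v]

    # -- ancestor order ----------------------------------------------------

    def preceq(self, x: str, y: str) -> bool:
        """x below-or-equal y in the ancestor order (y on the root path of x)."""
        if x not in self._parent or y not in self._parent:
            raise InputError(f"unknown vertex in order query: {x!r}/{y!r}")
        while self._depth[x] > self._depth[y]:
            x = self._parent[x]
        return x == y

    def preceq_ext(self, a: Place, b: Place) -> bool:
        """Ancestor order extended to vertices and oriented edges.

        For a vertex x and an edge e = (u, v): x <= e iff x <= v, and
        e <= x iff u <= x.  For edges e = (u, v), f = (p, q): e <= f iff
        v <= q (hence e <= e).
        """
        if isinstance(a, tuple):
            a_low, a_high = a[1], a[0]
        else:
            a_low = a_high = a
        if isinstance(b, tuple):
            b_ref = b[1]
        else:
            b_ref = b
        if isinstance(a, tuple) and not isinstance(b, tuple):
            return self.preceq(a_high, b_ref)
        return self.preceq(a_low, b_ref)

    def comparable_ext(self, a: Place, b: Place) -> bool:
        return self.preceq_ext(a, b) or self.preceq_ext(b, a)

    def lca(self, leaves: Iterable[str]) -> str:
        """Last common ancestor of a non-empty set of leaves (or vertices)."""
        it = list(leaves)
        if not it:
            raise InputError("lca of an empty set")
        for x in it:
            if x not in self._parent:
                raise InputError(f"unknown leaf label {x!r}")
        cur = it[0]
        for x in it[1:]:
            a, b = cur, x
            while self._depth[a] > self._depth[b]:
                a = self._parent[a]
            while self._depth[b] > self._depth[a]:
                b = self._parent[b]
            while a != b:
                a = self._parent[a]
                b = self._parent[b]
            cur = a
        return cur

    # -- restriction and display -------------------------------------------

    def restrict(self, leaf_set: Iterable[str]) -> "PlantedTree":
        """Unplanted restriction T|L': minimal connecting subtree with
        degree-two vertices suppressed.  Internal vertices are relabeled
        ``r<k>`` in preorder."""
        lp = set(leaf_set)
        if not lp:
            raise InputError("restriction to an empty leaf set")
        bad = lp - self._leaves
        if bad:
            raise InputError(f"not leaves of the tree: {sorted(bad)}")

        def build(v):
            if v in lp:
                return v
            kids = [build(c) for c in self._children.get(v, ())]
            kids = [k for k in kids if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]
            return tuple(kids)

        nested = build(self.root)
        return tree_from_nested(nested, planted=False, label_prefix="r")

    def displays(self, t: Union["RootedTriple", "FanTriple"]) -> bool:
        if isinstance(t, RootedTriple):
            x, y, z = t.a, t.b, t.outgroup
            for lbl in (x, y, z):
                if lbl not in self._leaves:
                    raise InputError(f"triple leaf {lbl!r} not in the tree")
            return self.lca((x, y)) != self.lca((x, y, z))
        if isinstance(t, FanTriple):
            x, y, z = sorted(t.members)
            for lbl in (x, y, z):
                if lbl not in self._leaves:
                    raise InputError(f"fan-triple leaf {lbl!r} not in the tree")
            top = self.lca((x, y, z))
            return (
                self.lca((x, y)) == top
                and self.lca((x, z)) == top
                and self.lca((y, z)) == top
            )
        raise TypeError(f"not a triple: {t!r}")

    # -- structural helpers --------------------------------------------------

    def canonical(self) -> object:
        """Canonical nested representation; equal iff trees are isomorphic
        as leaf-labeled (multifurcating) rooted trees.  Ignores planting."""

        def rec(v):
            cs = self._children.get(v, ())
            if not cs:
                return v
            return tuple(sorted((rec(c) for c in cs), key=repr))

        return rec(self.root)

    def isomorphic(self, other: "PlantedTree") -> bool:
        return self.canonical() == other.canonical()

    def plant(self, label: Optional[str] = None) -> "PlantedTree":
        """Return a planted copy of an unplanted tree (identity if planted)."""
        if self.is_planted:
            return self
        lbl = label or fresh_label("0", self.vertices)
        children = {v: cs for v, cs in self._children.items()}
        children[lbl] = (self.root,)
        return PlantedTree(children, root=self.root, planted_root=lbl)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"PlantedTree({write_newick(self)!r})"


def tree_from_nested(
    nested, planted: bool = True, label_prefix: str = "v"
) -> PlantedTree:
    """Build a tree from nested tuples/lists of leaf labels.

    A leaf is a string; an internal vertex is a tuple/list of children.
    Internal vertices are labeled ``<prefix><k>`` in preorder, skipping
    collisions with leaf labels.
    """
    leaf_labels: set[str] = set()

    def collect(n):
        if isinstance(n, str):
            leaf_labels.add(n)
        else:
            for c in n:
                collect(c)

    collect(nested)
    children: dict[str, tuple[str, ...]] = {}
    counter = [0]

    def build(n) -> str:
        if isinstance(n, str):
            return n
        counter[0] += 1
        lbl = f"{label_prefix}{counter[0]}"
        while lbl in leaf_labels or lbl in children:
            counter[0] += 1
            lbl = f"{label_prefix}{counter[0]}"
        children[lbl] = ()  # reserve before recursing
        kids = tuple(build(c) for c in n)
        children[lbl] = kids
        return lbl

    root = build(nested)
    if not planted:
        return PlantedTree(children, root=root)
    used = leaf_labels | set(children)
    pr = fresh_label("0", used)
    children[pr] = (root,)
    return PlantedTree(children, root=root, planted_root=pr)


# -- triples -----------------------------------------------------------------


class RootedTriple:
    """Rooted triple xy|z: the pair {x, y} diverges below the outgroup z."""

    __slots__ = ("a", "b", "outgroup")

    def __init__(self, x: str, y: str, z: str):
        if len({x, y, z}) != 3:
            raise InputError(f"triple leaves must be pairwise distinct: {x, y, z}")
        self.a, self.b = (x, y) if x <= y else (y, x)
        self.outgroup = z

    @property
    def leaves(self) -> frozenset:
        return frozenset((self.a, self.b, self.outgroup))

    def __eq__(self, other):
        return (
            isinstance(other, RootedTriple)
            and self.a == other.a
            and self.b == other.b
            and self.outgroup == other.outgroup
        )

    def __hash__(self):
        return hash((self.a, self.b, self.outgroup))

    def __lt__(self, other: "RootedTriple"):
        return (self.a, self.b, self.outgroup) < (other.a, other.b, other.outgroup)

    def __repr__(self):
        return f"{self.a},{self.b}|{self.outgroup}"


class FanTriple:
    """Fan triple x|y|z: the star tree on three leaves."""

    __slots__ = ("members",)

    def __init__(self, x: str, y: str, z: str):
        if len({x, y, z}) != 3:
            raise InputError(f"fan-triple leaves must be pairwise distinct: {x, y, z}")
        self.members = frozenset((x, y, z))

    def __eq__(self, other):
        return isinstance(other, FanTriple) and self.members == other.members

    def __hash__(self):
        return hash(self.members)

    def __repr__(self):
        return "|".join(sorted(self.members))


# -- time maps ---------------------------------------------------------------


def assign_time_map(
    tree: PlantedTree,
    leaf_times: Optional[Mapping[str, Number]] = None,
    scale: Number = 3,
) -> dict[str, Number]:
    """Time map with prescribed leaf stamps (default 0 everywhere).

    Internal vertices (and the planted root) receive
    ``scale * height(v) + max(leaf stamps)`` where height is the maximal
    edge count to a descendant leaf; every edge then strictly decreases
    toward the leaves.
    """
    if leaf_times is None:
        leaf_times = {}
    stamps: dict[str, Number] = {}
    offset = max((leaf_times.get(x, 0) for x in tree.leaves), default=0)
    height: dict[str, int] = {}
    for v in tree.postorder():
        cs = tree.children(v)
        if not cs:
            height[v] = 0
            stamps[v] = leaf_times.get(v, 0)
        else:
            height[v] = 1 + max(height[c] for c in cs)
            stamps[v] = scale * height[v] + offset
    for u, v in tree.edges():
        if not stamps[v] < stamps[u]:
            raise InputError(
                f"infeasible leaf times: edge {u}->{v} not strictly decreasing"
            )
    return stamps


# -- Newick I/O ---------------------------------------------------------------

_LABEL_FORBIDDEN = set("();,:[]' \t\n\r")


def read_newick(text: str, keep_inner_labels: bool = False) -> PlantedTree:
    """Parse a rooted, possibly multifurcating Newick string into a planted
    tree.  Branch lengths are accepted and ignored; inner-vertex labels are
    ignored unless *keep_inner_labels* is set.  A planted root is added."""
    pos = [0]
    n = len(text)

    def skip_ws():
        while pos[0] < n and text[pos[0]].isspace():
            pos[0] += 1

    def parse_label() -> str:
        if pos[0] < n and text[pos[0]] == "'":
            # quoted label; an embedded quote is doubled
            pos[0] += 1
            out = []
            while True:
                if pos[0] >= n:
                    raise NewickError("unterminated quoted label", pos[0])
                ch = text[pos[0]]
                if ch == "'":
                    if pos[0] + 1 < n and text[pos[0] + 1] == "'":
                        out.append("'")
                        pos[0] += 2
                        continue
                    pos[0] += 1
                    return "".join(out)
                out.append(ch)
                pos[0] += 1
        start = pos[0]
        while pos[0] < n and text[pos[0]] not in _LABEL_FORBIDDEN:
            pos[0] += 1
        return text[start : pos[0]]

    def skip_branch_length():
        if pos[0] < n and text[pos[0]] == ":":
            pos[0] += 1
            start = pos[0]
            while pos[0] < n and (text[pos[0]].isdigit() or text[pos[0]] in ".eE+-"):
                pos[0] += 1
            if pos[0] == start:
                raise NewickError("expected a branch length after ':'", pos[0])

    def parse_subtree():
        skip_ws()
        if pos[0] >= n:
            raise NewickError("unexpected end of input", pos[0])
        if text[pos[0]] == "(":
            pos[0] += 1
            kids = [parse_subtree()]
            skip_ws()
            while pos[0] < n and text[pos[0]] == ",":
                pos[0] += 1
                kids.append(parse_subtree())
                skip_ws()
            if pos[0] >= n or text[pos[0]] != ")":
                raise NewickError("expected ')' or ','", pos[0])
            pos[0] += 1
            label = parse_label()
            skip_branch_length()
            return (label, kids)
        label = parse_label()
        if not label:
            raise NewickError("expected a leaf label or '('", pos[0])
        skip_branch_length()
        return label

    structure = parse_subtree()
    skip_ws()
    if pos[0] >= n or text[pos[0]] != ";":
        raise NewickError("expected ';'", pos[0])
    pos[0] += 1
    skip_ws()
    if pos[0] != n:
        raise NewickError("trailing characters after ';'", pos[0])

    leaf_labels: set[str] = set()
    inner_labels: set[str] = set()

    def collect(node):
        if isinstance(node, str):
            if node in leaf_labels:
                raise NewickError(f"duplicate leaf label {node!r}", 0)
            leaf_labels.add(node)
        else:
            label, kids = node
            if keep_inner_labels and label:
                if label in inner_labels:
                    raise NewickError(f"duplicate inner label {label!r}", 0)
                inner_labels.add(label)
            for k in kids:
                collect(k)

    collect(structure)
    if keep_inner_labels and (inner_labels & leaf_labels):
        raise NewickError("inner labels collide with leaf labels", 0)

    children: dict[str, tuple[str, ...]] = {}
    counter = [0]
    used = leaf_labels | inner_labels

    def build(node) -> str:
        if isinstance(node, str):
            return node
        label, kids = node
        if keep_inner_labels and label:
            lbl = label
        else:
            counter[0] += 1
            lbl = f"v{counter[0]}"
            while lbl in used:
                counter[0] += 1
                lbl = f"v{counter[0]}"
            used.add(lbl)
        children[lbl] = ()
        children[lbl] = tuple(build(k) for k in kids)
        return lbl

    root = build(structure)
    if isinstance(structure, str):
        # single-leaf tree: the leaf itself is the root
        pr = fresh_label("0", used)
        children[pr] = (root,)
        return PlantedTree(children, root=root, planted_root=pr)
    pr = fresh_label("0", used)
    children[pr] = (root,)
    return PlantedTree(children, root=root, planted_root=pr)


def _quote_label(label: str) -> str:
    if label and not (set(label) & _LABEL_FORBIDDEN):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_newick(tree: PlantedTree, include_inner_labels: bool = False) -> str:
    """Serialize a tree (planted root omitted) as a Newick string; labels
    containing Newick metacharacters are single-quoted."""

    def rec(v: str) -> str:
        cs = tree.children(v)
        if not cs:
            return _quote_label(v)
        inner = ",".join(rec(c) for c in cs)
        lbl = _quote_label(v) if include_inner_labels else ""
        return f"({inner}){lbl}"

    return rec(tree.root) + ";"
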