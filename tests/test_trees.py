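"""Trees: lca, restriction, display, time maps, Newick round trips."""

import random
from itertools import combinations, permutations

import pytest

from edt.trees import (
    FanTriple,
    InputError,
    NewickError,
    PlantedTree,
    RootedTriple,
    assign_time_map,
    read_newick,
    tree_from_nested,
    write_newick,
)
from edt.triples import enumerate_trees


def random_nested(labels, rng):
    items = list(labels)
    rng.shuffle(items)
    while len(items) > 1:
        k = 2 if len(items) < 3 or rng.random() < 0.7 else 3
        picks = sorted(rng.sample(range(len(items)), k), reverse=True)
        merged = tuple(items[i] for i in picks)
        for i in picks:
            del items[i]
        items.append(merged)
    return items[0]


# -- lca -----------------------------------------------------------------------


def test_lca_star():
    t = tree_from_nested(("a", "b", "c"))
    assert t.lca(("a", "b")) == t.root


def test_lca_cherry():
    t = tree_from_nested((("a", "b"), "c"))
    assert t.lca(("a", "b")) != t.root
    assert t.preceq(t.lca(("a", "b")), t.root)
    assert t.lca(("a", "c")) == t.root


def test_lca_unknown_leaf():
    t = tree_from_nested((("a", "b"), "c"))
    with pytest.raises(InputError):
        t.lca(("a", "nope"))
    with pytest.raises(InputError):
        t.lca(())


def path_to_root(t, v):
    out = [v]
    while t.parent(out[-1]) is not None:
        out.append(t.parent(out[-1]))
    return out


def test_lca_path_intersection_oracle():
    # lca equals the first common vertex of root-to-leaf paths
    rng = random.Random(7)
    for trial in range(40):
        labels = [f"x{i}" for i in range(rng.randint(3, 10))]
        t = tree_from_nested(random_nested(labels, rng))
        subset = rng.sample(labels, rng.randint(1, len(labels)))
        paths = [path_to_root(t, x) for x in subset]
        common = set(paths[0]).intersection(*map(set, paths[1:]))
        expected = min(common, key=lambda v: -t.depth(v))
        assert t.lca(subset) == expected


# -- restriction ---------------------------------------------------------------


def test_restrict_forced_topology():
    t = tree_from_nested((("a", "b"), ("c", "d")))
    r = t.restrict({"a", "c", "d"})
    assert r.canonical() == tree_from_nested(("a", ("c", "d"))).canonical()


def test_restrict_identity():
    t = tree_from_nested((("a", "b"), ("c", "d")))
    assert t.restrict(t.leaves).isomorphic(t)


def test_restrict_errors():
    t = tree_from_nested((("a", "b"), "c"))
    with pytest.raises(InputError):
        t.restrict(set())
    with pytest.raises(InputError):
        t.restrict({"a", t.root})


def restriction_oracle(t, subset):
    """Independent restriction: keep leaves and pairwise lcas, compress
    parent chains."""
    keep = set(subset)
    for x, y in combinations(sorted(subset), 2):
        keep.add(t.lca((x, y)))

    def up(v):
        v = t.parent(v)
        while v is not None and v not in keep:
            v = t.parent(v)
        return v

    children = {v: [] for v in keep}
    for v in keep:
        p = up(v)
        if p in keep:
            children[p].append(v)
    # the root of the restriction is the unique keep-vertex without keep-ancestor
    (root,) = [v for v in keep if up(v) not in keep]

    def nest(v):
        if not children[v]:
            return v
        return tuple(nest(c) for c in children[v])

    return nest(root)


def test_restrict_against_contraction_oracle():
    rng = random.Random(11)
    for trial in range(40):
        labels = [f"x{i}" for i in range(rng.randint(4, 10))]
        t = tree_from_nested(random_nested(labels, rng))
        subset = rng.sample(labels, rng.randint(2, len(labels)))
        expected = tree_from_nested(restriction_oracle(t, subset)).canonical()
        assert t.restrict(subset).canonical() == expected


# -- displays ------------------------------------------------------------------


def test_displays_examples():
    t = tree_from_nested((("a", "b"), "c"))
    assert t.displays(RootedTriple("a", "b", "c"))
    assert not t.displays(RootedTriple("a", "c", "b"))
    star = tree_from_nested(("a", "b", "c"))
    assert star.displays(FanTriple("a", "b", "c"))
    for x, y, z in permutations("abc"):
        assert not star.displays(RootedTriple(x, y, z))


def test_displays_equals_restriction_exhaustively():
    # displays(xy|z) <=> restriction to {x,y,z} is the cherry ((x,y),z)
    labels = ["a", "b", "c", "d", "e"]
    count = 0
    for nested in enumerate_trees(labels):
        t = tree_from_nested(nested)
        count += 1
        if count > 300:  # all shapes are covered long before this
            break
        for x, y, z in combinations(labels, 3):
            for u, v, w in ((x, y, z), (x, z, y), (y, z, x)):
                expected = (
                    t.restrict({x, y, z}).canonical()
                    == tree_from_nested(((u, v), w)).canonical()
                )
                assert t.displays(RootedTriple(u, v, w)) == expected


# -- time maps -----------------------------------------------------------------


def test_time_map_cherry_scale3():
    s = tree_from_nested(("A", "B"))
    tau = assign_time_map(s)
    assert tau["A"] == 0 and tau["B"] == 0
    assert tau[s.root] == 3
    assert tau[s.planted_root] == 6


def test_time_map_single_leaf():
    s = tree_from_nested("a")
    tau = assign_time_map(s)
    assert tau["a"] == 0 and tau[s.planted_root] == 3


def test_time_map_strictly_decreasing():
    rng = random.Random(3)
    for trial in range(30):
        labels = [f"x{i}" for i in range(rng.randint(2, 9))]
        t = tree_from_nested(random_nested(labels, rng))
        lt = {x: rng.randint(0, 2) for x in labels}
        tau = assign_time_map(t, leaf_times=lt, scale=3)
        for u, v in t.edges():
            assert tau[v] < tau[u]


# -- Newick --------------------------------------------------------------------


def test_newick_examples():
    t = read_newick("((a,b),c);")
    assert t.displays(RootedTriple("a", "b", "c"))
    star = read_newick("(a,b,c);")
    assert star.leaves == {"a", "b", "c"}
    assert len(star.children(star.root)) == 3


def test_newick_roundtrip_random():
    rng = random.Random(5)
    for trial in range(30):
        labels = [f"x{i}" for i in range(rng.randint(1, 9))]
        t = tree_from_nested(random_nested(labels, rng))
        s = write_newick(t)
        again = read_newick(s)
        assert again.isomorphic(t)
        assert write_newick(again) == s


def test_newick_branch_lengths_ignored():
    t = read_newick("((a:0.1,b:0.2):0.3,c:0.4);")
    assert t.leaves == {"a", "b", "c"}


from hypothesis import given, settings
from hypothesis import strategies as st

_leaf_names = st.text(
    alphabet=st.characters(blacklist_characters="();,:[]\t\n\r", min_codepoint=33, max_codepoint=122),
    min_size=1,
    max_size=6,
)


@st.composite
def nested_trees(draw):
    labels = draw(st.sets(_leaf_names, min_size=1, max_size=8))
    rng = random.Random(draw(st.integers(0, 2**16)))
    return random_nested(sorted(labels), rng)


@settings(max_examples=60, deadline=None)
@given(nested_trees())
def test_newick_roundtrip_property(nested):
    t = tree_from_nested(nested)
    s = write_newick(t, include_inner_labels=True)
    again = read_newick(s, keep_inner_labels=True)
    assert again.isomorphic(t)
    assert write_newick(again, include_inner_labels=True) == s


def test_newick_errors_with_position():
    for bad in ["((a,b),c)", "((a,b);", "(a,,b);", "(a,b)c;x"]:
        with pytest.raises(NewickError) as ei:
            read_newick(bad)
        assert ei.value.position >= 0


def test_planted_tree_invariants():
    with pytest.raises(InputError):
        PlantedTree({"r": ("a",), "0": ("r",)}, root="r", planted_root="0")
    with pytest.raises(InputError):
        PlantedTree({"0": ("a", "b")}, root="a", planted_root="0")


def test_displays_hereditary(pool):
    # tree displays t => every restriction containing its leaves does
    rng = random.Random(17)
    for s, _ in pool[:20]:
        t = s.T
        leaves = sorted(t.leaves)
        if len(leaves) < 4:
            continue
        x, y, z = rng.sample(leaves, 3)
        trip = RootedTriple(x, y, z)
        if not t.displays(trip):
            trip = RootedTriple(x, z, y)
            if not t.displays(trip):
                continue
        extra = rng.sample(leaves, min(len(leaves), 5))
        sub = set(extra) | trip.leaves
        assert t.restrict(sub).displays(trip)
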