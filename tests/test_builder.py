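"""Scenario construction: auxiliary graphs, epsilon rule, recursion trace,
round trips, restricted mode and supplied species trees."""

import random
from fractions import Fraction

import pytest

from edt.trees import InputError, read_newick, tree_from_nested, assign_time_map
from edt.scenario import validate_relaxed, validate_restricted
from edt.divergence import divergence_partition, restrict_partition
from edt.builder import (
    BuildInputError,
    auxiliary_graphs,
    build_scenario,
    build_scenario_with_trace,
    epsilon,
)
from edt.simulate import fixture


def partitions_equal(a, b):
    return (
        a.ldt.edges == b.ldt.edges
        and a.edt.edges == b.edt.edges
        and a.pdt.edges == b.pdt.edges
    )


# -- auxiliary graphs ------------------------------------------------------------


def two_species_tree():
    s = tree_from_nested(("A", "B"), label_prefix="sv")
    return s, assign_time_map(s)


def test_auxiliary_graphs_worked_example():
    g = fixture("fig9_partition")
    S, _ = two_species_tree()
    aux = auxiliary_graphs(g, g.vertices, S.root, S)
    assert aux.components_h1 == [frozenset({"a", "a'", "b", "b'"})]
    assert aux.components_h2 == [frozenset({"a", "b"}), frozenset({"a'", "b'"})]
    assert all(len(c) == 1 for c in aux.components_h3)


def test_auxiliary_graphs_edgeless():
    sigma = {"x": "A", "y": "B"}
    from edt.divergence import GraphThreePartition

    g = GraphThreePartition.from_classes(sigma.keys(), sigma, pdt_edges=None)
    S, _ = two_species_tree()
    aux = auxiliary_graphs(g, g.vertices, S.root, S)
    assert not aux.h1_edges
    assert all(len(c) == 1 for c in aux.components_h1)


def test_auxiliary_component_nesting(pool):
    # every H3 component inside an H2 component inside an H1 component,
    # and H3 components are cliques
    for s, g in pool[:20]:
        S = s.S
        for u in sorted(S.inner_vertices):
            sub = [x for x in g.vertices if s.sigma[x] in S.subtree_leaves(u)]
            if len(sub) < 2:
                continue
            aux = auxiliary_graphs(g, sub, u, S)
            assert aux.h2_edges <= aux.h1_edges
            for c3 in aux.components_h3:
                assert any(c3 <= c2 for c2 in aux.components_h2)
                for x in c3:
                    for y in c3:
                        if x < y:
                            assert frozenset((x, y)) in aux.h3_edges
            for c2 in aux.components_h2:
                assert any(c2 <= c1 for c1 in aux.components_h1)


def test_auxiliary_requires_color_subset():
    g = fixture("fig9_partition")
    S = tree_from_nested((("A", "B"), "C"), label_prefix="sv")
    with pytest.raises(InputError):
        auxiliary_graphs(g, g.vertices, S.lca(("A",)), S)


# -- epsilon ---------------------------------------------------------------------


def test_epsilon_worked_example():
    S, tau = two_species_tree()
    assert epsilon(S, tau) == 1


def test_epsilon_unit_edges():
    S = tree_from_nested(("A", "B"), label_prefix="sv")
    tau = assign_time_map(S, scale=1)
    assert epsilon(S, tau) == Fraction(1, 3)


def test_epsilon_degenerate_edge():
    S = tree_from_nested(("A", "B"), label_prefix="sv")
    tau = {"A": 0, "B": 0, S.root: 0, S.planted_root: 3}
    with pytest.raises(InputError):
        epsilon(S, tau)


def test_epsilon_nesting_inequalities(pool):
    # tau(u) + eps stays below the parent, tau(u) - eps above children + eps
    for s, _ in pool[:10]:
        S, tau = s.S, s.tau_S
        eps = epsilon(S, tau)
        for u in S.inner_vertices:
            assert tau[u] + eps < tau[S.parent(u)]
            for c in S.children(u):
                assert tau[u] - eps > tau[c] + eps


# -- the worked-example trace -------------------------------------------------------------


def test_worked_example_trace_exact():
    g = fixture("fig9_partition")
    scen, trace = build_scenario_with_trace(g)
    assert scen.tau_S[scen.S.root] == 3 and scen.tau_S[scen.S.planted_root] == 6
    top = trace[0]
    assert top.kind == "local_root" and top.time == 4
    assert top.mu == (scen.S.planted_root, scen.S.root)
    h1 = [t for t in trace if t.kind == "h1"]
    assert len(h1) == 1 and h1[0].time == 3
    h2_ab = [t for t in trace if t.kind == "h2" and set(t.subset) == {"a", "b"}]
    assert len(h2_ab) == 1 and h2_ab[0].time == 2
    assert h2_ab[0].mu == (scen.S.root, "A")
    leaf_call = [
        t for t in trace if t.kind == "local_root" and t.subset == ("a",)
    ]
    assert len(leaf_call) == 1 and leaf_call[0].time == 1
    leaf_a = [t for t in trace if t.kind == "leaf" and t.vertex == "a"]
    assert leaf_a[0].time == 0 and leaf_a[0].mu == "A"
    assert partitions_equal(divergence_partition(scen), g)


def test_two_same_colored_genes():
    from edt.divergence import GraphThreePartition

    sigma = {"x1": "X", "x2": "X"}
    g = GraphThreePartition.from_classes(sigma.keys(), sigma, pdt_edges=None)
    scen = build_scenario(g)
    assert scen.T.leaves == {"x1", "x2"}
    assert scen.mu[scen.T.root] == (scen.S.planted_root, scen.S.root)
    assert partitions_equal(divergence_partition(scen), g)


def test_single_gene_input():
    from edt.divergence import GraphThreePartition

    g = GraphThreePartition.from_classes(["x"], {"x": "X"})
    scen = build_scenario(g)
    assert scen.T.leaves == {"x"}
    assert validate_relaxed(scen) == []


def test_empty_input_rejected():
    from edt.divergence import GraphThreePartition

    g = GraphThreePartition.from_classes([], {})
    with pytest.raises(InputError):
        build_scenario(g)


# -- round trips -----------------------------------------------------------------


def test_roundtrip_pool(pool):
    for s, g in pool:
        out = build_scenario(g)
        assert validate_relaxed(out) == []
        assert partitions_equal(divergence_partition(out), g)


def test_roundtrip_restricted_pool(pool):
    for s, g in pool[:40]:
        out = build_scenario(g, restricted=True)
        assert validate_relaxed(out) == []
        assert validate_restricted(out) == []
        assert partitions_equal(divergence_partition(out), g)


def test_worked_example_restricted_pins_both_edges():
    g = fixture("fig9_partition")
    out = build_scenario(g, restricted=True)
    assert validate_restricted(out) == []
    # the two H2-component vertices are mapped to different species edges
    edge_images = {
        m for m in out.mu.values() if isinstance(m, tuple) and m[0] == out.S.root
    }
    assert len(edge_images) == 2


def test_edt_edges_map_to_species_lca(pool):
    for _, g in pool[:30]:
        out = build_scenario(g)
        for e in g.edt.edges:
            x, y = sorted(e)
            lg = out.T.lca((x, y))
            assert out.mu[lg] == out.S.lca((out.sigma[x], out.sigma[y]))


def test_output_tree_phylogenetic(pool):
    for _, g in pool[:30]:
        out = build_scenario(g)
        for v in out.T.vertices:
            cs = out.T.children(v)
            if v == out.T.planted_root:
                assert len(cs) == 1
            else:
                assert len(cs) != 1


def test_supplied_species_tree_used_unchanged(pool):
    # any species tree agreeing with the triple system works unchanged
    for s, g in pool[:20]:
        out = build_scenario(g, species_tree=s.S, restricted=True)
        assert out.S is s.S or out.S.canonical() == s.S.canonical()
        assert partitions_equal(divergence_partition(out), g)
        assert validate_restricted(out) == []


def test_supplied_species_tree_with_unused_colors():
    g = fixture("fig9_partition")
    S = read_newick("((A,B),EXTRA);")
    out = build_scenario(g, species_tree=S)
    assert "EXTRA" in out.S.leaves
    assert partitions_equal(divergence_partition(out), g)


def test_disagreeing_species_tree_rejected():
    g = fixture("c6_partition")
    # species triples force {A,C,E} vs {B,D,F}; a tree splitting A|C fails
    bad = read_newick("((A,B,C),(D,E,F));")
    with pytest.raises(InputError):
        build_scenario(g, species_tree=bad)


def test_invalid_inputs_rejected_with_condition():
    from edt.divergence import GraphThreePartition

    sigma = dict.fromkeys(["a", "b"], "X")
    g = GraphThreePartition.from_classes(
        ["a", "b"], sigma, ldt_edges=[("a", "b")], pdt_edges=None
    )
    with pytest.raises(BuildInputError) as ei:
        build_scenario(g)
    assert ei.value.condition == "proper_coloring_ldt"
    obstruction = fixture("edt_obstruction")
    g2 = GraphThreePartition.from_classes(
        obstruction.vertices,
        dict(obstruction.sigma),
        edt_edges=[tuple(e) for e in obstruction.edges],
        pdt_edges=None,
    )
    with pytest.raises(BuildInputError) as ei2:
        build_scenario(g2)
    assert ei2.value.condition == "triples_inconsistent"


def test_explainable_restrictions_remain_explainable(pool):
    # hereditarity via the builder: restrictions of valid inputs still build
    rng = random.Random(71)
    for _, g in pool[:15]:
        verts = sorted(g.vertices)
        if len(verts) < 3:
            continue
        sub = rng.sample(verts, rng.randint(2, len(verts) - 1))
        gs = restrict_partition(g, sub)
        out = build_scenario(gs)
        assert partitions_equal(divergence_partition(out), gs)
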