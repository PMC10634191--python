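"""Decision procedures for divergence-time graphs.

Polynomial recognizers for explainable 3-partitions, PDT graphs, LDT
graphs and HGT-free EDT graphs; all return a constructed certificate
scenario rather than a bare boolean.  General EDT recognition is
NP-complete, so only a small-instance exponential oracle is provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional

from edt.trees import RootedTriple
from edt.scenario import Scenario
from edt.divergence import (
    ColoredGraph,
    GraphThreePartition,
    has_induced_path,
    has_odd_hole,
    is_cograph,
    is_properly_colored,
)
from edt.triples import aho_build
from edt.builder import classify_input, build_scenario

__all__ = [
    "InputVerdict",
    "OracleBudgetError",
    "is_valid_input",
    "recognize_pdt",
    "recognize_edt_hgt_free",
    "recognize_ldt",
    "edt_oracle",
]


@dataclass(frozen=True)
class InputVerdict:
    explainable: bool
    failed_condition: Optional[str] = None


class OracleBudgetError(RuntimeError):
    """The exponential oracle refused: too many undetermined pairs."""


def is_valid_input(g: GraphThreePartition) -> InputVerdict:
    """Explainability of a 3-partition by a relaxed scenario: G< and G=
    properly colored, G< and G> cographs, species triple system
    consistent.  Conditions are evaluated in that order and the first
    failure is reported."""
    failed, _, _ = classify_input(g)
    return InputVerdict(failed is None, failed)


def _neighbor_triples(G: ColoredGraph) -> set:
    """Species triples sigma(x)sigma(y)|sigma(z) for xz, yz in E and xy
    not in E with pairwise distinct colors."""
    out = set()
    sig = G.sigma
    for a, b, c in combinations(sorted(G.vertices), 3):
        if len({sig[a], sig[b], sig[c]}) != 3:
            continue
        for x, y, z in ((a, b, c), (a, c, b), (b, c, a)):
            if G.has_edge(x, z) and G.has_edge(y, z) and not G.has_edge(x, y):
                out.add(RootedTriple(sig[x], sig[y], sig[z]))
    return out


def _isolated_pair_triples(G: ColoredGraph) -> set:
    """Species triples sigma(x)sigma(y)|sigma(z) for xy in E and xz, yz
    not in E with pairwise distinct colors."""
    out = set()
    sig = G.sigma
    for a, b, c in combinations(sorted(G.vertices), 3):
        if len({sig[a], sig[b], sig[c]}) != 3:
            continue
        for x, y, z in ((a, b, c), (a, c, b), (b, c, a)):
            if G.has_edge(x, y) and not G.has_edge(x, z) and not G.has_edge(y, z):
                out.add(RootedTriple(sig[x], sig[y], sig[z]))
    return out


def recognize_pdt(G: ColoredGraph) -> Optional[Scenario]:
    """PDT recognition: G must be a cograph with properly colored
    complement and consistent triple set R(G); in the positive case a
    certificate scenario with G>(S) = G is returned."""
    if not is_cograph(G)[0]:
        return None
    if not is_properly_colored(G.complement()):
        return None
    r = _isolated_pair_triples(G)
    if aho_build(r, set(G.sigma.values())) is None:
        return None
    partition = GraphThreePartition(G.complement(), _edgeless(G), G)
    return build_scenario(partition, restricted=True)


def recognize_edt_hgt_free(G: ColoredGraph) -> Optional[Scenario]:
    """HGT-free EDT recognition: G must be a properly colored cograph with
    a consistent neighbor triple set; the returned certificate scenario is
    fully witnessed with an edgeless LDT graph, hence HGT-free."""
    if not is_properly_colored(G):
        return None
    if not is_cograph(G)[0]:
        return None
    r = _neighbor_triples(G)
    if aho_build(r, set(G.sigma.values())) is None:
        return None
    partition = GraphThreePartition(_edgeless(G), G, G.complement())
    return build_scenario(partition, restricted=True)


def recognize_ldt(G: ColoredGraph) -> Optional[Scenario]:
    """LDT recognition by reduction: test (G, empty, complement) for
    explainability and build in the positive case."""
    partition = GraphThreePartition(G, _edgeless(G), G.complement())
    if not is_valid_input(partition).explainable:
        return None
    return build_scenario(partition, restricted=True)


def _edgeless(G: ColoredGraph) -> ColoredGraph:
    return ColoredGraph(G.vertices, frozenset(), dict(G.sigma))


def edt_oracle(
    G: ColoredGraph, max_free_pairs: int = 20
) -> Optional[Scenario]:
    """Small-instance exhaustive EDT recognition.

    Necessary conditions (proper coloring, no induced P6, no odd hole) are
    tested first.  Same-colored non-edges and non-edges across distinct
    components of G are fixed to the PDT graph; every assignment of the
    remaining non-edges to {LDT, PDT} is then tried (fewest LDT edges
    first) until an explainable partition is found.  Raises
    :class:`OracleBudgetError` when the number of free pairs exceeds
    *max_free_pairs* -- an explicit refusal, distinct from the NONE that
    signals exhaustion of all assignments.
    """
    if not is_properly_colored(G):
        return None
    if has_induced_path(G, 6):
        return None
    if len(G.vertices) <= 11 and has_odd_hole(G):
        return None
    comps = G.components()
    comp_of = {v: c for c in comps for v in c}
    forced_gt, free = [], []
    sig = G.sigma
    for x, y in combinations(sorted(G.vertices), 2):
        if G.has_edge(x, y):
            continue
        if sig[x] == sig[y] or comp_of[x] is not comp_of[y]:
            forced_gt.append((x, y))
        else:
            free.append((x, y))
    if len(free) > max_free_pairs:
        raise OracleBudgetError(
            f"{len(free)} undetermined pairs exceed the budget of {max_free_pairs}"
        )
    for k in range(len(free) + 1):
        for ldt_pairs in combinations(free, k):
            ldt_set = set(ldt_pairs)
            gt = forced_gt + [p for p in free if p not in ldt_set]
            partition = GraphThreePartition.from_classes(
                G.vertices, dict(sig), ldt_pairs, [tuple(e) for e in G.edges], gt
            )
            if is_valid_input(partition).explainable:
                return build_scenario(partition, restricted=True)
    return None
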