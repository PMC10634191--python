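"""Relaxed and restricted reconciliation scenarios.

A scenario bundles a dated gene tree, a dated species tree, a leaf
coloring sigma and a reconciliation map mu sending gene-tree vertices to
species-tree vertices or oriented edges, subject to the time-consistency
axioms S0-S3.  Restricted scenarios additionally satisfy S4 (fully
witnessed), S5 and S6.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Union

from edt.trees import (
    Edge,
    InputError,
    Number,
    Place,
    PlantedTree,
    read_newick,
    write_newick,
)

__all__ = [
    "Scenario",
    "Violation",
    "ScenarioStructureError",
    "time_eq",
    "time_lt",
    "validate_relaxed",
    "validate_restricted",
    "hgt_edges",
    "witnesses",
    "is_fully_witnessed",
    "is_hgt_free",
    "is_generic",
    "scenario_to_dict",
    "scenario_from_dict",
    "write_scenario_json",
    "read_scenario_json",
]

DEFAULT_TOL = 1e-9


class ScenarioStructureError(ValueError):
    """The bundle is structurally broken (unknown vertices, partial maps);
    distinct from a mere axiom violation."""


@dataclass(frozen=True)
class Violation:
    axiom: str  # one of T(T), T(S), S0..S6
    subject: object  # offending vertex or edge
    detail: str

    def __str__(self):
        return f"{self.axiom} at {self.subject}: {self.detail}"


def _exact(x: Number) -> bool:
    return isinstance(x, (int, Fraction)) and not isinstance(x, bool)


def time_eq(a: Number, b: Number, tol: float = DEFAULT_TOL) -> bool:
    """Equality of time stamps: exact on ints/rationals, absolute tolerance
    otherwise."""
    if _exact(a) and _exact(b):
        return a == b
    return abs(a - b) <= tol


def time_lt(a: Number, b: Number, tol: float = DEFAULT_TOL) -> bool:
    if _exact(a) and _exact(b):
        return a < b
    return a < b - tol


@dataclass
class Scenario:
    """Relaxed scenario (T, S, sigma, mu, tau_T, tau_S)."""

    T: PlantedTree
    S: PlantedTree
    sigma: dict[str, str]
    mu: dict[str, Place]
    tau_T: dict[str, Number]
    tau_S: dict[str, Number]

    def mu_of(self, v: str) -> Place:
        return self.mu[v]

    def __post_init__(self):
        # normalize edge values to tuples
        self.mu = {
            v: tuple(m) if isinstance(m, (list, tuple)) else m
            for v, m in self.mu.items()
        }


def _check_structure(s: Scenario) -> None:
    vt = s.T.vertices
    vs = s.S.vertices
    missing = vt - set(s.mu)
    if missing:
        raise ScenarioStructureError(f"mu undefined on gene vertices {sorted(missing)}")
    for v, m in s.mu.items():
        if v not in vt:
            raise ScenarioStructureError(f"mu defined on unknown gene vertex {v!r}")
        if isinstance(m, tuple):
            if len(m) != 2 or m[0] not in vs or m[1] not in vs:
                raise ScenarioStructureError(f"mu({v!r}) references unknown edge {m!r}")
            if s.S.parent(m[1]) != m[0]:
                raise ScenarioStructureError(
                    f"mu({v!r}) = {m!r} is not a (parent, child) edge of S"
                )
        elif m not in vs:
            raise ScenarioStructureError(f"mu({v!r}) references unknown vertex {m!r}")
    for x in s.T.leaves:
        if x not in s.sigma:
            raise ScenarioStructureError(f"sigma undefined on leaf {x!r}")
        if s.sigma[x] not in s.S.leaves:
            raise ScenarioStructureError(
                f"sigma({x!r}) = {s.sigma[x]!r} is not a species leaf"
            )
    if vt - set(s.tau_T):
        raise ScenarioStructureError("tau_T is not total on V(T)")
    if vs - set(s.tau_S):
        raise ScenarioStructureError("tau_S is not total on V(S)")
    if not s.T.is_planted or not s.S.is_planted:
        raise ScenarioStructureError("both trees of a scenario must be planted")


def validate_relaxed(s: Scenario, tol: float = DEFAULT_TOL) -> list[Violation]:
    """All violations of the time-map requirement and axioms S0-S3.

    Violations are reported exhaustively, not fail-fast.  An empty list
    means the scenario is a valid relaxed scenario.
    """
    _check_structure(s)
    out: list[Violation] = []
    for tree, tau, tag in ((s.T, s.tau_T, "T(T)"), (s.S, s.tau_S, "T(S)")):
        for u, v in tree.edges():
            if not time_lt(tau[v], tau[u], tol):
                out.append(
                    Violation(tag, (u, v), f"tau({v})={tau[v]} !< tau({u})={tau[u]}")
                )
    zs = s.S.planted_root
    for x in s.T.vertices:
        m = s.mu[x]
        if (m == zs) != (x == s.T.planted_root):
            out.append(Violation("S0", x, f"mu({x})={m!r} vs planted root {zs!r}"))
        is_species_leaf = (not isinstance(m, tuple)) and s.S.is_leaf(m)
        if is_species_leaf != s.T.is_leaf(x):
            out.append(Violation("S1", x, f"mu({x})={m!r} leaf status mismatch"))
        elif s.T.is_leaf(x) and m != s.sigma[x]:
            out.append(Violation("S1", x, f"mu({x})={m!r} != sigma({x})={s.sigma[x]!r}"))
        if isinstance(m, tuple):
            u, v = m
            if not (
                time_lt(s.tau_S[v], s.tau_T[x], tol)
                and time_lt(s.tau_T[x], s.tau_S[u], tol)
            ):
                out.append(
                    Violation(
                        "S3",
                        x,
                        f"tau_T({x})={s.tau_T[x]} not inside "
                        f"({s.tau_S[v]}, {s.tau_S[u]}) of edge {m!r}",
                    )
                )
        else:
            if not time_eq(s.tau_S[m], s.tau_T[x], tol):
                out.append(
                    Violation(
                        "S2",
                        x,
                        f"tau_T({x})={s.tau_T[x]} != tau_S({m})={s.tau_S[m]}",
                    )
                )
    return out


def hgt_edges(s: Scenario) -> dict[Edge, int]:
    """HGT labeling: lam(uv) = 1 iff mu(u) and mu(v) are incomparable in S."""
    lam: dict[Edge, int] = {}
    for u, v in s.T.edges():
        lam[(u, v)] = 0 if s.S.comparable_ext(s.mu[u], s.mu[v]) else 1
    return lam


def witnesses(s: Scenario) -> dict[str, frozenset]:
    """For every gene-tree vertex the set of leaves reachable from it along
    a descending path free of HGT edges."""
    lam = hgt_edges(s)
    out: dict[str, frozenset] = {}
    for v in s.T.postorder():
        cs = s.T.children(v)
        if not cs:
            out[v] = frozenset((v,))
        else:
            acc: set = set()
            for c in cs:
                if lam[(v, c)] == 0:
                    acc |= out[c]
            out[v] = frozenset(acc)
    return out


def is_fully_witnessed(s: Scenario) -> bool:
    return all(w for w in witnesses(s).values())


def validate_restricted(s: Scenario, tol: float = DEFAULT_TOL) -> list[Violation]:
    """Violations of S4 (fully witnessed), S5 and S6 for a valid relaxed
    scenario."""
    out: list[Violation] = []
    wit = witnesses(s)
    for v, w in sorted(wit.items()):
        if not w:
            out.append(Violation("S4", v, "vertex has no witness"))
    v0s = s.S.inner_vertices
    for u in sorted(s.T.inner_vertices):
        m = s.mu[u]
        if isinstance(m, tuple) or m not in v0s:
            continue
        for c in s.T.children(u):
            mc = s.mu[c]
            if not (s.S.preceq_ext(mc, m) and mc != m):
                out.append(
                    Violation("S5", (u, c), f"mu({c})={mc!r} not strictly below mu({u})={m!r}")
                )
        ok = False
        ws = sorted(wit[u])
        for i, x in enumerate(ws):
            for y in ws[i + 1 :]:
                if s.T.lca((x, y)) == u and s.S.lca((s.sigma[x], s.sigma[y])) == m:
                    ok = True
                    break
            if ok:
                break
        if not ok:
            out.append(Violation("S6", u, "no witnessing leaf pair with matching lca"))
    return out


def is_hgt_free(s: Scenario) -> bool:
    return all(v == 0 for v in hgt_edges(s).values())


def is_generic(s: Scenario, tol: float = DEFAULT_TOL) -> bool:
    """Axiom (G): equal time stamps of a gene vertex and an inner species
    vertex force the reconciliation to that species vertex."""
    v0s = s.S.inner_vertices
    for v in s.T.inner_vertices:
        for u in v0s:
            if time_eq(s.tau_T[v], s.tau_S[u], tol) and s.mu[v] != u:
                return False
    return True


# -- JSON bundle ---------------------------------------------------------------


def _num_to_json(x: Number):
    if isinstance(x, Fraction):
        if x.denominator == 1:
            return int(x)
        return f"{x.numerator}/{x.denominator}"
    return x


def _num_from_json(x) -> Number:
    if isinstance(x, str):
        num, den = x.split("/")
        return Fraction(int(num), int(den))
    return x


def scenario_to_dict(s: Scenario) -> dict:
    return {
        "gene_tree": write_newick(s.T, include_inner_labels=True),
        "species_tree": write_newick(s.S, include_inner_labels=True),
        "gene_planted_root": s.T.planted_root,
        "species_planted_root": s.S.planted_root,
        "sigma": dict(sorted(s.sigma.items())),
        "mu": {
            v: (list(m) if isinstance(m, tuple) else m)
            for v, m in sorted(s.mu.items())
        },
        "tau_T": {v: _num_to_json(t) for v, t in sorted(s.tau_T.items())},
        "tau_S": {v: _num_to_json(t) for v, t in sorted(s.tau_S.items())},
    }


def _tree_from_bundle(newick: str, planted_root: str) -> PlantedTree:
    t = read_newick(newick, keep_inner_labels=True)
    # re-plant with the recorded planted-root label
    children = {v: t.children(v) for v in t.vertices if t.children(v)}
    del children[t.planted_root]
    children[planted_root] = (t.root,)
    return PlantedTree(children, root=t.root, planted_root=planted_root)


def scenario_from_dict(d: Mapping) -> Scenario:
    try:
        T = _tree_from_bundle(d["gene_tree"], d["gene_planted_root"])
        S = _tree_from_bundle(d["species_tree"], d["species_planted_root"])
        mu = {
            v: (tuple(m) if isinstance(m, list) else m) for v, m in d["mu"].items()
        }
        return Scenario(
            T=T,
            S=S,
            sigma=dict(d["sigma"]),
            mu=mu,
            tau_T={v: _num_from_json(t) for v, t in d["tau_T"].items()},
            tau_S={v: _num_from_json(t) for v, t in d["tau_S"].items()},
        )
    except KeyError as e:
        raise ScenarioStructureError(f"scenario bundle is missing key {e}") from e


def write_scenario_json(s: Scenario, path) -> None:
    with open(path, "w") as fh:
        json.dump(scenario_to_dict(s), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_scenario_json(path) -> Scenario:
    with open(path) as fh:
        return scenario_from_dict(json.load(fh))
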