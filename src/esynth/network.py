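"""Discrete Bayesian-network primitives.

Variables, conditional probability tables (CPTs) and the causal network
container that the rest of the package builds on.  Networks here are tiny
(a few dozen nodes at most), so everything is stored explicitly: a CPT is
a mapping from each full parent-state combination to a distribution over
the child's states, and the joint probability is the plain chain-rule
product.

Networks are immutable by contract: every mutating operation returns a new
``CausalNetwork`` and leaves its inputs untouched, which makes
sequential-versus-batch equivalence checks trivial.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Hashable, Iterable, Mapping

import networkx as nx

__all__ = [
    "BINARY_STATES",
    "ROLES",
    "DiscreteVariable",
    "Cpt",
    "CausalNetwork",
    "NetworkError",
    "add_variable",
    "attach_cpt",
    "validate_network",
    "joint_probability",
]

#: Canonical state ordering for all binary variables: (false, true).
BINARY_STATES: tuple[Hashable, ...] = (False, True)

#: Node role annotations.
ROLES = ("hypothesis", "indicator", "mechanism", "sub-mechanism", "report", "modulator")

#: Row-normalisation tolerance for CPT rows.
ROW_TOL = 1e-12


class NetworkError(ValueError):
    """Raised on structural violations (duplicates, cycles, bad CPTs)."""


@dataclass(frozen=True)
class DiscreteVariable:
    """A named discrete variable with an ordered, finite state space.

    All causal, indicator, mechanism and report variables are binary with
    states ``(False, True)``; explicit modulator nodes (e.g. a shared
    sponsorship-bias variable) may carry more states.
    """

    name: str
    states: tuple[Hashable, ...] = BINARY_STATES

    def __post_init__(self) -> None:
        if not self.name:
            raise NetworkError("variable name must be non-empty")
        object.__setattr__(self, "states", tuple(self.states))
        if len(self.states) < 2:
            raise NetworkError(f"variable {self.name!r} needs at least 2 states")
        if len(set(self.states)) != len(self.states):
            raise NetworkError(f"variable {self.name!r} has duplicate states")

    @property
    def cardinality(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class Cpt:
    """Conditional probability table P(child | parents).

    ``table`` maps every full parent-state combination (a tuple ordered
    like ``parents``; the empty tuple for root nodes) to a distribution
    over the child's states, ordered like the child's state list.
    """

    child: str
    parents: tuple[str, ...]
    table: Mapping[tuple[Hashable, ...], tuple[float, ...]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "parents", tuple(self.parents))
        frozen = {tuple(k): tuple(float(p) for p in v) for k, v in self.table.items()}
        object.__setattr__(self, "table", frozen)
        for combo, row in frozen.items():
            if len(combo) != len(self.parents):
                raise NetworkError(
                    f"CPT for {self.child!r}: combination {combo!r} does not match "
                    f"parent list {self.parents!r}"
                )
            if any(p < 0.0 or p > 1.0 for p in row):
                raise NetworkError(f"CPT for {self.child!r}: probability outside [0,1] in row {combo!r}")
            if abs(sum(row) - 1.0) > ROW_TOL:
                raise NetworkError(
                    f"unnormalized row for {self.child!r} given {dict(zip(self.parents, combo))!r}: "
                    f"sums to {sum(row)!r}"
                )

    def row(self, combo: tuple[Hashable, ...]) -> tuple[float, ...]:
        return self.table[tuple(combo)]

    def prob(self, child_index: int, combo: tuple[Hashable, ...]) -> float:
        return self.table[tuple(combo)][child_index]


@dataclass(frozen=True)
class CausalNetwork:
    """A DAG of discrete variables with one CPT per variable.

    ``tags`` annotates each node with its role (hypothesis, indicator,
    mechanism, sub-mechanism, report, modulator).  Exactly one node may be
    tagged ``hypothesis`` and it must be a root.
    """

    variables: Mapping[str, DiscreteVariable] = field(default_factory=dict)
    cpts: Mapping[str, Cpt] = field(default_factory=dict)
    tags: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", dict(self.variables))
        object.__setattr__(self, "cpts", dict(self.cpts))
        object.__setattr__(self, "tags", dict(self.tags))

    # -- read helpers ------------------------------------------------------
    def variable(self, name: str) -> DiscreteVariable:
        return self.variables[name]

    def parents(self, name: str) -> tuple[str, ...]:
        cpt = self.cpts.get(name)
        return cpt.parents if cpt is not None else ()

    def nodes_tagged(self, role: str) -> list[str]:
        return [n for n, r in self.tags.items() if r == role]

    @property
    def hypothesis(self) -> str:
        hyp = self.nodes_tagged("hypothesis")
        if len(hyp) != 1:
            raise NetworkError(f"expected exactly one hypothesis node, found {hyp!r}")
        return hyp[0]

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        for child, cpt in self.cpts.items():
            g.add_edges_from((p, child) for p in cpt.parents)
        return g

    def topological_order(self) -> list[str]:
        return list(nx.topological_sort(self.graph()))


def add_variable(net: CausalNetwork, var: DiscreteVariable, tag: str = "indicator") -> CausalNetwork:
    """Return a new network containing ``var`` with role ``tag``."""
    if var.name in net.variables:
        raise NetworkError(f"duplicate variable: {var.name!r}")
    if tag not in ROLES:
        raise NetworkError(f"unknown role {tag!r}; expected one of {ROLES}")
    if tag == "hypothesis" and net.nodes_tagged("hypothesis"):
        raise NetworkError("network already has a hypothesis node")
    variables = dict(net.variables)
    variables[var.name] = var
    tags = dict(net.tags)
    tags[var.name] = tag
    return replace(net, variables=variables, tags=tags)


def attach_cpt(net: CausalNetwork, cpt: Cpt) -> CausalNetwork:
    """Return a new network with ``cpt`` attached (replacing any previous CPT).

    Rejects CPTs that reference unknown nodes, omit or duplicate parent
    combinations, or would introduce a directed cycle.
    """
    if cpt.child not in net.variables:
        raise NetworkError(f"missing node: {cpt.child!r}")
    for p in cpt.parents:
        if p not in net.variables:
            raise NetworkError(f"missing node: {p!r}")
    if len(set(cpt.parents)) != len(cpt.parents):
        raise NetworkError(f"CPT for {cpt.child!r} lists a parent twice")

    expected = set(itertools.product(*(net.variables[p].states for p in cpt.parents)))
    got = set(cpt.table)
    if got != expected:
        missing = expected - got
        extra = got - expected
        raise NetworkError(
            f"CPT for {cpt.child!r}: parent combinations mismatch "
            f"(missing {sorted(map(str, missing))[:3]!r}, unexpected {sorted(map(str, extra))[:3]!r})"
        )
    width = net.variables[cpt.child].cardinality
    for combo, row in cpt.table.items():
        if len(row) != width:
            raise NetworkError(f"CPT for {cpt.child!r}: row {combo!r} has {len(row)} entries, expected {width}")

    cpts = dict(net.cpts)
    cpts[cpt.child] = cpt
    candidate = replace(net, cpts=cpts)
    if not nx.is_directed_acyclic_graph(candidate.graph()):
        raise NetworkError(f"cycle: attaching CPT for {cpt.child!r} creates a directed cycle")
    return candidate


def validate_network(net: CausalNetwork) -> list[str]:
    """Return diagnostics; an empty list means the network is well-formed.

    Checks: every variable has a CPT, the graph is acyclic, and the single
    hypothesis node is a root.  (Row normalisation and combination
    completeness are enforced at construction/attachment time.)
    """
    diagnostics: list[str] = []
    for name in net.variables:
        if name not in net.cpts:
            diagnostics.append(f"no CPT: {name}")
    if not nx.is_directed_acyclic_graph(net.graph()):
        diagnostics.append("cycle in network graph")
    hyp = net.nodes_tagged("hypothesis")
    if len(hyp) != 1:
        diagnostics.append(f"expected exactly one hypothesis node, found {len(hyp)}")
    elif net.parents(hyp[0]):
        diagnostics.append("hypothesis not a root")
    return diagnostics


def joint_probability(net: CausalNetwork, assignment: Mapping[str, Hashable]) -> float:
    """Chain-rule joint probability of a full state assignment."""
    missing = set(net.variables) - set(assignment)
    if missing:
        raise NetworkError(f"incomplete assignment: missing {sorted(missing)!r}")
    p = 1.0
    for name, var in net.variables.items():
        cpt = net.cpts[name]
        combo = tuple(assignment[par] for par in cpt.parents)
        idx = var.states.index(assignment[name])
        p *= cpt.prob(idx, combo)
        if p == 0.0:
            return 0.0
    return p


def all_assignments(net: CausalNetwork) -> Iterable[dict[str, Hashable]]:
    """Iterate over every full state assignment of the network."""
    names = list(net.variables)
    spaces = [net.variables[n].states for n in names]
    for combo in itertools.product(*spaces):
        yield dict(zip(names, combo))
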