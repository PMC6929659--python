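"""Mechanism sub-networks: alternative mechanism hypotheses, their
sub-mechanism chains, and basic-science evidence reports.

The existential node M ("some mechanism from drug to adverse effect
exists") fans out into concrete candidate mechanisms M_i, each decomposed
into an ordered chain of sub-mechanism links mu_{i,1} ... mu_{i,K}
(e.g. "the drug is metabolised to X", "X activates receptor Y", ...).
The CPTs encode three logical facts:

* a mechanism entails each of its links: P(link | M_i, ...) = 1;
* the conjunction of all links entails the mechanism, so the final link
  is impossible when the mechanism fails but every earlier link holds:
  P(mu_{i,K} | not M_i, earlier links all true) = 0;
* otherwise a link has its background probability of holding anyway —
  1 for biochemistry taken as established, 0.5 for indifference, or any
  elicited value.

Basic-science reports attach to individual links with a graded Bayes
factor: "confident" claims carry likelihoods 0.91/0.09 (BF ~ 10),
"cautious" claims 0.75/0.25 (BF = 3).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .causal import MECH
from .network import (
    BINARY_STATES,
    CausalNetwork,
    Cpt,
    DiscreteVariable,
    NetworkError,
    add_variable,
    attach_cpt,
)

__all__ = [
    "GRADE_LIKELIHOODS",
    "LinkSpec",
    "MechanismSpec",
    "MechReport",
    "chain_cpts",
    "build_mechanism_subnet",
    "attach_mech_report",
]

#: Likelihood pairs (P(rep=1 | link), P(rep=1 | not link)) by claim grade.
GRADE_LIKELIHOODS: dict[str, tuple[float, float]] = {
    "confident": (0.91, 0.09),
    "cautious": (0.75, 0.25),
}

ESTABLISHED = 1.0
INDIFFERENT = 0.5


@dataclass(frozen=True)
class LinkSpec:
    """One sub-mechanism link mu_{i,k}.

    ``background`` is the probability of the link holding when its
    mechanism fails (and the chain's inconsistency rule does not apply):
    1 for established biochemistry, 0.5 for indifference, or an elicited
    value.
    """

    id: str
    background: float = INDIFFERENT

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkError("link id must be non-empty")
        if not 0.0 <= self.background <= 1.0:
            raise NetworkError(f"link {self.id!r}: background {self.background!r} out of [0,1]")


@dataclass(frozen=True)
class MechReport:
    """A basic-science evidence report on one sub-mechanism link."""

    id: str
    link: str
    grade: str = "confident"
    outcome: int = 1
    likelihoods: tuple[float, float] | None = None  # custom (p1, p0) pair

    def __post_init__(self) -> None:
        if self.grade not in GRADE_LIKELIHOODS and self.grade != "custom":
            raise NetworkError(f"report {self.id!r}: unknown grade {self.grade!r}")
        if self.grade == "custom":
            if self.likelihoods is None:
                raise NetworkError(f"report {self.id!r}: custom grade requires likelihoods")
            p1, p0 = self.likelihoods
            if not (0.0 < p0 < p1 < 1.0):
                raise NetworkError(
                    f"report {self.id!r}: custom likelihoods must satisfy 0 < p0 < p1 < 1 "
                    f"(got {self.likelihoods!r})"
                )
        if self.outcome not in (0, 1):
            raise NetworkError(f"report {self.id!r}: outcome must be 0 or 1")

    @property
    def likelihood_pair(self) -> tuple[float, float]:
        if self.grade == "custom":
            assert self.likelihoods is not None
            return self.likelihoods
        return GRADE_LIKELIHOODS[self.grade]

    @property
    def report_node(self) -> str:
        return f"Rep[{self.id}]"


@dataclass(frozen=True)
class MechanismSpec:
    """A candidate mechanism M_i with its ordered sub-mechanism chain.

    ``p_given_m`` is P(M_i | M); P(M_i | not M) is fixed at 0 — if no
    mechanism exists, every concrete mechanism fails.  ``shared_links``
    names link nodes of *other* mechanisms that this mechanism also
    entails (it becomes an additional parent of those links).
    """

    id: str
    p_given_m: float
    links: tuple[LinkSpec, ...]
    reports: tuple[MechReport, ...] = ()
    shared_links: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "links", tuple(self.links))
        object.__setattr__(self, "reports", tuple(self.reports))
        object.__setattr__(self, "shared_links", tuple(self.shared_links))
        if not 0.0 <= self.p_given_m <= 1.0:
            raise NetworkError(f"mechanism {self.id!r}: p_given_m out of [0,1]")
        if not self.links:
            raise NetworkError(f"mechanism {self.id!r}: at least one link required")
        ids = [l.id for l in self.links]
        if len(set(ids)) != len(ids):
            raise NetworkError(f"mechanism {self.id!r}: duplicate link ids")
        own = set(ids)
        for r in self.reports:
            if r.link not in own:
                raise NetworkError(f"mechanism {self.id!r}: report {r.id!r} references missing link {r.link!r}")


def chain_cpts(spec: MechanismSpec) -> list[Cpt]:
    """CPTs of the chain links mu_{i,1} ... mu_{i,K} given M_i.

    Link k has parents (M_i, mu_{i,1}, ..., mu_{i,k-1}).  Rows: 1 whenever
    M_i is true; 0 for the final link when M_i is false and every earlier
    link is true (logical inconsistency); the link's background otherwise.
    """
    cpts: list[Cpt] = []
    n = len(spec.links)
    for k, link in enumerate(spec.links):
        parents = (spec.id,) + tuple(l.id for l in spec.links[:k])
        table: dict[tuple, tuple[float, float]] = {}
        for combo in itertools.product(BINARY_STATES, repeat=len(parents)):
            mech_true, earlier = combo[0], combo[1:]
            if mech_true:
                p = 1.0
            elif k == n - 1 and all(earlier):
                p = 0.0  # all links true would entail the mechanism
            else:
                p = link.background
            table[combo] = (1.0 - p, p)
        cpts.append(Cpt(link.id, parents, table))
    return cpts


def build_mechanism_subnet(net: CausalNetwork, specs: Sequence[MechanismSpec]) -> CausalNetwork:
    """Add mechanism hypotheses, chains and their reports below node M.

    Each M_i gets parent M with P(M_i | M) = p_given_m and
    P(M_i | not M) = 0; links follow :func:`chain_cpts`.  A link named in
    another mechanism's ``shared_links`` gains that mechanism as an extra
    parent and becomes true with probability 1 whenever *any* parent
    mechanism is true; otherwise the owning chain's rules apply.
    """
    if not specs:
        return net
    if MECH not in net.variables:
        raise NetworkError(f"node {MECH!r} missing: build the causal layer first")
    ids = [s.id for s in specs]
    if len(set(ids)) != len(ids):
        raise NetworkError("duplicate mechanism ids")
    all_links = {l.id for s in specs for l in s.links}
    # mechanism nodes
    for spec in specs:
        net = add_variable(net, DiscreteVariable(spec.id, BINARY_STATES), "mechanism")
        net = attach_cpt(
            net,
            Cpt(spec.id, (MECH,), {(True,): (1.0 - spec.p_given_m, spec.p_given_m), (False,): (1.0, 0.0)}),
        )
    # extra mechanism parents for shared links
    sharers: dict[str, list[str]] = {}
    for spec in specs:
        for link_id in spec.shared_links:
            if link_id not in all_links:
                raise NetworkError(f"missing link: {link_id!r} (shared by {spec.id!r})")
            if link_id in {l.id for l in spec.links}:
                raise NetworkError(f"mechanism {spec.id!r} shares its own link {link_id!r}")
            sharers.setdefault(link_id, []).append(spec.id)
    # link nodes
    for spec in specs:
        for base in chain_cpts(spec):
            extra = tuple(sharers.get(base.child, ()))
            net = add_variable(net, DiscreteVariable(base.child, BINARY_STATES), "sub-mechanism")
            if not extra:
                net = attach_cpt(net, base)
                continue
            parents = base.parents + extra
            table: dict[tuple, tuple[float, float]] = {}
            for combo, row in base.table.items():
                for extra_combo in itertools.product(BINARY_STATES, repeat=len(extra)):
                    p = 1.0 if any(extra_combo) else row[1]
                    table[combo + extra_combo] = (1.0 - p, p)
            net = attach_cpt(net, Cpt(base.child, parents, table))
    # reports
    for spec in specs:
        for report in spec.reports:
            net = attach_mech_report(net, report)
    return net


def attach_mech_report(net: CausalNetwork, report: MechReport) -> CausalNetwork:
    """Add one basic-science report node as a child of its link."""
    if report.link not in net.variables:
        raise NetworkError(f"missing link: {report.link!r}")
    p1, p0 = report.likelihood_pair
    net = add_variable(net, DiscreteVariable(report.report_node, BINARY_STATES), "report")
    return attach_cpt(
        net,
        Cpt(report.report_node, (report.link,), {(True,): (1.0 - p1, p1), (False,): (1.0 - p0, p0)}),
    )
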