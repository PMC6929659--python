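"""Exact inference: variable elimination, an enumeration oracle, and
sequential evidence trajectories.

The networks this package builds are small (the full worked case study is
about twenty nodes), so exact inference is both feasible and mandatory:
``posterior`` runs variable elimination with a greedy min-fill ordering,
and ``brute_force_posterior`` recomputes the same quantity by exhaustive
summation over the full joint — a deliberately independent code path used
as the verification oracle throughout the test suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd

from .network import CausalNetwork, Cpt, NetworkError

__all__ = [
    "posterior",
    "marginal_distribution",
    "brute_force_posterior",
    "trajectory",
    "sensitivity",
    "with_prior",
    "PosteriorTrajectory",
    "TrajectoryRow",
]


# --------------------------------------------------------------------------
# Factors for variable elimination
# --------------------------------------------------------------------------

class _Factor:
    """A nonnegative table over an ordered tuple of variables."""

    __slots__ = ("vars", "values")

    def __init__(self, vars: tuple[str, ...], values: np.ndarray):
        self.vars = vars
        self.values = values

    @classmethod
    def from_cpt(cls, net: CausalNetwork, cpt: Cpt) -> "_Factor":
        names = cpt.parents + (cpt.child,)
        shape = tuple(net.variables[n].cardinality for n in names)
        arr = np.empty(shape, dtype=float)
        parent_spaces = [net.variables[p].states for p in cpt.parents]
        for combo in itertools.product(*(range(len(s)) for s in parent_spaces)):
            labels = tuple(parent_spaces[i][ix] for i, ix in enumerate(combo))
            arr[combo] = cpt.row(labels)
        return cls(names, arr)

    def reduce(self, var: str, state_index: int) -> "_Factor":
        if var not in self.vars:
            return self
        axis = self.vars.index(var)
        values = np.take(self.values, state_index, axis=axis)
        vars = self.vars[:axis] + self.vars[axis + 1:]
        return _Factor(vars, values)

    def multiply(self, other: "_Factor") -> "_Factor":
        out_vars = self.vars + tuple(v for v in other.vars if v not in self.vars)
        a = self._broadcast(out_vars)
        b = other._broadcast(out_vars)
        return _Factor(out_vars, a * b)

    def _broadcast(self, out_vars: tuple[str, ...]) -> np.ndarray:
        src = {v: i for i, v in enumerate(self.vars)}
        perm = [src[v] for v in out_vars if v in src]
        arr = np.transpose(self.values, perm)
        dims = iter(arr.shape)
        shape = [next(dims) if v in src else 1 for v in out_vars]
        return arr.reshape(shape)

    def sum_out(self, var: str) -> "_Factor":
        axis = self.vars.index(var)
        return _Factor(self.vars[:axis] + self.vars[axis + 1:], self.values.sum(axis=axis))


def _min_fill_order(net: CausalNetwork, eliminate: set[str]) -> list[str]:
    """Greedy min-fill elimination ordering on the moral graph."""
    # adjacency over all variables; cliques from CPT families
    adj: dict[str, set[str]] = {v: set() for v in net.variables}
    for child, cpt in net.cpts.items():
        family = set(cpt.parents) | {child}
        for a in family:
            adj[a] |= family - {a}
    order: list[str] = []
    remaining = set(eliminate)
    while remaining:
        best, best_fill = None, None
        for v in sorted(remaining):
            nbrs = {n for n in adj[v] if n != v}
            fill = sum(
                1
                for a, b in itertools.combinations(sorted(nbrs), 2)
                if b not in adj[a]
            )
            if best_fill is None or fill < best_fill:
                best, best_fill = v, fill
        assert best is not None
        nbrs = {n for n in adj[best] if n != best}
        for a, b in itertools.combinations(nbrs, 2):
            adj[a].add(b)
            adj[b].add(a)
        for n in nbrs:
            adj[n].discard(best)
        del adj[best]
        remaining.discard(best)
        order.append(best)
    return order


def _check_evidence(net: CausalNetwork, evidence: Mapping[str, Hashable]) -> dict[str, int]:
    indexed: dict[str, int] = {}
    for name, state in evidence.items():
        if name not in net.variables:
            raise NetworkError(f"evidence on unknown node {name!r}")
        states = net.variables[name].states
        if state not in states:
            raise NetworkError(f"evidence state {state!r} not a state of {name!r}")
        indexed[name] = states.index(state)
    return indexed


def marginal_distribution(
    net: CausalNetwork,
    target: str,
    evidence: Mapping[str, Hashable] | None = None,
) -> np.ndarray:
    """Exact conditional distribution of ``target`` given ``evidence``.

    Returns the distribution over the target's states, ordered as in the
    variable's state list.  Raises on evidence with probability zero.
    """
    diagnostics = [d for d in _structural(net)]
    if diagnostics:
        raise NetworkError(f"invalid network: {diagnostics!r}")
    if target not in net.variables:
        raise NetworkError(f"unknown target {target!r}")
    ev = _check_evidence(net, evidence or {})
    if target in ev:
        rest = {n: s for n, s in (evidence or {}).items() if n != target}
        dist = marginal_distribution(net, target, rest)
        if dist[ev[target]] <= 0.0:
            raise NetworkError(f"impossible evidence: {dict(evidence or {})!r} has probability 0")
        out = np.zeros(net.variables[target].cardinality)
        out[ev[target]] = 1.0
        return out

    factors = [_Factor.from_cpt(net, cpt) for cpt in net.cpts.values()]
    for var, idx in ev.items():
        factors = [f.reduce(var, idx) for f in factors]
    eliminate = set(net.variables) - set(ev) - {target}
    for var in _min_fill_order(net, eliminate):
        involved = [f for f in factors if var in f.vars]
        rest = [f for f in factors if var not in f.vars]
        if not involved:
            continue
        prod = involved[0]
        for f in involved[1:]:
            prod = prod.multiply(f)
        factors = rest + [prod.sum_out(var)]
    result = _Factor((target,), np.ones(net.variables[target].cardinality))
    for f in factors:
        result = result.multiply(f)
    values = np.asarray(result.values, dtype=float).reshape(-1)
    total = values.sum()
    if total <= 0.0:
        raise NetworkError(f"impossible evidence: {dict(evidence or {})!r} has probability 0")
    return values / total


def _structural(net: CausalNetwork) -> list[str]:
    from .network import validate_network

    return validate_network(net)


def posterior(
    net: CausalNetwork,
    target: str | None = None,
    evidence: Mapping[str, Hashable] | None = None,
    *,
    state: Hashable = True,
) -> float:
    """Exact P(target = state | evidence) by variable elimination.

    ``target`` defaults to the network's hypothesis node and ``state`` to
    True, so ``posterior(net, evidence=...)`` is the posterior probability
    of causation given the observed reports.
    """
    if target is None:
        target = net.hypothesis
    dist = marginal_distribution(net, target, evidence)
    return float(dist[net.variables[target].states.index(state)])


# --------------------------------------------------------------------------
# Enumeration oracle
# --------------------------------------------------------------------------

#: The oracle refuses joints larger than this many configurations.
_BRUTE_FORCE_LIMIT = 2 ** 22


def brute_force_posterior(
    net: CausalNetwork,
    target: str | None = None,
    evidence: Mapping[str, Hashable] | None = None,
    *,
    state: Hashable = True,
) -> float:
    """Posterior by exhaustive summation over the full joint.

    Vectorised enumeration of every configuration; independent of the
    variable-elimination path and used as its correctness oracle.
    """
    if target is None:
        target = net.hypothesis
    diagnostics = _structural(net)
    if diagnostics:
        raise NetworkError(f"invalid network: {diagnostics!r}")
    ev = _check_evidence(net, evidence or {})
    names = list(net.variables)
    cards = [net.variables[n].cardinality for n in names]
    size = int(np.prod(cards))
    if size > _BRUTE_FORCE_LIMIT:
        raise NetworkError(f"network too large for brute force: {size} configurations")

    # grid[:, i] = state index of variable names[i] in each configuration
    grid = np.indices(cards).reshape(len(names), size).T
    col = {n: i for i, n in enumerate(names)}
    probs = np.ones(size)
    for name in names:
        cpt = net.cpts[name]
        parent_spaces = [net.variables[p].states for p in cpt.parents]
        table = np.empty([len(s) for s in parent_spaces] + [net.variables[name].cardinality])
        for combo in itertools.product(*(range(len(s)) for s in parent_spaces)):
            labels = tuple(parent_spaces[i][ix] for i, ix in enumerate(combo))
            table[combo] = cpt.row(labels)
        idx = tuple(grid[:, col[p]] for p in cpt.parents) + (grid[:, col[name]],)
        probs *= table[idx]
    mask = np.ones(size, dtype=bool)
    for name, state_idx in ev.items():
        mask &= grid[:, col[name]] == state_idx
    denom = probs[mask].sum()
    if denom <= 0.0:
        raise NetworkError(f"impossible evidence: {dict(evidence or {})!r} has probability 0")
    tgt_idx = net.variables[target].states.index(state)
    numer = probs[mask & (grid[:, col[target]] == tgt_idx)].sum()
    return float(numer / denom)


# --------------------------------------------------------------------------
# Trajectories and sensitivity analysis
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrajectoryRow:
    """Posterior state after incorporating one evidence item."""

    item_id: str
    posteriors: tuple[float, ...]  # one per configured prior
    lr_contributions: tuple[float, ...]  # odds ratio vs previous row, per prior


@dataclass(frozen=True)
class PosteriorTrajectory:
    """Ordered posteriors of the causal hypothesis under accumulating evidence.

    The first row (item_id ``"prior"``) carries the priors themselves;
    each later row conditions on all evidence up to and including that
    item.  ``lr_contributions`` is the factor by which the item multiplied
    the posterior odds.
    """

    priors: tuple[float, ...]
    rows: tuple[TrajectoryRow, ...]

    @property
    def final_posteriors(self) -> tuple[float, ...]:
        return self.rows[-1].posteriors

    def to_frame(self) -> pd.DataFrame:
        records = [
            {
                "item_id": row.item_id,
                "prior": prior,
                "posterior": post,
                "posterior_4dp": _round_half_up(post, 4),
                "lr_contribution": lr,
            }
            for row in self.rows
            for prior, post, lr in zip(self.priors, row.posteriors, row.lr_contributions)
        ]
        return pd.DataFrame.from_records(records)


def _round_half_up(x: float, digits: int) -> float:
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -digits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def with_prior(net: CausalNetwork, prior: float) -> CausalNetwork:
    """Return the network with the hypothesis prior replaced."""
    hyp = net.hypothesis
    cpts = dict(net.cpts)
    cpts[hyp] = Cpt(hyp, (), {(): (1.0 - prior, prior)})
    return replace(net, cpts=cpts)


def _odds(p: float) -> float:
    return p / (1.0 - p) if p < 1.0 else float("inf")


def trajectory(
    net: CausalNetwork,
    ordered_evidence: Sequence[tuple[str, Hashable]],
    priors: Sequence[float] | None = None,
) -> PosteriorTrajectory:
    """Posterior of the hypothesis after each successive evidence item.

    ``ordered_evidence`` is a list of (report node, observed state) pairs;
    nodes must be distinct.  For each prior the hypothesis CPT is swapped
    and the exact posterior recomputed for every prefix of the evidence,
    so the final row equals the batch posterior on the full set.
    """
    seen = set()
    for name, _ in ordered_evidence:
        if name in seen:
            raise NetworkError(f"duplicate evidence node {name!r}")
        seen.add(name)
    hyp = net.hypothesis
    if priors is None:
        priors = [posterior(net, target=hyp)]
    priors = tuple(float(p) for p in priors)

    rows = [TrajectoryRow("prior", priors, tuple(1.0 for _ in priors))]
    nets = [with_prior(net, p) for p in priors]
    prev = priors
    for t in range(1, len(ordered_evidence) + 1):
        evidence = dict(ordered_evidence[:t])
        posts = tuple(posterior(n, target=hyp, evidence=evidence) for n in nets)
        lrs = tuple(
            _odds(p) / _odds(q) if 0.0 < q < 1.0 else float("nan")
            for p, q in zip(posts, prev)
        )
        rows.append(TrajectoryRow(ordered_evidence[t - 1][0], posts, lrs))
        prev = posts
    return PosteriorTrajectory(priors, tuple(rows))


def sensitivity(
    net: CausalNetwork,
    evidence: Mapping[str, Hashable],
    priors: Sequence[float],
) -> pd.DataFrame:
    """Posterior of the hypothesis for each prior (sensitivity analysis)."""
    for p in priors:
        if not 0.0 < p < 1.0:
            raise NetworkError(f"degenerate prior {p!r}: must be strictly inside (0,1)")
    hyp = net.hypothesis
    records = []
    for p in priors:
        post = posterior(with_prior(net, p), target=hyp, evidence=evidence)
        records.append({"prior": p, "posterior": post, "posterior_4dp": _round_half_up(post, 4)})
    return pd.DataFrame.from_records(records)
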