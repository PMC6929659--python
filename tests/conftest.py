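import itertools

import numpy as np
import pytest

from esynth.network import (
    BINARY_STATES,
    CausalNetwork,
    Cpt,
    DiscreteVariable,
    add_variable,
    attach_cpt,
)


@pytest.fixture(scope="session")
def fixture_spec():
    from esynth.casefile import load_fixture

    return load_fixture()


@pytest.fixture(scope="session")
def fixture_network(fixture_spec):
    from esynth.casefile import build_case_network

    return build_case_network(fixture_spec)


@pytest.fixture(scope="session")
def mech_evidence(fixture_spec):
    """(report node, state) pairs for the six positive mechanistic reports."""
    return [
        (r.report_node, bool(r.outcome))
        for m in fixture_spec.mechanisms
        for r in m.reports
    ]


def random_network(rng: np.random.Generator, n_nodes: int, max_states: int = 3) -> CausalNetwork:
    """A random DAG over nodes v0..v(n-1) with random CPTs.

    Edges only point from lower to higher index, so acyclicity holds by
    construction.  Node v0 is the (binary, root) hypothesis.
    """
    net = CausalNetwork()
    cards = [2] + [int(rng.integers(2, max_states + 1)) for _ in range(n_nodes - 1)]
    for i, k in enumerate(cards):
        states = BINARY_STATES if k == 2 else tuple(range(k))
        net = add_variable(
            net,
            DiscreteVariable(f"v{i}", states),
            "hypothesis" if i == 0 else "indicator",
        )
    for i, k in enumerate(cards):
        if i == 0:
            parents: tuple[str, ...] = ()
        else:
            n_par = int(rng.integers(0, min(i, 3) + 1))
            parents = tuple(f"v{j}" for j in sorted(rng.choice(i, size=n_par, replace=False)))
        spaces = [net.variables[p].states for p in parents]
        table = {}
        for combo in itertools.product(*spaces):
            row = rng.dirichlet(np.ones(k))
            table[combo] = tuple(row / row.sum())
        # exact renormalisation to satisfy the 1e-12 row tolerance
        table = {c: tuple(p / sum(r) for p in r) for c, r in ((c, r) for c, r in table.items())}
        net = attach_cpt(net, Cpt(f"v{i}", parents, table))
    return net
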