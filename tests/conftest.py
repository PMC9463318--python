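"""Shared fixtures: tiny hand-checkable networks and a random-network
factory used for oracle-equivalence testing."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from opscc_cdm import (
    BayesianNetwork,
    CPT,
    DiscreteVariable,
    PatientDataset,
)


@pytest.fixture
def chain_ab() -> BayesianNetwork:
    """A -> B with P(a1)=0.5, P(b1|a1)=0.9, P(b1|a2)=0.1."""
    a = DiscreteVariable("A", ("a1", "a2"))
    b = DiscreteVariable("B", ("b1", "b2"))
    return BayesianNetwork(
        [a, b],
        cpts={
            "A": CPT("A", (), np.array([[0.5, 0.5]])),
            "B": CPT("B", ("A",), np.array([[0.9, 0.1], [0.1, 0.9]])),
        },
    )


@pytest.fixture
def single_prior() -> BayesianNetwork:
    """One parentless binary node with prior (0.3, 0.7)."""
    v = DiscreteVariable("X", ("x1", "x2"))
    return BayesianNetwork([v], cpts={"X": CPT("X", (), np.array([[0.3, 0.7]]))})


def make_random_network(rng: np.random.Generator, max_vars: int = 6,
                        max_states: int = 4) -> BayesianNetwork:
    """Random DAG over <= ``max_vars`` variables with <= ``max_states``
    states each and strictly positive random CPT rows."""
    n = int(rng.integers(2, max_vars + 1))
    variables = [
        DiscreteVariable(
            f"v{i}", tuple(f"s{j}" for j in range(rng.integers(2, max_states + 1)))
        )
        for i in range(n)
    ]
    edges = [
        (f"v{i}", f"v{j}")
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < 0.4
    ]
    net = BayesianNetwork(variables, edges=edges)
    cpts = {}
    for v in variables:
        cpt = net.cpt(v.name)
        table = rng.random(cpt.table.shape) + 1e-3
        cpts[v.name] = CPT(v.name, cpt.parents, table / table.sum(axis=1, keepdims=True))
    return net.with_cpts(cpts)


def random_query(rng: np.random.Generator, net: BayesianNetwork):
    """Random (evidence, query) pair for ``net``."""
    names = net.variable_names
    n_ev = int(rng.integers(0, len(names)))
    ev_vars = list(rng.choice(names, size=n_ev, replace=False))
    evidence = {
        v: net.variable(v).states[rng.integers(net.variable(v).n_states)]
        for v in ev_vars
    }
    free = [n for n in names if n not in evidence]
    query = free[int(rng.integers(len(free)))]
    return evidence, query


@pytest.fixture
def toy_dataset() -> PatientDataset:
    """Four records over {A, B}: (a1,b1) x3, (a1,b2) x1."""
    return PatientDataset(
        pd.DataFrame({"A": ["a1"] * 4, "B": ["b1", "b1", "b1", "b2"]})
    )
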