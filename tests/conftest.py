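"""Shared fixtures: toy networks, random model generators, calibrated BN."""

from __future__ import annotations

import numpy as np
import pytest

from cmbnet import (
    DAG,
    ArcConstraintSet,
    BayesianNetwork,
    CPT,
    VariableSchema,
    build_default_schema,
    default_calibrated_bn,
)
from cmbnet.schema import Variable


def make_bn(
    variables: list[tuple[str, tuple[str, ...], int]],
    arcs: set[tuple[str, str]],
    tables: dict[str, np.ndarray],
) -> BayesianNetwork:
    """Assemble a network from (name, levels, tier) specs and CPT arrays."""
    schema = VariableSchema(tuple(Variable(n, lv, t) for n, lv, t in variables))
    dag = DAG(schema.names, arcs)
    cpts = {}
    for name in schema.names:
        parents = dag.parents(name)
        cpts[name] = CPT(
            name,
            schema.levels(name),
            parents,
            tuple(schema.levels(p) for p in parents),
            tables[name],
        )
    return BayesianNetwork(schema, dag, cpts)


@pytest.fixture(scope="session")
def schema():
    return build_default_schema()


@pytest.fixture
def no_constraints():
    return ArcConstraintSet(frozenset(), frozenset())


@pytest.fixture(scope="session")
def toy_ab() -> BayesianNetwork:
    """A -> B, P(A=yes)=0.3, P(B=yes|A=yes)=0.9, P(B=yes|A=no)=0.2."""
    return make_bn(
        [("A", ("no", "yes"), 1), ("B", ("no", "yes"), 2)],
        {("A", "B")},
        {
            "A": np.array([[0.7, 0.3]]),
            "B": np.array([[0.8, 0.2], [0.1, 0.9]]),
        },
    )


@pytest.fixture(scope="session")
def calibrated_bn() -> BayesianNetwork:
    return default_calibrated_bn()


def random_bn(rng: np.random.Generator, n_nodes: int, max_levels: int = 3,
              arc_prob: float = 0.5) -> BayesianNetwork:
    """Random DAG (arcs respect node order) with Dirichlet(1) CPT rows."""
    names = [f"V{i}" for i in range(n_nodes)]
    variables = []
    for i, name in enumerate(names):
        r = int(rng.integers(2, max_levels + 1))
        variables.append((name, tuple(f"l{k}" for k in range(r)), min(i + 1, 6)))
    arcs = {
        (names[i], names[j])
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < arc_prob
    }
    schema = VariableSchema(tuple(Variable(n, lv, t) for n, lv, t in variables))
    dag = DAG(schema.names, arcs)
    tables = {}
    for name in names:
        r = len(schema.levels(name))
        q = int(np.prod([len(schema.levels(p)) for p in dag.parents(name)])) \
            if dag.parents(name) else 1
        tables[name] = rng.dirichlet(np.ones(r), size=q)
    return make_bn(variables, arcs, tables)


def five_node_bn() -> BayesianNetwork:
    """Fixed 5-node network with strong dependencies for recovery tests.

    Structure: A->B, A->D, B->C, C->E, D->E (one collider at E).  Rows are
    moderately peaked (faithful, no near-deterministic relations) with
    additive parent effects for E so it depends on both parents."""
    variables = [
        ("A", ("a0", "a1", "a2"), 1),
        ("B", ("b0", "b1"), 2),
        ("C", ("c0", "c1", "c2"), 3),
        ("D", ("d0", "d1"), 4),
        ("E", ("e0", "e1"), 5),
    ]
    arcs = {("A", "B"), ("A", "D"), ("B", "C"), ("C", "E"), ("D", "E")}
    # E's parents are (C, D) in sorted order: P(e1 | c, d) = .15+.15c+.35d
    e_rows = np.array(
        [[1 - p, p] for c in range(3) for d in range(2)
         for p in [0.1 + 0.2 * c + 0.4 * d]]
    )
    tables = {
        "A": np.array([[0.5, 0.3, 0.2]]),
        "B": np.array([[0.9, 0.1], [0.2, 0.8], [0.6, 0.4]]),
        "C": np.array([[0.7, 0.25, 0.05], [0.05, 0.25, 0.7]]),
        "D": np.array([[0.85, 0.15], [0.2, 0.8], [0.6, 0.4]]),
        "E": e_rows,
    }
    return make_bn(variables, arcs, tables)
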