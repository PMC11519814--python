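"""Probabilistic queries on discrete Bayesian networks.

Approximate conditional queries use likelihood weighting: forward samples
are drawn in topological order with evidence nodes clamped, and each
sample is weighted by the probability of the evidence values given the
sampled parents.  An exact full-enumeration oracle (for small state
spaces) and an exact variable-elimination marginal routine back the
approximate path in tests and calibration."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np

from .parameters import BayesianNetwork
from .schema import InvalidInputError

#: Effective-sample-size threshold below which a query warns.
ESS_WARN = 1_000

#: Default cap on the number of joint configurations exact_query will
#: enumerate.
EXACT_STATE_CAP = 10**6


class ImpossibleEvidenceError(ValueError):
    """Evidence has probability zero under the model."""


Evidence = Mapping[str, str]


def _check_evidence(bn: BayesianNetwork, evidence: Evidence) -> None:
    for var, level in evidence.items():
        if var not in bn.schema:
            raise InvalidInputError(f"unknown evidence variable {var!r}")
        if level not in bn.schema.levels(var):
            raise InvalidInputError(f"{var}: invalid level {level!r}")


@dataclass
class QueryResult:
    """Posterior distribution of one target variable."""

    target: str
    distribution: dict[str, float]
    n_samples: int
    effective_weight: float
    seed: int | None

    def __post_init__(self) -> None:
        total = sum(self.distribution.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise InvalidInputError(f"distribution sums to {total}, not 1")
        if self.effective_weight <= 0:
            raise InvalidInputError("effective weight must be positive")

    def probability(self, level: str) -> float:
        return self.distribution[level]

    def as_array(self) -> np.ndarray:
        return np.array(list(self.distribution.values()))


def joint_log_probability(bn: BayesianNetwork, record: Mapping[str, str]) -> float:
    """ln P(record) = sum over nodes of ln P(x_i | parents); -inf if any
    factor is zero."""
    missing = set(bn.schema.names) - set(record)
    if missing:
        raise InvalidInputError(f"record does not assign {sorted(missing)}")
    _check_evidence(bn, {k: v for k, v in record.items() if k in bn.schema})
    total = 0.0
    for node in bn.schema.names:
        cpt = bn.cpts[node]
        if cpt.parents:
            pcfg = np.ravel_multi_index(
                tuple(cpt.parent_levels[j].index(record[p])
                      for j, p in enumerate(cpt.parents)),
                tuple(len(pl) for pl in cpt.parent_levels),
            )
        else:
            pcfg = 0
        p = cpt.table[pcfg, cpt.levels.index(record[node])]
        if p <= 0:
            return -math.inf
        total += math.log(p)
    return total


def likelihood_weighting(
    bn: BayesianNetwork,
    evidence: Evidence,
    target: str,
    n_samples: int,
    seed: int,
) -> QueryResult:
    """Estimate P(target | evidence) from weighted forward samples."""
    if n_samples < 1:
        raise InvalidInputError("n_samples must be >= 1")
    if target in evidence:
        raise InvalidInputError("target must not be part of the evidence")
    if target not in bn.schema:
        raise InvalidInputError(f"unknown target {target!r}")
    _check_evidence(bn, evidence)
    rng = np.random.default_rng(seed)
    order = bn.dag.topological_order()
    samples: dict[str, np.ndarray] = {}
    log_w = np.zeros(n_samples)
    for node in order:
        cpt = bn.cpts[node]
        if cpt.parents:
            pcols = np.column_stack([samples[p] for p in cpt.parents])
            cfg = cpt.config_index(pcols)
        else:
            cfg = np.zeros(n_samples, dtype=np.int64)
        rows = cpt.table[cfg]
        if node in evidence:
            k = cpt.levels.index(evidence[node])
            with np.errstate(divide="ignore"):
                log_w += np.log(rows[:, k])
            samples[node] = np.full(n_samples, k, dtype=np.int64)
        else:
            u = rng.random(n_samples)
            cum = np.cumsum(rows, axis=1)
            samples[node] = (u[:, None] > cum).sum(axis=1).astype(np.int64)
    w = np.exp(log_w)
    total = w.sum()
    if total <= 0:
        raise ImpossibleEvidenceError(
            f"evidence {dict(evidence)!r} has zero weight in all samples"
        )
    ess = float(total**2 / np.square(w).sum())
    if ess < ESS_WARN:
        warnings.warn(
            f"likelihood weighting ESS {ess:.1f} < {ESS_WARN}; "
            "estimates may be unreliable", stacklevel=2,
        )
    levels = bn.schema.levels(target)
    probs = np.array([w[samples[target] == k].sum() for k in range(len(levels))])
    probs /= total
    probs /= probs.sum()  # renormalize float residue
    return QueryResult(
        target=target,
        distribution={lev: float(p) for lev, p in zip(levels, probs)},
        n_samples=n_samples,
        effective_weight=float(total),
        seed=seed,
    )


def _full_joint(bn: BayesianNetwork) -> np.ndarray:
    """Joint probability array with one axis per schema variable."""
    names = bn.schema.names
    pos = {n: i for i, n in enumerate(names)}
    dims = tuple(len(bn.schema.levels(n)) for n in names)
    joint = np.ones(dims)
    for node in names:
        cpt = bn.cpts[node]
        pdims = tuple(len(pl) for pl in cpt.parent_levels)
        arr = cpt.table.reshape(pdims + (len(cpt.levels),))
        axes = [pos[p] for p in cpt.parents] + [pos[node]]
        # move factor axes into schema order, broadcasting over the rest
        order = np.argsort(axes)
        arr = np.transpose(arr, order)
        shape = [1] * len(names)
        for ax, a in zip(sorted(axes), arr.shape):
            shape[ax] = a
        joint = joint * arr.reshape(shape)
    return joint


def exact_query(
    bn: BayesianNetwork,
    evidence: Evidence,
    target: str,
    max_states: int = EXACT_STATE_CAP,
) -> QueryResult:
    """Exact P(target | evidence) by full-joint enumeration.

    Refuses (with the size in the message) when the state space exceeds
    ``max_states`` configurations."""
    size = bn.state_space_size()
    if size > max_states:
        raise InvalidInputError(
            f"state space has {size:.3g} configurations, above the cap "
            f"{max_states}; use likelihood_weighting instead"
        )
    if target in evidence:
        raise InvalidInputError("target must not be part of the evidence")
    _check_evidence(bn, evidence)
    names = bn.schema.names
    joint = _full_joint(bn)
    idx: list[object] = [slice(None)] * len(names)
    for var, level in evidence.items():
        idx[names.index(var)] = bn.schema.levels(var).index(level)
    cond = joint[tuple(idx)]
    kept = [n for n in names if n not in evidence]
    taxis = kept.index(target)
    marg = cond.sum(axis=tuple(a for a in range(cond.ndim) if a != taxis))
    total = marg.sum()
    if total <= 0:
        raise ImpossibleEvidenceError(f"evidence {dict(evidence)!r} has probability 0")
    probs = marg / total
    return QueryResult(
        target=target,
        distribution={lev: float(p) for lev, p in
                      zip(bn.schema.levels(target), probs)},
        n_samples=0,
        effective_weight=float(total),
        seed=None,
    )


def relative_change(p_baseline: float, p_improved: float) -> float:
    """Percent change 100*(p_improved - p_baseline)/p_baseline."""
    if p_baseline <= 0:
        raise InvalidInputError("baseline probability must be positive")
    return 100.0 * (p_improved - p_baseline) / p_baseline


# ---------------------------------------------------------------------------
# Exact marginals by variable elimination (any network size)
# ---------------------------------------------------------------------------


@dataclass
class _Factor:
    vars: tuple[str, ...]
    table: np.ndarray  # one axis per var, in vars order


def _factor_product(a: _Factor, b: _Factor, pos: dict[str, int]) -> _Factor:
    union = tuple(sorted(set(a.vars) | set(b.vars), key=pos.get))

    def expand(f: _Factor) -> np.ndarray:
        order = tuple(sorted(range(len(f.vars)), key=lambda i: pos[f.vars[i]]))
        arr = np.transpose(f.table, order)
        svars = tuple(f.vars[i] for i in order)
        shape = []
        it = 0
        for v in union:
            if it < len(svars) and svars[it] == v:
                shape.append(arr.shape[it])
                it += 1
            else:
                shape.append(1)
        return arr.reshape(shape)

    return _Factor(union, expand(a) * expand(b))


def exact_marginal(bn: BayesianNetwork, node: str) -> np.ndarray:
    """Exact marginal of one node via variable elimination over its
    ancestral set (min-degree elimination order)."""
    if node not in bn.schema:
        raise InvalidInputError(f"unknown node {node!r}")
    g = bn.dag.to_networkx()
    relevant = nx.ancestors(g, node) | {node}
    pos = {n: i for i, n in enumerate(bn.schema.names)}
    factors = []
    for v in relevant:
        cpt = bn.cpts[v]
        dims = tuple(len(pl) for pl in cpt.parent_levels) + (len(cpt.levels),)
        factors.append(_Factor(cpt.parents + (v,), cpt.table.reshape(dims)))
    to_eliminate = set(relevant) - {node}
    while to_eliminate:
        # min-degree: eliminate the variable appearing with the fewest
        # distinct neighbors across current factors
        def degree(v: str) -> int:
            nbrs = set()
            for f in factors:
                if v in f.vars:
                    nbrs.update(f.vars)
            return len(nbrs)

        v = min(sorted(to_eliminate), key=degree)
        involved = [f for f in factors if v in f.vars]
        rest = [f for f in factors if v not in f.vars]
        prod = involved[0]
        for f in involved[1:]:
            prod = _factor_product(prod, f, pos)
        axis = prod.vars.index(v)
        summed = _Factor(
            tuple(x for x in prod.vars if x != v), prod.table.sum(axis=axis)
        )
        factors = rest + [summed]
        to_eliminate.discard(v)
    result = factors[0]
    for f in factors[1:]:
        result = _factor_product(result, f, pos)
    marg = result.table.reshape(-1)
    return marg / marg.sum()


def exact_marginals(bn: BayesianNetwork) -> dict[str, np.ndarray]:
    """Exact marginal distribution of every node."""
    return {n: exact_marginal(bn, n) for n in bn.schema.names}
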