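"""Score-based structure learning: BIC family scores and hill-climbing.

The search explores DAG space through single-arc additions, deletions and
reversals, constrained by the tier blacklist/whitelist, and accepts the
best strictly-improving move until a local optimum is reached.  The score
is the decomposable BIC (log-likelihood of each node given its parents
minus 0.5*ln(N) times the number of free parameters); a BDeu alternative
is available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .graphs import DAG, Arc, ArcConstraintSet
from .parameters import encode_codes
from .schema import InvalidInputError, VariableSchema

logger = logging.getLogger(__name__)

#: Minimum score gain for a move to count as strictly improving; guards
#: against floating-point noise cycling the search.
IMPROVEMENT_EPS = 1e-9

ScoreName = Literal["bic", "bdeu"]


def _family_counts(
    codes: np.ndarray, node_idx: int, parent_idx: tuple[int, ...], levels: np.ndarray
) -> np.ndarray:
    """(q, r) contingency counts of node levels by parent configuration."""
    r = int(levels[node_idx])
    dims = tuple(int(levels[j]) for j in parent_idx) + (r,)
    q = int(np.prod(dims[:-1], dtype=np.int64)) if parent_idx else 1
    if parent_idx:
        idx = np.ravel_multi_index(
            tuple(codes[:, j] for j in parent_idx) + (codes[:, node_idx],), dims
        )
    else:
        idx = codes[:, node_idx].astype(np.int64)
    counts = np.bincount(idx, minlength=q * r).reshape(q, r)
    return counts


def _bic_from_counts(counts: np.ndarray, n: int) -> float:
    row = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(counts > 0, counts * np.log(counts / np.where(row > 0, row, 1)), 0.0)
    q, r = counts.shape
    return float(ll.sum() - 0.5 * math.log(n) * q * (r - 1))


def _bdeu_from_counts(counts: np.ndarray, iss: float) -> float:
    q, r = counts.shape
    a_row = iss / q
    a_cell = iss / (q * r)
    row = counts.sum(axis=1)
    score = (
        gammaln(a_row) * q
        - gammaln(a_row + row).sum()
        + gammaln(a_cell + counts).sum()
        - gammaln(a_cell) * q * r
    )
    return float(score)


class ScoreCache:
    """Memoized family scores for one dataset.

    Keys are (node, sorted parent tuple); values equal recomputation by
    construction because the underlying code matrix is immutable.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        schema: VariableSchema,
        score: ScoreName = "bic",
        bdeu_iss: float = 1.0,
    ) -> None:
        if len(data) == 0:
            raise InvalidInputError("empty dataset")
        self.schema = schema
        self.codes = encode_codes(data, schema)
        self.codes.setflags(write=False)
        self.levels = np.array([len(schema.levels(n)) for n in schema.names])
        self.n = len(data)
        self.score = score
        self.bdeu_iss = bdeu_iss
        self.col = {name: i for i, name in enumerate(schema.names)}
        self._cache: dict[tuple[str, tuple[str, ...]], float] = {}
        self.fingerprint = hash(self.codes.tobytes())

    @classmethod
    def from_codes(
        cls, codes: np.ndarray, schema: VariableSchema,
        score: ScoreName = "bic", bdeu_iss: float = 1.0,
    ) -> "ScoreCache":
        obj = cls.__new__(cls)
        obj.schema = schema
        obj.codes = codes
        obj.levels = np.array([len(schema.levels(n)) for n in schema.names])
        obj.n = len(codes)
        obj.score = score
        obj.bdeu_iss = bdeu_iss
        obj.col = {name: i for i, name in enumerate(schema.names)}
        obj._cache = {}
        obj.fingerprint = hash(codes.tobytes())
        return obj

    def family(self, node: str, parents: tuple[str, ...]) -> float:
        key = (node, tuple(sorted(parents)))
        if key not in self._cache:
            counts = _family_counts(
                self.codes,
                self.col[node],
                tuple(self.col[p] for p in key[1]),
                self.levels,
            )
            if self.score == "bic":
                val = _bic_from_counts(counts, self.n)
            else:
                val = _bdeu_from_counts(counts, self.bdeu_iss)
            self._cache[key] = val
        return self._cache[key]


def family_score(
    node: str,
    parents: tuple[str, ...] | set[str] | list[str],
    data: pd.DataFrame,
    schema: VariableSchema,
    score: ScoreName = "bic",
) -> float:
    """BIC family score of ``node`` given ``parents`` on complete data.

    BIC = sum over parent configs j and levels k of N_jk * ln(N_jk / N_j)
    minus 0.5 * ln(N) * q * (r - 1), with 0*ln(0/.) taken as 0.
    """
    cache = ScoreCache(data, schema, score=score)
    return cache.family(node, tuple(parents))


def total_score(
    dag: DAG, data: pd.DataFrame, schema: VariableSchema, score: ScoreName = "bic"
) -> float:
    """Decomposable network score: the sum of family scores over nodes."""
    if set(dag.nodes) != set(schema.names):
        raise InvalidInputError("DAG nodes must match dataset variables")
    cache = ScoreCache(data, schema, score=score)
    return sum(cache.family(n, dag.parents(n)) for n in dag.nodes)


@dataclass(frozen=True)
class Move:
    op: str  # "add" | "delete" | "reverse"
    arc: Arc
    delta: float


@dataclass
class SearchTrace:
    """Sequence of accepted moves; replaying them from the start graph
    reproduces the final DAG."""

    start_arcs: frozenset[Arc]
    moves: list[Move] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"operation": m.op, "source": m.arc[0], "target": m.arc[1],
              "score_delta": m.delta} for m in self.moves]
        )

    def replay(self, nodes: tuple[str, ...]) -> DAG:
        dag = DAG(nodes, set(self.start_arcs))
        for m in self.moves:
            u, v = m.arc
            if m.op == "add":
                dag.add_arc(u, v)
            elif m.op == "delete":
                dag.remove_arc(u, v)
            else:
                dag.remove_arc(u, v)
                dag.add_arc(v, u)
        return dag


_OP_ORDER = {"add": 0, "delete": 1, "reverse": 2}


def hill_climb(
    data: pd.DataFrame | None,
    constraints: ArcConstraintSet,
    schema: VariableSchema,
    score: ScoreName = "bic",
    cache: ScoreCache | None = None,
    max_iter: int = 10_000,
) -> tuple[DAG, SearchTrace]:
    """Greedy constrained search from the whitelist-only graph.

    Each step scans every legal single-arc addition, deletion and reversal
    (legal: result acyclic, no blacklisted arc introduced, no whitelisted
    arc removed or reversed) and applies the strictly best-improving move;
    ties break lexicographically by (operation: add < delete < reverse,
    source, target), making the search deterministic for a given dataset.
    """
    if cache is None:
        if data is None:
            raise InvalidInputError("either data or a ScoreCache is required")
        cache = ScoreCache(data, schema, score=score)
    nodes = schema.names
    for u, v in constraints.whitelist | constraints.blacklist:
        if u not in nodes or v not in nodes:
            raise InvalidInputError(f"constraint arc {u}->{v} outside schema")
    dag = DAG(nodes, set(constraints.whitelist))
    trace = SearchTrace(frozenset(constraints.whitelist))
    scan_order = tuple(sorted(nodes))  # tie-break: lexicographic source, target
    parents: dict[str, tuple[str, ...]] = {n: dag.parents(n) for n in nodes}
    fam: dict[str, float] = {n: cache.family(n, parents[n]) for n in nodes}

    for _ in range(max_iter):
        best: Move | None = None
        # additions
        for u in scan_order:
            for v in scan_order:
                if u == v or dag.has_arc(u, v) or dag.has_arc(v, u):
                    continue
                if (u, v) in constraints.blacklist:
                    continue
                if dag.would_create_cycle(u, v):
                    continue
                delta = cache.family(v, parents[v] + (u,)) - fam[v]
                if delta > IMPROVEMENT_EPS and (best is None or delta > best.delta):
                    best = Move("add", (u, v), delta)
        # deletions
        for u, v in sorted(dag.arcs):
            if (u, v) in constraints.whitelist:
                continue
            reduced = tuple(p for p in parents[v] if p != u)
            delta = cache.family(v, reduced) - fam[v]
            if delta > IMPROVEMENT_EPS and (best is None or delta > best.delta):
                best = Move("delete", (u, v), delta)
        # reversals
        for u, v in sorted(dag.arcs):
            if (u, v) in constraints.whitelist:
                continue
            if (v, u) in constraints.blacklist:
                continue
            if dag.reversal_creates_cycle(u, v):
                continue
            delta = (
                cache.family(v, tuple(p for p in parents[v] if p != u))
                - fam[v]
                + cache.family(u, parents[u] + (v,))
                - fam[u]
            )
            if delta > IMPROVEMENT_EPS and (best is None or delta > best.delta):
                best = Move("reverse", (u, v), delta)
        if best is None:
            break
        u, v = best.arc
        if best.op == "add":
            dag.add_arc(u, v)
            parents[v] = dag.parents(v)
            fam[v] = cache.family(v, parents[v])
        elif best.op == "delete":
            dag.remove_arc(u, v)
            parents[v] = dag.parents(v)
            fam[v] = cache.family(v, parents[v])
        else:
            dag.remove_arc(u, v)
            dag.add_arc(v, u)
            parents[v] = dag.parents(v)
            parents[u] = dag.parents(u)
            fam[v] = cache.family(v, parents[v])
            fam[u] = cache.family(u, parents[u])
        trace.moves.append(best)
    else:
        raise RuntimeError("hill climbing failed to converge within max_iter")
    logger.debug("hill_climb: %d moves, %d arcs", len(trace.moves), len(dag.arcs))
    return dag, trace
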