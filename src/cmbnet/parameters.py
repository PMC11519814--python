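"""Conditional probability tables (CPTs) and parameter fitting.

A discrete Bayesian network factorizes the joint distribution of the
model variables as the product over nodes of P(X_i | parents(X_i)).  This
module holds the CPT container, maximum-likelihood and Dirichlet
(posterior-mean) estimation from complete data, and a plain-text CSV
serialization.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .graphs import DAG
from .schema import InvalidInputError, VariableSchema

logger = logging.getLogger(__name__)

ROW_SUM_TOL = 1e-9


def encode_codes(data: pd.DataFrame, schema: VariableSchema) -> np.ndarray:
    """Integer-code a complete dataset column-wise against the schema."""
    cols = []
    for name in schema.names:
        cat = pd.Categorical(data[name], categories=schema.levels(name))
        codes = cat.codes
        if (codes < 0).any():
            bad = sorted(set(data[name][codes < 0].dropna().unique()))
            raise InvalidInputError(f"{name}: values outside schema levels {bad!r}")
        cols.append(codes.astype(np.int64))
    return np.column_stack(cols)


@dataclass
class CPT:
    """One node's conditional probability table.

    ``table`` has one row per parent configuration (mixed-radix order with
    the last parent varying fastest, as in :func:`numpy.ravel_multi_index`)
    and one column per node level.
    """

    node: str
    levels: tuple[str, ...]
    parents: tuple[str, ...]
    parent_levels: tuple[tuple[str, ...], ...]
    table: np.ndarray
    unobserved_rows: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        q = int(np.prod([len(pl) for pl in self.parent_levels], dtype=np.int64)) if self.parents else 1
        if self.table.shape != (q, len(self.levels)):
            raise InvalidInputError(
                f"{self.node}: CPT shape {self.table.shape} != ({q}, {len(self.levels)})"
            )
        if (self.table < -ROW_SUM_TOL).any() or (self.table > 1 + ROW_SUM_TOL).any():
            raise InvalidInputError(f"{self.node}: probabilities outside [0, 1]")
        if not np.allclose(self.table.sum(axis=1), 1.0, atol=ROW_SUM_TOL):
            raise InvalidInputError(f"{self.node}: CPT rows must sum to 1")

    @property
    def n_configs(self) -> int:
        return self.table.shape[0]

    def config_index(self, parent_codes: np.ndarray) -> np.ndarray:
        """Row index for each sample given parent code columns (n, k)."""
        if not self.parents:
            return np.zeros(len(parent_codes), dtype=np.int64)
        dims = tuple(len(pl) for pl in self.parent_levels)
        return np.ravel_multi_index(tuple(parent_codes.T), dims)

    def normalized(self) -> "CPT":
        t = self.table / self.table.sum(axis=1, keepdims=True)
        return CPT(self.node, self.levels, self.parents, self.parent_levels, t,
                   self.unobserved_rows)


BNParameters = dict[str, CPT]


@dataclass
class BayesianNetwork:
    """A DAG plus one CPT per node over a variable schema."""

    schema: VariableSchema
    dag: DAG
    cpts: BNParameters = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.dag.nodes) != set(self.schema.names):
            raise InvalidInputError("DAG nodes must match schema variables")
        for node, cpt in self.cpts.items():
            if cpt.parents != self.dag.parents(node):
                raise InvalidInputError(
                    f"{node}: CPT parents {cpt.parents} != DAG parents {self.dag.parents(node)}"
                )
            if cpt.levels != self.schema.levels(node):
                raise InvalidInputError(f"{node}: CPT levels do not match schema")

    def state_space_size(self) -> int:
        return int(np.prod([len(self.schema.levels(n)) for n in self.schema.names],
                           dtype=np.float64))


def fit_cpts(
    dag: DAG,
    data: pd.DataFrame,
    schema: VariableSchema,
    method: str = "mle",
    iss: float = 1.0,
) -> BNParameters:
    """Fit one CPT per node from complete data.

    ``mle`` uses row-wise relative frequencies; parent configurations with
    zero observations get a uniform row and are flagged in
    ``unobserved_rows``.  ``bayes`` returns the Dirichlet posterior mean
    with total imaginary sample size ``iss`` split uniformly over the
    table's cells, i.e. (N_k + iss/(q*r)) / (N_row + iss/q).
    """
    if len(data) == 0:
        raise InvalidInputError("empty dataset")
    if method not in ("mle", "bayes"):
        raise InvalidInputError(f"unknown method {method!r}")
    if method == "bayes" and iss <= 0:
        raise InvalidInputError("iss must be positive")
    codes = encode_codes(data, schema)
    col = {name: i for i, name in enumerate(schema.names)}
    params: BNParameters = {}
    for node in schema.names:
        parents = dag.parents(node)
        levels = schema.levels(node)
        parent_levels = tuple(schema.levels(p) for p in parents)
        r = len(levels)
        q = int(np.prod([len(pl) for pl in parent_levels], dtype=np.int64)) if parents else 1
        dims = tuple(len(pl) for pl in parent_levels) + (r,)
        idx = np.ravel_multi_index(
            tuple(codes[:, col[p]] for p in parents) + (codes[:, col[node]],), dims
        )
        counts = np.bincount(idx, minlength=q * r).reshape(q, r).astype(float)
        row_sums = counts.sum(axis=1, keepdims=True)
        if method == "mle":
            unobserved = row_sums[:, 0] == 0
            if unobserved.any():
                logger.warning(
                    "%s: %d of %d parent configurations unobserved; "
                    "using uniform rows", node, int(unobserved.sum()), q,
                )
            table = np.where(row_sums > 0, counts / np.where(row_sums > 0, row_sums, 1),
                             1.0 / r)
            params[node] = CPT(node, levels, parents, parent_levels, table,
                               unobserved_rows=unobserved)
        else:
            alpha = iss / (q * r)
            table = (counts + alpha) / (row_sums + iss / q)
            params[node] = CPT(node, levels, parents, parent_levels, table)
    return params


# ---------------------------------------------------------------------------
# Serialization: one CSV per node + a JSON index
# ---------------------------------------------------------------------------


def _safe_name(node: str) -> str:
    return re.sub(r"[^A-Za-z0-9]+", "_", node).strip("_").lower()


def write_cpts(params: BNParameters, directory) -> None:
    """Write one CSV per node (parent-level columns, one probability column
    per node level) plus ``index.json`` mapping node names to files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index = {}
    for node, cpt in params.items():
        fname = f"cpt_{_safe_name(node)}.csv"
        index[node] = {"file": fname, "parents": list(cpt.parents),
                       "levels": list(cpt.levels)}
        dims = tuple(len(pl) for pl in cpt.parent_levels)
        rows = []
        for cfg in range(cpt.n_configs):
            pcfg = np.unravel_index(cfg, dims) if cpt.parents else ()
            row = {p: cpt.parent_levels[j][pcfg[j]] for j, p in enumerate(cpt.parents)}
            for k, lev in enumerate(cpt.levels):
                row[f"P({lev})"] = format(cpt.table[cfg, k], ".17g")
            rows.append(row)
        pd.DataFrame(rows).to_csv(directory / fname, index=False)
    with open(directory / "index.json", "w") as fh:
        json.dump(index, fh, indent=1, sort_keys=True)


def read_cpts(directory, schema: VariableSchema) -> BNParameters:
    directory = Path(directory)
    with open(directory / "index.json") as fh:
        index = json.load(fh)
    params: BNParameters = {}
    for node, meta in index.items():
        parents = tuple(meta["parents"])
        levels = tuple(meta["levels"])
        parent_levels = tuple(schema.levels(p) for p in parents)
        df = pd.read_csv(directory / meta["file"], dtype=str, keep_default_na=False)
        dims = tuple(len(pl) for pl in parent_levels)
        q = int(np.prod(dims, dtype=np.int64)) if parents else 1
        table = np.zeros((q, len(levels)))
        for _, row in df.iterrows():
            if parents:
                cfg = np.ravel_multi_index(
                    tuple(parent_levels[j].index(row[p]) for j, p in enumerate(parents)),
                    dims,
                )
            else:
                cfg = 0
            for k, lev in enumerate(levels):
                table[cfg, k] = float(row[f"P({lev})"])
        params[node] = CPT(node, levels, parents, parent_levels, table)
    return params
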