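"""Synthetic categorical data from a known ground-truth Bayesian network.

The default generator emulates the composite NHANES-like study population
(n = 29,078 complete adult records): an 18-node, tier-respecting network
whose arcs contain the four published mediating pathways from ethno-racial
group to adiposity-based chronic disease, and whose conditional
probability tables are calibrated so that every variable's marginal
matches the published summary table.  Only the marginals are published, so
dependence strengths are free parameters; they are set strong enough
(rows differing by total variation >= 0.15 per arc) for structure-recovery
experiments to have signal.  The calibrated network is therefore a test
bed, not a reproduction of the study's estimated networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graphs import DAG, DEFAULT_DRIVER_HIERARCHY, build_tier_constraints, validate
from .inference import exact_marginals
from .parameters import CPT, BayesianNetwork, BNParameters
from .schema import InvalidInputError, VariableSchema, build_default_schema

logger = logging.getLogger(__name__)

#: A ground-truth network is an ordinary Bayesian network whose CPTs are
#: known by construction rather than fitted.
GroundTruthBN = BayesianNetwork

#: Stream tags for deriving per-operation RNG children from one root seed
#: via ``numpy.random.SeedSequence([seed, tag])``.
_STREAM_FORWARD = 1
_STREAM_MISSING = 2

#: Published marginal percentages (summary table of the composite sample).
TABLE1_MARGINALS: dict[str, dict[str, float]] = {
    "Age": {"20–39": 31.3, "40–59": 33.1, "60+": 35.6},
    "Gender": {"Male": 50.5, "Female": 49.5},
    "Ethno-racial group": {
        "Non-Hispanic White": 48.8,
        "Non-Hispanic Black": 19.6,
        "Hispanic": 23.6,
        "Other or Multiracial": 8.0,
    },
    "Education": {
        "Less than high school": 24.7,
        "High school grad/GED": 23.5,
        "Some college or AA degree": 29.4,
        "College grad or above": 22.4,
    },
    "Income": {
        "<100% FPL": 18.7,
        "100–199% FPL": 26.7,
        "200–399% FPL": 27.3,
        ">400% FPL": 27.4,
    },
    "Employment status": {
        "Employed, homemaker, or student": 65.3,
        "Retired": 22.0,
        "Unemployed or unable to work": 12.8,
    },
    "Household food security": {
        "Full": 73.2, "Marginal": 9.7, "Low": 10.7, "Very low": 6.4,
    },
    "Health insurance status": {
        "No health insurance": 19.7,
        "Private": 56.1,
        "Public - Medicare": 13.4,
        "Public - other": 10.8,
    },
    "Routine healthcare site": {
        "No routine healthcare site": 14.7,
        "Routine site - ED": 2.7,
        "Routine site - not ED": 82.5,
    },
    "Diet": {"Not DASH-accordant": 87.4, "DASH-accordant": 12.6},
    "Physical activity": {"None": 23.7, "Not sufficient": 17.0, "Sufficient": 59.2},
    "Alcohol use": {"None": 32.7, "Light": 28.5, "Moderate": 26.6, "Heavy": 12.3},
    "Smoking status": {"Never": 52.7, "Former": 24.4, "Current": 22.9},
    "ABCD": {"Stage 0": 2.7, "Stage 1": 25.7, "Stage 2": 5.3, "Stage 3": 3.5,
             "Stage 4": 62.8},
    "DBCD": {"Stage 0": 2.1, "Stage 1": 60.2, "Stage 2": 2.0, "Stage 3": 0.7,
             "Stage 4": 35.0},
    "HBCD": {"Stage 0": 1.1, "Stage 1": 31.9, "Stage 2": 9.3, "Stage 3": 42.0,
             "Stage 4": 15.6},
    "LBCD": {"Stage 0": 1.2, "Stage 1": 55.6, "Stage 2": 26.9, "Stage 3": 12.6,
             "Stage 4": 3.6},
    "CMBCD": {"Stage 0": 0.8, "Stage 1": 88.4, "Stage 2–4": 10.8},
}

#: Ground-truth arcs: the four published mediating pathways, the mandated
#: driver hierarchy and driver->CMBCD arcs, plus tier-respecting SDOH and
#: demographic dependencies.
DEFAULT_TRUE_ARCS: frozenset[tuple[str, str]] = frozenset(
    {
        ("Ethno-racial group", "Education"),
        ("Ethno-racial group", "Diet"),
        ("Education", "Income"),
        ("Education", "Physical activity"),
        ("Education", "Smoking status"),
        ("Education", "Employment status"),
        ("Age", "Employment status"),
        ("Income", "Household food security"),
        ("Income", "Health insurance status"),
        ("Age", "Health insurance status"),
        ("Health insurance status", "Routine healthcare site"),
        ("Income", "Alcohol use"),
        ("Alcohol use", "Smoking status"),
        ("Smoking status", "Diet"),
        ("Diet", "ABCD"),
        ("Physical activity", "ABCD"),
        ("Age", "ABCD"),
        ("Age", "HBCD"),
    }
    | DEFAULT_DRIVER_HIERARCHY
    | {(d, "CMBCD") for d in ("ABCD", "DBCD", "HBCD", "LBCD")}
)

#: Per-(child, parent) tilt weights.  Signs encode plausible effect
#: directions (e.g. a DASH-accordant diet lowers adiposity stage); the
#: magnitudes set dependence strength and are free parameters.
_EFFECT_WEIGHTS: dict[str, dict[str, float]] = {
    "Education": {"Ethno-racial group": 1.0},
    "Income": {"Education": 1.2},
    "Employment status": {"Age": 1.5, "Education": 0.5},
    "Household food security": {"Income": -1.5},
    "Health insurance status": {"Age": 1.0, "Income": 0.8},
    "Routine healthcare site": {"Health insurance status": 1.2},
    "Diet": {"Ethno-racial group": 1.0, "Smoking status": -1.0},
    "Physical activity": {"Education": 1.3},
    "Alcohol use": {"Income": 1.0},
    "Smoking status": {"Alcohol use": 0.8, "Education": -1.0},
    "ABCD": {"Age": 0.7, "Diet": -0.9, "Physical activity": -0.8},
    "DBCD": {"ABCD": 1.2},
    "HBCD": {"ABCD": 0.6, "Age": 0.8, "DBCD": 0.6},
    "LBCD": {"ABCD": 0.8, "DBCD": 0.6},
    "CMBCD": {"ABCD": 0.7, "DBCD": 0.7, "HBCD": 0.7, "LBCD": 0.7},
}

#: Non-linear parent level scores where a plain linear ramp is unrealistic.
_PARENT_SCORES: dict[str, np.ndarray] = {
    "Ethno-racial group": np.array([0.8, -0.6, -0.8, 0.2]),
}

CALIBRATION_TOL = 1e-7
CALIBRATION_MAX_SWEEPS = 500


class CalibrationError(RuntimeError):
    pass


def _target_marginal(schema: VariableSchema, node: str) -> np.ndarray:
    pct = TABLE1_MARGINALS[node]
    m = np.array([pct[lev] for lev in schema.levels(node)])
    return m / m.sum()


def _parent_scores(parent: str, n_levels: int) -> np.ndarray:
    if parent in _PARENT_SCORES:
        return _PARENT_SCORES[parent]
    return np.linspace(-1.0, 1.0, n_levels)


def _tilted_cpt(schema: VariableSchema, node: str, parents: tuple[str, ...]) -> CPT:
    """Initial CPT: the target marginal exponentially tilted by a linear
    combination of parent level scores."""
    levels = schema.levels(node)
    m = _target_marginal(schema, node)
    z = np.linspace(-1.0, 1.0, len(levels))
    parent_levels = tuple(schema.levels(p) for p in parents)
    dims = tuple(len(pl) for pl in parent_levels)
    q = int(np.prod(dims)) if parents else 1
    weights = _EFFECT_WEIGHTS.get(node, {})
    table = np.empty((q, len(levels)))
    for cfg in range(q):
        pcfg = np.unravel_index(cfg, dims) if parents else ()
        e = sum(
            weights.get(p, 0.0) * _parent_scores(p, len(parent_levels[j]))[pcfg[j]]
            for j, p in enumerate(parents)
        )
        row = m * np.exp(e * z)
        table[cfg] = row / row.sum()
    return CPT(node, levels, parents, parent_levels, table)


def build_ground_truth_structure(schema: VariableSchema | None = None) -> DAG:
    schema = schema or build_default_schema()
    return DAG(schema.names, set(DEFAULT_TRUE_ARCS))


def _calibrate(bn: BayesianNetwork, tol: float = CALIBRATION_TOL,
               max_sweeps: int = CALIBRATION_MAX_SWEEPS) -> BayesianNetwork:
    """Iterative proportional adjustment of CPT columns until every node's
    exact marginal matches its target within ``tol``."""
    schema = bn.schema
    targets = {n: _target_marginal(schema, n) for n in schema.names}
    for sweep in range(max_sweeps):
        marg = exact_marginals(bn)
        dev = {n: float(np.abs(marg[n] - targets[n]).max()) for n in schema.names}
        if max(dev.values()) < tol:
            logger.info("calibration converged after %d sweeps", sweep)
            return bn
        new_cpts: BNParameters = {}
        for node in schema.names:
            cpt = bn.cpts[node]
            ratio = targets[node] / np.clip(marg[node], 1e-12, None)
            table = cpt.table * ratio[None, :]
            table /= table.sum(axis=1, keepdims=True)
            new_cpts[node] = CPT(node, cpt.levels, cpt.parents, cpt.parent_levels,
                                 table)
        bn = BayesianNetwork(schema, bn.dag, new_cpts)
    marg = exact_marginals(bn)
    offenders = {
        n: round(float(np.abs(marg[n] - targets[n]).max()), 6)
        for n in schema.names
        if np.abs(marg[n] - targets[n]).max() >= tol
    }
    raise CalibrationError(
        f"marginal calibration did not converge within {max_sweeps} sweeps; "
        f"max deviations: {offenders}"
    )


_DEFAULT_BN: BayesianNetwork | None = None


def default_calibrated_bn() -> GroundTruthBN:
    """The 18-node ground-truth network calibrated to the published
    marginals (cached; deterministic)."""
    global _DEFAULT_BN
    if _DEFAULT_BN is None:
        schema = build_default_schema()
        dag = build_ground_truth_structure(schema)
        constraints = build_tier_constraints(schema)
        violations = validate(dag, constraints)
        assert not violations, violations
        cpts = {n: _tilted_cpt(schema, n, dag.parents(n)) for n in schema.names}
        _DEFAULT_BN = _calibrate(BayesianNetwork(schema, dag, cpts))
    return _DEFAULT_BN


def forward_sample(bn: BayesianNetwork, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` complete records by ancestral (topological) sampling."""
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, _STREAM_FORWARD]))
    order = bn.dag.topological_order()
    codes: dict[str, np.ndarray] = {}
    for node in order:
        cpt = bn.cpts[node]
        if cpt.parents:
            pcols = np.column_stack([codes[p] for p in cpt.parents])
            rows = cpt.table[cpt.config_index(pcols)]
        else:
            rows = np.broadcast_to(cpt.table[0], (n, len(cpt.levels)))
        u = rng.random(n)
        cum = np.cumsum(rows, axis=1)
        codes[node] = (u[:, None] > cum).sum(axis=1).astype(np.int64)
    out = {}
    for name in bn.schema.names:
        levels = bn.schema.levels(name)
        out[name] = pd.Categorical.from_codes(codes[name], categories=list(levels))
    return pd.DataFrame(out).astype(str)


def inject_missingness(data: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Blank each cell independently with probability ``rate``."""
    if not 0 <= rate < 1:
        raise InvalidInputError("rate must lie in [0, 1)")
    out = data.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(np.random.SeedSequence([seed, _STREAM_MISSING]))
    mask = rng.random(out.shape) < rate
    values = out.to_numpy(dtype=object)
    values[mask] = np.nan
    return pd.DataFrame(values, columns=out.columns, index=out.index)
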