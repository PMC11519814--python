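"""End-to-end orchestration: learn, average, fit, and query networks.

``run_overall`` reproduces the full analysis plan on one dataset:
exclusions, bootstrap structure learning under the tier constraints,
L1-threshold consensus averaging, and parameter fitting.
``run_stratified`` repeats it per level of a stratification variable
(dropping the then-constant variable), and the query helpers estimate
stage probabilities and behavioral relative changes per demographic cell.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .averaging import ArcStrengthTable, bootstrap_strengths, consensus_network, \
    significance_threshold
from .graphs import Arc, DAG, DEFAULT_DRIVER_HIERARCHY, build_tier_constraints, validate
from .inference import likelihood_weighting, relative_change
from .parameters import BayesianNetwork, fit_cpts
from .schema import (
    DRIVERS,
    InvalidInputError,
    StagingRuleSet,
    VariableSchema,
    apply_exclusions,
    build_default_schema,
    read_dataset,
    validate_dataset,
    write_dataset,
)
from .structure import ScoreName

logger = logging.getLogger(__name__)

OUTCOME_VARIABLES = (*DRIVERS, "CMBCD")

#: Default "worst -> best" behavioral comparisons.
DEFAULT_BEHAVIOR_COMPARISONS: dict[str, tuple[str, str]] = {
    "Diet": ("Not DASH-accordant", "DASH-accordant"),
    "Physical activity": ("None", "Sufficient"),
    "Smoking status": ("Current", "Never"),
    "Alcohol use": ("Heavy", "None"),
}


@dataclass
class AnalysisConfig:
    """Configuration for a full pipeline run."""

    data_path: str | None = None
    output_dir: str | None = None
    B: int = 200
    seed: int = 0
    score: ScoreName = "bic"
    param_method: str = "bayes"
    iss: float = 1.0
    n_query_samples: int = 100_000
    stratify_variable: str = "Ethno-racial group"
    driver_hierarchy: tuple[Arc, ...] = tuple(sorted(DEFAULT_DRIVER_HIERARCHY))
    staging_rules_path: str | None = None
    min_stratum_records: int = 100

    def __post_init__(self) -> None:
        if self.B < 1:
            raise InvalidInputError("B must be >= 1")
        for path in (self.data_path, self.staging_rules_path):
            if path is not None and not Path(path).exists():
                raise InvalidInputError(f"referenced file does not exist: {path}")

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def staging_rules(self) -> StagingRuleSet:
        if self.staging_rules_path is None:
            return StagingRuleSet()
        return StagingRuleSet.from_yaml(self.staging_rules_path)


@dataclass
class PipelineResult:
    """Artifacts of one learning run (overall or one stratum)."""

    dag: DAG
    bn: BayesianNetwork
    strengths: ArcStrengthTable
    threshold: float
    manifest: dict
    exclusion_tally: dict[str, int]


def _write_artifacts(result: PipelineResult, outdir: Path, label: str) -> None:
    from .parameters import write_cpts

    outdir.mkdir(parents=True, exist_ok=True)
    result.dag.arcs_to_csv(outdir / f"{label}_arcs.csv")
    (outdir / f"{label}_network.dot").write_text(result.dag.to_dot())
    result.strengths.to_csv(outdir / f"{label}_strengths.csv")
    write_cpts(result.bn.cpts, outdir / f"{label}_cpts")
    with open(outdir / f"{label}_manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=1, sort_keys=True)


def run_overall(
    config: AnalysisConfig,
    data: pd.DataFrame | None = None,
    schema: VariableSchema | None = None,
    label: str = "overall",
) -> PipelineResult:
    """Exclusions -> bootstrap strengths -> threshold -> consensus -> CPTs."""
    schema = schema or build_default_schema()
    t0 = time.perf_counter()
    if data is None:
        if config.data_path is None:
            raise InvalidInputError("no data provided")
        data = read_dataset(config.data_path)
    clean, tally = apply_exclusions(data, schema)
    validate_dataset(clean, schema)
    if len(clean) == 0:
        raise InvalidInputError("no records remain after exclusions")
    constraints = build_tier_constraints(
        schema, [a for a in config.driver_hierarchy
                 if a[0] in schema.names and a[1] in schema.names]
    )
    strengths = bootstrap_strengths(
        clean, constraints, B=config.B, seed=config.seed, schema=schema,
        score=config.score,
    )
    threshold = significance_threshold(strengths.adjacency_strengths())
    strengths.threshold = threshold
    dag = consensus_network(strengths, constraints)
    assert not validate(dag, constraints)
    cpts = fit_cpts(dag, clean, schema, method=config.param_method, iss=config.iss)
    bn = BayesianNetwork(schema, dag, cpts)
    manifest = {
        "label": label,
        "package_version": _pkg_version(),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "B": config.B,
        "score": config.score,
        "param_method": config.param_method,
        "n_input_records": int(len(data)),
        "n_analyzed_records": int(len(clean)),
        "exclusion_tally": tally,
        "threshold": threshold,
        "n_consensus_arcs": len(dag.arcs),
        "elapsed_s": round(time.perf_counter() - t0, 3),
    }
    logger.info(
        "%s: %d records, threshold %.3f, %d arcs in %.1fs",
        label, len(clean), threshold, len(dag.arcs), manifest["elapsed_s"],
    )
    result = PipelineResult(dag, bn, strengths, threshold, manifest, tally)
    if config.output_dir is not None:
        _write_artifacts(result, Path(config.output_dir), label)
    return result


def run_stratified(
    config: AnalysisConfig,
    variable: str,
    data: pd.DataFrame | None = None,
    schema: VariableSchema | None = None,
) -> dict[str, PipelineResult]:
    """One full learning run per level of ``variable``.

    Each stratum drops the now-constant stratification variable from its
    schema; strata below ``config.min_stratum_records`` records (after
    exclusions within the subset) are skipped with a warning."""
    schema = schema or build_default_schema()
    if variable not in schema:
        raise InvalidInputError(f"unknown stratification variable {variable!r}")
    if data is None:
        if config.data_path is None:
            raise InvalidInputError("no data provided")
        data = read_dataset(config.data_path)
    results: dict[str, PipelineResult] = {}
    sub_schema = schema.drop(variable)
    for level in schema.levels(variable):
        subset = data[data[variable] == level].drop(columns=[variable])
        if len(subset) < config.min_stratum_records:
            logger.warning(
                "stratum %s=%r has %d records (< %d); skipped",
                variable, level, len(subset), config.min_stratum_records,
            )
            continue
        results[level] = run_overall(
            config, data=subset, schema=sub_schema,
            label=f"stratum_{level}",
        )
    return results


def enumerate_pathways(
    dag: DAG, source: str, sinks: Iterable[str]
) -> list[tuple[str, ...]]:
    """All simple directed paths from ``source`` to any sink, sorted
    lexicographically."""
    if source not in dag.nodes:
        raise InvalidInputError(f"unknown source {source!r}")
    g = dag.to_networkx()
    paths: set[tuple[str, ...]] = set()
    for sink in sinks:
        if sink not in dag.nodes or sink == source:
            continue
        for path in nx.all_simple_paths(g, source, sink):
            paths.add(tuple(path))
    return sorted(paths)


def _child_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % 2**31)


def query_demographics(
    models: Mapping[str, BayesianNetwork],
    sample_count: int,
    seed: int,
    outcomes: tuple[str, ...] = OUTCOME_VARIABLES,
) -> pd.DataFrame:
    """Stage distributions per (group, age, gender, outcome).

    For each demographic cell the group's stratified model is queried with
    age and gender as evidence via likelihood weighting; output is long
    format with one row per outcome level."""
    rows = []
    qidx = 0
    for group in sorted(models):
        bn = models[group]
        ages = bn.schema.levels("Age")
        genders = bn.schema.levels("Gender")
        for age in ages:
            for gender in genders:
                for outcome in outcomes:
                    res = likelihood_weighting(
                        bn, {"Age": age, "Gender": gender}, outcome,
                        n_samples=sample_count, seed=_child_seed(seed, qidx),
                    )
                    qidx += 1
                    for level, prob in res.distribution.items():
                        rows.append(
                            {"group": group, "age": age, "gender": gender,
                             "outcome": outcome, "level": level,
                             "probability": prob,
                             "effective_weight": res.effective_weight}
                        )
    return pd.DataFrame(rows)


def query_behavior_impact(
    models: Mapping[str, BayesianNetwork],
    behavior: str,
    worst_level: str,
    best_level: str,
    outcome: str,
    outcome_level: str,
    sample_count: int,
    seed: int,
) -> pd.DataFrame:
    """Relative change in P(outcome=level) under best vs worst behavior.

    When a stratum's DAG has no directed path from the behavior to the
    outcome the change is exactly 0 for every demographic cell in that
    stratum (the query distribution cannot depend on the behavior)."""
    rows = []
    qidx = 0
    for group in sorted(models):
        bn = models[group]
        if behavior not in bn.schema or outcome not in bn.schema:
            raise InvalidInputError(
                f"{behavior!r}/{outcome!r} not in stratum {group!r} schema"
            )
        has_path = nx.has_path(bn.dag.to_networkx(), behavior, outcome)
        for age in bn.schema.levels("Age"):
            for gender in bn.schema.levels("Gender"):
                if not has_path:
                    p_base = p_best = float("nan")
                    change = 0.0
                else:
                    base = likelihood_weighting(
                        bn, {"Age": age, "Gender": gender, behavior: worst_level},
                        outcome, n_samples=sample_count,
                        seed=_child_seed(seed, qidx),
                    )
                    best = likelihood_weighting(
                        bn, {"Age": age, "Gender": gender, behavior: best_level},
                        outcome, n_samples=sample_count,
                        seed=_child_seed(seed, qidx + 1),
                    )
                    qidx += 2
                    p_base = base.probability(outcome_level)
                    p_best = best.probability(outcome_level)
                    change = relative_change(p_base, p_best)
                rows.append(
                    {"group": group, "age": age, "gender": gender,
                     "behavior": behavior, "worst_level": worst_level,
                     "best_level": best_level, "outcome": outcome,
                     "outcome_level": outcome_level,
                     "p_baseline": p_base, "p_improved": p_best,
                     "relative_change_pct": change}
                )
    return pd.DataFrame(rows)


def _pkg_version() -> str:
    from . import __version__

    return __version__
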