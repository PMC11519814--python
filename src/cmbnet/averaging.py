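"""Bootstrap arc strengths, the L1-optimal significance threshold, and the
averaged consensus network.

Each bootstrap replicate resamples the data with replacement and relearns
the structure; an adjacency's *strength* is the fraction of replicates
whose network contains it (in either orientation), and its *direction
frequency* is the share of a given orientation among those inclusions.
The significance threshold is chosen by minimizing the L1 distance
between the empirical CDF of the observed strengths and an idealized
counterpart that puts all mass on {0, 1}."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .graphs import DAG, Arc, ArcConstraintSet, validate
from .schema import InvalidInputError, VariableSchema
from .structure import ScoreCache, ScoreName, hill_climb

logger = logging.getLogger(__name__)


@dataclass
class ArcStrengthTable:
    """Per-adjacency bootstrap inclusion and orientation frequencies.

    ``entries`` has columns source, target, strength, direction_frequency;
    strength is shared by both orientations of an unordered pair, and the
    direction frequencies of the two orientations sum to 1 whenever the
    adjacency was ever included.  Pairs never included appear once (in
    lexicographic order) with strength 0.
    """

    entries: pd.DataFrame
    B: int
    schema: VariableSchema
    threshold: float | None = None

    def __post_init__(self) -> None:
        s = self.entries["strength"]
        d = self.entries["direction_frequency"]
        if ((s < 0) | (s > 1)).any() or ((d < 0) | (d > 1)).any():
            raise InvalidInputError("strengths/direction frequencies outside [0, 1]")

    def adjacency_strengths(self) -> np.ndarray:
        """One strength per unordered pair (deduplicated)."""
        pairs = self.entries.assign(
            pair=[tuple(sorted((u, v))) for u, v in
                  zip(self.entries["source"], self.entries["target"])]
        )
        return pairs.groupby("pair")["strength"].first().to_numpy()

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)


def bootstrap_strengths(
    data: pd.DataFrame,
    constraints: ArcConstraintSet,
    B: int,
    seed: int,
    schema: VariableSchema,
    score: ScoreName = "bic",
) -> ArcStrengthTable:
    """Learn B networks on size-n resamples and tabulate arc strengths.

    Replicate b uses the RNG stream seeded by SeedSequence([seed, b]), so
    the table is reproducible and individual replicates are independent of
    B.
    """
    if B < 1:
        raise InvalidInputError("B must be >= 1")
    n = len(data)
    if n == 0:
        raise InvalidInputError("empty dataset")
    base_codes = ScoreCache(data, schema, score=score).codes
    arc_counts: dict[Arc, int] = {}
    for b in range(B):
        rng = np.random.default_rng(np.random.SeedSequence([seed, b]))
        idx = rng.integers(0, n, size=n)
        cache = ScoreCache.from_codes(base_codes[idx], schema, score=score)
        dag, _ = hill_climb(None, constraints, schema, cache=cache)
        for arc in dag.arcs:
            arc_counts[arc] = arc_counts.get(arc, 0) + 1
    rows = []
    seen_pairs = set()
    names = schema.names
    for i, u in enumerate(names):
        for v in names[i + 1:]:
            fwd = arc_counts.get((u, v), 0)
            rev = arc_counts.get((v, u), 0)
            inc = fwd + rev
            strength = inc / B
            if inc == 0:
                rows.append((u, v, 0.0, 0.0))
            else:
                if fwd:
                    rows.append((u, v, strength, fwd / inc))
                if rev:
                    rows.append((v, u, strength, rev / inc))
            seen_pairs.add((u, v))
    entries = pd.DataFrame(rows, columns=["source", "target", "strength",
                                          "direction_frequency"])
    entries = entries.sort_values(
        ["strength", "source", "target"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return ArcStrengthTable(entries, B=B, schema=schema)


def significance_threshold(strengths: Sequence[float]) -> float:
    """Threshold separating significant from noise arcs by L1-CDF fit.

    For each candidate t in {0} union the observed strengths, the
    idealized CDF puts mass p0 = (share of strengths <= t) at 0 and the
    rest at 1; the candidate minimizing the integral of |empirical CDF -
    idealized CDF| over [0, 1] is returned (the smallest such t on ties).
    Arcs with strength strictly above the threshold are significant.  The
    L1 objective is piecewise linear between observed values, so searching
    candidates at the observed values is exact.
    """
    s = np.asarray(list(strengths), dtype=float)
    if s.size == 0:
        raise InvalidInputError("empty strength list")
    if (s < 0).any() or (s > 1).any():
        raise InvalidInputError("strengths must lie in [0, 1]")
    xs = np.unique(s)
    m = s.size
    # empirical CDF breakpoints over [0, 1]
    knots = np.unique(np.concatenate(([0.0, 1.0], xs)))
    widths = np.diff(knots)
    # value of the empirical CDF on each interval [knots[i], knots[i+1])
    ecdf_vals = np.searchsorted(np.sort(s), knots[:-1], side="right") / m
    best_t, best_obj = None, np.inf
    for t in np.concatenate(([0.0], xs)):
        p0 = np.count_nonzero(s <= t) / m
        obj = float(np.sum(np.abs(ecdf_vals - p0) * widths))
        if obj < best_obj - 1e-15:
            best_obj, best_t = obj, float(t)
    return best_t


def consensus_network(
    table: ArcStrengthTable, constraints: ArcConstraintSet
) -> DAG:
    """Averaged network of adjacencies with strength above the threshold.

    Adjacencies are oriented by majority direction frequency (ties go
    toward the lower-tier node, then lexicographically) and inserted in
    decreasing strength order; any arc that would close a cycle or violate
    the constraints is skipped.  Whitelisted arcs are always present.
    """
    if table.threshold is None:
        raise InvalidInputError("threshold not set; run significance_threshold first")
    schema = table.schema
    dag = DAG(schema.names, set(constraints.whitelist))
    # candidate per unordered pair: orientation + strength
    by_pair: dict[tuple[str, str], list[tuple[str, str, float, float]]] = {}
    for row in table.entries.itertuples(index=False):
        pair = tuple(sorted((row.source, row.target)))
        by_pair.setdefault(pair, []).append(
            (row.source, row.target, row.strength, row.direction_frequency)
        )
    candidates: list[tuple[float, str, str]] = []
    for pair, rows in by_pair.items():
        strength = rows[0][2]
        if strength <= table.threshold:
            continue
        rows = sorted(rows, key=lambda r: -r[3])
        if len(rows) > 1 and abs(rows[0][3] - rows[1][3]) < 1e-12:
            # orientation tie: point toward the lower tier (larger tier
            # number); equal tiers resolve lexicographically by source
            a, b = pair
            if schema.tier(a) == schema.tier(b):
                u, v = a, b
            elif schema.tier(a) < schema.tier(b):
                u, v = a, b
            else:
                u, v = b, a
        else:
            u, v = rows[0][0], rows[0][1]
        candidates.append((strength, u, v))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    for strength, u, v in candidates:
        if dag.has_arc(u, v) or dag.has_arc(v, u):
            continue  # whitelisted already
        if (u, v) in constraints.blacklist:
            if (v, u) in constraints.blacklist or dag.would_create_cycle(v, u):
                logger.info("consensus: dropping %s-%s (constraints/cycle)", u, v)
                continue
            u, v = v, u
        if dag.would_create_cycle(u, v):
            logger.info("consensus: dropping %s->%s (would close a cycle)", u, v)
            continue
        dag.add_arc(u, v)
    assert not validate(dag, constraints)
    return dag
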