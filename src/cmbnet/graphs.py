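"""Directed acyclic graphs and the tiered blacklist/whitelist constraints.

Network learning is constrained by prior knowledge expressed through the
variable tiers: (1) no arc from a tier to any higher tier; (2) no arc into
the non-modifiable demographics (age, gender, ethno-racial group); (3) no
arc from ethno-racial group directly into the cardiometabolic drivers or
CMBCD; (4) a mandated hierarchy of arcs among the drivers; and (5)
mandated arcs from each driver into CMBCD.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import networkx as nx

from .schema import DRIVERS, InvalidInputError, VariableSchema

Arc = tuple[str, str]

#: Default mandated arcs among the drivers: adiposity is the most proximal
#: driver, feeding dysglycemia, and both feed blood pressure and lipids.
DEFAULT_DRIVER_HIERARCHY: frozenset[Arc] = frozenset(
    {
        ("ABCD", "DBCD"),
        ("ABCD", "HBCD"),
        ("ABCD", "LBCD"),
        ("DBCD", "HBCD"),
        ("DBCD", "LBCD"),
    }
)


class CycleError(InvalidInputError):
    """Raised when an operation would introduce a directed cycle."""


@dataclass
class DAG:
    """A directed acyclic graph over named nodes.

    Acyclicity is enforced on every mutation; arcs are stored as ordered
    (source, target) pairs without duplicates or self-loops.
    """

    nodes: tuple[str, ...]
    arcs: set[Arc] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise InvalidInputError("duplicate node names")
        self.arcs = set(self.arcs)
        known = set(self.nodes)
        for u, v in self.arcs:
            if u == v:
                raise InvalidInputError(f"self-loop {u}->{v}")
            if u not in known or v not in known:
                raise InvalidInputError(f"arc {u}->{v} references unknown node")
        if self.arcs and not nx.is_directed_acyclic_graph(self.to_networkx()):
            raise CycleError("initial arc set contains a cycle")

    # -- queries ----------------------------------------------------------
    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(u for u, v in self.arcs if v == node))

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(v for u, v in self.arcs if u == node))

    def has_arc(self, u: str, v: str) -> bool:
        return (u, v) in self.arcs

    def would_create_cycle(self, u: str, v: str) -> bool:
        """True if adding u->v closes a directed cycle (v reaches u)."""
        if u == v:
            return True
        return self._reaches(v, u, skip=None)

    def reversal_creates_cycle(self, u: str, v: str) -> bool:
        """True if reversing the existing arc u->v closes a cycle.

        Reversal is illegal iff a path u~>v exists that does not use the
        direct arc.
        """
        return self._reaches(u, v, skip=(u, v))

    def _reaches(self, start: str, goal: str, skip: Arc | None) -> bool:
        succ: dict[str, list[str]] = {n: [] for n in self.nodes}
        for a, b in self.arcs:
            if (a, b) != skip:
                succ[a].append(b)
        stack, seen = [start], {start}
        while stack:
            cur = stack.pop()
            if cur == goal:
                return True
            for nxt in succ[cur]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return False

    # -- mutation ---------------------------------------------------------
    def add_arc(self, u: str, v: str) -> None:
        if u not in self.nodes or v not in self.nodes:
            raise InvalidInputError(f"unknown node in arc {u}->{v}")
        if (u, v) in self.arcs:
            return
        if self.would_create_cycle(u, v):
            raise CycleError(f"adding {u}->{v} would create a cycle")
        self.arcs.add((u, v))

    def remove_arc(self, u: str, v: str) -> None:
        self.arcs.discard((u, v))

    def copy(self) -> "DAG":
        return DAG(self.nodes, set(self.arcs))

    # -- conversions ------------------------------------------------------
    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.arcs)
        return g

    def topological_order(self) -> list[str]:
        order = {n: i for i, n in enumerate(self.nodes)}
        return list(
            nx.lexicographical_topological_sort(self.to_networkx(), key=order.get)
        )

    def to_dot(self) -> str:
        lines = ["digraph G {"]
        for n in self.nodes:
            lines.append(f'  "{n}";')
        for u, v in sorted(self.arcs):
            lines.append(f'  "{u}" -> "{v}";')
        lines.append("}")
        return "\n".join(lines) + "\n"

    def arcs_to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["source", "target"])
            for u, v in sorted(self.arcs):
                w.writerow([u, v])

    @classmethod
    def arcs_from_csv(cls, path, nodes: Iterable[str]) -> "DAG":
        arcs = set()
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                arcs.add((row["source"], row["target"]))
        return cls(tuple(nodes), arcs)


# ---------------------------------------------------------------------------
# Constraints
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArcConstraintSet:
    """Forbidden (blacklist) and mandatory (whitelist) arcs."""

    blacklist: frozenset[Arc]
    whitelist: frozenset[Arc]

    def __post_init__(self) -> None:
        overlap = self.blacklist & self.whitelist
        if overlap:
            raise InvalidInputError(f"arcs both black- and whitelisted: {sorted(overlap)}")
        nodes = {n for a in self.whitelist for n in a}
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(self.whitelist)
        if not nx.is_directed_acyclic_graph(g):
            raise InvalidInputError("whitelist arcs form a cycle")

    def write_csv(self, blacklist_path, whitelist_path) -> None:
        for path, arcs in ((blacklist_path, self.blacklist), (whitelist_path, self.whitelist)):
            with open(path, "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["source", "target"])
                for u, v in sorted(arcs):
                    w.writerow([u, v])

    @classmethod
    def read_csv(cls, blacklist_path, whitelist_path) -> "ArcConstraintSet":
        out = []
        for path in (blacklist_path, whitelist_path):
            arcs = set()
            with open(path, newline="") as fh:
                for row in csv.DictReader(fh):
                    arcs.add((row["source"], row["target"]))
            out.append(frozenset(arcs))
        return cls(out[0], out[1])


def build_tier_constraints(
    schema: VariableSchema,
    driver_hierarchy: Iterable[Arc] = DEFAULT_DRIVER_HIERARCHY,
) -> ArcConstraintSet:
    """Build the five-part constraint system from the schema tiers.

    Blacklist: all upward-tier arcs, all arcs into tier-1 variables, and
    all arcs from ethno-racial group into the drivers or CMBCD.  Whitelist:
    the driver hierarchy plus the four driver->CMBCD arcs.  Whitelisted
    arcs take precedence and are removed from the blacklist.
    """
    hierarchy = set(driver_hierarchy)
    driver_set = set(DRIVERS)
    for u, v in hierarchy:
        if u not in driver_set or v not in driver_set:
            raise InvalidInputError(f"hierarchy arc {u}->{v} not among drivers")
    g = nx.DiGraph(hierarchy)
    if not nx.is_directed_acyclic_graph(g):
        raise InvalidInputError("driver hierarchy contains a cycle")

    names = schema.names
    blacklist: set[Arc] = set()
    for u in names:
        for v in names:
            if u == v:
                continue
            if schema.tier(v) < schema.tier(u):
                blacklist.add((u, v))  # no arc into a higher tier
            if schema.tier(v) == 1:
                blacklist.add((u, v))  # nothing points at non-modifiables
    if "Ethno-racial group" in schema:
        for v in (*DRIVERS, "CMBCD"):
            if v in schema:
                blacklist.add(("Ethno-racial group", v))
    whitelist = set(hierarchy) | {(d, "CMBCD") for d in DRIVERS if "CMBCD" in schema}
    whitelist = {a for a in whitelist if a[0] in schema.names and a[1] in schema.names}
    blacklist -= whitelist
    return ArcConstraintSet(frozenset(blacklist), frozenset(whitelist))


@dataclass(frozen=True)
class Violation:
    kind: str  # "forbidden-arc" | "missing-mandatory"
    arc: Arc

    def __str__(self) -> str:
        return f"{self.kind}: {self.arc[0]} -> {self.arc[1]}"


def validate(dag: DAG, constraints: ArcConstraintSet) -> list[Violation]:
    """Empty list iff no blacklisted arc is present and every whitelisted
    arc is present."""
    out = [
        Violation("forbidden-arc", a) for a in sorted(dag.arcs & constraints.blacklist)
    ]
    out.extend(
        Violation("missing-mandatory", a)
        for a in sorted(constraints.whitelist - dag.arcs)
    )
    return out


def markov_blanket(dag: DAG, node: str) -> set[str]:
    """Parents, children, and co-parents of children of ``node``."""
    if node not in dag.nodes:
        raise InvalidInputError(f"unknown node {node!r}")
    blanket = set(dag.parents(node)) | set(dag.children(node))
    for child in dag.children(node):
        blanket.update(dag.parents(child))
    blanket.discard(node)
    return blanket
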