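"""Biosynthesis pathway graph built from measured enzyme activities.

Starting from dietary/endogenous precursor fatty acids, the graph is the
closure of the precursors under every enzyme activity that qualifies: a
recorded substrate→product conversion at or above a percentage threshold,
or a qualitative (peak-only) activity.  Nodes are fatty acids; edges carry
the enzyme name and its activity label (e.g. "Δ8" or "C18→C20").

Every edge strictly increases chain length + double-bond count (elongation
adds two carbons, desaturation adds one bond), so the graph is necessarily
acyclic.

The default precursor set is the yeast/diet-available left column of the
reconstructed pathway map: 16:1n-7, 18:1n-9, 18:2n-6 and 18:3n-3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

import networkx as nx

from .enzymes import ConversionStatus, EnzymePanel, load_activity_panels
from .nomenclature import FattyAcid, classify_unsaturation, parse_shorthand

__all__ = [
    "DEFAULT_PRECURSORS",
    "DEFAULT_THRESHOLD",
    "PathwayGraph",
    "Route",
    "RouteStep",
    "build_graph",
    "enumerate_routes",
    "reachable_products",
]

#: Edge-inclusion threshold (percent conversion).  Separates every activity
#: the assays treat as functional from every one treated as absent or trace
#: (the largest sub-functional conversion is 3.9%, the smallest functional
#: one 5.7%... see the activity fixture).
DEFAULT_THRESHOLD = 5.0

DEFAULT_PRECURSORS: frozenset[FattyAcid] = frozenset(
    parse_shorthand(s) for s in ("16:1n-7", "18:1n-9", "18:2n-6", "18:3n-3")
)


@dataclass(frozen=True)
class RouteStep:
    substrate: FattyAcid
    product: FattyAcid
    enzyme_name: str
    activity_label: str


@dataclass(frozen=True)
class Route:
    """An ordered chain of reaction steps from a precursor to a target."""

    steps: tuple[RouteStep, ...]

    def __post_init__(self) -> None:
        for a, b in zip(self.steps, self.steps[1:]):
            if a.product != b.substrate:
                raise ValueError("route steps do not chain substrate→product")

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.activity_label for s in self.steps)

    def to_dict(self) -> list[dict[str, str]]:
        return [
            {
                "substrate": str(s.substrate),
                "product": str(s.product),
                "enzyme": s.enzyme_name,
                "activity": s.activity_label,
            }
            for s in self.steps
        ]


@dataclass
class PathwayGraph:
    """Directed acyclic reaction graph over fatty acids.

    Thin wrapper around a :class:`networkx.MultiDiGraph` (parallel edges
    appear when several enzymes catalyse the same conversion).
    """

    graph: nx.MultiDiGraph
    precursors: frozenset[FattyAcid]
    threshold: float

    @property
    def nodes(self) -> set[FattyAcid]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[FattyAcid, FattyAcid, str, str]]:
        return {
            (u, v, data["enzyme"], data["activity"])
            for u, v, data in self.graph.edges(data=True)
        }

    def assert_acyclic(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise AssertionError("pathway graph contains a cycle")

    def to_edge_rows(self) -> list[dict[str, str]]:
        rows = [
            {
                "substrate": str(u),
                "product": str(v),
                "enzyme": data["enzyme"],
                "activity": data["activity"],
                "conversion": data["conversion"],
            }
            for u, v, data in self.graph.edges(data=True)
        ]
        rows.sort(key=lambda r: (r["substrate"], r["product"], r["enzyme"]))
        return rows

    def to_csv(self, path: str | Path) -> None:
        import csv

        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["substrate", "product", "enzyme", "activity", "conversion"]
            )
            writer.writeheader()
            writer.writerows(self.to_edge_rows())

    def to_dot(self) -> str:
        lines = ["digraph pathway {"]
        for fa in sorted(self.nodes):
            shape = "box" if fa in self.precursors else "ellipse"
            lines.append(f'  "{fa}" [shape={shape}];')
        for row in self.to_edge_rows():
            lines.append(
                f'  "{row["substrate"]}" -> "{row["product"]}" '
                f'[label="{row["enzyme"]} ({row["activity"]})"];'
            )
        lines.append("}")
        return "\n".join(lines)


def _qualifies(record, threshold: float) -> bool:
    if record.conversion.status is ConversionStatus.QUALITATIVE:
        return True
    if record.conversion.status is ConversionStatus.NOT_DETECTED:
        return False
    return record.conversion.percent >= threshold


def build_graph(
    panels: Iterable[EnzymePanel] | None = None,
    precursors: Iterable[FattyAcid] = DEFAULT_PRECURSORS,
    threshold: float = DEFAULT_THRESHOLD,
) -> PathwayGraph:
    """Close the precursor set under all qualifying enzyme activities.

    Only conversions actually recorded in the panels become edges — the
    graph never extrapolates an operator to an unassayed substrate.
    """
    if panels is None:
        panels = load_activity_panels()
    precursors = frozenset(precursors)
    if not precursors:
        raise ValueError("precursor set must not be empty")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")

    records = [rec for panel in panels for rec in panel.records if _qualifies(rec, threshold)]
    g = nx.MultiDiGraph()
    g.add_nodes_from(precursors)
    frontier = set(precursors)
    while frontier:
        fa = frontier.pop()
        for rec in records:
            if rec.substrate == fa:
                if rec.product not in g:
                    frontier.add(rec.product)
                g.add_edge(
                    fa,
                    rec.product,
                    enzyme=rec.enzyme_name,
                    activity=rec.activity_label,
                    conversion=str(rec.conversion),
                )
    return PathwayGraph(graph=g, precursors=precursors, threshold=threshold)


def reachable_products(
    g: PathwayGraph, predicate: Callable[[FattyAcid], bool] = lambda fa: True
) -> set[FattyAcid]:
    """All non-precursor nodes satisfying ``predicate``."""
    return {fa for fa in g.nodes if fa not in g.precursors and predicate(fa)}


def _routes_dfs(g: PathwayGraph, start: FattyAcid, target: FattyAcid) -> list[Route]:
    routes: list[Route] = []
    path: list[RouteStep] = []

    def visit(node: FattyAcid, seen: set[FattyAcid]) -> None:
        if node == target:
            if path:  # a precursor is not a route to itself
                routes.append(Route(tuple(path)))
            return
        for _, nxt, data in g.graph.out_edges(node, data=True):
            if nxt in seen:
                continue
            path.append(RouteStep(node, nxt, data["enzyme"], data["activity"]))
            visit(nxt, seen | {nxt})
            path.pop()

    visit(start, {start})
    return routes


def enumerate_routes(g: PathwayGraph, target: FattyAcid) -> list[Route]:
    """All simple precursor→target routes, shortest first.

    Ties are ordered by the lexicographic sequence of enzyme names along
    the route.  A precursor target yields no routes.
    """
    if target not in g.nodes:
        raise KeyError(f"{target} is not a node of the pathway graph")
    routes: list[Route] = []
    for precursor in g.precursors:
        routes.extend(_routes_dfs(g, precursor, target))
    routes.sort(key=lambda r: (len(r), tuple(s.enzyme_name for s in r.steps)))
    return routes


def routes_to_json(routes: list[Route], path: str | Path | None = None) -> str:
    payload = json.dumps([r.to_dict() for r in routes], ensure_ascii=False, indent=2)
    if path is not None:
        Path(path).write_text(payload, encoding="utf-8")
    return payload
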