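"""Build the non-metric labeled graph of a maze.

One vertex per corner, one edge per straight corridor, and — for the
wormhole variant — one edge per wormhole crossing, carrying the
*experienced* (teleport-shortened) distance. Every ordered triplet of
neighboring vertices (i, j, k), including backtracks (i, j, i), carries
the turn angle a walker experiences at j when traveling i -> j -> k.
Labels are measured by walking the maze (:func:`cogmaps.maze.traverse`),
so around wormholes they reflect the locally experienced geometry, not
the Euclidean layout: the labels need not be jointly consistent with
any planar configuration, which is what makes the graph non-metric.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum

import networkx as nx
import numpy as np

from . import maze as mz
from .maze import MazeSpec

__all__ = [
    "Variant",
    "LabeledGraph",
    "GraphBuildError",
    "build_graph",
    "enumerate_triplets",
    "measure_labels",
    "read_graph_json",
    "write_graph_json",
]


class GraphBuildError(ValueError):
    pass


class Variant(str, Enum):
    """Which rendition of the maze the graph describes.

    ``WORMHOLE``: wormholes active; control-only corners excluded.
    ``CONTROL``: plain corridors everywhere; control corners included.
    """

    WORMHOLE = "wormhole"
    CONTROL = "control"


def _edge_key(u: int, v: int) -> tuple[int, int]:
    return (u, v) if u <= v else (v, u)


@dataclass
class LabeledGraph:
    """Vertices, distance-labeled edges, and turn-labeled triplets.

    ``edges`` maps the sorted vertex pair to the (symmetric, positive)
    distance label; ``triplets`` maps ordered (i, j, k) to the turn
    angle at j in degrees, CCW positive, in (-180, 180], with
    backtracks (i, j, i) at exactly 180.
    """

    vertices: list[int]
    edges: dict[tuple[int, int], float]
    triplets: dict[tuple[int, int, int], float] = field(default_factory=dict)

    def __post_init__(self):
        vs = set(self.vertices)
        for (u, v), d in self.edges.items():
            if u not in vs or v not in vs:
                raise GraphBuildError(f"edge ({u}, {v}) references unknown vertex")
            if not d > 0:
                raise GraphBuildError(f"edge ({u}, {v}) has non-positive label {d}")
        for (i, j, k) in self.triplets:
            if _edge_key(i, j) not in self.edges or _edge_key(j, k) not in self.edges:
                raise GraphBuildError(f"triplet ({i}, {j}, {k}) legs are not edges")

    def distance(self, u: int, v: int) -> float:
        return self.edges[_edge_key(u, v)]

    def neighbors(self, v: int) -> list[int]:
        out = []
        for a, b in self.edges:
            if a == v:
                out.append(b)
            elif b == v:
                out.append(a)
        return sorted(out)

    def mean_edge_length(self) -> float:
        return float(np.mean(list(self.edges.values())))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.vertices)
        for (u, v), d in self.edges.items():
            g.add_edge(u, v, weight=d)
        return g


def enumerate_triplets(graph: LabeledGraph) -> list[tuple[int, int, int]]:
    """All ordered triplets of neighboring vertices, plus backtracks.

    At a vertex of degree g this yields g*(g-1) through-triplets and g
    backtracks (i, j, i). Ordering is lexicographic, so enumeration is
    deterministic.
    """
    triplets: list[tuple[int, int, int]] = []
    for j in sorted(graph.vertices):
        nbrs = graph.neighbors(j)
        for i in nbrs:
            for k in nbrs:
                if i != k:
                    triplets.append((i, j, k))
            triplets.append((i, j, i))
    return sorted(triplets)


def measure_labels(spec: MazeSpec, graph: LabeledGraph, variant: Variant) -> LabeledGraph:
    """Populate triplet turn labels by walking i -> j -> k in the maze."""
    use_wh = variant == Variant.WORMHOLE
    triplets = {}
    for (i, j, k) in enumerate_triplets(graph):
        try:
            steps = mz.traverse(spec, (i, j, k), use_wormholes=use_wh)
        except mz.RouteError as err:
            raise GraphBuildError(f"triplet ({i}, {j}, {k}) is not walkable: {err}")
        triplets[(i, j, k)] = steps[0].turn_deg
    graph.triplets = triplets
    return graph


def build_graph(spec: MazeSpec, variant: Variant = Variant.WORMHOLE) -> LabeledGraph:
    """Construct the labeled graph for one variant of a validated maze.

    The wormhole variant drops control-only corners (and their
    corridors) and adds one edge per wormhole crossing with the
    experienced distance; the control variant keeps every corner and
    ignores wormholes.
    """
    mz.validate_maze(spec)
    variant = Variant(variant)
    if variant == Variant.WORMHOLE:
        vertices = sorted(set(spec.corners) - spec.control_corners)
    else:
        vertices = sorted(spec.corners)
    vset = set(vertices)

    edges: dict[tuple[int, int], float] = {}
    for a, b in spec.segments:
        if a in vset and b in vset:
            edges[_edge_key(a, b)] = float(
                np.linalg.norm(spec.corner_xy(b) - spec.corner_xy(a))
            )
    if variant == Variant.WORMHOLE:
        for (a, b), link in mz.wormhole_links(spec).items():
            if a in vset and b in vset:
                edges[_edge_key(a, b)] = link.distance

    graph = LabeledGraph(vertices=vertices, edges=edges)
    for v in vertices:
        if not graph.neighbors(v):
            raise GraphBuildError(f"vertex {v} has degree 0 in variant {variant.value}")
    return measure_labels(spec, graph, variant)


# ---------------------------------------------------------------------------
# JSON round-trip
# ---------------------------------------------------------------------------


def graph_to_dict(graph: LabeledGraph) -> dict:
    return {
        "vertices": list(graph.vertices),
        "edges": [[u, v, d] for (u, v), d in sorted(graph.edges.items())],
        "triplets": [
            [i, j, k, alpha] for (i, j, k), alpha in sorted(graph.triplets.items())
        ],
    }


def graph_from_dict(doc: dict) -> LabeledGraph:
    return LabeledGraph(
        vertices=[int(v) for v in doc["vertices"]],
        edges={_edge_key(int(u), int(v)): float(d) for u, v, d in doc["edges"]},
        triplets={
            (int(i), int(j), int(k)): float(a) for i, j, k, a in doc["triplets"]
        },
    )


def write_graph_json(graph: LabeledGraph, path) -> None:
    with open(path, "w") as fh:
        json.dump(graph_to_dict(graph), fh, indent=1)
        fh.write("\n")


def read_graph_json(path) -> LabeledGraph:
    with open(path) as fh:
        return graph_from_dict(json.load(fh))
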