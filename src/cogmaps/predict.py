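"""Shortcut-direction predictions under the competing map models.

Three models predict the direction a navigator should walk to shortcut
from one place to another:

* ``nonmetric`` — vector addition of egomotion labels along the
  shortest path in the labeled graph (Dijkstra), seeded with the
  ground-truth orientation of the first path arm;
* ``embedded`` — the straight line between the two vertices in the 2D
  stress-minimizing embedding (whose global orientation is arbitrary);
* ``ground_truth`` — the straight line in the veridical planar layout.

Because the embedding has no privileged reference direction, model
predictions and behavioral estimates are compared in a *local*
reference frame: angles relative to the orientation of the maze arm a
navigator departs along.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from . import maze as mz
from .geometry import unit_vector, wrap_signed_deg, wrap_unsigned_deg
from .graphbuild import LabeledGraph, Variant
from .embed import Embedding
from .maze import MazeSpec

__all__ = [
    "ShortcutPrediction",
    "PredictionError",
    "shortest_path",
    "path_vector",
    "predict_nonmetric",
    "predict_embedded",
    "predict_ground_truth",
    "to_local_reference",
    "start_arm_orientation",
]


class PredictionError(ValueError):
    pass


@dataclass(frozen=True)
class ShortcutPrediction:
    """A model's predicted shortcut between two vertices."""

    model: str  # "nonmetric" | "embedded" | "ground_truth"
    start: int
    goal: int
    direction_deg: float  # global direction in the model's frame, [0, 360)
    length: float
    path: tuple[int, ...] | None = None


def shortest_path(graph: LabeledGraph, a: int, b: int) -> list[int]:
    """Minimal-total-distance vertex path from a to b (Dijkstra).

    Among equal-cost paths the lexicographically smallest vertex
    sequence is returned, so results are reproducible regardless of
    hash ordering.
    """
    if a not in graph.vertices or b not in graph.vertices:
        raise PredictionError(f"vertices {a}, {b} must both be in the graph")
    if a == b:
        return [a]
    g = graph.to_networkx()
    try:
        dist_to_b = nx.single_source_dijkstra_path_length(g, b)
        total = dist_to_b[a]
    except KeyError:
        raise PredictionError(f"no path from {a} to {b}") from None
    # walk greedily downhill in remaining distance, smallest vertex first
    path = [a]
    v = a
    tol = 1e-9 * (1.0 + total)
    while v != b:
        nxt = None
        for u in graph.neighbors(v):  # sorted
            if u in dist_to_b and abs(
                dist_to_b[v] - (graph.distance(v, u) + dist_to_b[u])
            ) <= tol:
                nxt = u
                break
        if nxt is None:  # pragma: no cover - defensive
            raise PredictionError(f"shortest-path reconstruction failed at {v}")
        path.append(nxt)
        v = nxt
    return path


def path_vector(
    graph: LabeledGraph, path: list[int], start_heading: float = 0.0
) -> np.ndarray:
    """Dead-reckoning resultant of a path's distance and turn labels.

    Starts at the origin facing ``start_heading``, advances each edge's
    distance label and rotates by each interior triplet's turn label;
    returns the final displacement. On a planar-consistent graph this is
    path independent; on a wormhole graph it is not.
    """
    if len(path) < 2:
        raise PredictionError("path needs at least two vertices")
    heading = float(start_heading)
    pos = np.zeros(2)
    for n, (u, v) in enumerate(zip(path[:-1], path[1:])):
        try:
            d = graph.distance(u, v)
        except KeyError:
            raise PredictionError(f"path legs ({u}, {v}) is not an edge") from None
        pos = pos + d * unit_vector(heading)
        if n + 2 <= len(path) - 1:
            trip = (u, v, path[n + 2])
            if trip not in graph.triplets:
                raise PredictionError(f"missing triplet label for {trip}")
            heading += graph.triplets[trip]
    return pos


def start_arm_orientation(
    spec: MazeSpec,
    path: list[int],
    variant: Variant = Variant.WORMHOLE,
) -> float:
    """Ground-truth global orientation of the first arm of a path."""
    if len(path) < 2:
        raise PredictionError("path needs at least two vertices")
    return mz.departure_direction(
        spec, path[0], path[1], use_wormholes=Variant(variant) == Variant.WORMHOLE
    )


def predict_nonmetric(
    graph: LabeledGraph,
    spec: MazeSpec,
    a: int,
    b: int,
    variant: Variant = Variant.WORMHOLE,
) -> ShortcutPrediction:
    """Vector-addition shortcut prediction of the labeled-graph model."""
    if a == b:
        raise PredictionError("shortcut direction undefined for identical endpoints")
    path = shortest_path(graph, a, b)
    heading0 = start_arm_orientation(spec, path, variant)
    vec = path_vector(graph, path, start_heading=heading0)
    norm = float(np.linalg.norm(vec))
    if norm < 1e-12:
        raise PredictionError(f"zero resultant vector for pair ({a}, {b})")
    return ShortcutPrediction(
        model="nonmetric",
        start=a,
        goal=b,
        direction_deg=wrap_unsigned_deg(np.degrees(np.arctan2(vec[1], vec[0]))),
        length=norm,
        path=tuple(path),
    )


def predict_embedded(X: Embedding, a: int, b: int) -> ShortcutPrediction:
    """Straight-line shortcut prediction in the embedded map's frame."""
    if a == b:
        raise PredictionError("shortcut direction undefined for identical endpoints")
    pa, pb = X.coordinates[a], X.coordinates[b]
    if np.allclose(pa, pb):
        raise PredictionError(f"vertices {a} and {b} are embedded coincidently")
    return ShortcutPrediction(
        model="embedded",
        start=a,
        goal=b,
        direction_deg=wrap_unsigned_deg(X.direction(a, b)),
        length=float(np.linalg.norm(np.asarray(pb) - np.asarray(pa))),
    )


def predict_ground_truth(spec: MazeSpec, a: int, b: int) -> ShortcutPrediction:
    """Straight-line direction in the veridical planar layout."""
    if a == b:
        raise PredictionError("shortcut direction undefined for identical endpoints")
    pa, pb = spec.corner_xy(a), spec.corner_xy(b)
    return ShortcutPrediction(
        model="ground_truth",
        start=a,
        goal=b,
        direction_deg=wrap_unsigned_deg(mz.direction_deg(pa, pb)),
        length=float(np.linalg.norm(pb - pa)),
    )


def to_local_reference(direction_deg: float, start_arm_orientation_deg: float):
    """Angle of a direction relative to the starting arm, in (-180, 180].

    Invariant under any common rotation of both arguments, which is what
    makes estimates comparable across frames with arbitrary global
    orientation (the embedding's gauge freedom).
    """
    return wrap_signed_deg(
        np.asarray(direction_deg, dtype=float) - start_arm_orientation_deg
    )
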