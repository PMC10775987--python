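"""Ground-truth maze representation and egomotion measurement.

A maze is a planar network of straight corridors (segments between
corner points), optionally augmented with *wormholes*: directed
teleportation links that move a walker instantly from an entry pose to
an exit pose while rotating their world heading. The walker experiences
the teleport seamlessly — no perceived turn, no perceived jump — so the
egomotion measured along a route through a wormhole disagrees with the
Euclidean displacement between its endpoints. That disagreement is what
makes such an environment non-Euclidean.

All coordinates are in arbitrary planar length units; all headings are
degrees counterclockwise from east.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .geometry import direction_deg, unit_vector, wrap_signed_deg

__all__ = [
    "Pose",
    "Wormhole",
    "ObjectLocation",
    "MazeSpec",
    "EgomotionStep",
    "MazeValidationError",
    "RouteError",
    "validate_maze",
    "traverse",
    "dead_reckon",
    "departure_direction",
    "arrival_direction",
    "resolve_object",
    "object_position",
    "insert_object_corners",
    "read_maze_json",
    "write_maze_json",
]

_GEOM_TOL = 1e-9


class MazeValidationError(ValueError):
    """A maze specification violates one of its invariants."""


class RouteError(ValueError):
    """A route references corners that are not connected as required."""


@dataclass(frozen=True)
class Pose:
    """Position plus heading (degrees CCW from east)."""

    x: float
    y: float
    heading_deg: float

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y])

    def reversed(self) -> "Pose":
        return Pose(self.x, self.y, wrap_signed_deg(self.heading_deg + 180.0))


@dataclass(frozen=True)
class Wormhole:
    """Directed teleportation link with an imposed heading rotation.

    A walker crossing ``entry`` (moving along ``entry.heading_deg``) is
    instantly placed at ``exit`` facing ``exit.heading_deg``; the world
    heading therefore jumps by ``rotation_deg`` while the walker
    experiences straight, uninterrupted travel.
    """

    entry: Pose
    exit: Pose
    rotation_deg: float

    def reversed(self) -> "Wormhole":
        return Wormhole(
            entry=self.exit.reversed(),
            exit=self.entry.reversed(),
            rotation_deg=wrap_signed_deg(-self.rotation_deg),
        )


@dataclass(frozen=True)
class ObjectLocation:
    """An object sits at a corner, or partway along a segment.

    ``frac`` is the position along the segment from its first to its
    second corner (0 < frac < 1) when ``segment`` is given.
    """

    corner: int | None = None
    segment: tuple[int, int] | None = None
    frac: float | None = None


@dataclass(frozen=True)
class EgomotionStep:
    """One leg of walked egomotion: advance, then (optionally) turn.

    ``turn_deg`` is the heading change experienced at the far corner of
    the leg, counterclockwise positive, in (-180, 180]; it is ``None``
    for the final leg of a route.
    """

    distance: float
    turn_deg: float | None


@dataclass(frozen=True)
class MazeSpec:
    """Planar ground-truth maze with optional wormholes and objects."""

    corners: Mapping[int, tuple[float, float]]
    segments: tuple[tuple[int, int], ...]
    wormholes: tuple[Wormhole, ...] = ()
    objects: Mapping[str, ObjectLocation] = field(default_factory=dict)
    control_corners: frozenset[int] = frozenset()

    def corner_xy(self, cid: int) -> np.ndarray:
        x, y = self.corners[cid]
        return np.array([float(x), float(y)])


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def _segment_key(seg: Sequence[int]) -> tuple[int, int]:
    a, b = seg
    return (a, b) if a <= b else (b, a)


def validate_maze(spec: MazeSpec) -> MazeSpec:
    """Check all maze invariants; return the spec unchanged on success.

    Raises :class:`MazeValidationError` naming the offending element on
    dangling references, duplicate/degenerate segments, disconnected
    corridor networks, or wormholes that do not sit consistently on
    segments.
    """
    corners = dict(spec.corners)
    if not corners:
        raise MazeValidationError("maze has no corners")
    for cid, xy in corners.items():
        if len(xy) != 2 or not all(math.isfinite(float(v)) for v in xy):
            raise MazeValidationError(f"corner {cid} has non-finite coordinates {xy}")

    seen: set[tuple[int, int]] = set()
    for seg in spec.segments:
        a, b = seg
        if a not in corners or b not in corners:
            raise MazeValidationError(f"segment {seg} references unknown corner")
        if a == b:
            raise MazeValidationError(f"segment {seg} has identical endpoints")
        if np.allclose(spec.corner_xy(a), spec.corner_xy(b)):
            raise MazeValidationError(f"segment {seg} has zero length")
        key = _segment_key(seg)
        if key in seen:
            raise MazeValidationError(f"duplicate segment {seg}")
        seen.add(key)

    g = nx.Graph()
    g.add_nodes_from(corners)
    g.add_edges_from(spec.segments)
    if not nx.is_connected(g):
        comps = sorted(nx.connected_components(g), key=len)
        raise MazeValidationError(
            f"maze corridors are disconnected; smallest component: {sorted(comps[0])}"
        )

    for wh in spec.wormholes:
        if not math.isfinite(wh.rotation_deg):
            raise MazeValidationError("wormhole rotation is not finite")
        _locate_pose_on_segment(spec, wh.entry, "entry")
        _locate_pose_on_segment(spec, wh.exit, "exit")
        implied = wrap_signed_deg(wh.exit.heading_deg - wh.entry.heading_deg)
        if abs(wrap_signed_deg(implied - wh.rotation_deg)) > 1e-6:
            raise MazeValidationError(
                f"wormhole rotation {wh.rotation_deg} does not match the "
                f"entry/exit heading change {implied}"
            )

    for name, loc in spec.objects.items():
        if loc.corner is not None:
            if loc.corner not in corners:
                raise MazeValidationError(f"object {name!r} references unknown corner")
        elif loc.segment is not None:
            if _segment_key(loc.segment) not in seen:
                raise MazeValidationError(f"object {name!r} references unknown segment")
            if loc.frac is None or not (0.0 < loc.frac < 1.0):
                raise MazeValidationError(f"object {name!r} needs 0 < frac < 1")
        else:
            raise MazeValidationError(f"object {name!r} has no location")

    return spec


def _locate_pose_on_segment(spec: MazeSpec, pose: Pose, what: str) -> tuple[int, int]:
    """Find the (directed) segment a pose lies on, oriented along its heading.

    Returns (behind_corner, ahead_corner): the corner the pose is moving
    away from and the one it is moving toward.
    """
    p = pose.xy
    h = unit_vector(pose.heading_deg)
    for seg in spec.segments:
        a, b = seg
        pa, pb = spec.corner_xy(a), spec.corner_xy(b)
        d = pb - pa
        length = float(np.linalg.norm(d))
        t = float(np.dot(p - pa, d) / (length * length))
        off = np.linalg.norm(p - (pa + t * d))
        if off > 1e-6 or not (-_GEOM_TOL <= t <= 1.0 + _GEOM_TOL):
            continue
        # heading must be parallel to the segment, either way round
        along = d / length
        dot = float(np.dot(h, along))
        if abs(abs(dot) - 1.0) > 1e-9:
            raise MazeValidationError(
                f"wormhole {what} pose at ({pose.x}, {pose.y}) is not aligned "
                f"with segment {seg}"
            )
        return (a, b) if dot > 0 else (b, a)
    raise MazeValidationError(
        f"wormhole {what} pose at ({pose.x}, {pose.y}) lies on no segment"
    )


# ---------------------------------------------------------------------------
# traversal links
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Link:
    """Directed traversable connection between two corners.

    ``dep_heading``/``arr_heading`` are world headings when leaving the
    first corner and when arriving at the second; for a plain segment
    they coincide. ``wormhole`` is set when the link crosses one.
    """

    a: int
    b: int
    distance: float
    dep_heading: float
    arr_heading: float
    wormhole: Wormhole | None = None


def _segment_links(spec: MazeSpec) -> dict[tuple[int, int], _Link]:
    links: dict[tuple[int, int], _Link] = {}
    for a, b in spec.segments:
        pa, pb = spec.corner_xy(a), spec.corner_xy(b)
        d = float(np.linalg.norm(pb - pa))
        hab = direction_deg(pa, pb)
        hba = wrap_signed_deg(hab + 180.0)
        links[(a, b)] = _Link(a, b, d, hab, hab)
        links[(b, a)] = _Link(b, a, d, hba, hba)
    return links


def wormhole_links(spec: MazeSpec) -> dict[tuple[int, int], _Link]:
    """Directed corner-to-corner links implied by the wormholes.

    Each authored wormhole contributes the forward link (corner behind
    the entry -> corner ahead of the exit) and, implicitly, the reverse
    crossing. The experienced distance is entry-approach plus
    exit-runout: "shortened but not zero".
    """
    links: dict[tuple[int, int], _Link] = {}
    for wh in spec.wormholes:
        for w in (wh, wh.reversed()):
            behind, _ahead_in = _locate_pose_on_segment(spec, w.entry, "entry")
            _behind_out, ahead = _locate_pose_on_segment(spec, w.exit, "exit")
            d_in = float(np.linalg.norm(w.entry.xy - spec.corner_xy(behind)))
            d_out = float(np.linalg.norm(spec.corner_xy(ahead) - w.exit.xy))
            dist = d_in + d_out
            if dist <= _GEOM_TOL:
                raise MazeValidationError(
                    f"wormhole link {behind}->{ahead} has zero experienced length"
                )
            links[(behind, ahead)] = _Link(
                behind, ahead, dist, w.entry.heading_deg, w.exit.heading_deg, w
            )
    return links


def traversal_links(
    spec: MazeSpec, use_wormholes: bool = True
) -> dict[tuple[int, int], _Link]:
    """All directed links a walker can take (wormholes override segments)."""
    links = _segment_links(spec)
    if use_wormholes and spec.wormholes:
        links.update(wormhole_links(spec))
    return links


def departure_direction(
    spec: MazeSpec, a: int, b: int, use_wormholes: bool = True
) -> float:
    """World heading of a walker leaving corner ``a`` toward corner ``b``."""
    links = traversal_links(spec, use_wormholes)
    try:
        return links[(a, b)].dep_heading
    except KeyError:
        raise RouteError(f"corners {a} and {b} are not connected") from None


def arrival_direction(
    spec: MazeSpec, a: int, b: int, use_wormholes: bool = True
) -> float:
    """World heading of a walker arriving at corner ``b`` from corner ``a``."""
    links = traversal_links(spec, use_wormholes)
    try:
        return links[(a, b)].arr_heading
    except KeyError:
        raise RouteError(f"corners {a} and {b} are not connected") from None


# ---------------------------------------------------------------------------
# traversal
# ---------------------------------------------------------------------------


def traverse(
    spec: MazeSpec, route: Sequence[int], use_wormholes: bool = True
) -> list[EgomotionStep]:
    """Measure the egomotion (distances, heading changes) along a route.

    The route is a sequence of corner ids; consecutive corners must be
    connected by a segment or a wormhole crossing. Turns are recorded at
    interior corners; crossing a wormhole contributes no perceived turn,
    but the wormhole's rotation silently re-orients the walker in the
    world, so integrated egomotion diverges from the true layout beyond
    that point.
    """
    if len(route) < 2:
        raise RouteError("route needs at least two corners")
    links = traversal_links(spec, use_wormholes)
    legs: list[_Link] = []
    for a, b in zip(route[:-1], route[1:]):
        try:
            legs.append(links[(a, b)])
        except KeyError:
            raise RouteError(f"route corners {a} and {b} are not adjacent") from None
    steps: list[EgomotionStep] = []
    for i, leg in enumerate(legs):
        if i + 1 < len(legs):
            nxt = legs[i + 1]
            if nxt.a == leg.b and nxt.b == leg.a:
                turn = 180.0  # backtrack: exactly 180 by construction
            else:
                turn = wrap_signed_deg(nxt.dep_heading - leg.arr_heading)
        else:
            turn = None
        steps.append(EgomotionStep(leg.distance, turn))
    return steps


def dead_reckon(
    steps: Iterable[EgomotionStep], start_xy=(0.0, 0.0), start_heading: float = 0.0
) -> list[np.ndarray]:
    """Integrate egomotion steps into positions (path integration).

    Returns the list of positions visited, starting at ``start_xy``.
    In a wormhole-free maze this reproduces the ground-truth corner
    coordinates when seeded with the true initial pose; through a
    wormhole it does not — the defining mismatch of a non-Euclidean
    environment.
    """
    pos = np.array(start_xy, dtype=float)
    heading = float(start_heading)
    out = [pos.copy()]
    for step in steps:
        pos = pos + step.distance * unit_vector(heading)
        out.append(pos.copy())
        if step.turn_deg is not None:
            heading += step.turn_deg
    return out


# ---------------------------------------------------------------------------
# objects
# ---------------------------------------------------------------------------


def object_position(spec: MazeSpec, name: str) -> np.ndarray:
    """Ground-truth planar position of an object."""
    loc = spec.objects[name]
    if loc.corner is not None:
        return spec.corner_xy(loc.corner)
    a, b = loc.segment
    return (1.0 - loc.frac) * spec.corner_xy(a) + loc.frac * spec.corner_xy(b)


def resolve_object(spec: MazeSpec, name: str) -> int:
    """Corner id an object snaps to (nearest segment endpoint)."""
    loc = spec.objects[name]
    if loc.corner is not None:
        return loc.corner
    a, b = loc.segment
    return a if loc.frac <= 0.5 else b


def insert_object_corners(spec: MazeSpec) -> MazeSpec:
    """Return a maze in which mid-segment objects become real corners.

    Each object located at 0 < frac < 1 along a segment splits that
    segment in two at the object's position, so the object can be
    carried as a graph vertex instead of being snapped.
    """
    corners = dict(spec.corners)
    segments = [tuple(s) for s in spec.segments]
    objects = dict(spec.objects)
    next_id = max(corners) + 1
    for name, loc in spec.objects.items():
        if loc.corner is not None:
            continue
        key = _segment_key(loc.segment)
        pos = object_position(spec, name)
        seg = next(
            s for s in segments if _segment_key(s) == key
        )
        segments.remove(seg)
        a, b = loc.segment
        corners[next_id] = (float(pos[0]), float(pos[1]))
        segments.extend([(a, next_id), (next_id, b)])
        objects[name] = ObjectLocation(corner=next_id)
        next_id += 1
    return validate_maze(
        replace(
            spec,
            corners=corners,
            segments=tuple(segments),
            objects=objects,
        )
    )


# ---------------------------------------------------------------------------
# JSON round-trip
# ---------------------------------------------------------------------------


def maze_to_dict(spec: MazeSpec) -> dict:
    return {
        "corners": [[cid, x, y] for cid, (x, y) in sorted(spec.corners.items())],
        "segments": [list(s) for s in spec.segments],
        "wormholes": [
            {
                "entry": [w.entry.x, w.entry.y, w.entry.heading_deg],
                "exit": [w.exit.x, w.exit.y, w.exit.heading_deg],
                "rotation_deg": w.rotation_deg,
            }
            for w in spec.wormholes
        ],
        "objects": {
            name: (
                {"corner": loc.corner}
                if loc.corner is not None
                else {"segment": list(loc.segment), "frac": loc.frac}
            )
            for name, loc in spec.objects.items()
        },
        "control_corners": sorted(spec.control_corners),
    }


def maze_from_dict(doc: dict) -> MazeSpec:
    corners = {}
    for cid, x, y in doc["corners"]:
        if cid in corners:
            raise MazeValidationError(f"duplicate corner id {cid}")
        corners[int(cid)] = (float(x), float(y))
    objects = {}
    for name, loc in doc.get("objects", {}).items():
        if "corner" in loc:
            objects[name] = ObjectLocation(corner=int(loc["corner"]))
        else:
            objects[name] = ObjectLocation(
                segment=tuple(loc["segment"]), frac=float(loc["frac"])
            )
    spec = MazeSpec(
        corners=corners,
        segments=tuple(tuple(int(v) for v in s) for s in doc["segments"]),
        wormholes=tuple(
            Wormhole(
                entry=Pose(*w["entry"]),
                exit=Pose(*w["exit"]),
                rotation_deg=float(w["rotation_deg"]),
            )
            for w in doc.get("wormholes", [])
        ),
        objects=objects,
        control_corners=frozenset(doc.get("control_corners", [])),
    )
    return validate_maze(spec)


def write_maze_json(spec: MazeSpec, path) -> None:
    with open(path, "w") as fh:
        json.dump(maze_to_dict(spec), fh, indent=1)
        fh.write("\n")


def read_maze_json(path) -> MazeSpec:
    with open(path) as fh:
        return maze_from_dict(json.load(fh))
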