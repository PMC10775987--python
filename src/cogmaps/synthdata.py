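"""Synthetic mazes and synthetic subject estimate tables.

Two study designs are emulated so the whole pipeline can be exercised
without any downloaded data:

* ``route_finding`` — 10 subjects x 4 object pairs x 2 directions
  = 80 directional estimates;
* ``rips_folds`` — 11 subjects x 8 start objects x 3 targets
  = 264 directional estimates.

Estimates are a generative model's shortcut predictions perturbed by
von Mises angular noise; an optional second concentration adds a
per-subject bias so within-subject spread can exceed between-subject
spread, as in human data.

The wormhole replica maze is a schematic irregular corridor layout: 42
corners (ids 12 and 35 exist only in the control variant), two
wormholes whose crossings impose a +/-90 degree rotation, eight start
objects and three target objects. It reproduces the *structure* of the
original wormhole environment — corner count, control vertices,
wormhole count and rotation, corridor-like (sparsely looped) topology —
not its exact corridor lengths, which were never published.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import maze as mz
from .maze import MazeSpec, ObjectLocation, Pose, Wormhole

__all__ = [
    "StudyDesign",
    "EstimateTable",
    "make_euclidean_maze",
    "make_wormhole_replica",
    "generate_estimates",
    "read_estimates_csv",
    "write_estimates_csv",
]


# ---------------------------------------------------------------------------
# study designs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyDesign:
    """Roster of (subject, start, goal) cells an experiment produces."""

    tag: str  # "route_finding" | "rips_folds" | "custom"
    n_subjects: int
    pairs: tuple[tuple[str, str], ...]  # ordered (start, goal) cells per subject

    @property
    def n_rows(self) -> int:
        return self.n_subjects * len(self.pairs)

    @staticmethod
    def route_finding(
        pairs: tuple[tuple[str, str], ...] = (
            ("o2", "o8"),
            ("o3", "o5"),
            ("o1", "o4"),
            ("o6", "o7"),
        ),
        n_subjects: int = 10,
    ) -> "StudyDesign":
        """10 subjects, 4 object pairs, both directions: 80 rows."""
        if len(pairs) != 4:
            raise ValueError("route_finding uses exactly 4 object pairs")
        both = tuple(pairs) + tuple((b, a) for a, b in pairs)
        return StudyDesign("route_finding", n_subjects, both)

    @staticmethod
    def rips_folds(
        starts: tuple[str, ...] = ("o1", "o2", "o3", "o4", "o5", "o6", "o7", "o8"),
        targets: tuple[str, ...] = ("t1", "t2", "t3"),
        n_subjects: int = 11,
    ) -> "StudyDesign":
        """11 subjects, 8 starts x 3 targets: 264 rows."""
        if len(starts) != 8 or len(targets) != 3:
            raise ValueError("rips_folds uses 8 starts and 3 targets")
        cells = tuple((s, t) for s in starts for t in targets)
        return StudyDesign("rips_folds", n_subjects, cells)


@dataclass
class EstimateTable:
    """Per-subject global shortcut-direction estimates.

    ``data`` has columns subject, start, goal, estimate_deg (global
    directions in [0, 360)); ``meta`` records how the table was made.
    """

    data: pd.DataFrame
    design_tag: str = "custom"
    meta: dict = field(default_factory=dict)

    COLUMNS = ("subject", "start", "goal", "estimate_deg")

    def __post_init__(self):
        missing = [c for c in self.COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"estimate table is missing columns {missing}")


# ---------------------------------------------------------------------------
# maze generators
# ---------------------------------------------------------------------------


def make_euclidean_maze(seed: int, n_corners: int = 30) -> MazeSpec:
    """Random connected rectilinear corridor maze without wormholes.

    Grows a random blob of unit-grid cells and connects every pair of
    adjacent cells by a corridor, which yields loops (well-constrained
    embeddings) as well as straight runs and turns. Reproducible by
    seed; validated before return.
    """
    if n_corners < 3:
        raise ValueError("need at least 3 corners for a meaningful maze")
    rng = np.random.default_rng(seed)
    cells = {(0, 0)}
    frontier = [(0, 0)]
    moves = np.array([(1, 0), (-1, 0), (0, 1), (0, -1)])
    while len(cells) < n_corners:
        base = frontier[rng.integers(len(frontier))]
        step = moves[rng.integers(4)]
        cand = (base[0] + int(step[0]), base[1] + int(step[1]))
        if cand not in cells:
            cells.add(cand)
            frontier.append(cand)
    ordered = sorted(cells)
    ids = {cell: n + 1 for n, cell in enumerate(ordered)}
    corners = {ids[c]: (float(c[0]), float(c[1])) for c in ordered}
    segments = []
    for (x, y), cid in ids.items():
        for dx, dy in ((1, 0), (0, 1)):
            nb = (x + dx, y + dy)
            if nb in ids:
                segments.append((cid, ids[nb]))
    # a few spread-out objects at extreme cells
    corner_list = sorted(corners)
    objects = {
        "o1": ObjectLocation(corner=corner_list[0]),
        "o2": ObjectLocation(corner=corner_list[-1]),
        "o3": ObjectLocation(corner=corner_list[len(corner_list) // 2]),
    }
    return mz.validate_maze(
        MazeSpec(corners=corners, segments=tuple(segments), objects=objects)
    )


# Replica corner table: id -> (x, y). Ids 12 and 35 are the control-only
# corners sitting in the middle of the two wormhole corridors. The layout
# is an irregular corridor network (hedge-maze-like: varied corridor
# lengths and oblique junction angles around a loose grid skeleton);
# corners 37 and 31 are placed so that each wormhole's exit corridor is
# exactly perpendicular to its entry corridor, which pins the imposed
# rotation at +/-90 degrees. Coordinates are frozen at full precision so
# those exact angle relations survive serialization.
_REPLICA_CORNERS: Mapping[int, tuple[float, float]] = {
    1: (-0.5800911659989259, -0.3684652907654604),
    2: (2.4217842512889556, 0.11502685049011485),
    3: (3.431780099136559, -0.09362228366893666),
    4: (5.970671817397168, -0.47636551950809),
    5: (8.3284080119729, -0.5408591721100352),
    6: (-0.15228053330607316, 2.023436255669909),
    7: (1.9028792285798488, 2.1215180000133973),
    8: (4.332972902209024, 2.6387741567705376),
    9: (5.697881629248308, 2.2079660899117552),
    10: (8.274702395338217, 1.709809048617482),
    11: (-0.6979138830876294, 4.662844384672978),
    12: (11.717761712223625, -4.2604195971519285),
    13: (2.5483954986232202, 4.119228115847271),
    14: (3.959833531254564, 4.3825878135083425),
    15: (5.34248441072746, 4.289751133917873),
    16: (7.823941366869859, 3.427193798905961),
    17: (0.2247000943990527, 6.604049396637897),
    18: (1.5900676353134018, 6.18212627969948),
    19: (3.7174283269203947, 6.338459352097063),
    20: (6.311030731398964, 5.606201594396326),
    21: (8.461841623984037, 6.220713095222541),
    22: (0.2559184710044903, -1.551893949761251),
    23: (1.9000020660178467, -1.6378123543831133),
    24: (8.529872258532755, -2.556752109309096),
    25: (6.4896756724526155, -2.148501734314731),
    26: (-0.02844250708281504, 7.504868397661478),
    27: (2.277796882925931, 7.708770062382992),
    28: (8.519594809711025, 7.685524127727308),
    29: (6.086533606223246, 7.859518709582634),
    30: (10.158073288663415, 1.5752949356809731),
    31: (10.370492715369457, 4.179688417539195),
    32: (-1.6468872142830115, 2.093769024234077),
    33: (-1.410488451803898, 3.5880850675206264),
    34: (4.491261574428312, 7.536582235857921),
    35: (10.650100809251992, 10.173169819348612),
    36: (4.14963730321402, -1.3412177316143268),
    37: (12.49641427774895, 1.688840876402816),
    38: (11.375731261019352, 5.817000828532188),
    39: (-2.5811473189683447, 5.5709386140517205),
    40: (3.599413786969006, 10.502098705032266),
    41: (-0.5225430283943724, 9.71546087574523),
    42: (5.989985770494066, -3.5107554243346484),
}

_REPLICA_SEGMENTS: tuple[tuple[int, int], ...] = (
    # corridor skeleton: mostly tree-like with a handful of loops, so
    # the wormhole-frustrated cycles are long, as in a hedge maze
    (1, 2), (2, 3), (3, 4), (4, 5),
    (9, 10),
    (11, 13),
    (19, 20), (20, 21),
    (1, 6), (6, 11), (11, 17),
    (2, 7), (13, 18),
    (3, 8), (8, 14),
    (4, 9), (15, 20), (15, 16),
    (5, 10), (10, 16), (16, 21),
    # dead-end arms carrying the objects
    (1, 22), (22, 23),
    (5, 24), (24, 25), (25, 42),
    (17, 26), (26, 27),
    (21, 28), (28, 29),
    (6, 32), (32, 33), (33, 39),
    (19, 34), (34, 40), (40, 41),
    (3, 36),
    (10, 30), (30, 31), (30, 37), (37, 38),
    # wormhole corridors through the control-only corners 12 and 35
    (42, 12), (12, 37),
    (40, 35), (35, 31),
)

_REPLICA_WORMHOLES: tuple[Wormhole, ...] = (
    # corridor 42 -> 12 -> 37: entering just past corner 42 teleports to
    # just short of corner 37, with the heading rotated by +90.
    Wormhole(
        entry=Pose(6.98152918275319, -3.6405308519222026, -7.456615333165138),
        exit=Pose(12.366638850161396, 0.6972974641436919, 82.54338466683487),
        rotation_deg=90.0,
    ),
    # corridor 40 -> 35 -> 31: entering just past corner 40 teleports to
    # just short of corner 31, with the heading rotated by -90.
    Wormhole(
        entry=Pose(4.5983273539372425, 10.455497356051843, -2.6710279839497435),
        exit=Pose(10.417094064349879, 5.178601984507431, -92.67102798394974),
        rotation_deg=-90.0,
    ),
)

_REPLICA_OBJECTS: Mapping[str, int] = {
    "o1": 23, "o2": 25, "o3": 27, "o4": 29,
    "o5": 31, "o6": 33, "o7": 36, "o8": 38,
    "t1": 34, "t2": 39, "t3": 42,
}


def make_wormhole_replica(seed: int = 0) -> MazeSpec:
    """Schematic wormhole maze: 42 corners, 2 control-only, 2 wormholes.

    The layout is fixed (the seed is accepted for API symmetry with the
    other generators but does not alter it): the maze is a pinned study
    condition, not a random draw. Crossing either wormhole teleports
    the walker across the maze with a 90-degree rotation, so the
    wormhole-variant graph has 40 vertices and carries locally measured
    labels that admit no consistent planar configuration.
    """
    spec = MazeSpec(
        corners=dict(_REPLICA_CORNERS),
        segments=_REPLICA_SEGMENTS,
        wormholes=_REPLICA_WORMHOLES,
        objects={k: ObjectLocation(corner=v) for k, v in _REPLICA_OBJECTS.items()},
        control_corners=frozenset({12, 35}),
    )
    return mz.validate_maze(spec)


# ---------------------------------------------------------------------------
# estimate generation
# ---------------------------------------------------------------------------


def generate_estimates(
    predictions: Mapping[tuple[str, str], float],
    design: StudyDesign,
    kappa: float,
    seed: int,
    kappa_between: float | None = None,
) -> EstimateTable:
    """Draw a synthetic estimate table around a model's predictions.

    ``predictions`` maps (start, goal) object pairs to the generative
    model's global shortcut direction in degrees. Every design cell
    receives that prediction plus von Mises(0, kappa) noise; if
    ``kappa_between`` is given, each subject additionally carries a von
    Mises(0, kappa_between) constant bias, separating within- from
    between-subject spread. ``kappa = inf`` means noiseless.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    missing = [p for p in design.pairs if p not in predictions]
    if missing:
        raise ValueError(f"no prediction for design cells {missing}")
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(1, design.n_subjects + 1):
        if kappa_between is not None and np.isfinite(kappa_between):
            bias = float(np.degrees(rng.vonmises(0.0, kappa_between)))
        else:
            bias = 0.0
        for start, goal in design.pairs:
            pred = predictions[(start, goal)]
            if np.isinf(kappa):
                noise = 0.0
            else:
                noise = float(np.degrees(rng.vonmises(0.0, kappa)))
            rows.append(
                {
                    "subject": f"s{s:02d}",
                    "start": start,
                    "goal": goal,
                    "estimate_deg": float(np.mod(pred + bias + noise, 360.0)),
                }
            )
    meta = {
        "design": design.tag,
        "kappa": None if np.isinf(kappa) else kappa,
        "kappa_between": kappa_between,
        "seed": seed,
    }
    return EstimateTable(
        data=pd.DataFrame(rows, columns=list(EstimateTable.COLUMNS)),
        design_tag=design.tag,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------


def write_estimates_csv(table: EstimateTable, path, sidecar_path=None) -> None:
    table.data.to_csv(path, index=False)  # repr floats: lossless round-trip
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump({"design": table.design_tag, **table.meta}, fh, indent=1)
            fh.write("\n")


def read_estimates_csv(path, sidecar_path=None) -> EstimateTable:
    df = pd.read_csv(
        path,
        dtype={"subject": str, "start": str, "goal": str},
        float_precision="round_trip",
    )
    meta = {}
    if sidecar_path is not None:
        with open(sidecar_path) as fh:
            meta = json.load(fh)
    return EstimateTable(
        data=df, design_tag=meta.get("design", "custom"), meta=meta
    )
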