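"""Shared fixtures: small mazes, the replica, and prebuilt graphs.

Expensive artifacts (replica graphs, multi-restart embeddings) are
session-scoped so the suite builds each of them once.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from cogmaps import (
    EmbedConfig,
    MazeSpec,
    ObjectLocation,
    Variant,
    build_graph,
    embed_graph,
    make_euclidean_maze,
    make_wormhole_replica,
    validate_maze,
)

settings.register_profile("ci", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def replica():
    return make_wormhole_replica()


@pytest.fixture(scope="session")
def replica_graph(replica):
    return build_graph(replica, Variant.WORMHOLE)


@pytest.fixture(scope="session")
def replica_control_graph(replica):
    return build_graph(replica, Variant.CONTROL)


@pytest.fixture(scope="session")
def replica_minima(replica_graph):
    """Distinct stress minima of the replica graph, 60 restarts."""
    return embed_graph(replica_graph, EmbedConfig(n_restarts=60, seed=11))


@pytest.fixture(scope="session")
def euclid_maze():
    return make_euclidean_maze(seed=7, n_corners=20)


@pytest.fixture(scope="session")
def euclid_graph(euclid_maze):
    return build_graph(euclid_maze, Variant.CONTROL)


@pytest.fixture
def corridor():
    """Three collinear corners, two unit segments."""
    return validate_maze(
        MazeSpec(
            corners={1: (0.0, 0.0), 2: (1.0, 0.0), 3: (2.0, 0.0)},
            segments=((1, 2), (2, 3)),
        )
    )


@pytest.fixture
def square():
    """Unit square loop."""
    return validate_maze(
        MazeSpec(
            corners={1: (0.0, 0.0), 2: (1.0, 0.0), 3: (1.0, 1.0), 4: (0.0, 1.0)},
            segments=((1, 2), (2, 3), (3, 4), (4, 1)),
            objects={"a": ObjectLocation(corner=1), "b": ObjectLocation(corner=3)},
        )
    )
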