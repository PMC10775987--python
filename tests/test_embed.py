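"""Stress function, analytic gradient, multi-restart embedding, alignment."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cogmaps import (
    EmbedConfig,
    Embedding,
    EmbedError,
    LabeledGraph,
    Variant,
    align,
    build_graph,
    embed_graph,
    make_euclidean_maze,
    procrustes_distance,
    stress,
    stress_gradient,
)
from cogmaps.embed import _StressProblem
from cogmaps.geometry import rotation_matrix


@pytest.fixture
def right_turn_graph():
    """Single right-angle triplet (1,2,3): d=1,1, alpha=+90."""
    return LabeledGraph(
        vertices=[1, 2, 3],
        edges={(1, 2): 1.0, (2, 3): 1.0},
        triplets={(1, 2, 3): 90.0, (3, 2, 1): -90.0, (1, 2, 1): 180.0,
                  (3, 2, 3): 180.0, (2, 1, 2): 180.0, (2, 3, 2): 180.0},
    )


class TestStress:
    def test_exact_right_turn_has_zero_stress(self, right_turn_graph):
        g = LabeledGraph(
            vertices=[1, 2, 3],
            edges=right_turn_graph.edges,
            triplets={(1, 2, 3): 90.0},
        )
        X = {1: (0.0, 0.0), 2: (1.0, 0.0), 3: (1.0, 1.0)}
        assert stress(X, g) == pytest.approx(0.0, abs=1e-15)

    def test_backtrack_pair_has_zero_stress(self):
        g = LabeledGraph(
            vertices=[1, 2], edges={(1, 2): 1.0}, triplets={(1, 2, 1): 180.0}
        )
        assert stress({1: (0.0, 0.0), 2: (1.0, 0.0)}, g) == pytest.approx(0.0)

    def test_perturbed_right_turn_stress_value(self):
        """Hand evaluation: residuals 0.1 (dot) and -0.1 (cross)."""
        g = LabeledGraph(
            vertices=[1, 2, 3],
            edges={(1, 2): 1.0, (2, 3): 1.0},
            triplets={(1, 2, 3): 90.0},
        )
        X = {1: (0.0, 0.0), 2: (1.0, 0.0), 3: (1.1, 0.9)}
        assert stress(X, g) == pytest.approx(0.02)

    def test_missing_coordinate_raises(self, right_turn_graph):
        with pytest.raises(EmbedError, match="missing coordinates"):
            stress({1: (0.0, 0.0), 2: (1.0, 0.0)}, right_turn_graph)

    def test_rotation_translation_invariance(self, euclid_graph):
        rng = np.random.default_rng(0)
        X = {v: rng.normal(size=2) for v in euclid_graph.vertices}
        R = rotation_matrix(37.5)
        t = np.array([3.1, -2.2])
        Y = {v: R @ X[v] + t for v in X}
        assert stress(Y, euclid_graph) == pytest.approx(
            stress(X, euclid_graph), rel=1e-9
        )

    def test_reflection_changes_stress(self, euclid_graph):
        """The signed-area term flips under reflection, so stress is
        generally not mirror invariant."""
        rng = np.random.default_rng(1)
        X = {v: rng.normal(size=2) for v in euclid_graph.vertices}
        Y = {v: np.array([X[v][0], -X[v][1]]) for v in X}
        assert abs(stress(Y, euclid_graph) - stress(X, euclid_graph)) > 1e-6

    @given(st.integers(0, 10_000))
    def test_dot_cross_magnitude_identity(self, seed):
        """(u.w)^2 + (u x w)^2 == |u|^2 |w|^2 for planar vectors."""
        rng = np.random.default_rng(seed)
        u, w = rng.normal(size=2), rng.normal(size=2)
        dot = float(u @ w)
        cross = u[0] * w[1] - u[1] * w[0]
        assert dot**2 + cross**2 == pytest.approx(
            (u @ u) * (w @ w), rel=1e-12
        )


class TestGradient:
    def test_zero_at_global_minimum(self, euclid_maze, euclid_graph):
        gt = {v: euclid_maze.corner_xy(v) for v in euclid_graph.vertices}
        g = stress_gradient(gt, euclid_graph)
        assert max(np.linalg.norm(v) for v in g.values()) < 1e-8

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_finite_differences(self, euclid_graph, seed):
        cfg = EmbedConfig()
        prob = _StressProblem(euclid_graph, cfg)
        rng = np.random.default_rng(seed)
        x = rng.normal(scale=2.0, size=2 * prob.n)
        _, grad = prob.value_and_grad(x)
        eps = 1e-6
        num = np.empty_like(x)
        for i in range(x.size):
            xp, xm = x.copy(), x.copy()
            xp[i] += eps
            xm[i] -= eps
            num[i] = (prob.value(xp) - prob.value(xm)) / (2 * eps)
        assert np.max(np.abs(grad - num)) / np.max(np.abs(num)) < 1e-5

    def test_zero_weights_give_zero_gradient(self, euclid_graph):
        cfg = EmbedConfig(lambda1=0.0, lambda2=0.0)
        rng = np.random.default_rng(3)
        X = {v: rng.normal(size=2) for v in euclid_graph.vertices}
        g = stress_gradient(X, euclid_graph, cfg)
        assert max(np.linalg.norm(v) for v in g.values()) == 0.0


class TestEmbedGraph:
    def test_square_graph_recovers_consistent_layout(self, square):
        g = build_graph(square, Variant.CONTROL)
        minima = embed_graph(g, EmbedConfig(n_restarts=20, seed=0))
        assert minima[0].stress < 1e-6
        assert len(minima) == 1

    def test_single_triplet_reaches_zero_stress(self, right_turn_graph):
        minima = embed_graph(right_turn_graph, EmbedConfig(n_restarts=5, seed=1))
        assert minima[0].stress < 1e-10

    def test_final_stress_never_exceeds_initial(self, euclid_graph):
        for m in embed_graph(euclid_graph, EmbedConfig(n_restarts=10, seed=2)):
            assert m.stress <= m.initial_stress

    def test_reproducible_given_seed(self, right_turn_graph):
        a = embed_graph(right_turn_graph, EmbedConfig(n_restarts=3, seed=9))
        b = embed_graph(right_turn_graph, EmbedConfig(n_restarts=3, seed=9))
        assert a[0].stress == b[0].stress
        for v in a[0].coordinates:
            assert a[0].coordinates[v] == pytest.approx(b[0].coordinates[v])

    def test_wormhole_graph_has_residual_stress_and_two_minima(self, replica_minima):
        assert all(m.stress > 1.0 for m in replica_minima)
        assert len(replica_minima) >= 2


class TestAlignment:
    def _embedding(self, coords):
        return Embedding(
            coordinates={k: np.asarray(v, float) for k, v in coords.items()},
            stress=0.0,
        )

    def test_align_to_self_is_identity(self):
        e = self._embedding({1: (0.3, 1.0), 2: (2.0, -1.0), 3: (4.0, 0.5)})
        out = align(e, e)
        for v in e.coordinates:
            assert out.coordinates[v] == pytest.approx(e.coordinates[v], abs=1e-12)

    def test_reference_mode_undoes_rigid_motion(self):
        rng = np.random.default_rng(5)
        e = self._embedding({v: rng.normal(size=2) for v in range(6)})
        R = rotation_matrix(123.4)
        t = np.array([-4.0, 2.5])
        moved = self._embedding({v: R @ e.coordinates[v] + t for v in e.coordinates})
        back = align(moved, e)
        assert procrustes_distance(back, e) < 1e-9

    def test_edge_mode_makes_edge_horizontal(self):
        e = self._embedding({2: (1.0, 2.0), 3: (3.0, 5.0), 4: (0.0, 1.0)})
        out = align(e, (2, 3))
        assert out.coordinates[2] == pytest.approx([0.0, 0.0], abs=1e-12)
        assert out.coordinates[3][1] == pytest.approx(0.0, abs=1e-12)
        assert out.coordinates[3][0] > 0

    def test_zero_length_reference_edge_fails(self):
        e = self._embedding({1: (1.0, 1.0), 2: (1.0, 1.0)})
        with pytest.raises(EmbedError, match="zero length"):
            align(e, (1, 2))


class TestProcrustes:
    def test_identical_configurations_give_zero(self):
        e = Embedding({1: np.array([0.0, 0.0]), 2: np.array([1.0, 2.0])}, 0.0)
        assert procrustes_distance(e, e) == pytest.approx(0.0, abs=1e-12)

    def test_reflection_detected_when_disallowed(self):
        """A chiral triangle and its mirror image cannot be superposed by
        a proper rotation."""
        tri = {1: np.array([0.0, 0.0]), 2: np.array([3.0, 0.0]), 3: np.array([0.0, 1.0])}
        mirror = {k: np.array([v[0], -v[1]]) for k, v in tri.items()}
        assert procrustes_distance(tri, mirror, allow_reflection=False) > 0.1
        assert procrustes_distance(tri, mirror, allow_reflection=True) < 1e-12

    def test_mismatched_vertex_sets_fail(self):
        a = Embedding({1: np.zeros(2)}, 0.0)
        b = Embedding({2: np.zeros(2)}, 0.0)
        with pytest.raises(EmbedError, match="different vertex sets"):
            procrustes_distance(a, b)
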