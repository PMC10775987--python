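"""Euclidean embedding of a labeled graph by triplet-stress minimization.

Every labeled triplet (i, j, k) constrains the embedded coordinates: if
u = x_j - x_i is the displacement into j and w = x_k - x_j the
displacement out of j, then a perfectly consistent configuration
satisfies

    u . w   = d_ij * d_jk * cos(alpha_ijk)        (dot product)
    u (x) w = d_ij * d_jk * sin(alpha_ijk)        (planar cross product)

where (x) is the scalar cross product u1*w2 - u2*w1 (twice the signed
triangle area). The stress is the weighted sum of squared residuals of
these two constraints over all triplets. For a graph measured in a
planar maze the global minimum is zero and recovers the layout up to a
rigid motion; for a wormhole graph no consistent configuration exists
and a strictly positive residual stress remains.

The sign convention (w points *out of* j) makes backtracking triplets
(i, j, i) carry alpha = 180 consistently: u . w = -|u|^2 matches
d^2 cos(180).

Minimization is multi-restart quasi-Newton (L-BFGS-B with the analytic
gradient) from uniform random initial configurations, followed by a
deterministic Gauss-Newton polish of each solution; distinct local
minima are identified by stress value and rigid-superposition distance.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares, minimize

from .geometry import direction_deg, rigid_superpose, rotation_matrix
from .graphbuild import LabeledGraph

__all__ = [
    "EmbedConfig",
    "Embedding",
    "EmbedError",
    "stress",
    "stress_gradient",
    "embed_graph",
    "align",
    "procrustes_distance",
    "read_embedding_csv",
    "write_embedding_csv",
]


class EmbedError(RuntimeError):
    pass


@dataclass(frozen=True)
class EmbedConfig:
    """Knobs of the stress minimization.

    lambda1/lambda2 weigh the dot-product and cross-product residuals
    (both 1 by default); initial coordinates are uniform on
    (init_lo, init_hi)^2, the conventional (0, 20)^2 by default.
    """

    lambda1: float = 1.0
    lambda2: float = 1.0
    n_restarts: int = 100
    init_lo: float = 0.0
    init_hi: float = 20.0
    seed: int = 0
    gtol: float = 1e-8
    max_iter: int = 5000
    polish: bool = True
    dedup_stress_rtol: float = 1e-6
    dedup_rmsd_factor: float = 1e-4

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda weights must be nonnegative")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if not self.init_hi > self.init_lo:
            raise ValueError("init range must be nonempty")


@dataclass
class Embedding:
    """2D coordinates per vertex plus optimization metadata."""

    coordinates: dict[int, np.ndarray]
    stress: float
    restart_index: int = -1
    converged: bool = True
    seed: int | None = None
    initial_stress: float | None = None
    n_hits: int = 1

    def array(self, order: Sequence[int]) -> np.ndarray:
        return np.array([self.coordinates[v] for v in order], dtype=float)

    def direction(self, a: int, b: int) -> float:
        """Global direction from vertex a to vertex b in this frame."""
        return direction_deg(self.coordinates[a], self.coordinates[b])


# ---------------------------------------------------------------------------
# stress, gradient, residuals
# ---------------------------------------------------------------------------


class _StressProblem:
    """Vectorized triplet constraints for a fixed vertex ordering."""

    def __init__(self, graph: LabeledGraph, config: EmbedConfig):
        if not graph.triplets:
            raise EmbedError("graph has no labeled triplets")
        self.order = list(graph.vertices)
        index = {v: n for n, v in enumerate(self.order)}
        trips = sorted(graph.triplets.items())
        self.I = np.array([index[i] for (i, _, _), _ in trips])
        self.J = np.array([index[j] for (_, j, _), _ in trips])
        self.K = np.array([index[k] for (_, _, k), _ in trips])
        dd = np.array(
            [graph.distance(i, j) * graph.distance(j, k) for (i, j, k), _ in trips]
        )
        alpha = np.radians(np.array([a for _, a in trips]))
        self.target_dot = dd * np.cos(alpha)
        self.target_cross = dd * np.sin(alpha)
        self.lam1 = config.lambda1
        self.lam2 = config.lambda2
        self.n = len(self.order)

    def _uv(self, x: np.ndarray):
        X = x.reshape(self.n, 2)
        u = X[self.J] - X[self.I]
        w = X[self.K] - X[self.J]
        return u, w

    def residuals(self, x: np.ndarray) -> np.ndarray:
        u, w = self._uv(x)
        dot = np.einsum("ij,ij->i", u, w)
        cross = u[:, 0] * w[:, 1] - u[:, 1] * w[:, 0]
        return np.concatenate(
            [
                np.sqrt(self.lam1) * (dot - self.target_dot),
                np.sqrt(self.lam2) * (cross - self.target_cross),
            ]
        )

    def value(self, x: np.ndarray) -> float:
        r = self.residuals(x)
        return float(r @ r)

    def value_and_grad(self, x: np.ndarray):
        u, w = self._uv(x)
        dot = np.einsum("ij,ij->i", u, w)
        cross = u[:, 0] * w[:, 1] - u[:, 1] * w[:, 0]
        rd = dot - self.target_dot
        rc = cross - self.target_cross
        f = float(self.lam1 * rd @ rd + self.lam2 * rc @ rc)

        g = np.zeros((self.n, 2))
        # d(dot)/dxi = -w ; d(dot)/dxj = w - u ; d(dot)/dxk = u
        cd = (2.0 * self.lam1 * rd)[:, None]
        np.add.at(g, self.I, -cd * w)
        np.add.at(g, self.J, cd * (w - u))
        np.add.at(g, self.K, cd * u)
        # cross c = u1 w2 - u2 w1:
        # dc/du = ( w2, -w1), dc/dw = (-u2, u1)
        cc = 2.0 * self.lam2 * rc
        dcu = np.column_stack([w[:, 1], -w[:, 0]])
        dcw = np.column_stack([-u[:, 1], u[:, 0]])
        np.add.at(g, self.I, -cc[:, None] * dcu)
        np.add.at(g, self.J, cc[:, None] * (dcu - dcw))
        np.add.at(g, self.K, cc[:, None] * dcw)
        return f, g.ravel()

    def jac(self, x: np.ndarray) -> np.ndarray:
        u, w = self._uv(x)
        m = len(self.I)
        J = np.zeros((2 * m, 2 * self.n))
        rows = np.arange(m)
        s1, s2 = np.sqrt(self.lam1), np.sqrt(self.lam2)

        def add(rowblock, cols, vals):
            np.add.at(J, (rowblock[:, None], cols), vals)

        colsI = np.column_stack([2 * self.I, 2 * self.I + 1])
        colsJ = np.column_stack([2 * self.J, 2 * self.J + 1])
        colsK = np.column_stack([2 * self.K, 2 * self.K + 1])
        # dot rows
        add(rows, colsI, -s1 * w)
        add(rows, colsJ, s1 * (w - u))
        add(rows, colsK, s1 * u)
        # cross rows
        dcu = np.column_stack([w[:, 1], -w[:, 0]])
        dcw = np.column_stack([-u[:, 1], u[:, 0]])
        add(rows + m, colsI, -s2 * dcu)
        add(rows + m, colsJ, s2 * (dcu - dcw))
        add(rows + m, colsK, s2 * dcw)
        return J


def _coords_to_array(
    X: Mapping[int, Sequence[float]], order: Sequence[int]
) -> np.ndarray:
    try:
        return np.array([np.asarray(X[v], dtype=float) for v in order])
    except KeyError as err:
        raise EmbedError(f"missing coordinates for vertex {err.args[0]}") from None


def stress(
    X: Mapping[int, Sequence[float]] | Embedding,
    graph: LabeledGraph,
    config: EmbedConfig = EmbedConfig(),
) -> float:
    """Triplet stress of a configuration (lower is better, 0 is perfect)."""
    if isinstance(X, Embedding):
        X = X.coordinates
    prob = _StressProblem(graph, config)
    return prob.value(_coords_to_array(X, prob.order).ravel())


def stress_gradient(
    X: Mapping[int, Sequence[float]] | Embedding,
    graph: LabeledGraph,
    config: EmbedConfig = EmbedConfig(),
) -> dict[int, np.ndarray]:
    """Analytic gradient of the stress with respect to every coordinate."""
    if isinstance(X, Embedding):
        X = X.coordinates
    prob = _StressProblem(graph, config)
    _, g = prob.value_and_grad(_coords_to_array(X, prob.order).ravel())
    g = g.reshape(-1, 2)
    return {v: g[n].copy() for n, v in enumerate(prob.order)}


# ---------------------------------------------------------------------------
# multi-restart minimization
# ---------------------------------------------------------------------------


def _minimize_once(prob: _StressProblem, x0: np.ndarray, config: EmbedConfig):
    res = minimize(
        prob.value_and_grad,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={
            "maxiter": config.max_iter,
            "ftol": 1e-15,
            "gtol": config.gtol,
            "maxcor": 20,
        },
    )
    x, ok = res.x, bool(res.success)
    if config.polish:
        ls = least_squares(
            prob.residuals,
            x,
            jac=prob.jac,
            method="lm" if 2 * len(prob.I) >= 2 * prob.n else "trf",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            max_nfev=200,
        )
        if prob.value(ls.x) <= prob.value(x):
            x, ok = ls.x, ok or bool(ls.success)
    return x, ok


def embed_graph(graph: LabeledGraph, config: EmbedConfig = EmbedConfig()) -> list[Embedding]:
    """Embed a labeled graph from many random starts.

    Returns the distinct local minima found, sorted by stress
    (ascending). Two solutions count as the same minimum when their
    stress values agree to ``dedup_stress_rtol`` and their
    reflection-allowed rigid-superposition RMSD is below
    ``dedup_rmsd_factor`` times the mean edge length. ``n_hits`` on each
    returned embedding counts how many restarts landed there.
    """
    prob = _StressProblem(graph, config)
    rng = np.random.default_rng(config.seed)
    mean_edge = graph.mean_edge_length()
    solutions = []
    failures = []
    for r in range(config.n_restarts):
        x0 = rng.uniform(config.init_lo, config.init_hi, size=2 * prob.n)
        f0 = prob.value(x0)
        try:
            x, ok = _minimize_once(prob, x0, config)
        except Exception as err:  # pragma: no cover - diagnostic path
            failures.append((r, repr(err)))
            continue
        solutions.append((prob.value(x), x, r, ok, f0))
    if not solutions:
        raise EmbedError(f"optimizer failed on every restart: {failures[:5]}")

    solutions.sort(key=lambda s: s[0])
    minima: list[Embedding] = []
    reps: list[np.ndarray] = []
    for f, x, r, ok, f0 in solutions:
        X = x.reshape(prob.n, 2)
        matched = False
        for n_min, (emb, rep) in enumerate(zip(minima, reps)):
            close_f = abs(f - emb.stress) < config.dedup_stress_rtol * (1.0 + emb.stress)
            if close_f:
                _, _, rmsd = rigid_superpose(X, rep, allow_reflection=True)
                if rmsd < config.dedup_rmsd_factor * mean_edge:
                    emb.n_hits += 1
                    # representative: the member reached from the earliest
                    # restart, so reports are reproducible even when two
                    # restarts tie in stress to the last bit
                    if r < emb.restart_index:
                        minima[n_min] = replace(
                            emb,
                            coordinates={
                                v: X[i].copy() for i, v in enumerate(prob.order)
                            },
                            stress=f,
                            restart_index=r,
                            converged=ok,
                            initial_stress=f0,
                            n_hits=emb.n_hits,
                        )
                        reps[n_min] = X.copy()
                    matched = True
                    break
        if not matched:
            minima.append(
                Embedding(
                    coordinates={v: X[n].copy() for n, v in enumerate(prob.order)},
                    stress=f,
                    restart_index=r,
                    converged=ok,
                    seed=config.seed,
                    initial_stress=f0,
                )
            )
            reps.append(X.copy())
    return minima


# ---------------------------------------------------------------------------
# gauge fixing and comparison
# ---------------------------------------------------------------------------


def align(
    embedding: Embedding,
    reference: tuple[int, int] | Embedding,
    allow_reflection: bool = False,
) -> Embedding:
    """Fix the gauge of an embedding.

    Edge mode (``reference`` is a vertex pair (a, b)): rigidly move the
    embedding so vertex a sits at the origin and the edge a -> b is
    horizontal (b on the positive x-axis). Reference mode (``reference``
    is another Embedding over the same vertices): least-squares rigid
    superposition onto it, optionally allowing reflection.
    """
    coords = embedding.coordinates
    if isinstance(reference, Embedding):
        order = sorted(coords)
        if sorted(reference.coordinates) != order:
            raise EmbedError("reference embedding has a different vertex set")
        P = embedding.array(order)
        Q = reference.array(order)
        R, t, _ = rigid_superpose(P, Q, allow_reflection=allow_reflection)
        new = {v: R @ coords[v] + t for v in coords}
    else:
        a, b = reference
        pa, pb = np.asarray(coords[a], float), np.asarray(coords[b], float)
        if np.allclose(pa, pb):
            raise EmbedError(f"reference edge ({a}, {b}) has zero length")
        R = rotation_matrix(-direction_deg(pa, pb))
        new = {v: R @ (np.asarray(coords[v], float) - pa) for v in coords}
    return replace(embedding, coordinates=new)


def procrustes_distance(
    X: Embedding | Mapping[int, Sequence[float]],
    Y: Embedding | Mapping[int, Sequence[float]],
    allow_reflection: bool = False,
) -> float:
    """RMSD between two configurations after optimal rigid superposition."""
    cx = X.coordinates if isinstance(X, Embedding) else X
    cy = Y.coordinates if isinstance(Y, Embedding) else Y
    if sorted(cx) != sorted(cy):
        raise EmbedError("configurations cover different vertex sets")
    order = sorted(cx)
    P = np.array([np.asarray(cx[v], float) for v in order])
    Q = np.array([np.asarray(cy[v], float) for v in order])
    _, _, rmsd = rigid_superpose(P, Q, allow_reflection=allow_reflection)
    return rmsd


# ---------------------------------------------------------------------------
# I/O: CSV coordinates + JSON sidecar
# ---------------------------------------------------------------------------


def write_embedding_csv(embedding: Embedding, path, sidecar_path=None) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["vertex_id", "x", "y"])
        for v in sorted(embedding.coordinates):
            x, y = embedding.coordinates[v]
            writer.writerow([v, repr(float(x)), repr(float(y))])
    if sidecar_path is not None:
        meta = {
            "stress": embedding.stress,
            "restart_index": embedding.restart_index,
            "converged": embedding.converged,
            "seed": embedding.seed,
            "n_hits": embedding.n_hits,
        }
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=1)
            fh.write("\n")


def read_embedding_csv(path, sidecar_path=None) -> Embedding:
    coords = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            coords[int(row["vertex_id"])] = np.array(
                [float(row["x"]), float(row["y"])]
            )
    meta = {}
    if sidecar_path is not None:
        with open(sidecar_path) as fh:
            meta = json.load(fh)
    return Embedding(
        coordinates=coords,
        stress=float(meta.get("stress", np.nan)),
        restart_index=int(meta.get("restart_index", -1)),
        converged=bool(meta.get("converged", True)),
        seed=meta.get("seed"),
        n_hits=int(meta.get("n_hits", 1)),
    )
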