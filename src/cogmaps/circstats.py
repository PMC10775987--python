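"""Circular statistics, von Mises noise modelling, and BIC scoring.

Conventions: all public angles are degrees; the angular deviation is
AD = sqrt(2 * (1 - R)) (radians, reported in degrees), the circular
analogue of a standard deviation, bounded by sqrt(2) rad ~ 81 deg.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special, stats

from .geometry import wrap_signed_deg
from .graphbuild import LabeledGraph

__all__ = [
    "CircularSummary",
    "TestResult",
    "NoiseModel",
    "ModelScore",
    "circ_summary",
    "rayleigh_test",
    "watson_williams",
    "cohens_d_circular",
    "fit_von_mises",
    "von_mises_loglik",
    "bic",
    "count_parameters",
    "KAPPA_CAP",
]

KAPPA_CAP = 1e4


@dataclass(frozen=True)
class CircularSummary:
    mean_deg: float  # nan when undefined (R == 0)
    mean_defined: bool
    resultant_length: float  # R in [0, 1]
    angular_deviation_deg: float  # sqrt(2(1-R)) in degrees
    n: int


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: tuple[float, ...]
    p_value: float
    effect_size: float | None = None


@dataclass(frozen=True)
class NoiseModel:
    """Von Mises error distribution: mean direction and concentration."""

    mu_deg: float
    kappa: float
    mu_defined: bool = True


@dataclass(frozen=True)
class ModelScore:
    k: int
    n: int
    loglik: float
    bic: float


def _to_radians(angles_deg) -> np.ndarray:
    a = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise ValueError("need at least one angle")
    return np.radians(a)


def _mean_resultant(rad: np.ndarray) -> tuple[float, float]:
    c = float(np.mean(np.cos(rad)))
    s = float(np.mean(np.sin(rad)))
    R = math.hypot(c, s)
    mu = math.degrees(math.atan2(s, c))
    return mu, min(R, 1.0)


def circ_summary(angles_deg: Sequence[float]) -> CircularSummary:
    """Mean direction, resultant length and angular deviation."""
    rad = _to_radians(angles_deg)
    mu, R = _mean_resultant(rad)
    defined = R > 1e-12
    ad = math.degrees(math.sqrt(max(2.0 * (1.0 - R), 0.0)))
    return CircularSummary(
        mean_deg=mu if defined else float("nan"),
        mean_defined=defined,
        resultant_length=R,
        angular_deviation_deg=ad,
        n=rad.size,
    )


def rayleigh_test(angles_deg: Sequence[float]) -> TestResult:
    """Rayleigh test of uniformity: z = n * R^2.

    The p-value uses the standard series approximation
    p = exp(sqrt(1 + 4n + 4(n^2 - Rn^2)) - (1 + 2n)) with Rn = n * R.
    """
    rad = _to_radians(angles_deg)
    n = rad.size
    if n < 2:
        raise ValueError("Rayleigh test needs n >= 2")
    _, R = _mean_resultant(rad)
    Rn = n * R
    z = n * R * R
    p = math.exp(math.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - Rn * Rn)) - (1.0 + 2.0 * n))
    return TestResult(statistic=z, df=(float(n),), p_value=min(p, 1.0))


def _kappa_from_R(R: float) -> float:
    """Maximum-likelihood concentration from the mean resultant length.

    Standard three-branch approximation of the inverse of
    A(kappa) = I1(kappa) / I0(kappa); capped at KAPPA_CAP.
    """
    if R < 0.53:
        k = 2.0 * R + R**3 + 5.0 * R**5 / 6.0
    elif R < 0.85:
        k = -0.4 + 1.39 * R + 0.43 / (1.0 - R)
    else:
        denom = R**3 - 4.0 * R**2 + 3.0 * R
        k = 1.0 / denom if denom > 0 else KAPPA_CAP
    return float(min(max(k, 0.0), KAPPA_CAP))


def fit_von_mises(errors_deg: Sequence[float]) -> NoiseModel:
    """Fit a von Mises noise model to angular errors (degrees)."""
    rad = _to_radians(errors_deg)
    if rad.size < 2:
        raise ValueError("need n >= 2 to fit a noise model")
    mu, R = _mean_resultant(rad)
    defined = R > 1e-12
    return NoiseModel(
        mu_deg=mu if defined else float("nan"),
        kappa=_kappa_from_R(R) if defined else 0.0,
        mu_defined=defined,
    )


def von_mises_loglik(
    errors_deg: Sequence[float], model: NoiseModel | None = None
) -> tuple[float, NoiseModel]:
    """Maximized (or evaluated) von Mises log-likelihood of errors.

    If no model is given, the maximum-likelihood fit to the errors is
    used, matching the usual plug-in likelihood for information
    criteria. Uses exponentially scaled Bessel functions so large
    concentrations do not overflow.
    """
    rad = _to_radians(errors_deg)
    if model is None:
        model = fit_von_mises(errors_deg)
    kappa = model.kappa
    mu = math.radians(model.mu_deg if model.mu_defined else 0.0)
    # log I0(kappa) = log(i0e(kappa)) + kappa
    log_i0 = math.log(special.i0e(kappa)) + kappa
    ll = float(np.sum(kappa * np.cos(rad - mu) - math.log(2.0 * math.pi) - log_i0))
    return ll, model


def watson_williams(groups: Sequence[Sequence[float]]) -> TestResult:
    """Watson-Williams test for equal mean directions of >= 2 groups.

    Circular one-way ANOVA: F = K * ((N - g) * (sum_i R_i - R)) /
    ((g - 1) * (N - sum_i R_i)) with the concentration correction
    K = 1 + 3 / (8 * kappa_hat). Assumes reasonably concentrated von
    Mises samples; a warning is issued when the pooled concentration
    estimate falls below 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    rads = [_to_radians(g) for g in groups]
    ns = np.array([r.size for r in rads])
    if np.any(ns < 2):
        raise ValueError("every group needs n >= 2")
    g = len(rads)
    N = int(ns.sum())
    Rs = []
    for r in rads:
        _, R = _mean_resultant(r)
        if R <= 1e-12:
            raise ValueError("a group has zero resultant length; means undefined")
        Rs.append(R * r.size)
    sumR = float(np.sum(Rs))
    pooled = np.concatenate(rads)
    _, Rbar_pooled = _mean_resultant(pooled)
    R_all = Rbar_pooled * N

    rw = sumR / N
    kappa = _kappa_from_R(rw)
    if kappa < 1.0:
        warnings.warn(
            "Watson-Williams assumes concentrated samples; pooled kappa "
            f"estimate {kappa:.2f} < 1",
            stacklevel=2,
        )
    K = 1.0 + 3.0 / (8.0 * kappa) if kappa > 0 else 1.0
    df1, df2 = g - 1, N - g
    denom = N - sumR
    if denom <= 0:
        return TestResult(statistic=0.0, df=(df1, df2), p_value=1.0)
    F = K * ((df2) * (sumR - R_all)) / ((df1) * denom)
    F = max(F, 0.0)
    p = float(stats.f.sf(F, df1, df2))
    return TestResult(statistic=float(F), df=(float(df1), float(df2)), p_value=p)


def cohens_d_circular(
    errors1_deg: Sequence[float], errors2_deg: Sequence[float]
) -> float:
    """Effect size: circular mean difference over pooled angular deviation.

    d = |mu1 - mu2| (shortest arc, degrees) / pooled AD (degrees), with
    the usual (n-1)-weighted pooling of the squared deviations. Infinite
    (with a warning) when both samples are perfectly concentrated at
    different means.
    """
    s1 = circ_summary(errors1_deg)
    s2 = circ_summary(errors2_deg)
    if not (s1.mean_defined and s2.mean_defined):
        raise ValueError("mean direction undefined in one of the samples")
    diff = abs(wrap_signed_deg(s1.mean_deg - s2.mean_deg))
    n1, n2 = s1.n, s2.n
    pooled_var = (
        (n1 - 1) * s1.angular_deviation_deg**2 + (n2 - 1) * s2.angular_deviation_deg**2
    ) / max(n1 + n2 - 2, 1)
    pooled_ad = math.sqrt(pooled_var)
    if pooled_ad == 0.0:
        if diff == 0.0:
            return 0.0
        warnings.warn("zero pooled deviation with unequal means: infinite effect size")
        return float("inf")
    return diff / pooled_ad


def bic(k: int, n: int, loglik: float) -> ModelScore:
    """Bayesian information criterion: k * ln(n) - 2 * loglik."""
    if n < 1 or k < 0:
        raise ValueError("need n >= 1 and k >= 0")
    return ModelScore(k=k, n=n, loglik=loglik, bic=k * math.log(n) - 2.0 * loglik)


def count_parameters(
    model: str, graph: LabeledGraph, convention: str = "ordered_triplets"
) -> int:
    """Free-parameter count of a map model on a given graph.

    ``embedded``: two planar coordinates per vertex plus the two von
    Mises noise parameters (mu, kappa).

    ``nonmetric``: one distance label per edge plus turn-angle labels
    plus the noise pair. The label-counting convention is configurable
    because independent angle labels can be enumerated per ordered
    through-triplet (default; backtracks are fixed at 180 and carry no
    freedom) or per unordered corner ('unordered_triplets', counting
    reversal pairs once).
    """
    if model == "embedded":
        return 2 * len(graph.vertices) + 2
    if model == "ground_truth":
        return 2  # layout fixed by the world; only the noise pair
    if model != "nonmetric":
        raise ValueError(f"unknown model {model!r}")
    n_dist = len(graph.edges)
    through = [t for t in graph.triplets if t[0] != t[2]]
    if convention == "ordered_triplets":
        n_ang = len(through)
    elif convention == "unordered_triplets":
        n_ang = len({(min(i, k), j, max(i, k)) for i, j, k in through})
    else:
        raise ValueError(f"unknown counting convention {convention!r}")
    return n_dist + n_ang + 2
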