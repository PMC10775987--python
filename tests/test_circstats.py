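"""Circular descriptive statistics, tests, von Mises fits, BIC, parameter counts."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cogmaps import (
    LabeledGraph,
    bic,
    circ_summary,
    cohens_d_circular,
    count_parameters,
    fit_von_mises,
    rayleigh_test,
    von_mises_loglik,
    watson_williams,
)
from cogmaps.circstats import KAPPA_CAP


def _two_point_sample(mean_deg, ad_deg, n=2):
    """Symmetric two-point sample with exact mean and angular deviation."""
    ad_rad = math.radians(ad_deg)
    half = math.degrees(math.acos(1.0 - ad_rad**2 / 2.0))
    return [mean_deg - half, mean_deg + half]


class TestCircSummary:
    def test_concentrated_sample(self):
        s = circ_summary([10.0, 10.0])
        assert s.mean_deg == pytest.approx(10.0)
        assert s.resultant_length == pytest.approx(1.0)
        assert s.angular_deviation_deg == pytest.approx(0.0, abs=1e-6)

    def test_quarter_spread(self):
        s = circ_summary([0.0, 90.0])
        assert s.mean_deg == pytest.approx(45.0)
        assert s.resultant_length == pytest.approx(math.sqrt(0.5))
        expected_ad = math.degrees(math.sqrt(2 * (1 - math.sqrt(0.5))))
        assert s.angular_deviation_deg == pytest.approx(expected_ad)

    def test_antipodal_sample_has_undefined_mean(self):
        s = circ_summary([0.0, 180.0])
        assert not s.mean_defined
        assert s.resultant_length == pytest.approx(0.0, abs=1e-12)

    @given(st.floats(-360, 360), st.integers(0, 2**31 - 1))
    def test_rotation_equivariance(self, rot, seed):
        rng = np.random.default_rng(seed)
        a = np.degrees(rng.vonmises(0.5, 2.0, 12))
        s0 = circ_summary(a)
        s1 = circ_summary(a + rot)
        assert s1.resultant_length == pytest.approx(s0.resultant_length, abs=1e-9)
        assert s1.angular_deviation_deg == pytest.approx(
            s0.angular_deviation_deg, abs=1e-9
        )
        diff = (s1.mean_deg - s0.mean_deg - rot) % 360.0
        assert min(diff, 360.0 - diff) < 1e-6


class TestRayleigh:
    def test_identical_angles_give_z_equal_n(self):
        r = rayleigh_test([42.0] * 7)
        assert r.statistic == pytest.approx(7.0)

    def test_half_resultant(self):
        assert rayleigh_test([0.0, 90.0]).statistic == pytest.approx(1.0)

    def test_uniform_grid_is_flat(self):
        angles = np.arange(360.0)
        r = rayleigh_test(angles)
        assert r.statistic < 1e-12
        assert r.p_value > 0.99

    def test_z_is_n_R_squared(self):
        rng = np.random.default_rng(8)
        a = np.degrees(rng.vonmises(1.0, 3.0, 25))
        s = circ_summary(a)
        assert rayleigh_test(a).statistic == pytest.approx(
            s.n * s.resultant_length**2
        )

    def test_matches_independent_implementation(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        a = rng.vonmises(0.0, 1.5, 50)
        z, p = pg.circ_rayleigh(a)
        mine = rayleigh_test(np.degrees(a))
        assert mine.statistic == pytest.approx(z, rel=1e-12)
        assert mine.p_value == pytest.approx(p, rel=1e-9)


class TestWatsonWilliams:
    def test_identical_groups_give_zero_f(self):
        g = [10.0, 20.0, 30.0, 15.0, 25.0]
        r = watson_williams([g, list(g)])
        assert r.statistic == pytest.approx(0.0, abs=1e-10)
        assert r.p_value > 0.99

    def test_degrees_of_freedom(self):
        rng = np.random.default_rng(0)
        g1 = np.degrees(rng.vonmises(0.0, 4.0, 10))
        g2 = np.degrees(rng.vonmises(0.5, 4.0, 10))
        r = watson_williams([g1, g2])
        assert r.df == (1.0, 18.0)

    def test_low_concentration_warns(self):
        rng = np.random.default_rng(1)
        g1 = np.degrees(rng.uniform(-np.pi, np.pi, 20))
        g2 = np.degrees(rng.uniform(-np.pi, np.pi, 20))
        with pytest.warns(UserWarning, match="concentrated"):
            watson_williams([g1, g2])

    def test_agrees_with_permutation_oracle_in_rank(self):
        """The parametric p-value lands where the permutation null puts it."""
        rng = np.random.default_rng(42)
        g1 = np.degrees(rng.vonmises(0.0, 4.0, 12))
        g2 = np.degrees(rng.vonmises(0.35, 4.0, 12))
        obs = watson_williams([g1, g2])
        pooled = np.concatenate([g1, g2])
        n1 = len(g1)
        stats = []
        for _ in range(10_000):
            perm = rng.permutation(pooled)
            with np.errstate(all="ignore"):
                stats.append(watson_williams([perm[:n1], perm[n1:]]).statistic)
        p_perm = float(np.mean(np.asarray(stats) >= obs.statistic))
        assert obs.p_value == pytest.approx(p_perm, abs=0.03)


class TestCohensD:
    def test_identical_samples_give_zero(self):
        s = _two_point_sample(15.0, 12.0)
        assert cohens_d_circular(s, list(s)) == pytest.approx(0.0, abs=1e-9)

    def test_unit_effect_size(self):
        """Means 0 and 10 with pooled AD 10 give d = 1."""
        s1 = _two_point_sample(0.0, 10.0)
        s2 = _two_point_sample(10.0, 10.0)
        assert cohens_d_circular(s1, s2) == pytest.approx(1.0, rel=1e-6)

    def test_symmetric_in_arguments(self):
        s1 = _two_point_sample(0.0, 8.0)
        s2 = _two_point_sample(25.0, 14.0)
        assert cohens_d_circular(s1, s2) == cohens_d_circular(s2, s1)

    def test_zero_pooled_deviation_flags_infinite(self):
        with pytest.warns(UserWarning, match="infinite"):
            assert cohens_d_circular([0.0, 0.0], [10.0, 10.0]) == float("inf")


class TestVonMises:
    def test_equal_angles_hit_kappa_cap(self):
        assert fit_von_mises([33.0, 33.0, 33.0]).kappa == KAPPA_CAP

    def test_recovers_simulated_concentration(self):
        rng = np.random.default_rng(7)
        draws = np.degrees(rng.vonmises(math.radians(30.0), 4.0, 2000))
        nm = fit_von_mises(draws)
        assert nm.kappa == pytest.approx(4.0, rel=0.10)
        assert abs(nm.mu_deg - 30.0) < 3.0

    def test_uniform_sample_gives_tiny_kappa(self):
        nm = fit_von_mises(np.arange(0.0, 360.0, 1.0))
        assert nm.kappa < 1e-6

    def test_loglik_matches_scipy(self):
        from scipy import stats as ss

        rng = np.random.default_rng(9)
        errs = np.degrees(rng.vonmises(0.2, 3.0, 40))
        ll, nm = von_mises_loglik(errs)
        ref = ss.vonmises.logpdf(
            np.radians(errs), nm.kappa, loc=math.radians(nm.mu_deg)
        ).sum()
        assert ll == pytest.approx(float(ref), rel=1e-9)


class TestBic:
    def test_closed_form(self):
        s = bic(2, 100, -50.0)
        assert s.bic == pytest.approx(2 * math.log(100) + 100.0)

    def test_parameter_penalty_cancels_equal_logliks(self):
        ll = -123.4
        delta = bic(162, 264, ll).bic - bic(82, 264, ll).bic
        assert delta == pytest.approx(80 * math.log(264))

    def test_strictly_increasing_in_k(self):
        vals = [bic(k, 3, -1.0).bic for k in range(5)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            bic(-1, 10, 0.0)
        with pytest.raises(ValueError):
            bic(1, 0, 0.0)


class TestCountParameters:
    def test_embedded_replica_has_82(self, replica_graph):
        assert count_parameters("embedded", replica_graph) == 82

    def test_embedded_counts_scale_with_vertices(self):
        g = LabeledGraph(vertices=[1, 2, 3], edges={(1, 2): 1.0, (2, 3): 1.0})
        assert count_parameters("embedded", g) == 8
        empty = LabeledGraph(vertices=[], edges={})
        assert count_parameters("embedded", empty) == 2

    def test_nonmetric_conventions(self, replica_graph):
        ordered = count_parameters("nonmetric", replica_graph, "ordered_triplets")
        unordered = count_parameters(
            "nonmetric", replica_graph, "unordered_triplets"
        )
        n_edges = len(replica_graph.edges)
        n_through = sum(1 for t in replica_graph.triplets if t[0] != t[2])
        assert ordered == n_edges + n_through + 2
        assert unordered == n_edges + n_through // 2 + 2
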