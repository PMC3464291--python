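import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

import cercalsim as cs
from cercalsim.geometry import DomainError, SurfacePoint, geodesic_analytic
from cercalsim.model import (
    Hair,
    HairConfiguration,
    ModelParams,
    angle_cost,
    delta_cost_move,
    hair_cost,
    lambda_s,
    m_concentration,
    pair_cost,
    prescribed_angle,
    total_cost,
)


class TestParams:
    def test_defaults_are_published_values(self, default_params):
        p = default_params
        assert (p.n_hairs, p.c1, p.a_star, p.p_iterations) == (300, 10.0, 0.1, 10**5)
        assert (p.lambda_base, p.lambda_tip) == (0.2, 0.4)

    @pytest.mark.parametrize(
        "kw",
        [
            {"c1": -1.0},
            {"a_star": 1.0},
            {"a_star": -0.1},
            {"lambda_base": 0.0},
            {"ventral_sign": 2},
            {"p_iterations": -1},
        ],
    )
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            ModelParams(**kw)


class TestSpacingField:
    @pytest.mark.parametrize("axial,expected", [(0.0, 0.2), (5.2, 0.4), (2.6, 0.3)])
    def test_decay_length_linear(self, default_params, domain, axial, expected):
        assert lambda_s(default_params, domain, axial) == pytest.approx(expected)

    def test_decay_length_outside_domain(self, default_params, domain):
        with pytest.raises(DomainError):
            lambda_s(default_params, domain, 6.0)

    def test_pair_cost_coincident_is_one(self, default_params, domain):
        h = Hair(SurfacePoint(1.0, 0.2), 0.0)
        assert pair_cost(default_params, domain, h, h) == pytest.approx(1.0)

    def test_pair_cost_exponential_decay(self, default_params, domain):
        # two hairs on the lateral line, axial separation set so that the
        # slant distance is 0.3 decay lengths (closed-form, not via the
        # geodesic under test)
        slant = math.hypot(1.0, (0.13 - 0.27) / 5.2)

        def f(dx):
            lam_mid = 0.2 + 0.2 * (2.0 + dx / 2) / 5.2
            return dx * slant - 0.3 * lam_mid

        dx = brentq(f, 0.0, 1.0)
        h1 = Hair(SurfacePoint(2.0, 0.0), 0.0)
        h2 = Hair(SurfacePoint(2.0 + dx, 0.0), 0.0)
        assert pair_cost(default_params, domain, h1, h2) == pytest.approx(
            math.exp(-0.3), rel=1e-9
        )

    def test_pair_cost_far_pairs_negligible(self, default_params, domain):
        h1 = Hair(SurfacePoint(0.0, 0.0), 0.0)
        h2 = Hair(SurfacePoint(5.2, 0.0), 0.0)
        # >= 10 decay lengths away
        assert pair_cost(default_params, domain, h1, h2) < 5e-5

    @given(
        st.floats(0, 5.2),
        st.floats(-1, 1),
        st.floats(0, 5.2),
        st.floats(-1, 1),
    )
    @settings(deadline=None, max_examples=50)
    def test_pair_cost_symmetric_and_bounded(self, ax1, ci1, ax2, ci2):
        params, domain = ModelParams(), cs.ConeDomain()
        h1, h2 = Hair(SurfacePoint(ax1, ci1), 0.0), Hair(SurfacePoint(ax2, ci2), 0.0)
        c12 = pair_cost(params, domain, h1, h2)
        assert 0 < c12 <= 1.0
        assert c12 == pytest.approx(pair_cost(params, domain, h2, h1), rel=1e-12)


class TestMovementField:
    @pytest.mark.parametrize("x,expected", [(0.0, 1.0), (0.5, 0.0), (1.0, 1.0)])
    def test_concentration_endpoints(self, default_params, x, expected):
        assert m_concentration(default_params, x) == pytest.approx(expected)

    def test_concentration_outside_range(self, default_params):
        with pytest.raises(DomainError):
            m_concentration(default_params, 1.1)

    def test_concentration_decreases_toward_midline(self, default_params):
        x = np.linspace(0, 0.5, 50)
        m = m_concentration(default_params, x)
        assert np.all(np.diff(m) < 0)

    @pytest.mark.parametrize(
        "circum,expected", [(0.0, 0.0), (1.0, 0.0), (-1.0, 0.0), (0.5, 90.0), (-0.5, 90.0)]
    )
    def test_prescribed_angle(self, default_params, circum, expected):
        assert prescribed_angle(default_params, SurfacePoint(2.0, circum)) == pytest.approx(
            expected, abs=1e-9
        )


class TestAngleCost:
    def test_aligned_is_free(self, default_params):
        h = Hair(SurfacePoint(2.0, -0.3), prescribed_angle(default_params, SurfacePoint(2.0, -0.3)))
        assert angle_cost(default_params, h) == pytest.approx(0.0, abs=1e-12)

    def test_180_flip_is_free(self, default_params):
        p = SurfacePoint(2.0, -0.3)
        th = prescribed_angle(default_params, p) + 180.0
        assert angle_cost(default_params, Hair(p, th)) == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_dorsal_pays_c1(self, default_params):
        p = SurfacePoint(2.0, -0.3)  # dorsal half (ventral_sign=+1)
        th = prescribed_angle(default_params, p) + 90.0
        assert angle_cost(default_params, Hair(p, th)) == pytest.approx(10.0)

    def test_orthogonal_ventral_positive_discounted(self, default_params):
        p = SurfacePoint(2.0, 0.5)  # ventral half, theta* = 90 -> theta = 180 > 0
        th = prescribed_angle(default_params, p) + 90.0
        assert th > 0
        assert angle_cost(default_params, Hair(p, th)) == pytest.approx(9.0)

    @given(st.floats(-180, 180), st.floats(-0.999, -0.001))
    @settings(deadline=None, max_examples=50)
    def test_axis_periodicity_dorsal(self, theta, circum):
        """On the dorsal half (no discount) the cost is invariant under a
        180-degree flip of the movement direction."""
        params = ModelParams()
        p = SurfacePoint(2.0, circum)
        c1 = angle_cost(params, Hair(p, theta))
        c2 = angle_cost(params, Hair(p, theta + 180.0))
        assert c1 == pytest.approx(c2, abs=1e-9)
        assert 0 <= c1 <= params.c1


class TestTotalCost:
    def test_empty_configuration(self, default_params, domain):
        assert total_cost(default_params, HairConfiguration.empty(domain)) == 0.0

    def test_single_misaligned_hair(self, default_params, domain):
        config = HairConfiguration(domain, [2.0], [-0.3], [prescribed_angle(default_params, SurfacePoint(2.0, -0.3)) + 90.0])
        assert total_cost(default_params, config) == pytest.approx(10.0)

    def test_single_aligned_hair_costs_nothing(self, default_params, domain):
        th = prescribed_angle(default_params, SurfacePoint(2.0, -0.3))
        config = HairConfiguration(domain, [2.0], [-0.3], [th])
        assert hair_cost(default_params, config, 0) == pytest.approx(0.0, abs=1e-12)

    def test_two_aligned_hairs_pair_counted_twice(self, default_params, domain):
        # both on the lateral line, aligned (theta* = 0), slant distance set
        # to 0.3 decay lengths as in the pair-cost test
        slant = math.hypot(1.0, (0.13 - 0.27) / 5.2)
        dx = brentq(
            lambda d: d * slant - 0.3 * (0.2 + 0.2 * (2.0 + d / 2) / 5.2), 0.0, 1.0
        )
        config = HairConfiguration(domain, [2.0, 2.0 + dx], [0.0, 0.0], [0.0, 0.0])
        e_pair = math.exp(-0.3)
        assert hair_cost(default_params, config, 0) == pytest.approx(e_pair, rel=1e-9)
        assert total_cost(default_params, config) == pytest.approx(2 * e_pair, rel=1e-9)

    def test_hair_cost_index_error(self, default_params, domain):
        config = HairConfiguration(domain, [2.0], [0.0], [0.0])
        with pytest.raises(IndexError):
            hair_cost(default_params, config, 1)


class TestDeltaCost:
    def test_null_move_is_zero(self, default_params, domain):
        config = HairConfiguration(domain, [2.0, 3.0], [0.1, -0.2], [10.0, 20.0])
        d = delta_cost_move(default_params, config, 0, SurfacePoint(2.0, 0.1), 10.0)
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_isolated_hair_rotated_to_orthogonal(self, default_params, domain):
        p = SurfacePoint(2.0, -0.3)
        th = prescribed_angle(default_params, p)
        config = HairConfiguration(domain, [p.axial], [p.circum], [th])
        d = delta_cost_move(default_params, config, 0, p, th + 90.0)
        assert d == pytest.approx(10.0)

    def test_matches_brute_force_recomputation(self, default_params, domain):
        """Incremental cost change equals the full total-cost difference."""
        rng = np.random.default_rng(42)
        from cercalsim.optimize import initialize, propose

        params = default_params.with_(n_hairs=20)
        config = initialize(params, domain, rng)
        for _ in range(200):
            i, pos, th = propose(config, rng)
            before = total_cost(params, config)
            d = delta_cost_move(params, config, i, pos, th)
            moved = config.copy()
            moved.axial[i], moved.circum[i], moved.theta[i] = pos.axial, pos.circum, th
            after = total_cost(params, moved)
            assert d == pytest.approx(after - before, rel=1e-9, abs=1e-9)
            config = moved

    def test_out_of_domain_proposal_rejected(self, default_params, domain):
        config = HairConfiguration(domain, [2.0], [0.0], [0.0])
        with pytest.raises(DomainError):
            delta_cost_move(default_params, config, 0, SurfacePoint(6.0, 0.0), 0.0)


class TestConfigurationContainer:
    def test_round_trip_through_hairs(self, domain):
        hairs = [Hair(SurfacePoint(1.0, 0.5), 30.0), Hair(SurfacePoint(2.0, -1.0), 200.0)]
        config = HairConfiguration.from_hairs(domain, hairs)
        assert len(config) == 2
        # canonicalization: circum -1 -> 1, theta 200 -> -160
        assert config[1].pos.circum == pytest.approx(1.0)
        assert config[1].theta == pytest.approx(-160.0)

    def test_positions_validated(self, domain):
        with pytest.raises(DomainError):
            HairConfiguration(domain, [7.0], [0.0], [0.0])
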