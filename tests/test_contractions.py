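import math

import numpy as np
import pytest
from scipy.integrate import quad

from lumenflow.contractions import (ContractionSchedule, JunctionModel,
                                    PerinuclearSheet,
                                    PinchParameterDistributions, PinchSite,
                                    junction_source, pinch_b, pinch_radius,
                                    pinch_source, pinch_source_at,
                                    sample_junction_schedule,
                                    sample_junction_volumes,
                                    sample_pinch_schedule, sheet_source)
from lumenflow.network import build_honeycomb

R = 0.03
B0 = 0.01 * R
T = 0.03625  # half of the mean event duration 2T = 0.0725 s


def make_site(events):
    return PinchSite(edge_index=0, edge_length=1.0, z0=0.5, b0=B0, radius=R,
                     events=np.array(events))


class TestPinchKinematics:
    def test_b_endpoints_and_midpoint(self):
        b, bdot = pinch_b(B0, R, T, 0.0)
        assert b == pytest.approx(R)
        assert bdot == pytest.approx(0.0, abs=1e-15)
        b, _ = pinch_b(B0, R, T, T)
        assert b == pytest.approx(B0)
        b, _ = pinch_b(B0, R, T, 0.5 * T)
        assert b == pytest.approx(0.5 * (R + B0))
        b, bdot = pinch_b(B0, R, T, 2 * T)
        assert b == pytest.approx(R)
        assert bdot == pytest.approx(0.0, abs=1e-15)

    def test_radius_profile(self):
        site = make_site([(0.0, T, 0.07)])
        # at t=0 the pinch has not narrowed yet
        assert site.radius_at(0.5, 0.0) == pytest.approx(R)
        # mid-event, at the centre: a = b0
        assert site.radius_at(0.5, T) == pytest.approx(B0)
        # pinch edges stay at R, outside region returns R
        assert site.radius_at(0.5 + 0.07, T) == pytest.approx(R)
        assert site.radius_at(0.9, T) == pytest.approx(R)
        # half-way in time at the centre: (R + b0)/2
        assert site.radius_at(0.5, 0.5 * T) == pytest.approx(0.5 * (R + B0))
        # linear in |z - z0|
        a_quarter = site.radius_at(0.5 + 0.035, T)
        assert a_quarter == pytest.approx(B0 + (R - B0) * 0.5)
        assert pinch_radius(site, 0.5, T) == pytest.approx(B0)

    def test_source_zero_outside_events(self):
        site = make_site([(1.0, T, 0.07)])
        assert pinch_source_at(site, 0.5) == 0.0
        assert pinch_source_at(site, 1.0 + 2 * T + 1e-9) == 0.0

    def test_source_sign_during_contraction(self):
        site = make_site([(0.0, T, 0.07)])
        assert pinch_source_at(site, 0.5 * T) > 0  # contracting expels fluid
        assert pinch_source_at(site, 1.5 * T) < 0  # relaxing takes it back

    def test_event_integral_vanishes(self):
        site = make_site([(0.0, T, 0.07)])
        val, _ = quad(lambda t: pinch_source_at(site, t), 0, 2 * T, limit=200)
        assert abs(val) < 1e-12

    def test_contraction_integral_matches_volume_change(self):
        """∫q over [0,T] equals the analytic pinch-region volume difference."""
        L = 0.07
        site = make_site([(0.0, T, L)])
        val, _ = quad(lambda t: pinch_source_at(site, t), 0, T, limit=200)
        analytic = (2 * math.pi * L / 3) * (2 * R ** 2 - R * B0 - B0 ** 2)
        assert val == pytest.approx(analytic, rel=1e-9)
        # cross-check: volume of a linear cone-section region 2πL(R²+Rb+b²)/3
        def region_volume(b):
            return 2 * math.pi * L * (R ** 2 + R * b + b ** 2) / 3.0
        assert analytic == pytest.approx(region_volume(R) - region_volume(B0),
                                         rel=1e-12)

    def test_source_continuous_at_boundaries(self):
        site = make_site([(0.0, T, 0.07)])
        eps = 1e-9
        assert abs(pinch_source_at(site, eps)) < 1e-6
        assert abs(pinch_source_at(site, 2 * T - eps)) < 1e-6


@pytest.fixture(scope="module")
def big_schedule():
    # one long edge so pinch lengths are never clamped
    from lumenflow.network import TubularNetwork
    net = TubularNetwork(
        np.array([0, 1]), np.array([[0.0, 0.0], [10.0, 0.0]]),
        ["exit", "exit"], np.array([[0, 1]]), np.array([10.0]),
        np.array([R]))
    sites = sample_pinch_schedule(net, t_end=60000.0, seed=42)
    return sites[0].events


class TestScheduleSampling:
    def test_duration_mean(self, big_schedule):
        two_T = 2 * big_schedule[:, 1]
        n = len(two_T)
        assert n > 1e5
        mean, se = two_T.mean(), two_T.std() / math.sqrt(n)
        assert abs(mean - 0.0725) < 3 * se + 1e-4

    def test_wait_mean(self, big_schedule):
        ev = big_schedule
        waits = ev[1:, 0] - (ev[:-1, 0] + 2 * ev[:-1, 1])
        assert np.all(waits >= 0)  # events never overlap
        n = len(waits)
        mean, se = waits.mean(), waits.std() / math.sqrt(n)
        assert abs(mean - 0.370) < 3 * se + 1e-3

    def test_length_uniform_support(self, big_schedule):
        two_L = 2 * big_schedule[:, 2]
        lo = 0.14 - math.sqrt(3 * 0.062 ** 2 / math.log(10))
        hi = 0.14 + math.sqrt(3 * 0.062 ** 2 / math.log(10))
        assert two_L.min() >= lo - 1e-12
        assert two_L.max() <= hi + 1e-12
        assert two_L.mean() == pytest.approx(0.14, abs=3 * two_L.std()
                                             / math.sqrt(len(two_L)))

    def test_alpha_beta_scaling(self):
        net = build_honeycomb(2, 2, 1.0)
        d = PinchParameterDistributions(alpha=10.0, beta=5.0)
        sites = sample_pinch_schedule(net, d, t_end=2000.0, seed=0)
        two_T = np.concatenate([2 * s.events[:, 1] for s in sites])
        assert two_T.mean() == pytest.approx(0.00725, rel=0.05)

    def test_full_tubule_policy(self):
        net = build_honeycomb(2, 2, 1.0)
        sites = sample_pinch_schedule(net, t_end=10.0, seed=0,
                                      length_policy="full-tubule")
        for s in sites:
            assert np.all(2 * s.events[:, 2] == s.edge_length)

    def test_sampled_lengths_clamped_to_edge(self):
        from lumenflow.network import TubularNetwork
        net = TubularNetwork(
            np.array([0, 1]), np.array([[0.0, 0.0], [0.1, 0.0]]),
            ["exit", "exit"], np.array([[0, 1]]), np.array([0.1]),
            np.array([R]))
        sites = sample_pinch_schedule(net, t_end=200.0, seed=1)
        assert 2 * sites[0].events[:, 2].max() <= 0.1 + 1e-12

    def test_deterministic(self):
        net = build_honeycomb(2, 2, 1.0)
        a = sample_pinch_schedule(net, t_end=5.0, seed=9)
        b = sample_pinch_schedule(net, t_end=5.0, seed=9)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.events, sb.events)


class TestJunctionAndSheet:
    def test_junction_contraction_integral(self):
        dv, Th = 0.0045, 0.03625
        val, _ = quad(lambda t: junction_source(dv, Th, t), 0, Th)
        assert val == pytest.approx(dv, rel=1e-10)
        total, _ = quad(lambda t: junction_source(dv, Th, t), 0, 2 * Th)
        assert abs(total) < 1e-15

    def test_junction_source_boundary_zeros_and_peak(self):
        dv, Th = 0.0045, 0.03625
        assert junction_source(dv, Th, 0.0) == 0.0
        assert abs(junction_source(dv, Th, Th)) < 1e-15
        peak = junction_source(dv, Th, 0.5 * Th)
        assert peak == pytest.approx(dv * math.pi / (2 * Th), rel=1e-12)
        # numerical max over the contraction equals the analytic peak
        taus = np.linspace(0, Th, 2001)
        vals = [junction_source(dv, Th, t) for t in taus]
        assert max(vals) == pytest.approx(peak, rel=1e-6)

    def test_sheet_source_values(self):
        # Vsheet = 10 µm³ over 2T = 5 s
        Th = 2.5
        val, _ = quad(lambda t: sheet_source(10.0, Th, t), 0, Th)
        assert val == pytest.approx(10.0, rel=1e-10)
        assert sheet_source(10.0, Th, 0.5 * Th) == pytest.approx(
            10 * math.pi / 5.0)
        assert sheet_source(0.0, Th, 1.0) == 0.0

    def test_sampled_volumes_within_bounds(self):
        v = sample_junction_volumes(5000, seed=0)
        assert v.min() >= 0.0020
        assert v.max() <= 0.0081

    def test_sampled_volume_mean_matches_truncated_normal(self):
        n = 100000
        v = sample_junction_volumes(n, seed=1)
        mean, sd, lo, hi = 0.0045, 0.0021, 0.0020, 0.0081
        dens = lambda x: math.exp(-0.5 * ((x - mean) / sd) ** 2)
        z, _ = quad(dens, lo, hi)
        m, _ = quad(lambda x: x * dens(x), lo, hi)
        expected = m / z
        se = v.std() / math.sqrt(n)
        assert abs(v.mean() - expected) < 3 * se

    def test_sampling_deterministic(self):
        assert np.array_equal(sample_junction_volumes(100, seed=3),
                              sample_junction_volumes(100, seed=3))

    def test_junction_schedule_per_node_volume_constant(self):
        net = build_honeycomb(2, 2, 1.0)
        sched = sample_junction_schedule(net, JunctionModel(), t_end=50.0,
                                         seed=2)
        for node, ev in sched.items():
            if len(ev) > 1:
                assert np.allclose(ev[:, 2], ev[0, 2])

    def test_schedule_serialisation_round_trip(self):
        net = build_honeycomb(2, 2, 1.0)
        sched = ContractionSchedule(
            t_end=3.0,
            pinch_sites=sample_pinch_schedule(net, t_end=3.0, seed=5),
            junction_events=sample_junction_schedule(
                net, JunctionModel(), t_end=3.0, seed=6),
            sheet=PerinuclearSheet([3, 4], v_sheet=10.0, T=2.5))
        back = ContractionSchedule.from_json(sched.to_json())
        assert back.t_end == sched.t_end
        for a, b in zip(back.pinch_sites, sched.pinch_sites):
            assert np.array_equal(a.events, b.events)
        for k in sched.junction_events:
            assert np.array_equal(back.junction_events[k],
                                  sched.junction_events[k])
        assert back.sheet.v_sheet == 10.0


class TestDistributionValidation:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PinchParameterDistributions(alpha=0.0)
        with pytest.raises(ValueError):
            PinchParameterDistributions(duration_rate=-1.0)
        with pytest.raises(ValueError):
            JunctionModel(f=1.5)

    def test_goodness_of_fit_exponential(self):
        """Sampled 2T at alpha=1 matches the exponential law (KS test)."""
        from scipy import stats
        from lumenflow.network import TubularNetwork
        net = TubularNetwork(
            np.array([0, 1]), np.array([[0.0, 0.0], [10.0, 0.0]]),
            ["exit", "exit"], np.array([[0, 1]]), np.array([10.0]),
            np.array([R]))
        sites = sample_pinch_schedule(net, t_end=50000.0, seed=11)
        two_T = 2 * sites[0].events[:, 1]
        lam = math.log(10) / 0.167
        p = stats.kstest(two_T, "expon", args=(0, 1 / lam)).pvalue
        assert p > 0.01
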