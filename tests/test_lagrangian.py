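"""Particle kinematics, fate engines and the event driver."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import edna_dispersal as ed
from edna_dispersal.lagrangian import EARTH_RADIUS_M, OutOfDomainError, _stream

from conftest import T0, make_release, make_uniform_field


class TestInterpolation:
    def test_uniform_field_everywhere(self, still_water):
        field = make_uniform_field(0.3, -0.1)
        u, v = ed.interpolate_velocity(field, -4.5, 47.7, T0 + pd.Timedelta("90min"))
        assert u == pytest.approx(0.3)
        assert v == pytest.approx(-0.1)

    def test_exact_at_grid_nodes(self, quiet_field):
        ds = quiet_field
        lon = float(ds["lon"][3])
        lat = float(ds["lat"][5])
        u, v = ed.interpolate_velocity(ds, lon, lat, pd.Timestamp(ds["time"][7].values))
        assert u == pytest.approx(float(ds["u"][7, 5, 3]), abs=1e-12)
        assert v == pytest.approx(float(ds["v"][7, 5, 3]), abs=1e-12)

    def test_bilinear_midpoint_of_four_nodes(self):
        field = make_uniform_field(0.0, 0.0, half_width_km=40, spacing_m=10_000)
        u = field["u"].values
        u[:, :, :] = 0.0
        # corner values 0,0,1,1 around one cell -> 0.5 at the cell centre
        u[:, 5, 5] = 0.0
        u[:, 5, 6] = 0.0
        u[:, 6, 5] = 1.0
        u[:, 6, 6] = 1.0
        mid_lon = 0.5 * (float(field["lon"][5]) + float(field["lon"][6]))
        mid_lat = 0.5 * (float(field["lat"][5]) + float(field["lat"][6]))
        got, _ = ed.interpolate_velocity(field, mid_lon, mid_lat, T0)
        assert got == pytest.approx(0.5, abs=1e-12)

    def test_outside_grid_raises(self, still_water):
        with pytest.raises(OutOfDomainError):
            ed.interpolate_velocity(still_water, 10.0, 80.0, T0)


class TestRK4:
    def test_zero_field_is_fixed_point(self, still_water):
        interp = ed.FlowFieldInterpolator(still_water)
        lon, lat, ok = ed.rk4_step(-4.51, 47.68, interp.velocity, 0.0, 180.0)
        assert ok.all()
        assert lon[0] == -4.51 and lat[0] == 47.68

    def test_uniform_eastward_displacement(self):
        field = make_uniform_field(1.0, 0.0)
        interp = ed.FlowFieldInterpolator(field)
        lat0 = 47.68
        lon, lat, ok = ed.rk4_step(-4.51, lat0, interp.velocity, 0.0, 180.0)
        expected_deg = 180.0 / (EARTH_RADIUS_M * math.cos(math.radians(lat0))) \
            * 180.0 / math.pi
        assert lat[0] == pytest.approx(lat0, abs=1e-12)
        assert lon[0] - (-4.51) == pytest.approx(expected_deg, rel=1e-9)

    def test_solid_body_rotation_closes_orbit(self):
        """RK4 on an analytic solid-body rotation returns to the start
        after one period to within 0.1% of the orbit radius."""
        lat_c, lon_c = 47.68, -4.51
        omega = 2.0 * math.pi / (6.0 * 3600.0)  # 6-h rotation period

        def velocity(lon, lat, t_h):
            x = (np.asarray(lon) - lon_c) * math.cos(math.radians(lat_c)) \
                * math.pi / 180.0 * EARTH_RADIUS_M
            y = (np.asarray(lat) - lat_c) * math.pi / 180.0 * EARTH_RADIUS_M
            return -omega * y, omega * x, np.ones(np.shape(lon), bool)

        radius_m = 2000.0
        lon = np.array([lon_c + radius_m / (EARTH_RADIUS_M
                        * math.cos(math.radians(lat_c))) * 180.0 / math.pi])
        lat = np.array([lat_c])
        start = (lon[0], lat[0])
        n_steps = int(6 * 3600 / 180)
        for i in range(n_steps):
            lon, lat, _ = ed.rk4_step(lon, lat, velocity, i * 0.05, 180.0)
        err_km = ed.haversine_km(lon[0], lat[0], start[0], start[1])
        assert err_km * 1000.0 < 1e-3 * radius_m


class TestDiffusion:
    def test_zero_diffusivity_is_identity(self):
        rng = np.random.default_rng(0)
        lon, lat = ed.diffusion_step(-4.51, 47.68, 0.0, 180.0, rng)
        assert lon[0] == -4.51 and lat[0] == 47.68

    def test_mean_squared_displacement_law(self):
        """2-D random walk: MSD after time t is 4 K t (within 2% at 1e5
        particles over one hour of 3-min steps)."""
        rng = np.random.default_rng(42)
        n = 100_000
        lat0 = 47.68
        lon = np.full(n, -4.51)
        lat = np.full(n, lat0)
        for _ in range(20):
            lon, lat = ed.diffusion_step(lon, lat, 1.0, 180.0, rng)
        kx = EARTH_RADIUS_M * math.cos(math.radians(lat0)) * math.pi / 180.0
        ky = EARTH_RADIUS_M * math.pi / 180.0
        msd = np.mean(((lon + 4.51) * kx) ** 2 + ((lat - lat0) * ky) ** 2)
        assert msd == pytest.approx(4.0 * 1.0 * 3600.0, rel=0.02)

    def test_seeded_reproducibility(self):
        a = ed.diffusion_step(0.0, 45.0, 1.0, 180.0, np.random.default_rng(5))
        b = ed.diffusion_step(0.0, 45.0, 1.0, 180.0, np.random.default_rng(5))
        assert a == b


class TestSchedule:
    def test_two_month_schedule_has_732_releases(self):
        events = ed.build_release_schedule(
            [(2018, 1), (2018, 9)], 2.0, [ed.QUIET_SITE],
            [ed.DecayScenarioSpec(kind="exponential")],
        )
        assert len(events) == 732

    def test_four_scenarios_give_2928_events(self):
        scens = [ed.DecayScenarioSpec(kind=k)
                 for k in ("no_decay", "exponential", "biphasic", "delayed")]
        events = ed.build_release_schedule([(2018, 1), (2018, 9)], 2.0,
                                           [ed.QUIET_SITE], scens)
        assert len(events) == 2928

    def test_daily_cadence_in_a_31_day_month(self):
        events = ed.build_release_schedule(
            [(2018, 1)], 24.0, [ed.QUIET_SITE],
            [ed.DecayScenarioSpec(kind="no_decay")],
        )
        assert len(events) == 31

    def test_invalid_inputs_rejected(self):
        scen = [ed.DecayScenarioSpec(kind="no_decay")]
        with pytest.raises(ValueError, match="month"):
            ed.build_release_schedule([(2018, 13)], 2.0, [ed.QUIET_SITE], scen)
        with pytest.raises(ValueError, match="cadence"):
            ed.build_release_schedule([(2018, 1)], 7.0, [ed.QUIET_SITE], scen)


class TestFateEngines:
    def test_survival_probability_identities(self):
        assert ed.survival_probability(0.0, 1.0) == 1.0
        assert ed.survival_probability(math.log(2) / 6.4, 6.4) == pytest.approx(0.5)
        # exponential semigroup: two steps of dt equal one step of 2 dt
        one = ed.survival_probability(0.3, 2.0)
        two = ed.survival_probability(0.3, 1.0) ** 2
        assert one == pytest.approx(two, rel=1e-12)

    def test_no_decay_keeps_every_particle(self):
        p = ed.ParticleState.point_release(0.0, 45.0, 500)
        scen = ed.DecayScenarioSpec(kind="no_decay")
        ed.apply_decay_step(p, scen, 12.0, 1.0, 10.0, np.random.default_rng(0))
        assert p.n_alive == 500

    def test_exponential_survivor_count_after_one_hour(self):
        """10 000 particles at k = 0.1083/h leave ~8974 survivors."""
        law = ed.TemperatureDecayLaw(a=0.1083, b=0.0)  # fixed-rate law
        scen = ed.DecayScenarioSpec(kind="exponential", law=law)
        p = ed.ParticleState.point_release(0.0, 45.0, 10_000)
        rng = np.random.default_rng(1)
        for _ in range(20):  # one hour of 3-min steps
            ed.apply_decay_step(p, scen, 12.0, 180.0 / 3600.0, 10.0, rng)
        expected = 10_000 * math.exp(-0.1083)
        se = math.sqrt(10_000 * 0.8974 * (1 - 0.8974))
        assert abs(p.n_alive - expected) < 4 * se

    def test_biphasic_survival_matches_mixture(self):
        scen = ed.DecayScenarioSpec(kind="biphasic")
        p = ed.ParticleState.point_release(0.0, 45.0, 10_000)
        rng = np.random.default_rng(2)
        ed.assign_biphasic_groups(p, rng=rng)
        dt_h = 0.05
        for _ in range(int(24 / dt_h)):
            ed.apply_decay_step(p, scen, 12.0, dt_h, 10.0, rng)
        expected_frac = 0.7 * math.exp(-0.5 * 24) + 0.3 * math.exp(-0.013 * 24)
        se = math.sqrt(expected_frac * (1 - expected_frac) / 10_000)
        assert abs(p.n_alive / 10_000 - expected_frac) < 4 * se

    def test_biphasic_without_groups_is_an_error(self):
        p = ed.ParticleState.point_release(0.0, 45.0, 10)
        scen = ed.DecayScenarioSpec(kind="biphasic")
        with pytest.raises(RuntimeError, match="group"):
            ed.apply_decay_step(p, scen, 12.0, 1.0, 10.0,
                                np.random.default_rng(0))

    @pytest.mark.parametrize("n, expected", [(10_000, (7000, 3000)),
                                             (10, (7, 3))])
    def test_biphasic_group_split_is_exact(self, n, expected):
        p = ed.ParticleState.point_release(0.0, 45.0, n)
        ed.assign_biphasic_groups(p, rng=np.random.default_rng(0))
        assert (np.sum(p.group == 0), np.sum(p.group == 1)) == expected

    def test_group_counts_invariant_under_reseeding(self):
        counts = set()
        members = []
        for seed in range(3):
            p = ed.ParticleState.point_release(0.0, 45.0, 100)
            ed.assign_biphasic_groups(p, rng=np.random.default_rng(seed))
            counts.add((np.sum(p.group == 0), np.sum(p.group == 1)))
            members.append(p.group.copy())
        assert counts == {(70, 30)}
        assert not all(np.array_equal(members[0], m) for m in members[1:])

    def test_single_division_hour_adds_twenty_percent(self):
        p = ed.ParticleState.point_release(0.0, 45.0, 10_000)
        ed.apply_delayed_division(p, 1.0, rng=np.random.default_rng(0))
        assert p.n_alive == 12_000

    def test_six_division_hours_triple_the_count(self):
        p = ed.ParticleState.point_release(0.0, 45.0, 10_000)
        for h in range(1, 7):
            ed.apply_delayed_division(p, float(h), rng=np.random.default_rng(h))
        assert p.n_alive == 29_860

    def test_division_stops_after_growth_phase(self):
        p = ed.ParticleState.point_release(0.0, 45.0, 1000)
        ed.apply_delayed_division(p, 7.0, rng=np.random.default_rng(0))
        assert p.n == 1000

    def test_children_copy_parent_position_and_record_parent(self):
        p = ed.ParticleState.point_release(0.0, 45.0, 50)
        p.lon[:] = np.linspace(-1, 1, 50)
        ed.apply_delayed_division(p, 1.0, rng=np.random.default_rng(3))
        child = slice(50, None)
        parents = p.parent[child]
        assert (parents >= 0).all()
        np.testing.assert_array_equal(p.lon[child], p.lon[parents])


class TestRunEvent:
    def test_still_water_no_decay_stays_at_release(self, still_water):
        ev = make_release(still_water, "no_decay")
        cfg = ed.SimulationConfig(diffusivity_K=0.0, n_particles=50,
                                  tracking_horizon_h=24.0, seed=0)
        tab = ed.run_event(ev, still_water, cfg)
        assert len(tab) == 25 * 50
        assert tab["alive"].all()
        assert (tab["lon"] == ev.release_lon).all()
        assert (tab["lat"] == ev.release_lat).all()

    def test_exponential_alive_counts_decay_log_linearly(self, still_water):
        """Hourly alive counts follow exp(-k t) with the temperature-law
        rate: regression slope within 5% of -k at N = 10 000."""
        ev = make_release(still_water, "exponential")
        cfg = ed.SimulationConfig(n_particles=10_000, seed=4)
        tab = ed.run_event(ev, still_water, cfg)
        alive = tab[tab["alive"]].groupby("hour").size()
        k_true = ed.TemperatureDecayLaw()(12.0)  # field temperature 12 degC
        slope = np.polyfit(alive.index, np.log(alive.values), 1)[0]
        assert abs(-slope - k_true) / k_true < 0.05

    def test_exponential_survival_increments_are_binomial(self, still_water):
        """Each hourly transition N(t) -> N(t+1) is Binomial(N(t), e^-k);
        the standardized increments are independent, so a 4-sigma bound
        over the 24 transitions is a sharp and stable check."""
        ev = make_release(still_water, "exponential")
        cfg = ed.SimulationConfig(n_particles=10_000, seed=9)
        tab = ed.run_event(ev, still_water, cfg)
        alive = tab[tab["alive"]].groupby("hour").size().sort_index()
        k = ed.TemperatureDecayLaw()(12.0)
        p = math.exp(-k)  # per-hour survival
        for n_prev, n_next in zip(alive.values[:-1], alive.values[1:]):
            se = math.sqrt(n_prev * p * (1 - p))
            assert abs(n_next - n_prev * p) <= max(4 * se, 2.0)

    def test_delayed_triples_by_hour_six_and_tracks_mean_flow(self):
        field = make_uniform_field(0.5, 0.0, half_width_km=80,
                                   spacing_m=8000.0)
        ev = make_release(field, "delayed")
        cfg = ed.SimulationConfig(n_particles=2000, seed=5,
                                  tracking_horizon_h=6.0)
        tab = ed.run_event(ev, field, cfg)
        alive6 = tab[(tab["hour"] == 6.0) & tab["alive"]]
        assert len(alive6) == pytest.approx(3 * 2000, rel=0.01)
        com = (alive6["lon"].mean(), alive6["lat"].mean())
        expected_km = 0.5 * 6 * 3600 / 1000.0
        got_km = ed.haversine_km(ev.release_lon, ev.release_lat, *com)
        assert got_km == pytest.approx(expected_km, rel=0.02)

    def test_alive_never_exceeds_created_and_never_resurrects(self, still_water):
        ev = make_release(still_water, "delayed")
        cfg = ed.SimulationConfig(n_particles=500, seed=6)
        tab = ed.run_event(ev, still_water, cfg)
        by_hour = tab.groupby("hour")
        created = by_hour.size()
        alive = by_hour["alive"].sum()
        assert (alive <= created).all()
        # one-way alive -> dead per particle
        flips = tab.sort_values("hour").groupby("particle_id")["alive"].apply(
            lambda s: (s.astype(int).diff() > 0).any())
        assert not flips.any()

    def test_decay_and_transport_commute_statistically(self, quiet_field):
        """Positions of survivors under exponential decay are distributed
        like no-decay positions (decay is position-independent): two-sample
        KS distance < 0.05 per axis at N = 10 000, compared at hour 12."""
        cfg = ed.SimulationConfig(n_particles=10_000, seed=7,
                                  tracking_horizon_h=12.0)
        ev_nd = make_release(quiet_field, "no_decay", site="quiet")
        ev_ex = make_release(quiet_field, "exponential", site="quiet")
        nd = ed.run_event(ev_nd, quiet_field, cfg)
        ex = ed.run_event(ev_ex, quiet_field, cfg)
        nd12 = nd[(nd["hour"] == 12.0) & nd["alive"]]
        ex12 = ex[(ex["hour"] == 12.0) & ex["alive"]]
        for axis in ("lon", "lat"):
            ks = stats.ks_2samp(nd12[axis], ex12[axis]).statistic
            assert ks < 0.05

    def test_same_seed_reproduces_trajectories(self, still_water):
        ev = make_release(still_water, "biphasic")
        cfg = ed.SimulationConfig(n_particles=200, seed=8,
                                  tracking_horizon_h=6.0)
        a = ed.run_event(ev, still_water, cfg)
        b = ed.run_event(ev, still_water, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_horizon_outside_field_rejected(self, still_water):
        ev = make_release(still_water, "no_decay")
        cfg = ed.SimulationConfig(tracking_horizon_h=100.0, n_particles=10)
        with pytest.raises(ValueError, match="horizon"):
            ed.run_event(ev, still_water, cfg)

    def test_event_streams_are_independent(self):
        a = _stream(1, "fate:x")
        b = _stream(1, "fate:y")
        assert a.random() != b.random()
        c = _stream(1, "fate:x")
        assert _stream(1, "fate:x").random() == c.random()
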