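"""Coupled simulator, SAC cycles, optimizer, schedules."""

import numpy as np
import pytest

from phycolight import synthgen
from phycolight.growth_sim import (
    LightSchedule,
    SacPlan,
    Segment,
    optimize_initial_od,
    simulate_fed_batch,
    simulate_growth,
    simulate_sac,
)


class StubLdpm:
    """Always returns the same mid-gray LDP (never extrapolated)."""

    def __init__(self, value=128):
        self.grid = np.full((18, 40), value, dtype=int)

    def predict(self, intensity, concentration):
        from phycolight.ldpm import LdpPrediction

        return LdpPrediction(grid=self.grid, extrapolated=False)


class StubGrm:
    """Returns a fixed rate regardless of the LDP."""

    def __init__(self, rate):
        self.rate = rate

    def predict_rate(self, ldp):
        return self.rate


class TestSchedules:
    def test_contiguity_enforced(self):
        with pytest.raises(ValueError):
            LightSchedule((Segment(0, 5, 100.0), Segment(6, 10, 100.0)))

    def test_intensity_lookup(self):
        sched = LightSchedule.from_steps([(8, 178.0), (8, 714.0), (8, 178.0)])
        assert sched.intensity_at(0.0) == 178.0
        assert sched.intensity_at(8.5) == 714.0
        assert sched.intensity_at(24.0) == 178.0
        assert sched.horizon_h == 24.0

    def test_texas_summer_program_covers_a_day(self):
        sched = LightSchedule.texas_summer()
        assert sched.horizon_h == 24.0
        assert sched.intensity_at(5.0) == 1500.0  # 10-h midday plateau
        assert sched.intensity_at(20.0) == 0.0    # night
        assert max(s.intensity for s in sched.segments) == 1500.0

    def test_csv_round_trip(self, tmp_path):
        sched = LightSchedule.changing_light(n_sources=2)
        sched.to_csv(tmp_path / "s.csv")
        assert LightSchedule.from_csv(tmp_path / "s.csv") == sched


class TestSimulateGrowth:
    def test_zero_rate_stub_keeps_trajectory_flat(self):
        res = simulate_growth(StubLdpm(), StubGrm(0.0), 2.0,
                              LightSchedule.constant(574, 24.0))
        assert np.allclose(res.od730, 2.0)

    def test_constant_rate_stub_is_exact_euler_line(self):
        k = 0.05
        res = simulate_growth(StubLdpm(), StubGrm(k), 1.0,
                              LightSchedule.constant(574, 24.0), dt=1.0)
        assert np.allclose(res.od730, 1.0 + k * res.times)

    def test_dt_must_divide_segment_boundaries(self):
        sched = LightSchedule.from_steps([(1.5, 100.0), (22.5, 500.0)])
        with pytest.raises(ValueError):
            simulate_growth(StubLdpm(), StubGrm(0.0), 1.0, sched, dt=1.0)

    def test_coupled_simulation_tracks_generator_truth(self, pbr_bundle):
        """24 h of coupled surrogate growth stays within 5 % of the
        reference trajectory (seeded double-574 benchmark)."""
        b = pbr_bundle
        sched = LightSchedule.constant(574.0, 24.0, 2)
        sim = simulate_growth(b.ldpm, b.grm, 2.3, sched, dt=1.0)
        truth = synthgen.simulate_true_growth(2.3, sched, b.truth,
                                              b.geometry, b.optics, dt=1.0)
        rel = np.abs(sim.od730 - truth.od730) / truth.od730
        assert rel.max() <= 0.05

    def test_halving_dt_changes_final_od_below_1pct(self, pbr_bundle):
        b = pbr_bundle
        sched = LightSchedule.constant(574.0, 24.0, 2)
        od_1h = simulate_growth(b.ldpm, b.grm, 2.3, sched, dt=1.0).od730[-1]
        od_05h = simulate_growth(b.ldpm, b.grm, 2.3, sched, dt=0.5).od730[-1]
        assert abs(od_05h - od_1h) / od_1h < 0.01


class TestFedBatch:
    def test_single_interval_equals_simulate_growth(self):
        sched = LightSchedule.constant(300.0, 24.0)
        res, daily = simulate_fed_batch(StubLdpm(), StubGrm(0.04), 1.0, sched)
        direct = simulate_growth(StubLdpm(), StubGrm(0.04), 1.0, sched)
        assert np.array_equal(res.od730, direct.od730)
        assert daily.shape == (1,)

    def test_zero_rate_stub_yields_zero_daily_productivity(self):
        sched = LightSchedule.constant(300.0, 24.0)
        _, daily = simulate_fed_batch(StubLdpm(), StubGrm(0.0), 1.0, sched,
                                      horizon_h=72.0)
        assert np.allclose(daily, 0.0)
        assert daily.shape == (3,)

    def test_daily_productivity_declines_once_shading_dominates(
            self, pbr_bundle):
        """Without harvests the culture densifies past the dark-area onset
        and daily productivity decays, the fed-batch failure mode."""
        b = pbr_bundle
        sched = LightSchedule.constant(574.0, 24.0, 2)
        res, daily = simulate_fed_batch(b.ldpm, b.grm, 2.3, sched,
                                        horizon_h=96.0)
        onset_crossed = res.dark_fraction > b.truth.dark_penalty_onset
        assert onset_crossed.any()
        assert np.all(np.diff(daily) <= 1e-9)


class TestSac:
    def test_constant_rate_cycles_are_identical(self):
        k = 0.04
        plan = SacPlan(24.0, 2.0, 5)
        report = simulate_sac(StubLdpm(), StubGrm(k), plan,
                              LightSchedule.constant(574, 24.0))
        expected = 24.0 * k * 0.39
        assert np.allclose(report.per_cycle_g_per_l_day, expected)

    def test_cumulative_yield_is_additive_over_cycles(self):
        plan = SacPlan(24.0, 2.0, 7)
        report = simulate_sac(StubLdpm(), StubGrm(0.04), plan,
                              LightSchedule.constant(574, 24.0))
        assert report.cumulative_yield_g_per_l == pytest.approx(
            7 * report.per_cycle_g_per_l_day[0]
        )

    def test_single_cycle_matches_direct_simulation_formula(self, tiny_bundle):
        b = tiny_bundle
        sched = LightSchedule.constant(574.0, 24.0, 2)
        plan = SacPlan(24.0, 1.5, 1)
        report = simulate_sac(b.ldpm, b.grm, plan, sched)
        direct = simulate_growth(b.ldpm, b.grm, 1.5, sched)
        expected = (direct.od730[-1] - 1.5) * 0.39
        assert report.per_cycle_g_per_l_day[0] == pytest.approx(expected)

    def test_shrinking_culture_reports_negative_productivity_with_warning(self):
        plan = SacPlan(24.0, 2.0, 1)
        report = simulate_sac(StubLdpm(), StubGrm(-0.01), plan,
                              LightSchedule.constant(574, 24.0))
        assert report.per_cycle_g_per_l_day[0] < 0
        assert report.warnings

    def test_schedule_period_must_match_harvest_interval(self):
        with pytest.raises(ValueError):
            simulate_sac(StubLdpm(), StubGrm(0.0), SacPlan(24.0, 2.0, 1),
                         LightSchedule.constant(574, 12.0))

    def test_pond_mode_reports_areal_productivity(self):
        from phycolight.bioprocess import PondGeometry

        plan = SacPlan(24.0, 1.0, 2)
        report = simulate_sac(StubLdpm(), StubGrm(0.05), plan,
                              LightSchedule.constant(1000, 24.0),
                              pond=PondGeometry(depth_m=0.20))
        assert np.allclose(report.per_cycle_g_per_m2_day,
                           report.per_cycle_g_per_l_day * 200.0)


class TestOptimizer:
    def test_rate_independent_of_od_ties_break_to_lowest(self):
        plan = SacPlan(24.0, 1.0, 1)
        res = optimize_initial_od(StubLdpm(), StubGrm(0.05),
                                  [3.0, 1.0, 2.0], plan,
                                  LightSchedule.constant(574, 24.0))
        assert res.best_od == 1.0
        assert np.allclose(res.productivities, res.productivities[0])

    def test_result_invariant_to_candidate_ordering(self, tiny_bundle):
        b = tiny_bundle
        sched = LightSchedule.constant(574.0, 24.0, 2)
        plan = SacPlan(24.0, 1.0, 1)
        cands = [0.5, 1.0, 1.5, 2.0, 2.5]
        a = optimize_initial_od(b.ldpm, b.grm, cands, plan, sched)
        bwd = optimize_initial_od(b.ldpm, b.grm, cands[::-1], plan, sched)
        assert a.best_od == bwd.best_od
        assert np.array_equal(a.productivities, bwd.productivities)

    def test_too_few_candidates_rejected(self):
        with pytest.raises(ValueError):
            optimize_initial_od(StubLdpm(), StubGrm(0.0), [1.0, 2.0],
                                SacPlan(), LightSchedule.constant(574, 24.0))
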