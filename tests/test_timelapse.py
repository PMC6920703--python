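import numpy as np
import pytest

from fluxlens.binding import SensorParams
from fluxlens.errors import (
    DegenerateNormalizationError,
    GridTooCoarseError,
    IncompleteTraceError,
    InsufficientCyclesError,
    InvalidInputError,
    OutOfCycleError,
)
from fluxlens.synthetic import CycleConfig, ImagingConfig, SimConfig, simulate_cell_traces
from fluxlens.timelapse import (
    LN2,
    CellCycle,
    CellTrace,
    assemble_volume,
    detrend_normalize,
    gp_smooth,
    mean_event_phase,
    phase_map,
    production_rate,
    segment_cycles,
    spheroid_volume,
    uncoupling,
    uncoupling_profile,
)


class TestSpheroidVolume:
    def test_unit_sphere(self):
        assert spheroid_volume(1.0, 1.0) == pytest.approx(4.0 * np.pi / 3.0)

    def test_direct_formula(self):
        assert spheroid_volume(3.0, 2.0) == pytest.approx(16.0 * np.pi)

    def test_major_minor_asymmetry(self):
        assert spheroid_volume(2.0, 3.0) != pytest.approx(spheroid_volume(3.0, 2.0))

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(InvalidInputError):
            spheroid_volume(0.0, 1.0)


def flat_trace(times, cyts, buds, mother=(2.3, 2.0), yfp=None, mch=None):
    n = times.size
    return CellTrace(
        cell_id="t",
        times=times,
        mother_major=np.full(n, mother[0]),
        mother_minor=np.full(n, mother[1]),
        yfp_mean=np.full(n, 10.0) if yfp is None else yfp,
        mcherry_mean=np.full(n, 10.0) if mch is None else mch,
        budding_times=np.array(buds),
        cytokinesis_times=np.array(cyts),
    )


class TestSegmentCycles:
    def test_duration_filter_and_reasons(self):
        t = np.arange(0.0, 526.0, 6.0)
        tr = flat_trace(t, cyts=[0.0, 200.0, 520.0], buds=[60.0, 260.0])
        kept, dropped = segment_cycles(tr)
        assert len(kept) == 1 and kept[0].duration == 200.0
        assert dropped == [("t", 200.0, "too-long")]

    def test_missing_budding_dropped(self):
        t = np.arange(0.0, 406.0, 6.0)
        tr = flat_trace(t, cyts=[0.0, 200.0, 400.0], buds=[60.0])
        kept, dropped = segment_cycles(tr)
        assert len(kept) == 1
        assert ("t", 200.0, "missing-budding") in dropped

    def test_exact_boundary_durations_kept(self):
        t = np.arange(0.0, 460.0, 6.0)
        tr = flat_trace(t, cyts=[0.0, 150.0, 450.0], buds=[50.0, 250.0])
        kept, _ = segment_cycles(tr)
        assert [c.duration for c in kept] == [150.0, 300.0]


class TestAssembleVolume:
    def test_constant_mother_without_daughter(self):
        t = np.arange(0.0, 200.0, 6.0)
        tr = flat_trace(t, cyts=[0.0, 198.0], buds=[60.0])
        cyc = CellCycle("t", 0.0, 198.0, 60.0)
        with pytest.warns(UserWarning, match="daughter never segmented"):
            _, v = assemble_volume(tr, cyc)
        assert np.allclose(v, (4 / 3) * np.pi * 2.3 * 4.0)

    def test_linear_interpolation_from_budding(self):
        t = np.arange(0.0, 200.0, 15.0)
        n = t.size
        dR = np.full(n, np.nan)
        dr = np.full(n, np.nan)
        # first measured daughter at t=90 with volume 6 fl
        r6 = (6.0 * 3.0 / (4.0 * np.pi)) ** (1 / 3)
        i90 = int(np.where(t == 90.0)[0][0])
        dR[i90:], dr[i90:] = r6, r6
        tr = CellTrace(
            cell_id="t",
            times=t,
            mother_major=np.full(n, 2.3),
            mother_minor=np.full(n, 2.0),
            daughter_major=dR,
            daughter_minor=dr,
            yfp_mean=np.full(n, 1.0),
            mcherry_mean=np.full(n, 1.0),
            budding_times=np.array([60.0]),
            cytokinesis_times=np.array([0.0, 195.0]),
        )
        cyc = CellCycle("t", 0.0, 195.0, 60.0)
        times, v = assemble_volume(tr, cyc)
        v_mother = (4 / 3) * np.pi * 2.3 * 4.0
        i75 = int(np.where(times == 75.0)[0][0])
        assert v[i75] - v_mother == pytest.approx(3.0)

    def test_matches_direct_recomputation_on_synthetic_trace(self):
        cfg = SimConfig(seed=2, imaging=ImagingConfig(radius_noise_sd=0.0, fluor_noise_sd=0.0))
        trace = simulate_cell_traces(cfg, 1)[0][0]
        cyc = segment_cycles(trace)[0][0]
        times, v = assemble_volume(trace, cyc)
        # independent oracle straight from the radii arrays
        mask = (trace.times >= cyc.cyt_start) & (trace.times <= cyc.cyt_end)
        vm = (4 / 3) * np.pi * trace.mother_major[mask] * trace.mother_minor[mask] ** 2
        dR, dr = trace.daughter_major[mask], trace.daughter_minor[mask]
        tt = trace.times[mask]
        meas = np.isfinite(dR) & (tt > cyc.budding_time)
        vd = np.zeros_like(vm)
        vd[meas] = (4 / 3) * np.pi * dR[meas] * dr[meas] ** 2
        ramp = (tt > cyc.budding_time) & ~meas & (tt < tt[meas][0])
        vd[ramp] = vd[meas][0] * (tt[ramp] - cyc.budding_time) / (tt[meas][0] - cyc.budding_time)
        inner = (times >= tt[0]) & (times <= tt[-1])
        np.testing.assert_allclose(v[inner], vm + vd, rtol=1e-12)

    def test_missing_mother_radii_rejected(self):
        t = np.arange(0.0, 200.0, 6.0)
        tr = flat_trace(t, cyts=[0.0, 198.0], buds=[60.0])
        broken = CellTrace(
            cell_id="t",
            times=tr.times,
            mother_major=np.where(tr.times == 60.0, np.nan, tr.mother_major),
            mother_minor=tr.mother_minor,
            yfp_mean=tr.yfp_mean,
            mcherry_mean=tr.mcherry_mean,
            budding_times=tr.budding_times,
            cytokinesis_times=tr.cytokinesis_times,
        )
        with pytest.raises(IncompleteTraceError):
            assemble_volume(broken, CellCycle("t", 0.0, 198.0, 60.0))


class TestGpSmooth:
    def test_constant_series_reproduced(self):
        t = np.arange(0.0, 300.0, 6.0)
        out = gp_smooth(t, np.full(t.size, 10.0), np.linspace(0, 294, 295))
        np.testing.assert_allclose(out, 10.0, atol=1e-6)

    def test_slow_sinusoid_tracked_within_2pct(self):
        t = np.arange(0.0, 300.0 + 1e-9, 6.0)
        y = 5.0 + 2.0 * np.sin(2 * np.pi * t / 300.0)
        dense = np.linspace(0, 300, 301)
        truth = 5.0 + 2.0 * np.sin(2 * np.pi * dense / 300.0)
        out = gp_smooth(t, y, dense, seed=0)
        assert np.abs(out - truth).max() < 0.02 * 2.0

    def test_white_noise_shrunk_toward_mean(self):
        hits = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            t = np.arange(0.0, 300.0, 6.0)
            y = 5.0 + rng.normal(0, 1.0, t.size)
            out = gp_smooth(t, y, t, seed=seed)
            hits.append(np.mean((out > 4.5) & (out < 5.5)))
        assert np.mean(hits) >= 0.95

    def test_too_few_points(self):
        with pytest.raises(Exception):
            gp_smooth(np.arange(5.0), np.arange(5.0), np.arange(5.0))


class TestProductionRate:
    def test_linear_abundance_gives_constant_rate(self):
        t = np.arange(0.0, 100.0, 1.0)
        r = production_rate(3.0 * t, 1.0, 20.0)
        np.testing.assert_allclose(r, 3.0, atol=1e-9)

    def test_quadratic_abundance_analytic(self):
        t = np.arange(0.0, 100.0, 1.0)
        r = production_rate(t**2, 1.0, LN2)
        np.testing.assert_allclose(r[1:-1], 2.0 + 2.0 * t[1:-1], rtol=1e-9)

    def test_ode_inversion_recovers_production_program(self):
        # forward-simulate maturation for a smooth program, invert, compare
        from scipy.integrate import solve_ivp

        t = np.arange(0.0, 400.0, 1.0)
        t_half = 50.0
        k = LN2 / t_half

        def program(tt):
            return 2.0 + np.sin(2 * np.pi * tt / 200.0)

        sol = solve_ivp(
            lambda tt, y: [program(tt) - k * y[0], k * y[0]],
            (0.0, 400.0),
            [program(0.0) / k, 0.0],
            t_eval=t,
            rtol=1e-10,
            atol=1e-12,
        )
        r = production_rate(sol.y[1], 1.0, t_half)
        inner = slice(5, -5)
        rel = np.abs(r[inner] - program(t[inner])) / program(t[inner])
        assert rel.max() < 0.02

    def test_coarse_grid_rejected(self):
        with pytest.raises(GridTooCoarseError):
            production_rate(np.arange(10.0), 6.0, 20.0)


class TestDetrendNormalize:
    def test_linear_rate_degenerate(self):
        with pytest.raises(DegenerateNormalizationError):
            detrend_normalize(np.linspace(1.0, 5.0, 50))

    def test_sine_extremes_and_argmax(self):
        t = np.linspace(0.0, 1.0, 201)
        out = detrend_normalize(np.sin(2 * np.pi * t))
        assert out.min() == 0.0 and out.max() == 1.0
        assert abs(t[np.argmax(out)] - 0.25) <= 1.0 / 200

    def test_bounds_attained_bitwise(self):
        rng = np.random.default_rng(0)
        out = detrend_normalize(rng.normal(size=100))
        assert out.min() == 0.0 and out.max() == 1.0


class TestUncoupling:
    def test_identical_inputs_give_zero(self):
        x = np.random.default_rng(1).uniform(0, 1, 50)
        np.testing.assert_array_equal(uncoupling(x, x), np.zeros(50))

    def test_extreme_difference(self):
        assert uncoupling(np.array([1.0]), np.array([0.0]))[0] == 1.0

    def test_quarter_period_shifted_sinusoids(self):
        t = np.linspace(0.0, 1.0, 400, endpoint=False)
        a = 0.5 + 0.5 * np.sin(2 * np.pi * t)
        b = 0.5 + 0.5 * np.sin(2 * np.pi * (t - 0.25))
        # sin x - cos'... difference of quarter-shifted sines is a scaled sine
        expected = np.sqrt(2) * 0.5 * np.sin(2 * np.pi * t + np.pi / 4)
        np.testing.assert_allclose(uncoupling(a, b), expected, atol=1e-12)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            uncoupling(np.zeros(5), np.zeros(6))


class TestPhaseFormulas:
    def test_mean_event_phase_single_cycle(self):
        c = CellCycle("t", 0.0, 200.0, 50.0)
        assert mean_event_phase([c])["budding"] == pytest.approx(0.25)

    def test_mean_event_phase_averages(self):
        cs = [CellCycle("t", 0.0, 200.0, 50.0), CellCycle("t", 0.0, 200.0, 60.0)]
        phases = mean_event_phase(cs)
        assert phases["budding"] == pytest.approx(0.275)
        assert phases["cytokinesis"] == 0.0
        assert phases["next_cytokinesis"] == 1.0

    def test_phase_map_hand_example(self):
        cyc = CellCycle("t", 0.0, 240.0, 60.0)
        phases = {"cytokinesis": 0.0, "budding": 0.25, "next_cytokinesis": 1.0}
        assert phase_map(120.0, cyc, phases) == pytest.approx(0.5)
        assert phase_map(60.0, cyc, phases) == 0.25
        assert phase_map(0.0, cyc, phases) == 0.0

    def test_phase_map_monotone_on_random_cycles(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            c0 = rng.uniform(0, 100)
            dur = rng.uniform(150, 300)
            bud = c0 + rng.uniform(0.1, 0.9) * dur
            cyc = CellCycle("t", c0, c0 + dur, bud)
            phases = {
                "cytokinesis": 0.0,
                "budding": rng.uniform(0.05, 0.95),
                "next_cytokinesis": 1.0,
            }
            t = np.sort(rng.uniform(c0, c0 + dur, 30))
            out = phase_map(t, cyc, phases)
            assert np.all(np.diff(out) > 0)

    def test_phase_map_out_of_cycle(self):
        cyc = CellCycle("t", 0.0, 240.0, 60.0)
        with pytest.raises(OutOfCycleError):
            phase_map(250.0, cyc, {"cytokinesis": 0.0, "budding": 0.25, "next_cytokinesis": 1.0})


class TestUncouplingProfile:
    def test_insufficient_cycles(self):
        t = np.arange(0.0, 526.0, 6.0)
        tr = flat_trace(t, cyts=[0.0, 200.0], buds=[60.0])
        with pytest.raises(InsufficientCyclesError):
            uncoupling_profile([tr], SensorParams.preset("WT"), min_cycles=3)

    def test_constant_fluorescence_cycles_all_excluded(self):
        # flat signals make the detrended rate degenerate in every cycle
        t = np.arange(0.0, 706.0, 6.0)
        tr = flat_trace(t, cyts=[0.0, 200.0, 400.0, 600.0], buds=[60.0, 260.0, 460.0])
        with pytest.raises(InsufficientCyclesError):
            uncoupling_profile([tr], SensorParams.preset("WT"))

    def test_profile_structure_and_determinism(self):
        cfg = SimConfig(seed=31, cycle=CycleConfig(n_cycles=2))
        traces, _ = simulate_cell_traces(cfg, 2)
        prof1 = uncoupling_profile(traces, cfg.sensor, seed=9)
        prof2 = uncoupling_profile(traces, cfg.sensor, seed=9)
        assert prof1.n_cycles >= 3
        assert np.all(prof1.ci_low <= prof1.mean + 1e-12)
        assert np.all(prof1.mean <= prof1.ci_high + 1e-12)
        assert 0.0 < prof1.mean_budding_phase < 1.0
        np.testing.assert_array_equal(prof1.mean, prof2.mean)
        np.testing.assert_array_equal(prof1.ci_low, prof2.ci_low)
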