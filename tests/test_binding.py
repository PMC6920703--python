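import numpy as np
import pytest

from fluxlens import binding
from fluxlens.binding import (
    BindingFit,
    GelLane,
    MeltCurve,
    SensorParams,
    TmSeries,
    extract_tm,
    fit_tm_binding,
    fraction_bound,
    gel_bound_fraction,
    gel_release_ratio,
    normalize_tm_to_fraction,
    sensor_transfer,
    sensor_transfer_bounds,
)
from fluxlens.errors import (
    DegenerateCurveError,
    DegenerateNormalizationError,
    EmptyLaneError,
    InsufficientDataError,
    InvalidInputError,
)

TEMPS = np.arange(20.0, 99.0 + 1e-9, 0.5)


def logistic_melt(tm, scale=1.5, amp=100.0):
    return amp / (1.0 + np.exp(-(TEMPS - tm) / scale))


class TestExtractTm:
    def test_logistic_midpoint_recovered(self):
        curve = MeltCurve(0.0, TEMPS, logistic_melt(55.0))
        assert extract_tm(curve) == pytest.approx(55.0, abs=0.5)

    def test_flat_curve_is_degenerate(self):
        curve = MeltCurve(0.0, TEMPS, np.full_like(TEMPS, 3.0))
        with pytest.raises(DegenerateCurveError):
            extract_tm(curve)

    def test_matches_bruteforce_argmax_with_drift(self):
        # independent oracle: argmax over the centered finite-difference vector
        f = logistic_melt(60.0, scale=2.0) + 0.01 * TEMPS
        curve = MeltCurve(0.0, TEMPS, f)
        deriv = (f[2:] - f[:-2]) / (TEMPS[2:] - TEMPS[:-2])
        oracle = TEMPS[1:-1][np.argmax(deriv)]
        assert extract_tm(curve) == oracle

    def test_non_monotone_temperatures_rejected(self):
        t = TEMPS.copy()
        t[10] = t[9]
        with pytest.raises(InvalidInputError):
            MeltCurve(0.0, t, logistic_melt(55.0))


def hill_tm_series(kd, n, tm0=50.0, span=8.0, noise_sd=0.0, reps=1, rng=None):
    concs = np.array(binding.THERMAL_SHIFT_CONCENTRATIONS_MM)
    cc, tt = [], []
    for c in concs:
        tm = tm0 + span * (c**n / (kd**n + c**n) if c > 0 else 0.0)
        for _ in range(reps):
            obs = tm + (rng.normal(0, noise_sd) if noise_sd else 0.0)
            cc.append(c)
            tt.append(obs)
    return TmSeries(np.array(cc), np.array(tt))


class TestFitTmBinding:
    @pytest.mark.parametrize("kd", [0.1, 0.5, 1.0, 2.6, 10.0])
    @pytest.mark.parametrize("n", [1.0, 2.0])
    def test_noise_free_recovery_within_1pct(self, kd, n):
        fit = fit_tm_binding(hill_tm_series(kd, n))
        assert fit.bindable
        assert fit.kd == pytest.approx(kd, rel=0.01)
        assert fit.hill_n == pytest.approx(n, rel=0.01)
        assert fit.tm_unbound == pytest.approx(50.0, abs=0.05)
        assert fit.tm_span == pytest.approx(8.0, rel=0.01)

    def test_zero_span_flagged_unbindable(self):
        fit = fit_tm_binding(hill_tm_series(1.0, 1.0, span=0.0))
        assert not fit.bindable
        assert fit.kd_ci[0] <= 0.01 and fit.kd_ci[1] >= 100.0

    def test_too_few_concentrations(self):
        s = TmSeries(np.array([0.0, 1.0, 10.0]), np.array([50.0, 54.0, 57.0]))
        with pytest.raises(InsufficientDataError):
            fit_tm_binding(s)

    def test_kd_ci_brackets_estimate(self):
        rng = np.random.default_rng(0)
        fit = fit_tm_binding(hill_tm_series(1.0, 1.0, noise_sd=0.3, reps=5, rng=rng))
        assert fit.kd_ci[0] <= fit.kd <= fit.kd_ci[1]


class TestFractionBound:
    def test_half_occupancy_at_kd(self):
        assert fraction_bound(1.0, 1.0, 1.0) == pytest.approx(0.5)
        assert fraction_bound(2.6, 1.0, 2.6) == pytest.approx(0.5)

    def test_zero_ligand_unbound(self):
        assert fraction_bound(1.0, 1.0, 0.0) == 0.0

    def test_monotone_in_ligand_and_kd(self):
        grid = np.linspace(0, 20, 500)
        f = fraction_bound(1.0, 1.0, grid)
        assert np.all(np.diff(f) >= 0)
        # weaker binder is below the tighter binder everywhere (L > 0)
        assert np.all(fraction_bound(1.5, 1.0, grid[1:]) < fraction_bound(0.8, 1.0, grid[1:]))

    def test_negative_ligand_rejected(self):
        with pytest.raises(InvalidInputError):
            fraction_bound(1.0, 1.0, -0.5)

    def test_wt_vs_r250a_differ_most_at_intermediate_fbp(self):
        # the two variants' occupancy curves separate maximally between
        # their dissociation constants, i.e. at intermediate FBP
        wt = SensorParams.preset("WT")
        mut = SensorParams.preset("R250A")
        grid = np.arange(0.0, 10.0, 0.01)
        delta = np.abs(
            fraction_bound(wt.kd, wt.hill_n, grid) - fraction_bound(mut.kd, mut.hill_n, grid)
        )
        argmax = grid[np.argmax(delta)]
        assert 1.0 <= argmax <= 2.5


class TestNormalizeTm:
    def test_midpoint_fraction(self):
        s = TmSeries(np.array([0.0, 1.0, 36.0]), np.array([50.0, 54.0, 58.0]))
        out = normalize_tm_to_fraction(s)
        frac = dict(zip(out["ligand_mM"], out["fraction"]))
        assert frac[1.0] == pytest.approx(0.5)
        assert frac[0.0] == 0.0 and frac[36.0] == 1.0

    def test_flat_series_degenerate(self):
        s = TmSeries(np.array([0.0, 1.0, 36.0]), np.array([50.0, 50.0, 50.0]))
        with pytest.raises(DegenerateNormalizationError):
            normalize_tm_to_fraction(s)

    def test_endpoints_exact_for_noisy_series(self):
        rng = np.random.default_rng(1)
        s = hill_tm_series(1.0, 1.0, noise_sd=0.3, reps=5, rng=rng)
        out = normalize_tm_to_fraction(s)
        frac = dict(zip(out["ligand_mM"], out["fraction"]))
        assert frac[0.0] == 0.0
        assert frac[36.0] == 1.0


class TestGelOps:
    @pytest.mark.parametrize(
        "cx,free,expected", [(50.0, 50.0, 0.5), (30.0, 70.0, 0.3), (100.0, 0.0, 1.0)]
    )
    def test_bound_fraction(self, cx, free, expected):
        assert gel_bound_fraction(GelLane(0.0, cx, free)) == pytest.approx(expected)

    def test_empty_lane(self):
        with pytest.raises(EmptyLaneError):
            gel_bound_fraction(GelLane(0.0, 0.0, 0.0))

    def test_release_ratio(self):
        lanes = [GelLane(0.0, 90.0, 10.0), GelLane(20.0, 30.0, 70.0)]
        assert gel_release_ratio(lanes).ratio == pytest.approx(3.0)

    def test_no_release(self):
        lanes = [GelLane(0.0, 50.0, 50.0), GelLane(20.0, 50.0, 50.0)]
        out = gel_release_ratio(lanes)
        assert out.ratio == pytest.approx(1.0) and not out.infinite

    def test_infinite_release_flag(self):
        lanes = [GelLane(0.0, 90.0, 10.0), GelLane(20.0, 0.0, 70.0)]
        out = gel_release_ratio(lanes)
        assert out.infinite


class TestSensorTransfer:
    def test_full_repression_leaves_basal_leak(self):
        p = SensorParams(kd=1.0, theta_max=1.0, basal_activity=0.05)
        assert sensor_transfer(p, 0.0) == pytest.approx(0.05)

    def test_limits_match_closed_forms(self):
        p = SensorParams.preset("R250A")
        lo, hi = sensor_transfer_bounds(p)
        assert sensor_transfer(p, 0.0) == pytest.approx(lo)
        assert sensor_transfer(p, 1e7) == pytest.approx(hi, rel=1e-4)

    def test_monotone_on_physiological_grid(self):
        p = SensorParams.preset("WT")
        out = sensor_transfer(p, np.linspace(0.0, 8.0, 400))
        assert np.all(np.diff(out) >= 0)

    def test_preset_fold_changes(self):
        wt = SensorParams.preset("WT").kd
        assert wt == 1.0
        assert SensorParams.preset("R250A").kd / wt == pytest.approx(1.5)
        assert SensorParams.preset("T151V").kd / wt == pytest.approx(2.6)
        assert wt / SensorParams.preset("T152S").kd == pytest.approx(1.6)

    def test_invalid_params_rejected(self):
        with pytest.raises(InvalidInputError):
            SensorParams(kd=-1.0)
        with pytest.raises(InvalidInputError):
            SensorParams(kd=1.0, residual_bound=1.5)
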