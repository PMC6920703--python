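"""Synthetic-data generators with known ground truth for every pipeline input.

Each generator is a pure function of (config, seed) and emulates the
statistical structure the corresponding analysis module assumes:

- single-cell traces: exponential volume growth subdivided by budding and
  cytokinesis, a circular-Gaussian cell-cycle FBP program driving
  sensor-regulated YFP and constitutive mCherry through first-order
  maturation, additive Gaussian imaging noise on fluorescence and radii;
- cytometry: log-normal two-channel intensities per strain preset over an
  autofluorescence floor, mixed at exact (deterministic) counts;
- thermal shift: Hill-form Tm shifts with Gaussian replicate noise, plus
  raw logistic melting curves;
- conditions: a linear FBP-flux structure with replicate FBP scatter and
  condition-level flux/growth uncertainty;
- batch: exponential growth with constant yields.

Ground truth is returned alongside every dataset so that recovery tests can
compare against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from fluxlens.binding import (
    THERMAL_SHIFT_CONCENTRATIONS_MM,
    MeltCurve,
    SensorParams,
    TmSeries,
    fraction_bound,
    sensor_transfer,
)
from fluxlens.calibration import ConditionDataset
from fluxlens.cytometry import EventTable
from fluxlens.errors import ConfigError
from fluxlens.physiology import BatchTimecourse
from fluxlens.timelapse import LN2, CellTrace

# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class CycleConfig:
    """Cell-cycle and FBP-program parameters.

    The FBP program is a circular Gaussian bump on the phase axis:
    baseline 1 mM rising to 4 mM at the peak, spanning the physiological
    window; the peak sits just before cytokinesis by default.
    """

    duration_mean: float = 220.0  # min
    duration_sd: float = 35.0
    duration_clip: Tuple[float, float] = (155.0, 295.0)
    budding_phase: float = 0.30
    budding_phase_sd: float = 0.06
    fbp_baseline: float = 1.0  # mM
    fbp_peak: float = 3.0  # mM above baseline
    fbp_peak_phase: float = 0.95
    fbp_peak_width: float = 0.12
    expression_amp: float = 0.0  # shared cell-cycle modulation of expression
    expression_phase: float = 0.45  # phase of maximal global expression
    n_cycles: int = 3
    volume_birth: float = 30.0  # fl, mother volume at trace start
    mother_growth_per_cycle: float = 1.2  # fold mother volume gain per cycle
    daughter_fraction: float = 0.55  # bud volume at cytokinesis / mother volume at budding


@dataclass(frozen=True)
class ImagingConfig:
    """Time-lapse acquisition: 6-min frames, additive Gaussian noise."""

    interval: float = 6.0  # min
    fluor_noise_sd: float = 2.0  # a.u., on ~100 a.u. signals
    radius_noise_sd: float = 0.03  # um
    aspect_ratio: float = 1.15  # major/minor radius
    daughter_seg_lag: float = 12.0  # min from budding to first bud segmentation


@dataclass(frozen=True)
class CytometryConfig:
    """Two-strain mixture presets on log-ratio scale.

    The strain log-ratio means differ by 1.2 natural-log units with sd 0.35
    so that the two clouds separate the way distinct high-/low-flux strains
    do; these are fixture constants of the generator, not measured values.
    """

    strain_log_ratio: Dict[str, float] = field(
        default_factory=lambda: {"WT": 0.6, "TM6": -0.6}
    )
    log_ratio_sd: float = 0.35
    fl3_log_mean: float = math.log(600.0)
    fl3_log_sd: float = 0.30
    autofluor_fl1: float = 50.0
    autofluor_fl3: float = 40.0
    autofluor_log_sd: float = 0.25
    n_events: int = 100_000


@dataclass(frozen=True)
class CalibrationConfig:
    """Linear FBP-flux structure across steady-state conditions."""

    slope: float = 1.4  # flux units per mM
    intercept: float = -0.2
    fbp_condition_means: Tuple[float, ...] = (0.3, 1.0, 2.0, 3.5, 5.5, 7.5)
    measurements_per_condition: Tuple[int, ...] = (9, 9, 9, 9, 9, 8)  # 53 total
    fbp_cv: float = 0.15  # replicate scatter, multiplicative
    flux_sd_frac: float = 0.08
    flux_sd_floor: float = 0.05
    growth_intercept: float = 0.10  # h^-1
    growth_slope: float = 0.025  # per flux unit
    growth_noise_sd: float = 0.05
    growth_sd: float = 0.02


@dataclass(frozen=True)
class ThermalConfig:
    """Thermal-shift protocol emulation."""

    tm_unbound: float = 50.0  # degC
    tm_span: float = 8.0
    tm_noise_sd: float = 0.3
    n_replicates: int = 5
    concentrations: Tuple[float, ...] = THERMAL_SHIFT_CONCENTRATIONS_MM
    temp_start: float = 20.0
    temp_stop: float = 99.0
    temp_step: float = 0.5
    melt_steepness: float = 1.5  # degC, logistic scale of the raw melt


@dataclass(frozen=True)
class BatchConfig:
    """Exponential batch culture with constant yields."""

    x0: float = 0.1  # gDW/l
    mu: float = 0.3  # h^-1
    t_end: float = 6.0  # h
    dt: float = 1.0
    metabolites: Dict[str, Tuple[float, float, str]] = field(
        default_factory=lambda: {
            "glucose": (10.0, 5.0, "uptake"),
            "ethanol": (0.0, 3.0, "product"),
        }
    )  # name -> (c0, q, role)
    noise_sd: float = 0.0


@dataclass(frozen=True)
class SimConfig:
    """Top-level simulation scenario."""

    seed: int = 0
    scenario: str = "default"
    sensor: SensorParams = field(default_factory=lambda: SensorParams.preset("R250A"))
    cycle: CycleConfig = field(default_factory=CycleConfig)
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    cytometry: CytometryConfig = field(default_factory=CytometryConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    thermal: ThermalConfig = field(default_factory=ThermalConfig)
    batch: BatchConfig = field(default_factory=BatchConfig)

    def __post_init__(self) -> None:
        for name, value in (
            ("cycle.duration_sd", self.cycle.duration_sd),
            ("imaging.fluor_noise_sd", self.imaging.fluor_noise_sd),
            ("imaging.radius_noise_sd", self.imaging.radius_noise_sd),
            ("thermal.tm_noise_sd", self.thermal.tm_noise_sd),
        ):
            if value < 0:
                raise ConfigError(f"{name}: must be non-negative")
        for name, value in (
            ("cycle.budding_phase", self.cycle.budding_phase),
            ("cycle.fbp_peak_phase", self.cycle.fbp_peak_phase),
        ):
            if not 0 <= value < 1:
                raise ConfigError(f"{name}: must lie in [0, 1)")


# ---------------------------------------------------------------------------
# single-cell traces


def _circular_bump(phase: np.ndarray, center: float, width: float) -> np.ndarray:
    d = np.abs(phase - center)
    d = np.minimum(d, 1.0 - d)
    return np.exp(-0.5 * (d / width) ** 2)


# expression scales chosen so that steady-state matured concentrations sit
# around 100 a.u. with ~200-min cycles (a.u. are arbitrary but shared by the
# imaging noise sd)
_K_EXPR_YFP = 1.0
_K_EXPR_MCH = 0.4


def _phase_timeline(t: np.ndarray, cyts: np.ndarray, durations: np.ndarray) -> np.ndarray:
    """Continuous cell-cycle phase for all times, extrapolating beyond the
    first/last cytokinesis with the adjacent cycle's duration."""
    phi = np.empty_like(t)
    before = t < cyts[0]
    phi[before] = ((t[before] - cyts[0]) / durations[0]) % 1.0
    after = t >= cyts[-1]
    phi[after] = ((t[after] - cyts[-1]) / durations[-1]) % 1.0
    for j in range(len(durations)):
        sel = (t >= cyts[j]) & (t < cyts[j + 1])
        phi[sel] = (t[sel] - cyts[j]) / durations[j]
    return phi


def simulate_cell_traces(
    cfg: SimConfig, n_cells: int, seed: int | None = None
) -> tuple[List[CellTrace], dict]:
    """Simulate segmented time-lapse traces with known FBP ground truth.

    Per cell: cycle durations are drawn from a clipped normal; the mother
    grows exponentially (slowly) throughout while each bud grows from zero
    at budding to its final size at cytokinesis along a smoothstep, then
    detaches. A circular-Gaussian FBP program on the phase axis drives
    YFP production through the sensor transfer function while mCherry is
    produced constitutively; both channels pass through the two-pool
    (immature/mature) first-order maturation ODE, tracked as concentrations
    so that cytokinesis (a volume drop at constant concentration) needs no
    special casing. Observed per-pixel fluorescence is the mature
    concentration plus Gaussian noise; ellipse radii are back-computed from
    mother/daughter volumes at a fixed aspect ratio plus noise. Events are
    reported exactly.

    Returns (traces, truth) where truth carries, per cell, the event times,
    durations, and the FBP/phase/production programs on the 1-min grid.
    """
    if n_cells < 1:
        raise ConfigError("n_cells: must be >= 1")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    cyc, img = cfg.cycle, cfg.imaging
    lead, tail = 60.0, 60.0

    traces: List[CellTrace] = []
    truth_cells: List[dict] = []
    for i in range(n_cells):
        crng = np.random.default_rng(rng.integers(0, 2**31))
        durations = np.clip(
            crng.normal(cyc.duration_mean, cyc.duration_sd, size=cyc.n_cycles),
            *cyc.duration_clip,
        )
        cyts = lead + np.concatenate([[0.0], np.cumsum(durations)])
        bud_phases = np.clip(
            crng.normal(cyc.budding_phase, cyc.budding_phase_sd, size=cyc.n_cycles),
            0.05,
            0.9,
        )
        buddings = cyts[:-1] + bud_phases * durations
        t_end = cyts[-1] + tail

        # 1-min simulation grid
        sim_t = np.arange(0.0, t_end + 0.5, 1.0)
        phi = _phase_timeline(sim_t, cyts, durations)
        fbp = cyc.fbp_baseline + cyc.fbp_peak * _circular_bump(
            phi, cyc.fbp_peak_phase, cyc.fbp_peak_width
        )
        activity = np.asarray(sensor_transfer(cfg.sensor, fbp))

        # Smooth volume program: the mother grows exponentially throughout
        # (slow, ~20% per cycle); each bud grows from zero at budding to its
        # final size at cytokinesis along a smoothstep (zero slope at both
        # ends — bud growth plateaus before cytokinesis), then detaches.
        # Total volume and its derivative are then C^1 along the whole
        # trace, as real mother+bud trajectories are to imaging resolution.
        g_m = math.log(cyc.mother_growth_per_cycle) / float(np.mean(durations))
        v_birth = cyc.volume_birth * (1 + 0.1 * crng.standard_normal())
        v_m = v_birth * np.exp(g_m * sim_t)
        v_d = np.zeros_like(sim_t)
        dv_d = np.zeros_like(sim_t)
        for j in range(cyc.n_cycles):
            sel = (sim_t > buddings[j]) & (sim_t <= cyts[j + 1])
            span = cyts[j + 1] - buddings[j]
            x = (sim_t[sel] - buddings[j]) / span
            v_final = cyc.daughter_fraction * v_birth * math.exp(g_m * (buddings[j]))
            # quintic smoothstep: zero first and second derivatives at both
            # ends, so dilution stays C^1 across budding and cytokinesis
            v_d[sel] = v_final * x**3 * (10.0 - 15.0 * x + 6.0 * x**2)
            dv_d[sel] = v_final * 30.0 * x**2 * (1.0 - x) ** 2 / span
        v_tot = v_m + v_d
        g_of_t = (g_m * v_m + dv_d) / v_tot  # dilution rate of the mother+bud unit

        # two-pool maturation, tracked as concentrations:
        #   cI' = s(t) - (k + g) cI ;  cA' = k cI - g cA
        def integrate(s: np.ndarray, k: float) -> np.ndarray:
            c_i = np.empty_like(sim_t)
            c_a = np.empty_like(sim_t)
            g0 = g_of_t[0]
            c_i[0] = s[0] / (k + g0)
            c_a[0] = k * c_i[0] / g0
            for m in range(sim_t.size - 1):
                h = sim_t[m + 1] - sim_t[m]
                gm, gp_ = g_of_t[m], g_of_t[m + 1]
                g_mid = 0.5 * (gm + gp_)
                sm, sp = s[m], s[m + 1]
                s_mid = 0.5 * (sm + sp)

                def rhs(ci, ca, sv, g):
                    return sv - (k + g) * ci, k * ci - g * ca

                k1i, k1a = rhs(c_i[m], c_a[m], sm, gm)
                k2i, k2a = rhs(c_i[m] + 0.5 * h * k1i, c_a[m] + 0.5 * h * k1a, s_mid, g_mid)
                k3i, k3a = rhs(c_i[m] + 0.5 * h * k2i, c_a[m] + 0.5 * h * k2a, s_mid, g_mid)
                k4i, k4a = rhs(c_i[m] + h * k3i, c_a[m] + h * k3a, sp, gp_)
                c_i[m + 1] = c_i[m] + h / 6 * (k1i + 2 * k2i + 2 * k3i + k4i)
                c_a[m + 1] = c_a[m] + h / 6 * (k1a + 2 * k2a + 2 * k3a + k4a)
            return c_a

        # production per unit volume: a shared cell-cycle expression-activity
        # modulation (the extrinsic variation the mCherry channel exists to
        # normalize away) multiplies both channels; the sensor additionally
        # modulates YFP; total production is proportional to V(t)
        expr = 1.0 + cyc.expression_amp * np.cos(
            2.0 * np.pi * (phi - cyc.expression_phase)
        )
        k_y = LN2 / cfg.sensor.yfp_mat_halftime
        k_c = LN2 / cfg.sensor.mcherry_mat_halftime
        s_yfp = _K_EXPR_YFP * expr * activity
        s_mch = _K_EXPR_MCH * expr
        conc_y = integrate(s_yfp, k_y)
        conc_c = integrate(s_mch, k_c)

        # sample frames
        frames = np.arange(0.0, t_end + 1e-9, img.interval)
        fi = np.searchsorted(sim_t, frames)  # sim grid is 1-min, frames align
        yfp = conc_y[fi] + crng.normal(0.0, img.fluor_noise_sd, frames.size)
        mch = conc_c[fi] + crng.normal(0.0, img.fluor_noise_sd, frames.size)

        a = img.aspect_ratio

        def radii(volumes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            minor = np.cbrt(3.0 * volumes / (4.0 * np.pi * a))
            return a * minor, minor

        mR, mr = radii(v_m[fi])
        mR = mR + crng.normal(0.0, img.radius_noise_sd, frames.size)
        mr = mr + crng.normal(0.0, img.radius_noise_sd, frames.size)

        dR = np.full(frames.size, np.nan)
        dr = np.full(frames.size, np.nan)
        for j in range(cyc.n_cycles):
            vis = (frames >= buddings[j] + img.daughter_seg_lag) & (frames <= cyts[j + 1])
            if np.any(vis):
                dRj, drj = radii(np.maximum(v_d[fi][vis], 1e-3))
                dR[vis] = dRj + crng.normal(0.0, img.radius_noise_sd, int(vis.sum()))
                dr[vis] = drj + crng.normal(0.0, img.radius_noise_sd, int(vis.sum()))

        traces.append(
            CellTrace(
                cell_id=f"cell{i:03d}",
                times=frames,
                mother_major=mR,
                mother_minor=mr,
                daughter_major=dR,
                daughter_minor=dr,
                yfp_mean=yfp,
                mcherry_mean=mch,
                budding_times=buddings,
                cytokinesis_times=cyts,
            )
        )
        truth_cells.append(
            {
                "cell_id": f"cell{i:03d}",
                "cytokinesis_times": cyts.tolist(),
                "budding_times": buddings.tolist(),
                "durations": durations.tolist(),
                "sim_times": sim_t,
                "fbp": fbp,
                "phase": phi,
                "yfp_production_per_fl": s_yfp,
                "volume_total": v_m + v_d,
            }
        )
    truth = {
        "fbp_peak_phase": cfg.cycle.fbp_peak_phase,
        "fbp_baseline": cfg.cycle.fbp_baseline,
        "fbp_peak": cfg.cycle.fbp_peak,
        "cells": truth_cells,
    }
    return traces, truth


# ---------------------------------------------------------------------------
# cytometry


def simulate_cytometry(
    cfg: SimConfig,
    fractions: Dict[str, float] | None = None,
    n_events: int | None = None,
    seed: int | None = None,
) -> tuple[EventTable, EventTable, dict]:
    """Simulate a two-strain mixture and its non-fluorescent control.

    Channel intensities are log-normal per strain over a log-normal
    autofluorescence floor; mixture counts are exact (``round(f * n)``), not
    binomial. Returns (sample, control, truth).
    """
    cy = cfg.cytometry
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    if fractions is None:
        fractions = {"WT": 1.0}
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ConfigError("cytometry.fractions: must sum to 1")
    for strain in fractions:
        if strain not in cy.strain_log_ratio:
            raise ConfigError(f"cytometry.fractions: unknown strain {strain!r}")
    n = cy.n_events if n_events is None else n_events

    # exact counts, remainder to the largest fraction
    counts = {s: int(round(f * n)) for s, f in fractions.items()}
    largest = max(fractions, key=lambda s: fractions[s])
    counts[largest] += n - sum(counts.values())

    fl1_parts, fl3_parts, labels = [], [], []
    for strain, m in counts.items():
        if m == 0:
            continue
        fl3_sig = np.exp(rng.normal(cy.fl3_log_mean, cy.fl3_log_sd, m))
        ratio = np.exp(rng.normal(cy.strain_log_ratio[strain], cy.log_ratio_sd, m))
        af1 = np.exp(rng.normal(math.log(cy.autofluor_fl1), cy.autofluor_log_sd, m))
        af3 = np.exp(rng.normal(math.log(cy.autofluor_fl3), cy.autofluor_log_sd, m))
        fl1_parts.append(ratio * fl3_sig + af1)
        fl3_parts.append(fl3_sig + af3)
        labels.append(np.full(m, strain))
    fl1 = np.concatenate(fl1_parts)
    fl3 = np.concatenate(fl3_parts)
    order = rng.permutation(fl1.size)
    sample = EventTable(fl1[order], fl3[order], sample_id="mixture")

    m_ctrl = max(n // 10, 1000)
    control = EventTable(
        np.exp(rng.normal(math.log(cy.autofluor_fl1), cy.autofluor_log_sd, m_ctrl)),
        np.exp(rng.normal(math.log(cy.autofluor_fl3), cy.autofluor_log_sd, m_ctrl)),
        sample_id="control",
    )
    truth = {
        "fractions": dict(fractions),
        "counts": counts,
        "strain_log_ratio": dict(cy.strain_log_ratio),
        "labels": np.concatenate(labels)[order],
    }
    return sample, control, truth


# ---------------------------------------------------------------------------
# thermal shift


def simulate_thermal_shift(
    cfg: SimConfig,
    sensor: SensorParams | None = None,
    seed: int | None = None,
    with_curves: bool = False,
) -> tuple[TmSeries, List[MeltCurve], dict]:
    """Simulate a Tm-vs-concentration series (and optionally raw melts).

    True Tm values follow the Hill-form shift model with the sensor's K_D
    and Hill coefficient; replicate noise is Gaussian. Raw curves, when
    requested, are logistic melts with midpoint at the (noisy) Tm.
    """
    th = cfg.thermal
    sensor = cfg.sensor if sensor is None else sensor
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    concs, tms = [], []
    curves: List[MeltCurve] = []
    temp_grid = np.arange(th.temp_start, th.temp_stop + 1e-9, th.temp_step)
    for c in th.concentrations:
        tm_true = th.tm_unbound + th.tm_span * fraction_bound(sensor.kd, sensor.hill_n, c)
        for rep in range(th.n_replicates):
            tm_obs = tm_true + rng.normal(0.0, th.tm_noise_sd)
            concs.append(c)
            tms.append(tm_obs)
            if with_curves:
                f = 100.0 / (1.0 + np.exp(-(temp_grid - tm_obs) / th.melt_steepness))
                curves.append(
                    MeltCurve(
                        ligand_concentration=c,
                        temperatures=temp_grid,
                        fluorescence=f,
                        replicate_id=f"c{c}_r{rep}",
                    )
                )
    series = TmSeries(np.array(concs), np.array(tms))
    truth = {
        "kd": sensor.kd,
        "hill_n": sensor.hill_n,
        "tm_unbound": th.tm_unbound,
        "tm_span": th.tm_span,
    }
    return series, curves, truth


# ---------------------------------------------------------------------------
# conditions (FBP-flux calibration)


def simulate_conditions(
    cfg: SimConfig, seed: int | None = None
) -> tuple[List[ConditionDataset], dict]:
    """Simulate steady-state conditions with a linear FBP-flux backbone.

    Six conditions span the physiological FBP window; each contributes
    several replicate FBP measurements (multiplicative log-normal scatter)
    and a condition-level flux mean exactly on the line, with an sd that is
    a fraction of its magnitude. Growth rate is only weakly tied to flux.
    """
    cal = cfg.calibration
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    if len(cal.fbp_condition_means) != len(cal.measurements_per_condition):
        raise ConfigError("calibration: condition means and counts differ in length")
    conditions: List[ConditionDataset] = []
    sigma = math.sqrt(math.log(1.0 + cal.fbp_cv**2))
    for idx, (fbp_mean, n_meas) in enumerate(
        zip(cal.fbp_condition_means, cal.measurements_per_condition)
    ):
        fbp = fbp_mean * np.exp(rng.normal(-0.5 * sigma**2, sigma, n_meas))
        flux = cal.slope * fbp_mean + cal.intercept
        flux_sd = cal.flux_sd_frac * abs(flux) + cal.flux_sd_floor
        growth = (
            cal.growth_intercept
            + cal.growth_slope * flux
            + rng.normal(0.0, cal.growth_noise_sd)
        )
        conditions.append(
            ConditionDataset(
                condition_id=f"cond{idx}",
                fbp_measurements=fbp,
                flux_mean=flux,
                flux_sd=flux_sd,
                growth_mean=max(growth, 0.01),
                growth_sd=cal.growth_sd,
            )
        )
    truth = {"slope": cal.slope, "intercept": cal.intercept}
    return conditions, truth


# ---------------------------------------------------------------------------
# batch time course


def simulate_batch(cfg: SimConfig, seed: int | None = None) -> tuple[BatchTimecourse, dict]:
    """Simulate an exponential-growth, constant-yield batch time course."""
    b = cfg.batch
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    t = np.arange(0.0, b.t_end + 1e-9, b.dt)
    x = b.x0 * np.exp(b.mu * t)
    metabolites: Dict[str, np.ndarray] = {}
    roles: Dict[str, str] = {}
    for name, (c0, q, role) in b.metabolites.items():
        sign = -1.0 if role == "uptake" else 1.0
        c = c0 + sign * (q / b.mu) * b.x0 * (np.exp(b.mu * t) - 1.0)
        if b.noise_sd > 0:
            c = c + rng.normal(0.0, b.noise_sd * max(float(np.ptp(c)), 1.0), t.size)
        metabolites[name] = c
        roles[name] = role
    tc = BatchTimecourse(times=t, biomass=x, metabolites=metabolites, roles=roles)
    truth = {"mu": b.mu, "x0": b.x0, "q": {n: v[1] for n, v in b.metabolites.items()}}
    return tc, truth
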