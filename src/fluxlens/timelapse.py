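"""Single-cell time-lapse pipeline: from segmented trajectories to the
cell-cycle-aligned YFP/mCherry uncoupling profile.

The chain per cell cycle (the interval between two consecutive cytokinesis
events, budding in between) is:

1. total cell volume from prolate-spheroid mother/daughter ellipse radii,
   with the early unsegmentable daughter linearly interpolated from zero
   volume at budding;
2. Gaussian-process smoothing of volume and the two fluorescence channels
   (RBF kernel, length scale bounded to [30, 48] min, plus a white-noise
   kernel with free level; 50 min of adjacent-cycle data pad each end of
   the fit);
3. abundances ``A_X = V * F_X`` and maturation-corrected production rates
   ``r_X = (t_half / ln 2) * A_X'' + A_X'`` (first-order maturation,
   half-times 20 min YFP / 50 min mCherry);
4. linear detrending between the cycle endpoints and min-max normalization
   to [0, 1];
5. the uncoupling ``u = r~_YFP - r~_mCherry`` as a proxy for momentary FBP;
6. alignment onto a common cell-cycle phase axis anchored at cytokinesis
   (phase 0/1) and the population-mean budding phase, then averaging across
   cycles with a percentile bootstrap confidence band.

Times are in minutes throughout; volumes in fl (1 um^3 = 1 fl).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from fluxlens.binding import SensorParams
from fluxlens.errors import (
    DegenerateNormalizationError,
    GridTooCoarseError,
    IncompleteTraceError,
    InsufficientCyclesError,
    InsufficientDataError,
    InvalidInputError,
    OutOfCycleError,
)

LN2 = math.log(2.0)

#: Cycle-duration inclusion filter (min), closed on both ends.
DEFAULT_MIN_DURATION = 150.0
DEFAULT_MAX_DURATION = 300.0

#: Padding taken from the adjacent cycles to stabilize smoothing edges (min).
DEFAULT_PAD = 50.0

#: Dense evaluation grid step for smoothing and derivatives (min).
DEFAULT_GRID_STEP = 1.0

#: RBF length-scale bounds (min) for the smoothing prior.
LENGTH_SCALE_BOUNDS = (30.0, 48.0)


@dataclass(frozen=True)
class CellTrace:
    """One segmented cell: per-frame ellipse radii (um), mean fluorescence
    (a.u./pixel, background-corrected) and cell-cycle event times (min).

    Daughter radii are NaN before budding and wherever the bud was too small
    to segment.
    """

    cell_id: str
    times: np.ndarray
    mother_major: np.ndarray
    mother_minor: np.ndarray
    yfp_mean: np.ndarray
    mcherry_mean: np.ndarray
    budding_times: np.ndarray
    cytokinesis_times: np.ndarray
    daughter_major: np.ndarray | None = None
    daughter_minor: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        for name in ("mother_major", "mother_minor", "yfp_mean", "mcherry_mean"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size != t.size:
                raise InvalidInputError(f"{name} length mismatch with times")
            object.__setattr__(self, name, arr)
        for name in ("daughter_major", "daughter_minor"):
            arr = getattr(self, name)
            arr = np.full(t.size, np.nan) if arr is None else np.asarray(arr, float)
            if arr.size != t.size:
                raise InvalidInputError(f"{name} length mismatch with times")
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "budding_times", np.sort(np.asarray(self.budding_times, float)))
        object.__setattr__(
            self, "cytokinesis_times", np.sort(np.asarray(self.cytokinesis_times, float))
        )
        if t.size and not np.all(np.diff(t) > 0):
            raise InvalidInputError("times must be strictly increasing")
        for ev in np.concatenate([self.budding_times, self.cytokinesis_times]):
            if not (t[0] <= ev <= t[-1]):
                raise InvalidInputError(f"event at {ev} min lies outside the trace")


@dataclass(frozen=True)
class CellCycle:
    """Half-open interval (cyt_start, cyt_end] with one budding inside."""

    cell_id: str
    cyt_start: float
    cyt_end: float
    budding_time: float

    @property
    def duration(self) -> float:
        return self.cyt_end - self.cyt_start

    @property
    def budding_fraction(self) -> float:
        return (self.budding_time - self.cyt_start) / self.duration


@dataclass(frozen=True)
class PhaseProfile:
    """Cell-cycle-aligned mean uncoupling with a bootstrap confidence band."""

    phase: np.ndarray
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_cycles: int
    mean_budding_phase: float
    seed: int
    exclusions: Tuple[Tuple[str, float, str], ...] = ()

    def peak_phase(self) -> float:
        """Phase of the maximal mean uncoupling."""
        return float(self.phase[int(np.argmax(self.mean))])


def spheroid_volume(major, minor):
    """Prolate-spheroid volume (fl) from ellipse major/minor radii (um):
    ``(4/3) * pi * R * r^2``."""
    R = np.asarray(major, dtype=float)
    r = np.asarray(minor, dtype=float)
    if np.any(R <= 0) or np.any(r <= 0):
        raise InvalidInputError("radii must be positive")
    out = (4.0 / 3.0) * np.pi * R * r**2
    return float(out) if out.ndim == 0 else out


def segment_cycles(
    trace: CellTrace,
    min_duration: float = DEFAULT_MIN_DURATION,
    max_duration: float = DEFAULT_MAX_DURATION,
) -> tuple[List[CellCycle], List[Tuple[str, float, str]]]:
    """Cut a trace into cycles (cyt_i, cyt_{i+1}] passing the filters.

    Returns (kept cycles, dropped list) where each dropped entry is
    (cell_id, cyt_start, reason) with reason one of too-short, too-long,
    missing-budding, multiple-budding. Duration bounds are closed.
    """
    cyts = trace.cytokinesis_times
    kept: List[CellCycle] = []
    dropped: List[Tuple[str, float, str]] = []
    for c0, c1 in zip(cyts[:-1], cyts[1:]):
        buds = trace.budding_times[(trace.budding_times > c0) & (trace.budding_times <= c1)]
        dur = c1 - c0
        if buds.size == 0:
            dropped.append((trace.cell_id, c0, "missing-budding"))
        elif buds.size > 1:
            dropped.append((trace.cell_id, c0, "multiple-budding"))
        elif dur < min_duration:
            dropped.append((trace.cell_id, c0, "too-short"))
        elif dur > max_duration:
            dropped.append((trace.cell_id, c0, "too-long"))
        else:
            kept.append(CellCycle(trace.cell_id, float(c0), float(c1), float(buds[0])))
    return kept, dropped


def assemble_volume(
    trace: CellTrace, cycle: CellCycle, pad: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Total (mother + daughter) volume at the trace's sample times.

    Covers the window [cyt_start - pad, cyt_end + pad]. The daughter is zero
    before budding; between budding (zero volume) and the first frame with
    measured daughter radii it is linearly interpolated in time; afterwards
    it comes from the measured radii, held at the last measured value beyond
    them. Missing mother radii inside the window raise
    :class:`IncompleteTraceError`; a daughter that is never segmented after
    budding triggers a warning and stays at zero (flat interpolant).
    """
    lo, hi = cycle.cyt_start - pad, cycle.cyt_end + pad
    mask = (trace.times >= lo) & (trace.times <= hi)
    t = trace.times[mask]
    mR, mr = trace.mother_major[mask], trace.mother_minor[mask]
    if np.any(~np.isfinite(mR)) or np.any(~np.isfinite(mr)):
        raise IncompleteTraceError(
            f"cell {trace.cell_id}: mother radii missing inside the cycle window"
        )
    v_m = spheroid_volume(mR, mr)

    dR, dr = trace.daughter_major[mask], trace.daughter_minor[mask]
    measured = np.isfinite(dR) & np.isfinite(dr) & (t > cycle.budding_time)
    v_d = np.zeros_like(t)
    if np.any(measured):
        v_meas = spheroid_volume(dR[measured], dr[measured])
        t_meas = t[measured]
        # anchor at (budding, 0), interpolate through measurements, hold last
        xp = np.concatenate([[cycle.budding_time], t_meas])
        fp = np.concatenate([[0.0], np.atleast_1d(v_meas)])
        after_bud = t > cycle.budding_time
        v_d[after_bud] = np.interp(t[after_bud], xp, fp)
    elif cycle.budding_time <= t[-1]:
        warnings.warn(
            f"cell {trace.cell_id}: daughter never segmented after budding; "
            "daughter volume kept at zero",
            stacklevel=2,
        )
    return t, v_m + v_d


def gp_smooth(
    times: np.ndarray,
    values: np.ndarray,
    out_times: np.ndarray,
    seed: int = 0,
    n_restarts: int = 5,
    length_scale_bounds: tuple[float, float] = LENGTH_SCALE_BOUNDS,
) -> np.ndarray:
    """Gaussian-process posterior mean of ``values`` on ``out_times``.

    Kernel: amplitude * RBF(length scale bounded to ``length_scale_bounds``)
    + white noise with free level; hyperparameters maximize the log-marginal
    likelihood with ``n_restarts`` seeded restarts. The fit uses all input
    points (the caller passes cycle plus padding); the output covers only
    ``out_times``.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 8:
        raise InsufficientDataError("GP smoothing needs >= 8 points including padding")
    if float(np.ptp(y)) == 0.0:
        return np.full(np.asarray(out_times).shape, y[0], dtype=float)
    kernel = ConstantKernel(1.0, (1e-4, 1e4)) * RBF(
        np.mean(length_scale_bounds), length_scale_bounds
    ) + WhiteKernel(1e-2, (1e-10, 1e2))
    gp = GaussianProcessRegressor(
        kernel=kernel,
        n_restarts_optimizer=n_restarts,
        normalize_y=True,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        gp.fit(t[:, None], y)
    return gp.predict(np.asarray(out_times, dtype=float)[:, None])


def production_rate(
    abundance: np.ndarray, step: float, mat_halftime: float
) -> np.ndarray:
    """Maturation-corrected production rate from a dense abundance series.

    First-order maturation with rate ``k = ln 2 / t_half`` gives
    ``r(t) = (t_half / ln 2) * A''(t) + A'(t)``; derivatives are centered
    finite differences on the dense grid (one-sided at the endpoints).
    """
    if step > 3.0:
        raise GridTooCoarseError(f"grid step {step} min > 3 min is too coarse")
    if mat_halftime <= 0:
        raise InvalidInputError("maturation half-time must be positive")
    a = np.asarray(abundance, dtype=float)
    d1 = np.gradient(a, step, edge_order=2)
    d2 = np.gradient(d1, step, edge_order=2)
    return (mat_halftime / LN2) * d2 + d1


def detrend_normalize(rate: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Detrend by the endpoint-connecting line, then min-max normalize.

    The returned series attains 0 and 1 exactly. A series that is flat after
    detrending (e.g. an exactly linear rate) raises
    :class:`DegenerateNormalizationError`.
    """
    r = np.asarray(rate, dtype=float)
    line = np.linspace(r[0], r[-1], r.size)
    detrended = r - line
    span = float(np.ptp(detrended))
    scale = max(float(np.abs(r).max()), 1.0)
    if span <= tol * scale:
        raise DegenerateNormalizationError("rate is flat after detrending")
    return (detrended - detrended.min()) / span


def uncoupling(r_yfp: np.ndarray, r_mcherry: np.ndarray) -> np.ndarray:
    """Pointwise difference of the normalized production rates, in [-1, 1]."""
    a = np.asarray(r_yfp, dtype=float)
    b = np.asarray(r_mcherry, dtype=float)
    if a.shape != b.shape:
        raise InvalidInputError("normalized rates must share one grid")
    return a - b


def mean_event_phase(cycles: Sequence[CellCycle]) -> Dict[str, float]:
    """Population-mean relative timing of each anchoring event.

    For every cycle the events are mapped to (t_e - t_cyt)/(t_nextcyt -
    t_cyt) and averaged: cytokinesis is 0 and the next cytokinesis 1 by
    construction; budding lands strictly between.
    """
    if not cycles:
        raise InsufficientDataError("need at least one cycle")
    for c in cycles:
        if not (c.cyt_start < c.budding_time <= c.cyt_end):
            raise OutOfCycleError(f"budding at {c.budding_time} outside cycle")
    phi_bud = float(np.mean([c.budding_fraction for c in cycles]))
    return {"cytokinesis": 0.0, "budding": phi_bud, "next_cytokinesis": 1.0}


def phase_map(t, cycle: CellCycle, mean_phases: Dict[str, float]):
    """Map in-cycle times to cell-cycle phase, piecewise-linearly.

    The three anchor events (cytokinesis, budding, next cytokinesis) of this
    cycle are sent to their population-mean phases (0, phi_budding, 1); time
    in between is interpolated linearly, so the map is continuous and
    strictly increasing.
    """
    tt = np.asarray(t, dtype=float)
    if np.any(tt < cycle.cyt_start) or np.any(tt > cycle.cyt_end):
        raise OutOfCycleError("time outside the cycle interval")
    knots_t = np.array([cycle.cyt_start, cycle.budding_time, cycle.cyt_end])
    knots_phi = np.array(
        [mean_phases["cytokinesis"], mean_phases["budding"], mean_phases["next_cytokinesis"]]
    )
    out = np.interp(tt, knots_t, knots_phi)
    return float(out) if out.ndim == 0 else out


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Fan one top-level seed out into n child seeds deterministically."""
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def cycle_uncoupling(
    trace: CellTrace,
    cycle: CellCycle,
    params: SensorParams,
    seed: int = 0,
    pad: float = DEFAULT_PAD,
    grid_step: float = DEFAULT_GRID_STEP,
    gp_restarts: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the per-cycle pipeline; returns (dense times, uncoupling).

    Stages: volume assembly -> GP smoothing of V, F_YFP, F_mCherry (fit on
    the padded window, evaluated on the dense in-cycle grid) -> abundances
    -> maturation-corrected rates -> detrend/normalize -> difference.
    """
    t_samp, v_samp = assemble_volume(trace, cycle, pad=pad)
    mask = (trace.times >= cycle.cyt_start - pad) & (trace.times <= cycle.cyt_end + pad)
    f_y = trace.yfp_mean[mask]
    f_c = trace.mcherry_mean[mask]

    # exact endpoints so detrending anchors at the cytokineses; the realized
    # step is duration/round(duration/step), within rounding of grid_step
    n_steps = max(int(round(cycle.duration / grid_step)), 4)
    dense = np.linspace(cycle.cyt_start, cycle.cyt_end, n_steps + 1)
    step = cycle.duration / n_steps
    s_v, s_y, s_c = _spawn_seeds(seed, 3)
    v = gp_smooth(t_samp, v_samp, dense, seed=s_v, n_restarts=gp_restarts)
    fy = gp_smooth(t_samp, f_y, dense, seed=s_y, n_restarts=gp_restarts)
    fc = gp_smooth(t_samp, f_c, dense, seed=s_c, n_restarts=gp_restarts)

    a_y = v * fy
    a_c = v * fc
    r_y = production_rate(a_y, step, params.yfp_mat_halftime)
    r_c = production_rate(a_c, step, params.mcherry_mat_halftime)
    u = uncoupling(detrend_normalize(r_y), detrend_normalize(r_c))
    return dense, u


def uncoupling_profile(
    traces: Sequence[CellTrace],
    params: SensorParams,
    seed: int = 0,
    n_bootstrap: int = 5000,
    n_phase: int = 100,
    min_duration: float = DEFAULT_MIN_DURATION,
    max_duration: float = DEFAULT_MAX_DURATION,
    pad: float = DEFAULT_PAD,
    grid_step: float = DEFAULT_GRID_STEP,
    gp_restarts: int = 5,
    min_cycles: int = 3,
) -> PhaseProfile:
    """Cell-cycle-aligned mean uncoupling across all usable cycles.

    Cycles come from :func:`segment_cycles` (duration filter closed at both
    ends); each is processed by :func:`cycle_uncoupling`, mapped onto the
    phase axis via the population-mean budding phase, and linearly resampled
    onto a common ``n_phase``-point grid. The confidence band is the
    2.5/97.5 percentile of profile means over ``n_bootstrap`` resamplings of
    whole cycles with replacement. Cycles failing any stage are excluded and
    logged with a reason.
    """
    all_cycles: List[Tuple[CellTrace, CellCycle]] = []
    exclusions: List[Tuple[str, float, str]] = []
    for trace in traces:
        kept, dropped = segment_cycles(trace, min_duration, max_duration)
        exclusions.extend(dropped)
        all_cycles.extend((trace, c) for c in kept)
    if len(all_cycles) < min_cycles:
        raise InsufficientCyclesError(
            f"only {len(all_cycles)} cycles pass the duration filter (need {min_cycles})"
        )

    mean_phases = mean_event_phase([c for _, c in all_cycles])
    phase_grid = np.linspace(0.0, 1.0, n_phase, endpoint=False)

    cycle_seeds = _spawn_seeds(seed, len(all_cycles) + 1)
    boot_seed = cycle_seeds[-1]
    rows: List[np.ndarray] = []
    for (trace, cyc), s in zip(all_cycles, cycle_seeds):
        try:
            dense, u = cycle_uncoupling(
                trace, cyc, params, seed=s, pad=pad, grid_step=grid_step,
                gp_restarts=gp_restarts,
            )
        except DegenerateNormalizationError:
            exclusions.append((trace.cell_id, cyc.cyt_start, "degenerate-normalization"))
            continue
        except IncompleteTraceError:
            exclusions.append((trace.cell_id, cyc.cyt_start, "incomplete-trace"))
            continue
        except InsufficientDataError:
            exclusions.append((trace.cell_id, cyc.cyt_start, "insufficient-data"))
            continue
        phases = phase_map(dense, cyc, mean_phases)
        rows.append(np.interp(phase_grid, phases, u))
    if len(rows) < min_cycles:
        raise InsufficientCyclesError(
            f"only {len(rows)} cycles survived the pipeline (need {min_cycles})"
        )

    profiles = np.vstack(rows)
    n = profiles.shape[0]
    mean = profiles.mean(axis=0)
    rng = np.random.default_rng(boot_seed)
    counts = rng.multinomial(n, np.full(n, 1.0 / n), size=n_bootstrap)
    boot_means = (counts @ profiles) / n
    ci_low, ci_high = np.percentile(boot_means, [2.5, 97.5], axis=0)
    return PhaseProfile(
        phase=phase_grid,
        mean=mean,
        ci_low=ci_low,
        ci_high=ci_high,
        n_cycles=n,
        mean_budding_phase=mean_phases["budding"],
        seed=seed,
        exclusions=tuple(exclusions),
    )
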