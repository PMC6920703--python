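"""FBP–flux (and FBP–growth) calibration.

Each metabolic condition (strain x carbon source) contributes several FBP
concentration measurements but only a condition-level mean and standard
deviation for the glycolytic flux (F6P -> FBP reaction, mmol gDW^-1 h^-1)
and the growth rate (h^-1), because fluxes come from sampling a constrained
flux solution space rather than from direct per-replicate measurement. The
bootstrap therefore pairs each resampled FBP *measurement* with an
independent normal draw from its condition's flux (or growth)
*distribution*, and summarizes Pearson's r over many such resamples.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from fluxlens.binding import SensorParams, sensor_transfer, sensor_transfer_bounds
from fluxlens.errors import (
    DegenerateBootstrapError,
    InsufficientDataError,
    InvalidInputError,
    OutOfRangeError,
    SingularFitError,
)


@dataclass(frozen=True)
class ConditionDataset:
    """One metabolic condition: pooled FBP measurements plus flux/growth
    summaries."""

    condition_id: str
    fbp_measurements: np.ndarray
    flux_mean: float
    flux_sd: float
    growth_mean: float = float("nan")
    growth_sd: float = float("nan")

    def __post_init__(self) -> None:
        fbp = np.atleast_1d(np.asarray(self.fbp_measurements, dtype=float))
        object.__setattr__(self, "fbp_measurements", fbp)
        if fbp.size < 1:
            raise InvalidInputError("at least one FBP measurement per condition")
        if np.any(fbp <= 0):
            raise InvalidInputError("FBP measurements must be positive")
        if self.flux_sd < 0:
            raise InvalidInputError("flux_sd must be non-negative")


@dataclass(frozen=True)
class BootstrapResult:
    """Bootstrap summary of Pearson's r.

    ``r_mean`` averages r over non-degenerate resamples; ``r_plugin`` is the
    single plug-in estimate pairing every measurement with its condition
    mean. The CI is the 2.5/97.5 percentile interval and the p-value uses
    the normal approximation on the bootstrap distribution ("normal
    bootstrap").
    """

    r_mean: float
    ci_low: float
    ci_high: float
    n_iterations: int
    seed: int
    p_value: float
    r_plugin: float
    n_degenerate: int = 0
    p_value_method: str = "normal bootstrap"

    def to_dict(self) -> dict:
        return {
            "r_mean": self.r_mean,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "p_value": self.p_value,
            "r_plugin": self.r_plugin,
            "n_degenerate": self.n_degenerate,
            "p_value_method": self.p_value_method,
        }


def _pooled_arrays(
    conditions: Sequence[ConditionDataset], target: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flatten conditions into per-measurement (fbp, target_mean, target_sd)."""
    if target not in ("flux", "growth"):
        raise InvalidInputError("target must be 'flux' or 'growth'")
    fbp, mean, sd = [], [], []
    for cond in conditions:
        m = cond.flux_mean if target == "flux" else cond.growth_mean
        s = cond.flux_sd if target == "flux" else cond.growth_sd
        if not np.isfinite(m) or not np.isfinite(s):
            raise InvalidInputError(f"condition {cond.condition_id}: missing {target} summary")
        n = cond.fbp_measurements.size
        fbp.append(cond.fbp_measurements)
        mean.append(np.full(n, m))
        sd.append(np.full(n, s))
    return np.concatenate(fbp), np.concatenate(mean), np.concatenate(sd)


def _rowwise_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r per row; rows with zero variance yield NaN."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc).sum(axis=1) / (sx * sy)
    r[(sx == 0) | (sy == 0)] = np.nan
    return r


def bootstrap_pearson(
    conditions: Sequence[ConditionDataset],
    target: Literal["flux", "growth"] = "flux",
    n_iterations: int = 100_000,
    seed: int = 0,
    redraw_targets: bool = True,
    method: Literal["sample", "exhaustive"] = "sample",
    chunk: int = 20_000,
) -> BootstrapResult:
    """Measurement-vs-distribution bootstrap of Pearson's r.

    Each iteration draws N measurement indices with replacement from the
    pooled FBP list; each drawn pair's target value is an independent
    N(mean, sd) draw from its condition's summary (``redraw_targets=False``
    keeps the condition means — a classical pairs bootstrap). Resamples with
    zero variance in either coordinate are discarded and counted.

    ``method='exhaustive'`` enumerates all N^N index tuples instead of
    sampling; it requires all target sds to be zero (the resample is then
    fully deterministic) and is intended for small-N correctness checks.
    """
    fbp, mean, sd = _pooled_arrays(conditions, target)
    n = fbp.size
    if n < 3 or len(conditions) < 2:
        raise InsufficientDataError("need >= 3 measurements spanning >= 2 conditions")
    if n_iterations < 1:
        raise InvalidInputError("n_iterations must be >= 1")

    r_plugin = float(_rowwise_pearson(fbp[None, :], mean[None, :])[0])

    if method == "exhaustive":
        if np.any(sd != 0):
            raise InvalidInputError("exhaustive enumeration requires all target sds = 0")
        idx = np.array(list(itertools.product(range(n), repeat=n)), dtype=int)
        r = _rowwise_pearson(fbp[idx], mean[idx])
        r_valid = r[~np.isnan(r)]
        n_degenerate = int(np.isnan(r).sum())
        if r_valid.size == 0:
            raise DegenerateBootstrapError("all enumerated resamples are degenerate")
        r_mean = float(r_valid.mean())
        lo, hi = np.percentile(r_valid, [2.5, 97.5])
        sd_boot = float(r_valid.std(ddof=0))
        p = _normal_bootstrap_p(r_mean, sd_boot)
        return BootstrapResult(
            r_mean, float(lo), float(hi), idx.shape[0], seed, p, r_plugin, n_degenerate
        )

    rng = np.random.default_rng(seed)
    rs: list[np.ndarray] = []
    n_degenerate = 0
    remaining = n_iterations
    while remaining > 0:
        m = min(chunk, remaining)
        idx = rng.integers(0, n, size=(m, n))
        x = fbp[idx]
        if redraw_targets:
            y = mean[idx] + sd[idx] * rng.standard_normal((m, n))
        else:
            y = mean[idx]
        r = _rowwise_pearson(x, y)
        bad = np.isnan(r)
        n_degenerate += int(bad.sum())
        rs.append(r[~bad])
        remaining -= m
    r_all = np.concatenate(rs)
    if r_all.size == 0:
        raise DegenerateBootstrapError("all bootstrap iterations were degenerate")
    r_mean = float(r_all.mean())
    lo, hi = np.percentile(r_all, [2.5, 97.5])
    p = _normal_bootstrap_p(r_mean, float(r_all.std(ddof=0)))
    return BootstrapResult(
        r_mean, float(lo), float(hi), n_iterations, seed, p, r_plugin, n_degenerate
    )


def _normal_bootstrap_p(r_mean: float, sd_boot: float) -> float:
    """Two-sided normal-approximation p-value for r != 0."""
    if sd_boot == 0:
        return 0.0 if r_mean != 0 else 1.0
    z = abs(r_mean) / sd_boot
    return float(2.0 * stats.norm.sf(z))


@dataclass(frozen=True)
class LinearCalibration:
    """Straight-line FBP -> flux map fitted on condition summaries."""

    slope: float
    intercept: float
    residual_sd: float
    fit_range: tuple[float, float] = (0.2, 8.0)

    def __post_init__(self) -> None:
        if not self.fit_range[0] < self.fit_range[1]:
            raise InvalidInputError("fit_range must be (low, high) with low < high")

    def predict(self, fbp) -> np.ndarray | float:
        return self.slope * np.asarray(fbp, dtype=float) + self.intercept

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "residual_sd": self.residual_sd,
            "fit_range": list(self.fit_range),
        }


def fit_linear_calibration(
    conditions: Sequence[ConditionDataset],
    fit_range: tuple[float, float] = (0.2, 8.0),
) -> LinearCalibration:
    """Weighted least squares of condition flux means on condition mean FBP.

    Weights are 1/flux_sd^2 when every condition has a positive sd,
    otherwise the fit is unweighted. The residual sd is the root mean square
    of the unweighted residuals with 2 degrees of freedom removed.
    """
    x = np.array([c.fbp_measurements.mean() for c in conditions], dtype=float)
    y = np.array([c.flux_mean for c in conditions], dtype=float)
    sds = np.array([c.flux_sd for c in conditions], dtype=float)
    if np.unique(x).size < 2:
        raise SingularFitError("need >= 2 conditions with distinct mean FBP")
    w = 1.0 / sds**2 if np.all(sds > 0) else np.ones_like(x)
    W = np.diag(w)
    A = np.column_stack([x, np.ones_like(x)])
    coef = np.linalg.solve(A.T @ W @ A, A.T @ W @ y)
    resid = y - A @ coef
    dof = max(x.size - 2, 1)
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof)) if x.size > 2 else 0.0
    return LinearCalibration(float(coef[0]), float(coef[1]), residual_sd, fit_range)


@dataclass(frozen=True)
class FluxEstimate:
    """Flux inferred from a sensor ratio, with first-order propagated sd."""

    flux: float
    flux_sd: float
    fbp: float
    clipped: bool = False


def invert_transfer(
    params: SensorParams,
    ratio: float,
    fbp_bracket: tuple[float, float] = (0.0, 50.0),
    tol: float = 1e-6,
) -> tuple[float, bool]:
    """Invert the monotone sensor transfer by bisection to ``tol`` mM.

    Returns (fbp, clipped); out-of-range ratios are clipped to the bracket
    endpoint and flagged.
    """
    lo, hi = fbp_bracket
    f_lo = sensor_transfer(params, lo)
    f_hi = sensor_transfer(params, hi)
    if ratio <= f_lo:
        return lo, ratio < f_lo
    if ratio >= f_hi:
        return hi, ratio > f_hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if sensor_transfer(params, mid) < ratio:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi), False


def flux_from_ratio(
    cal: LinearCalibration,
    params: SensorParams,
    ratio: float,
    ratio_sd: float = 0.0,
    fbp_bracket: tuple[float, float] = (0.0, 50.0),
    tol: float = 1e-6,
) -> FluxEstimate:
    """Map a YFP/mCherry ratio to a flux estimate via transfer inversion.

    The ratio is inverted to FBP on the monotone transfer curve (bisection,
    ``tol`` mM) and pushed through the linear calibration. The sd combines,
    by the first-order delta method, the ratio uncertainty (through the
    local slope of the inverse transfer) and the calibration residual sd.
    Ratios outside the attainable range raise nothing but return a clipped,
    flagged estimate per :class:`FluxEstimate`.
    """
    bounds = sensor_transfer_bounds(params)
    if ratio < bounds[0] - 1e-12:
        # below the basal floor: no FBP level can produce this ratio
        fbp, clipped = fbp_bracket[0], True
    else:
        fbp, clipped = invert_transfer(params, ratio, fbp_bracket, tol)
    flux = float(cal.predict(fbp))
    # d fbp / d ratio = 1 / T'(fbp), numeric central difference
    h = max(1e-4, tol)
    t_prime = (
        sensor_transfer(params, fbp + h) - sensor_transfer(params, max(fbp - h, 0.0))
    ) / (h + min(h, fbp))
    dfbp_dratio = 1.0 / t_prime if t_prime > 0 else np.inf
    sd_fbp = abs(ratio_sd * dfbp_dratio)
    flux_sd = float(np.hypot(cal.slope * sd_fbp, cal.residual_sd))
    return FluxEstimate(flux=flux, flux_sd=flux_sd, fbp=float(fbp), clipped=clipped)
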