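"""CggR–FBP and CggR–DNA binding models.

Thermal shift assays report a protein melting temperature (Tm) that rises as
ligand stabilizes the folded state; fitting a Hill-form shift
``Tm(L) = Tm0 + dTm * L^n / (Kd^n + L^n)`` to the Tm-vs-concentration series
yields the dissociation constant K_D. Electrophoretic mobility shift assays
(EMSA) quantify the repressor's DNA occupancy from band intensities. The
sensor transfer function composes FBP occupancy of CggR with promoter
de-repression into an expected YFP/mCherry ratio.

Units: ligand concentrations in mM, temperatures in degrees Celsius,
maturation half-times in minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from fluxlens.errors import (
    DegenerateCurveError,
    DegenerateNormalizationError,
    EmptyLaneError,
    FitFailedError,
    InsufficientDataError,
    InvalidInputError,
)

# Dissociation constants of the CggR variants relative to wild type
# (wild type 1.0 mM; mutants as fold changes: three slightly tighter,
# R250A and T151V weaker binders used to widen the sensor's dynamic range).
_WT_KD_MM = 1.0
_PRESET_KD_FOLD = {
    "WT": 1.0,
    "T151S": 1.0 / 1.1,
    "E269Q": 1.0 / 1.5,
    "T152S": 1.0 / 1.6,
    "R250A": 1.5,
    "T151V": 2.6,
}

#: Ligand concentration grid (mM) of the standard thermal-shift protocol.
THERMAL_SHIFT_CONCENTRATIONS_MM = (0.0, 0.01, 0.1, 0.5, 0.75, 1.0, 2.5, 10.0, 20.0, 36.0)

#: Physiological FBP window in growing yeast (mM).
PHYSIOLOGICAL_FBP_RANGE_MM = (0.2, 8.0)


@dataclass(frozen=True)
class MeltCurve:
    """One thermal-shift melting curve at a fixed ligand concentration.

    ``temperatures`` must be strictly increasing with at least 5 points;
    ``fluorescence`` is the SYPRO-Orange-type unfolding signal (a.u.).
    """

    ligand_concentration: float
    temperatures: np.ndarray
    fluorescence: np.ndarray
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "fluorescence", f)
        if self.ligand_concentration < 0:
            raise InvalidInputError("ligand_concentration must be non-negative")
        if t.size < 5:
            raise InvalidInputError("melt curve needs at least 5 temperature points")
        if f.size != t.size:
            raise InvalidInputError("temperatures and fluorescence differ in length")
        if not np.all(np.diff(t) > 0):
            raise InvalidInputError("temperatures must be strictly increasing")
        if not np.all(np.isfinite(f)):
            raise InvalidInputError("fluorescence must be finite")


@dataclass(frozen=True)
class TmSeries:
    """Melting temperatures across ligand concentrations, replicates allowed.

    ``ligand_concentrations`` and ``tm_values`` are parallel per-observation
    vectors; the same concentration may appear several times (one entry per
    replicate).
    """

    ligand_concentrations: np.ndarray
    tm_values: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.ligand_concentrations, dtype=float)
        t = np.asarray(self.tm_values, dtype=float)
        object.__setattr__(self, "ligand_concentrations", c)
        object.__setattr__(self, "tm_values", t)
        if c.size != t.size or c.size == 0:
            raise InvalidInputError("concentrations and tm_values must be equal-length, non-empty")
        if np.any(c < 0):
            raise InvalidInputError("ligand concentrations must be non-negative")
        if 0.0 not in c:
            raise InvalidInputError("series must include the 0 mM reference")

    def mean_by_concentration(self) -> pd.Series:
        """Replicate-averaged Tm indexed by concentration (ascending)."""
        return (
            pd.Series(self.tm_values, index=self.ligand_concentrations)
            .groupby(level=0)
            .mean()
            .sort_index()
        )


@dataclass(frozen=True)
class BindingFit:
    """Result of fitting the Hill-form Tm shift model.

    ``kd_ci`` is the asymptotic 95% confidence interval. ``bindable`` is
    False when the fitted span is indistinguishable from zero (no thermal
    stabilization, K_D unidentifiable).
    """

    kd: float
    hill_n: float
    tm_unbound: float
    tm_span: float
    kd_ci: tuple[float, float]
    bindable: bool = True
    sse: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "kd": self.kd,
            "hill_n": self.hill_n,
            "tm_unbound": self.tm_unbound,
            "tm_span": self.tm_span,
            "kd_ci": list(self.kd_ci),
            "bindable": self.bindable,
            "sse": self.sse,
        }


@dataclass(frozen=True)
class GelLane:
    """One quantified EMSA lane: complex and free-DNA band intensities."""

    fbp_concentration: float
    complex_intensity: float
    free_intensity: float

    def __post_init__(self) -> None:
        if self.complex_intensity < 0 or self.free_intensity < 0:
            raise InvalidInputError("band intensities must be non-negative")


@dataclass(frozen=True)
class SensorParams:
    """Binding and maturation constants defining one sensor variant.

    ``residual_bound`` is the fraction of repressor remaining DNA-bound at
    saturating FBP (EMSA shows ~30% for WT and R250A); ``theta_max`` is the
    promoter occupancy at zero FBP; ``basal_activity`` is the promoter leak
    when fully repressed. Maturation half-times are 20 min (YFP) and 50 min
    (mCherry).
    """

    kd: float
    hill_n: float = 1.0
    residual_bound: float = 0.30
    yfp_mat_halftime: float = 20.0
    mcherry_mat_halftime: float = 50.0
    basal_activity: float = 0.05
    theta_max: float = 0.95
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.kd <= 0 or self.hill_n <= 0:
            raise InvalidInputError("kd and hill_n must be positive")
        if not 0 <= self.residual_bound <= 1:
            raise InvalidInputError("residual_bound must lie in [0, 1]")
        if not 0 <= self.basal_activity <= 1:
            raise InvalidInputError("basal_activity must lie in [0, 1]")
        if not 0 < self.theta_max <= 1:
            raise InvalidInputError("theta_max must lie in (0, 1]")
        if self.yfp_mat_halftime <= 0 or self.mcherry_mat_halftime <= 0:
            raise InvalidInputError("maturation half-times must be positive")

    @classmethod
    def preset(cls, name: str, **overrides) -> "SensorParams":
        """Return a named variant preset (WT or one of the point mutants)."""
        if name not in _PRESET_KD_FOLD:
            raise InvalidInputError(
                f"unknown preset {name!r}; choose from {sorted(_PRESET_KD_FOLD)}"
            )
        params = cls(kd=_WT_KD_MM * _PRESET_KD_FOLD[name], name=name)
        return replace(params, **overrides) if overrides else params

    @classmethod
    def preset_names(cls) -> tuple[str, ...]:
        return tuple(_PRESET_KD_FOLD)


def extract_tm(curve: MeltCurve, tie_tol: float = 1e-9) -> float:
    """Melting temperature: temperature of the maximal first derivative.

    The derivative is taken by centered finite differences on the raw grid
    (no pre-smoothing); first and last grid points are excluded. Ties within
    ``tie_tol`` of the maximum are broken toward the lowest temperature. A
    curve whose derivative has no dynamic range raises
    :class:`DegenerateCurveError`.
    """
    t, f = curve.temperatures, curve.fluorescence
    deriv = (f[2:] - f[:-2]) / (t[2:] - t[:-2])
    t_mid = t[1:-1]
    span = float(np.ptp(deriv))
    scale = max(np.abs(deriv).max(), 1.0)
    if span <= tie_tol * scale:
        raise DegenerateCurveError(
            "flat melting curve: maximum of dF/dT is not unique within tolerance"
        )
    return float(t_mid[int(np.argmax(deriv))])


def _hill(ligand: np.ndarray, kd: float, n: float) -> np.ndarray:
    ligand = np.asarray(ligand, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ln = np.power(ligand, n)
        out = ln / (kd**n + ln)
    return np.where(ligand == 0, 0.0, out)


# Deterministic multi-start grid for the K_D fit: log-spaced K_D values
# crossed with a small set of Hill exponents. The two linear parameters
# (tm_unbound, tm_span) are profiled out exactly at every grid point.
_KD_GRID = np.logspace(-2, 2, 17)
_N_GRID = (0.5, 1.0, 2.0, 4.0)


def fit_tm_binding(series: TmSeries) -> BindingFit:
    """Fit the cooperative (Hill-form) Tm shift model to a Tm series.

    All replicates are pooled into one least-squares problem. A seedless
    multi-start grid over (K_D, n) — with the linear parameters solved in
    closed form at each start — chooses the best basin; a bounded
    Levenberg-Marquardt/trust-region refinement follows. The 95% K_D
    confidence interval comes from the asymptotic covariance. If the fitted
    span is indistinguishable from zero the series is flagged unbindable and
    the interval spans the full search range.
    """
    conc = series.ligand_concentrations
    tm = series.tm_values
    if np.unique(conc).size < 4:
        raise InsufficientDataError("need Tm at >= 4 distinct concentrations")

    best = None
    for kd0 in _KD_GRID:
        for n0 in _N_GRID:
            h = _hill(conc, kd0, n0)
            design = np.column_stack([np.ones_like(h), h])
            coef, res, rank, _ = np.linalg.lstsq(design, tm, rcond=None)
            pred = design @ coef
            sse = float(np.sum((tm - pred) ** 2))
            if best is None or sse < best[0]:
                best = (sse, kd0, n0, coef[0], coef[1])
    assert best is not None
    _, kd0, n0, t0, span0 = best

    def model(L, kd, n, tm_unbound, tm_span):
        return tm_unbound + tm_span * _hill(L, kd, n)

    try:
        popt, pcov = curve_fit(
            model,
            conc,
            tm,
            p0=[kd0, n0, t0, span0],
            bounds=([1e-4, 0.05, -np.inf, -np.inf], [1e4, 12.0, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - multi-start makes this rare
        raise FitFailedError(f"Tm binding fit did not converge: {exc}") from exc

    kd, hill_n, tm_unbound, tm_span = (float(v) for v in popt)
    resid = tm - model(conc, *popt)
    sse = float(np.sum(resid**2))
    with np.errstate(invalid="ignore"):
        kd_se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.inf
        span_se = float(np.sqrt(pcov[3, 3])) if np.isfinite(pcov[3, 3]) else np.inf

    # a span below a micro-degree carries no binding signal regardless of fit
    bindable = abs(tm_span) > max(2.0 * span_se, 1e-6)
    if not bindable or not np.isfinite(kd_se):
        kd_ci = (float(_KD_GRID[0]), float(_KD_GRID[-1]))
    else:
        kd_ci = (kd - 1.96 * kd_se, kd + 1.96 * kd_se)
        kd_ci = (min(kd_ci[0], kd), max(kd_ci[1], kd))
    return BindingFit(
        kd=kd,
        hill_n=hill_n,
        tm_unbound=tm_unbound,
        tm_span=tm_span,
        kd_ci=kd_ci,
        bindable=bindable,
        sse=sse,
    )


def fraction_bound(kd: float, hill_n: float, ligand) -> np.ndarray | float:
    """One-site/Hill fraction of protein bound: ``L^n / (Kd^n + L^n)``.

    Monotone nondecreasing in ligand; exactly 0.5 at ``L = kd`` for n = 1.
    Accepts a scalar or array ligand concentration (mM).
    """
    if kd <= 0 or hill_n <= 0:
        raise InvalidInputError("kd and hill_n must be positive")
    arr = np.asarray(ligand, dtype=float)
    if np.any(arr < 0):
        raise InvalidInputError("ligand concentration must be non-negative")
    out = _hill(arr, kd, hill_n)
    return float(out) if np.isscalar(ligand) or arr.ndim == 0 else out


def normalize_tm_to_fraction(
    series: TmSeries, saturating: float | None = None
) -> pd.DataFrame:
    """Convert a Tm series to fraction bound with fixed endpoints.

    The Tm at 0 mM defines the unbound state and the Tm at the saturating
    concentration (default: the series maximum, protocol standard 36 mM)
    the fully bound state; fractions are 0 and 1 there exactly by
    construction. Replicates are averaged per concentration first.
    """
    tm_by_conc = series.mean_by_concentration()
    if saturating is None:
        saturating = float(tm_by_conc.index.max())
    if saturating not in tm_by_conc.index:
        raise InvalidInputError(f"saturating concentration {saturating} mM not in series")
    tm0 = tm_by_conc.loc[0.0]
    tm_sat = tm_by_conc.loc[saturating]
    denom = tm_sat - tm0
    if denom == 0:
        raise DegenerateNormalizationError("Tm at saturating ligand equals Tm at 0 mM")
    frac = (tm_by_conc - tm0) / denom
    frac.loc[0.0] = 0.0
    frac.loc[saturating] = 1.0
    return pd.DataFrame({"ligand_mM": frac.index.to_numpy(), "fraction": frac.to_numpy()})


def gel_bound_fraction(lane: GelLane) -> float:
    """DNA-bound fraction from one lane: complex / (complex + free)."""
    total = lane.complex_intensity + lane.free_intensity
    if total <= 0:
        raise EmptyLaneError("both band intensities are zero")
    return lane.complex_intensity / total


@dataclass(frozen=True)
class ReleaseRatio:
    """Bound-fraction ratio at 0 vs saturating FBP; > 1 means FBP releases
    the repressor from DNA. ``infinite`` flags a zero bound fraction at the
    saturating concentration."""

    ratio: float
    infinite: bool = False


def gel_release_ratio(
    lanes: Sequence[GelLane], reference: float = 0.0, saturating: float = 20.0
) -> ReleaseRatio:
    """Ratio of DNA-bound fractions at ``reference`` vs ``saturating`` FBP."""
    by_conc = {lane.fbp_concentration: lane for lane in lanes}
    if reference not in by_conc or saturating not in by_conc:
        raise InvalidInputError(
            f"lanes at {reference} and {saturating} mM FBP are both required"
        )
    f_ref = gel_bound_fraction(by_conc[reference])
    f_sat = gel_bound_fraction(by_conc[saturating])
    if f_sat == 0:
        return ReleaseRatio(ratio=math.inf, infinite=True)
    return ReleaseRatio(ratio=f_ref / f_sat)


def sensor_transfer(params: SensorParams, fbp) -> np.ndarray | float:
    """Expected YFP/mCherry ratio (normalized to [0, 1] promoter activity).

    Promoter occupancy by the repressor decreases with FBP but is floored by
    the residually bound fraction::

        theta(FBP) = theta_max * (1 - (1 - residual_bound) * f_b(FBP))
        output     = basal + (1 - basal) * (1 - theta(FBP))

    with ``f_b`` the Hill fraction bound. The output is strictly increasing
    in FBP and bounded by the closed forms

    - at FBP = 0:      ``basal + (1 - basal) * (1 - theta_max)``
    - as FBP -> inf:   ``basal + (1 - basal) * (1 - theta_max * residual_bound)``
    """
    arr = np.asarray(fbp, dtype=float)
    if np.any(arr < 0):
        raise InvalidInputError("fbp must be non-negative")
    fb = _hill(arr, params.kd, params.hill_n)
    theta = params.theta_max * (1.0 - (1.0 - params.residual_bound) * fb)
    out = params.basal_activity + (1.0 - params.basal_activity) * (1.0 - theta)
    return float(out) if np.isscalar(fbp) or arr.ndim == 0 else out


def sensor_transfer_bounds(params: SensorParams) -> tuple[float, float]:
    """Closed-form (min, max) of the transfer function over FBP in [0, inf)."""
    b, tmax, rb = params.basal_activity, params.theta_max, params.residual_bound
    lo = b + (1 - b) * (1 - tmax)
    hi = b + (1 - b) * (1 - tmax * rb)
    return lo, hi
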