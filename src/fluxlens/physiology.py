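"""Batch-culture physiology: growth and uptake/secretion rates.

Under exponential growth with constant yields, biomass follows
``X(t) = X0 * exp(mu t)`` and each extracellular metabolite follows
``c_i(t) = c_i0 -/+ (q_i / mu) * X0 * (exp(mu t) - 1)`` (minus for
substrates taken up, plus for products secreted). All species share one
growth clock, so the rates are estimated by a joint nonlinear least-squares
fit with a shared ``mu``.

Sign convention: ``q`` is positive for consumption of an uptake species and
positive for secretion of a product species. Units follow the input series;
the module ships a molar-mass table to convert g/l-based rates to
mmol gDW^-1 h^-1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Literal, Mapping

import numpy as np
from scipy.optimize import least_squares

from fluxlens.errors import InvalidInputError, NoGrowthError

#: Molar masses (g/mol) of the common batch-culture metabolites.
MOLAR_MASS_G_MOL: Mapping[str, float] = {
    "glucose": 180.16,
    "ethanol": 46.07,
    "acetate": 60.05,
    "glycerol": 92.09,
    "pyruvate": 88.06,
    "maltose": 342.30,
    "galactose": 180.16,
}

Role = Literal["uptake", "product"]


@dataclass(frozen=True)
class BatchTimecourse:
    """Times (h), biomass (gDW/l) and named metabolite series with roles."""

    times: np.ndarray
    biomass: np.ndarray
    metabolites: Dict[str, np.ndarray]
    roles: Dict[str, Role]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.biomass, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "biomass", x)
        object.__setattr__(
            self, "metabolites", {k: np.asarray(v, float) for k, v in self.metabolites.items()}
        )
        if t.size < 4:
            raise InvalidInputError("need >= 4 time points")
        if not np.all(np.diff(t) > 0):
            raise InvalidInputError("times must be strictly increasing")
        if np.any(x <= 0):
            raise InvalidInputError("biomass must be positive")
        for name, series in self.metabolites.items():
            if series.size != t.size:
                raise InvalidInputError(f"metabolite {name!r} length mismatch")
            if name not in self.roles:
                raise InvalidInputError(f"metabolite {name!r} has no declared role")
            if self.roles[name] not in ("uptake", "product"):
                raise InvalidInputError(f"metabolite {name!r}: role must be uptake|product")


@dataclass(frozen=True)
class RateEstimate:
    """Fitted growth rate, biomass-specific rates and initial values."""

    mu: float
    q: Dict[str, float]
    x0: float
    c0: Dict[str, float]
    fit_sse: float
    model_mismatch: bool = False

    def to_dict(self) -> dict:
        return {
            "mu": self.mu,
            "q": dict(self.q),
            "x0": self.x0,
            "c0": dict(self.c0),
            "fit_sse": self.fit_sse,
            "model_mismatch": self.model_mismatch,
        }


def _model_concentration(t, c0, q_signed, mu, x0):
    return c0 + (q_signed / mu) * x0 * (np.exp(mu * t) - 1.0)


def fit_batch_rates(
    tc: BatchTimecourse,
    weights: Mapping[str, float] | None = None,
    negative_tol: float = 1e-6,
) -> RateEstimate:
    """Joint exponential-growth / constant-yield fit of (mu, q_i).

    Initialization is deterministic: mu and X0 from a log-linear biomass
    regression, q_i from the slope of concentration vs biomass (the yield).
    ``weights`` optionally scales each species' residuals (default: unit
    weights). Fitted concentration trajectories dipping below
    ``-negative_tol * range`` set the ``model_mismatch`` flag.
    """
    t = tc.times - tc.times[0]  # shift-invariant: only initial values change
    x = tc.biomass
    if x[-1] <= x[0]:
        raise NoGrowthError("final biomass does not exceed initial biomass")

    names = list(tc.metabolites)
    signs = {n: (-1.0 if tc.roles[n] == "uptake" else 1.0) for n in names}
    w = {n: 1.0 for n in names}
    if weights:
        w.update(weights)

    # deterministic init
    b, loga = np.polyfit(t, np.log(x), 1)
    mu0, x00 = max(b, 1e-6), float(np.exp(loga))
    q0, c00 = {}, {}
    for n in names:
        c = tc.metabolites[n]
        slope = np.polyfit(x, c, 1)[0]  # dc/dX = sign * q / mu
        q0[n] = signs[n] * slope * mu0
        c00[n] = float(c[0])

    def unpack(p):
        mu, x0 = p[0], p[1]
        qs = dict(zip(names, p[2 : 2 + len(names)]))
        c0s = dict(zip(names, p[2 + len(names) :]))
        return mu, x0, qs, c0s

    def residuals(p):
        mu, x0, qs, c0s = unpack(p)
        res = [x0 * np.exp(mu * t) - x]
        for n in names:
            pred = _model_concentration(t, c0s[n], signs[n] * qs[n], mu, x0)
            res.append(w[n] * (pred - tc.metabolites[n]))
        return np.concatenate(res)

    p0 = np.array([mu0, x00] + [q0[n] for n in names] + [c00[n] for n in names])
    sol = least_squares(residuals, p0, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    mu, x0, qs, c0s = unpack(sol.x)
    if mu <= 0:
        raise NoGrowthError(f"fitted growth rate is non-positive (mu = {mu:.3g})")

    mismatch = False
    for n in names:
        pred = _model_concentration(t, c0s[n], signs[n] * qs[n], mu, x0)
        rng = max(float(np.ptp(tc.metabolites[n])), 1.0)
        if np.any(pred < -negative_tol * rng):
            mismatch = True
    sse = float(np.sum(residuals(sol.x) ** 2))
    return RateEstimate(
        mu=float(mu),
        q={n: float(qs[n]) for n in names},
        x0=float(x0),
        c0={n: float(c0s[n]) for n in names},
        fit_sse=sse,
        model_mismatch=mismatch,
    )


def q_to_mmol(q_g_per_gdw_h: float, metabolite: str,
              molar_mass: Mapping[str, float] | None = None) -> float:
    """Convert a g l^-1-based specific rate to mmol gDW^-1 h^-1."""
    table = dict(MOLAR_MASS_G_MOL)
    if molar_mass:
        table.update(molar_mass)
    if metabolite not in table:
        raise InvalidInputError(f"no molar mass for {metabolite!r}; supply one")
    return q_g_per_gdw_h / table[metabolite] * 1000.0
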