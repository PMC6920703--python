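"""Exception hierarchy shared across fluxlens modules."""


class FluxlensError(Exception):
    """Base class for all fluxlens errors."""


class InvalidInputError(FluxlensError, ValueError):
    """Input violates a documented precondition (non-monotone grid, negative
    ligand, non-positive radius, mismatched grids, ...)."""


class DegenerateCurveError(FluxlensError):
    """A melting curve is too flat for the melting temperature to be defined."""


class DegenerateNormalizationError(FluxlensError):
    """Normalization denominator vanishes (no dynamic range in the signal)."""


class InsufficientDataError(FluxlensError):
    """Fewer data points / concentrations / events / cycles than the method
    needs."""


class FitFailedError(FluxlensError):
    """Nonlinear fit did not converge from any start point."""


class EmptyLaneError(FluxlensError):
    """Gel lane carries no quantifiable intensity in either band."""


class SingularFitError(FluxlensError):
    """Regression design is singular (e.g. identical abscissae)."""


class DegenerateBootstrapError(FluxlensError):
    """Every bootstrap resample was degenerate (zero variance)."""


class NoGrowthError(FluxlensError):
    """Biomass series is inconsistent with exponential growth."""


class NoUsableEventsError(FluxlensError):
    """All cytometry events were excluded by the background correction."""


class OutOfRangeError(FluxlensError):
    """Requested value lies outside the attainable range of a monotone map."""


class IncompleteTraceError(FluxlensError):
    """Mother-cell radii are missing at in-cycle time points."""


class GridTooCoarseError(FluxlensError, ValueError):
    """Numerical differentiation grid is too coarse for the derivative
    formulas."""


class InsufficientCyclesError(FluxlensError):
    """Fewer than the minimum number of usable cell cycles survived."""


class OutOfCycleError(FluxlensError, ValueError):
    """A time point lies outside the cell cycle it was mapped against."""


class ConfigError(FluxlensError, ValueError):
    """A configuration value violates the schema; message names the field
    path."""
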