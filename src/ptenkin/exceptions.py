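"""Exception hierarchy shared across the fitting modules."""


class PtenkinError(Exception):
    """Base class for all package errors."""


class DomainError(PtenkinError, ValueError):
    """Invalid physical input (negative concentration, non-finite value, ...)."""


class DesignError(PtenkinError, ValueError):
    """A dataset does not satisfy the design its analysis requires."""


class FitError(PtenkinError, RuntimeError):
    """A nonlinear fit failed to converge or produced invalid estimates."""


class SubstrateInhibitionError(FitError):
    """Monotonically decreasing velocity data; truncate the high-surface-
    concentration points before fitting a rectangular hyperbola."""


class InconsistentFitsError(FitError):
    """Apparent fits violate the interfacial model (e.g. Vmax_SD < Vmax_BD)."""


class NoSaturationError(FitError):
    """No saturation detectable; use the linear-efficiency analysis instead."""


class CurvatureError(FitError):
    """Velocity data are significantly curved; use a full Michaelis-Menten fit."""


class UnreachableTargetError(PtenkinError, ValueError):
    """A requested interpolation target lies outside a fitted curve's range."""
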