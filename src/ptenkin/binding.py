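"""Liposome co-sedimentation binding analysis.

Large multilamellar vesicles (LMVs) containing a chosen mol% of anionic lipid
(PIP2 or PS) are pelleted by ultracentrifugation; protein partitioning is
read out densitometrically from pellet and supernatant bands, giving

    fraction_bound = pellet / (pellet + supernatant).

A saturable hyperbola f = fmax * c / (c50 + c) in anionic mol% c is fitted to
each series so that different protein forms can be compared at matched
binding levels (inverse interpolation), smoothing blot noise.  The hyperbola
is descriptive plumbing, not a mechanistic isotherm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from scipy.optimize import curve_fit

from .exceptions import DesignError, DomainError, FitError, UnreachableTargetError


@dataclass(frozen=True)
class BindingPoint:
    """One co-sedimentation measurement at a given anionic lipid mol%."""

    anionic_molpct: float
    pellet_intensity: float
    supernatant_intensity: float

    def __post_init__(self):
        if self.anionic_molpct < 0:
            raise DomainError("anionic mol% must be >= 0")
        if self.pellet_intensity < 0 or self.supernatant_intensity < 0:
            raise DomainError("band intensities must be >= 0")

    @property
    def fraction_bound(self) -> float:
        return fraction_bound(self.pellet_intensity, self.supernatant_intensity)


@dataclass
class BindingSeries:
    """A titration of anionic lipid content for one protein sample."""

    sample: str
    lipid: Literal["PIP2", "PS"]
    points: list[BindingPoint]

    def __post_init__(self):
        if len(self.points) < 3:
            raise DesignError("a binding series needs >= 3 points")

    def molpct(self) -> np.ndarray:
        return np.array([p.anionic_molpct for p in self.points], dtype=float)

    def fractions(self) -> np.ndarray:
        return np.array([p.fraction_bound for p in self.points], dtype=float)


@dataclass(frozen=True)
class BindingCurveFit:
    """Fitted saturable curve f = fmax*c/(c50+c); ``poor_fit`` flags series
    that are flat or non-monotone beyond noise."""

    c50: float
    fmax: float
    se_c50: Optional[float]
    se_fmax: Optional[float]
    poor_fit: bool = False

    def predict(self, c):
        c = np.asarray(c, dtype=float)
        return self.fmax * c / (self.c50 + c)

    def invert(self, f: float) -> float:
        """Anionic mol% at which the fitted curve reaches fraction ``f``."""
        if f == 0:
            return 0.0
        if f >= self.fmax:
            raise UnreachableTargetError(
                f"target fraction {f:g} is at or above the fitted plateau fmax={self.fmax:g}"
            )
        return self.c50 * f / (self.fmax - f)


def fraction_bound(pellet: float, supernatant: float) -> float:
    """pellet / (pellet + supernatant); undefined when both are zero."""
    if pellet < 0 or supernatant < 0:
        raise DomainError("intensities must be >= 0")
    total = pellet + supernatant
    if total == 0:
        raise DomainError("both intensities are zero; fraction bound undefined")
    return pellet / total


def fit_binding_curve(series: BindingSeries) -> BindingCurveFit:
    """Least-squares fit of the saturable binding hyperbola to a series.

    Flat or decreasing series are returned with ``poor_fit=True`` (fmax near
    zero, c50 unidentifiable) rather than raised, since "no binding" is a
    legitimate experimental outcome.
    """
    c = series.molpct()
    f = series.fractions()
    if len(np.unique(c)) < 3:
        raise DesignError("need >= 3 distinct mol% values")
    span = f.max() - f.min()
    trend = np.polyfit(c, f, 1)[0]
    if span < 1e-3 or trend <= 0:
        return BindingCurveFit(
            c50=float("nan"), fmax=float(f.mean()), se_c50=None, se_fmax=None, poor_fit=True
        )
    fmax0 = min(max(f.max() * 1.1, 1e-3), 1.0)
    c500 = float(np.median(c[c > 0])) if np.any(c > 0) else 1.0
    try:
        popt, pcov = curve_fit(
            lambda cc, fmax, c50: fmax * cc / (c50 + cc),
            c,
            f,
            p0=(fmax0, c500),
            bounds=([0, 0], [1.5, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"binding-curve fit did not converge: {exc}") from exc
    se = np.sqrt(np.diag(pcov))
    # non-monotone beyond noise: residual spread comparable to the signal
    resid = f - popt[0] * c / (popt[1] + c)
    poor = float(np.std(resid)) > 0.5 * span
    return BindingCurveFit(
        c50=float(popt[1]),
        fmax=float(popt[0]),
        se_c50=float(se[1]),
        se_fmax=float(se[0]),
        poor_fit=poor,
    )


def equivalent_composition(
    series_a: BindingSeries,
    series_b: BindingSeries,
    target_fraction: float,
) -> tuple[float, float]:
    """Anionic mol% at which each series reaches the same bound fraction.

    Answers questions of the form "how much more anionic lipid does form A
    need to bind as well as form B?"; both series are interpolated on their
    fitted hyperbolas.
    """
    if not (0 <= target_fraction <= 1):
        raise DomainError("target fraction must be in [0, 1]")
    fits = (fit_binding_curve(series_a), fit_binding_curve(series_b))
    for s, ft in zip((series_a, series_b), fits):
        if ft.poor_fit:
            raise FitError(f"series {s.sample!r} has no usable binding curve")
    return fits[0].invert(target_fraction), fits[1].invert(target_fraction)
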