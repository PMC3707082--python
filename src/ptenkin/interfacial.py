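"""Surface-dilution (interfacial) kinetics for vesicle-substrate lipid phosphatases.

An interfacial enzyme such as PTEN acts on a substrate (PIP3) that is embedded
in a lipid bilayer, so its initial velocity depends on two concentrations at
once: the bulk substrate concentration ``S0`` (µM, controlling how much vesicle
surface is available) and the surface concentration ``Xs`` (mol% of substrate
within the bilayer, controlling the local density the membrane-bound enzyme
sees).  The forward model is the surface-dilution rate law

    V0 = Vmax * Xs * S0 / (iKm * Ks + iKm * S0 + Xs * S0),   Vmax = kcat * ET

where ``iKm`` is the interfacial Michaelis constant (mol%) and ``Ks`` the
membrane dissociation constant (µM, bulk).  Two paired experiment designs
expose the parameters:

* bulk dilution (BD): ``Xs`` fixed, ``S0`` varied -> apparent hyperbola with
  ``Vmax_app = Vmax*Xs/(iKm+Xs)`` and ``Km_app = iKm*Ks/(iKm+Xs)``;
* surface dilution (SD): ``S0`` fixed, ``Xs`` varied -> ``Vmax_app = Vmax``
  and ``Km_app = iKm*(Ks+S0)/S0``.

The apparent fits from the two designs are combined algebraically:

    iKm  = (Vmax_SD / Vmax_BD - 1) * Xs_fixed
    Ks   = Km_BD * (Xs_fixed / iKm + 1)
    kcat = Vmax_SD / ET

Surface-dilution curves often show apparent substrate inhibition at high mol%;
the standard workaround, implemented here, is to fit only the lowest few
surface concentrations (default: four).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .exceptions import (
    DesignError,
    DomainError,
    FitError,
    InconsistentFitsError,
    SubstrateInhibitionError,
)

logger = logging.getLogger(__name__)

Design = Literal["bulk_dilution", "surface_dilution", "soluble"]
VALID_DESIGNS = ("bulk_dilution", "surface_dilution", "soluble")


@dataclass(frozen=True)
class InterfacialParams:
    """Full parameter set of the interfacial rate law.

    Attributes
    ----------
    kcat : float
        Turnover number, min^-1.
    iKm : float
        Interfacial Michaelis constant, mol%.
    Ks : float
        Membrane dissociation constant, µM (bulk).
    ET : float
        Total enzyme concentration, µM.
    se_kcat, se_iKm, se_Ks : float or None
        First-order propagated standard errors, populated by
        :func:`combine_interfacial`; ``None`` for hand-constructed truth.
    """

    kcat: float
    iKm: float
    Ks: float
    ET: float
    se_kcat: Optional[float] = None
    se_iKm: Optional[float] = None
    se_Ks: Optional[float] = None

    def __post_init__(self):
        for name in ("kcat", "iKm", "Ks", "ET"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise DomainError(f"{name} must be strictly positive and finite, got {v}")

    @property
    def Vmax(self) -> float:
        """Maximal bulk velocity kcat*ET, µM/min (derived, never stored)."""
        return self.kcat * self.ET


@dataclass(frozen=True)
class VelocityPoint:
    """One initial-velocity measurement.

    S0 in µM, Xs in mol% (0-100), V0 in µM/min.
    """

    S0: float
    Xs: float
    V0: float
    replicate_id: str = "r1"

    def __post_init__(self):
        if not np.isfinite(self.S0) or self.S0 < 0:
            raise DomainError(f"S0 must be >= 0, got {self.S0}")
        if not np.isfinite(self.Xs) or not (0 <= self.Xs <= 100):
            raise DomainError(f"Xs must be in [0, 100] mol%, got {self.Xs}")
        if not np.isfinite(self.V0):
            raise DomainError(f"V0 must be finite, got {self.V0}")


@dataclass
class VelocityDataset:
    """Ordered collection of velocity points tagged by experiment design.

    ``fixed_value`` is the held-constant quantity: Xs (mol%) for
    bulk_dilution, S0 (µM) for surface_dilution, ``None`` for soluble assays.
    """

    points: list[VelocityPoint]
    design: Design
    ET: float
    fixed_value: Optional[float] = None
    sample: str = ""

    def __post_init__(self):
        if self.design not in VALID_DESIGNS:
            raise DesignError(f"unknown design {self.design!r}")
        if not (np.isfinite(self.ET) and self.ET > 0):
            raise DomainError(f"ET must be strictly positive, got {self.ET}")
        if not self.points:
            raise DesignError("dataset has no points")
        if self.design == "bulk_dilution":
            xs = {p.Xs for p in self.points}
            if self.fixed_value is None:
                self.fixed_value = next(iter(xs))
            if len(xs) > 1 or not math.isclose(next(iter(xs)), self.fixed_value):
                raise DesignError("bulk_dilution requires a single shared Xs")
        elif self.design == "surface_dilution":
            s0 = {p.S0 for p in self.points}
            if self.fixed_value is None:
                self.fixed_value = next(iter(s0))
            if len(s0) > 1 or not math.isclose(next(iter(s0)), self.fixed_value):
                raise DesignError("surface_dilution requires a single shared S0")

    @property
    def varied_name(self) -> str:
        return "Xs" if self.design == "surface_dilution" else "S0"

    def varied(self) -> np.ndarray:
        """Values of the varied independent variable, in point order."""
        attr = self.varied_name
        return np.array([getattr(p, attr) for p in self.points], dtype=float)

    def velocities(self) -> np.ndarray:
        return np.array([p.V0 for p in self.points], dtype=float)

    def n_distinct(self) -> int:
        return len(np.unique(self.varied()))


@dataclass(frozen=True)
class ApparentMMFit:
    """Apparent Michaelis-Menten parameters from one dilution design.

    ``Km_app`` is in µM for bulk_dilution and mol% for surface_dilution.
    ``cov_VK`` is the fitted Vmax_app/Km_app covariance, kept so combined
    parameters can be propagated to first order without assuming the two
    estimates within one fit are independent.
    """

    Vmax_app: float
    Km_app: float
    se_Vmax: float
    se_Km: float
    design: Design
    n_points_used: int
    cov_VK: float = 0.0

    def __post_init__(self):
        if self.Vmax_app <= 0 or self.Km_app <= 0:
            raise FitError(
                f"apparent parameters must be positive "
                f"(Vmax_app={self.Vmax_app}, Km_app={self.Km_app})"
            )


def interfacial_velocity(params: InterfacialParams, Xs, S0):
    """Initial velocity (µM/min) of the surface-dilution rate law.

    Accepts scalar or array ``Xs`` (mol%) and ``S0`` (µM); returns the same
    shape.  Zero substrate in either dimension gives zero velocity.
    """
    Xs = np.asarray(Xs, dtype=float)
    S0 = np.asarray(S0, dtype=float)
    if not np.all(np.isfinite(Xs)) or np.any(Xs < 0):
        raise DomainError("Xs must be finite and >= 0")
    if not np.all(np.isfinite(S0)) or np.any(S0 < 0):
        raise DomainError("S0 must be finite and >= 0")
    num = params.Vmax * Xs * S0
    den = params.iKm * params.Ks + params.iKm * S0 + Xs * S0
    v = num / den
    if v.ndim == 0:
        return float(v)
    return v


def truncate_substrate_inhibition(ds: VelocityDataset, n_keep: int = 4) -> VelocityDataset:
    """Keep only the ``n_keep`` lowest distinct surface concentrations.

    Surface-dilution curves show apparent substrate inhibition at high mol%;
    apparent Vmax/Km are therefore obtained from the low-Xs limb only.  All
    replicates at the kept Xs values are retained and the original point
    order is preserved.
    """
    if ds.design != "surface_dilution":
        raise DesignError("truncation applies to surface_dilution datasets only")
    if n_keep < 3:
        raise DesignError(f"n_keep={n_keep} leaves too few concentrations to fit")
    distinct = np.unique(ds.varied())
    if n_keep > len(distinct):
        raise DesignError(
            f"n_keep={n_keep} exceeds the {len(distinct)} distinct Xs values present"
        )
    kept = set(distinct[:n_keep])
    points = [p for p in ds.points if p.Xs in kept]
    return replace(ds, points=points)


def _hanes_guess(x: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Initial (Vmax, Km) from the Hanes linearization x/V = x/Vmax + Km/Vmax."""
    ok = v > 0
    if ok.sum() >= 2:
        slope, intercept = np.polyfit(x[ok], x[ok] / v[ok], 1)
        if slope > 0 and intercept > 0:
            return 1.0 / slope, intercept / slope
    return float(np.max(v)) * 1.5, float(np.median(x))


def fit_apparent_mm(
    ds: VelocityDataset,
    weighting: Literal["none", "inv_v2"] = "none",
) -> ApparentMMFit:
    """Fit the apparent rectangular hyperbola V = Vmax_app*x/(Km_app + x).

    ``x`` is the varied variable of the design (S0 for bulk dilution, Xs for
    surface dilution).  Unweighted least squares by default; ``inv_v2``
    applies 1/V^2 weighting.  Negative velocities (possible after blank
    subtraction) are clipped to zero with a logged warning.
    """
    if ds.design not in ("bulk_dilution", "surface_dilution"):
        raise DesignError("apparent MM fit requires a bulk_dilution or surface_dilution design")
    if ds.n_distinct() < 4:
        raise DesignError(
            f"need >= 4 distinct values of the varied variable, got {ds.n_distinct()}"
        )
    x = ds.varied()
    v = ds.velocities()
    if np.any(v < 0):
        logger.warning("clipping %d negative velocities to zero", int((v < 0).sum()))
        v = np.clip(v, 0.0, None)

    # decreasing overall trend cannot be a rectangular hyperbola
    if np.polyfit(x, v, 1)[0] < 0:
        raise SubstrateInhibitionError(
            "velocities decrease with the varied variable; for surface-dilution "
            "data apply truncate_substrate_inhibition before fitting"
        )

    p0 = _hanes_guess(x, v)
    sigma = v.clip(min=np.max(v) * 1e-3) if weighting == "inv_v2" else None
    try:
        popt, pcov = curve_fit(
            lambda xx, Vm, Km: Vm * xx / (Km + xx),
            x,
            v,
            p0=p0,
            sigma=sigma,
            bounds=(0, np.inf),
            maxfev=20000,
            xtol=1e-12,
            gtol=1e-12,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise FitError(f"apparent MM fit did not converge: {exc}") from exc
    Vm, Km = popt
    if not (Vm > 0 and Km > 0):
        raise FitError(f"non-positive apparent estimates Vmax={Vm}, Km={Km}")
    se = np.sqrt(np.diag(pcov))
    return ApparentMMFit(
        Vmax_app=float(Vm),
        Km_app=float(Km),
        se_Vmax=float(se[0]),
        se_Km=float(se[1]),
        design=ds.design,
        n_points_used=len(x),
        cov_VK=float(pcov[0, 1]),
    )


def combine_interfacial(
    bd: ApparentMMFit,
    sd: ApparentMMFit,
    Xs_fixed: float,
    ET: float,
) -> InterfacialParams:
    """Combine the BD and SD apparent fits into (kcat, iKm, Ks).

    Uses the closed-form combining equations (module docstring) and propagates
    uncertainty to first order by the delta method, treating the BD and SD
    fits as independent while keeping each fit's internal Vmax/Km covariance.
    """
    if bd.design != "bulk_dilution" or sd.design != "surface_dilution":
        raise DesignError("combine_interfacial expects (bulk_dilution, surface_dilution) fits")
    if not (Xs_fixed > 0 and ET > 0):
        raise DomainError("Xs_fixed and ET must be positive")
    if sd.Vmax_app < bd.Vmax_app:
        raise InconsistentFitsError(
            f"Vmax_SD ({sd.Vmax_app:g}) < Vmax_BD ({bd.Vmax_app:g}): "
            "the interfacial model requires Vmax_SD >= Vmax_BD"
        )
    ratio = sd.Vmax_app / bd.Vmax_app
    iKm = (ratio - 1.0) * Xs_fixed
    if iKm <= 0:
        raise InconsistentFitsError(
            "no interfacial saturation detectable: Vmax_SD equals Vmax_BD so iKm = 0 "
            "and Ks is undefined"
        )
    Ks = bd.Km_app * (Xs_fixed / iKm + 1.0)
    kcat = sd.Vmax_app / ET

    # delta method
    d_iKm_dVsd = Xs_fixed / bd.Vmax_app
    d_iKm_dVbd = -Xs_fixed * sd.Vmax_app / bd.Vmax_app**2
    var_iKm = (d_iKm_dVsd * sd.se_Vmax) ** 2 + (d_iKm_dVbd * bd.se_Vmax) ** 2

    d_Ks_dKbd = Xs_fixed / iKm + 1.0
    d_Ks_diKm = -bd.Km_app * Xs_fixed / iKm**2
    # Ks depends on (Km_BD, Vmax_BD, Vmax_SD); keep the BD Vmax/Km covariance
    d_Ks_dVbd = d_Ks_diKm * d_iKm_dVbd
    d_Ks_dVsd = d_Ks_diKm * d_iKm_dVsd
    var_Ks = (
        (d_Ks_dKbd * bd.se_Km) ** 2
        + (d_Ks_dVbd * bd.se_Vmax) ** 2
        + (d_Ks_dVsd * sd.se_Vmax) ** 2
        + 2.0 * d_Ks_dKbd * d_Ks_dVbd * bd.cov_VK
    )
    return InterfacialParams(
        kcat=kcat,
        iKm=iKm,
        Ks=Ks,
        ET=ET,
        se_kcat=sd.se_Vmax / ET,
        se_iKm=math.sqrt(max(var_iKm, 0.0)),
        se_Ks=math.sqrt(max(var_Ks, 0.0)),
    )


def bootstrap_interfacial(
    bd_ds: VelocityDataset,
    sd_ds: VelocityDataset,
    n_boot: int = 200,
    seed: int = 0,
) -> dict[str, float]:
    """Bootstrap standard errors for the combined interfacial parameters.

    Resamples replicates (whole replicate traces, preserving the design
    structure) with replacement, refits and recombines; an alternative to
    the delta-method propagation of :func:`combine_interfacial`.  Returns
    the bootstrap SE of each parameter and the number of resamples that
    produced a valid combination.
    """
    rng = np.random.default_rng(seed)

    def _replicates(ds: VelocityDataset) -> list[list[VelocityPoint]]:
        groups: dict[str, list[VelocityPoint]] = {}
        for p in ds.points:
            groups.setdefault(p.replicate_id, []).append(p)
        return list(groups.values())

    bd_reps, sd_reps = _replicates(bd_ds), _replicates(sd_ds)
    draws = []
    for _ in range(n_boot):
        bd_pts = [p for i in rng.integers(len(bd_reps), size=len(bd_reps)) for p in bd_reps[i]]
        sd_pts = [p for i in rng.integers(len(sd_reps), size=len(sd_reps)) for p in sd_reps[i]]
        try:
            bd = fit_apparent_mm(replace(bd_ds, points=bd_pts))
            sd = fit_apparent_mm(replace(sd_ds, points=sd_pts))
            p = combine_interfacial(bd, sd, Xs_fixed=bd_ds.fixed_value, ET=bd_ds.ET)
            draws.append((p.kcat, p.iKm, p.Ks))
        except (FitError, DesignError):
            continue
    if len(draws) < max(10, n_boot // 4):
        raise FitError(f"only {len(draws)}/{n_boot} bootstrap resamples were fittable")
    arr = np.array(draws)
    se = arr.std(axis=0, ddof=1)
    return {
        "se_kcat": float(se[0]),
        "se_iKm": float(se[1]),
        "se_Ks": float(se[2]),
        "n_valid": len(draws),
    }


def apparent_bd(params: InterfacialParams, Xs: float) -> tuple[float, float]:
    """Closed-form apparent (Vmax, Km) of a bulk-dilution experiment at fixed Xs."""
    return (
        params.Vmax * Xs / (params.iKm + Xs),
        params.iKm * params.Ks / (params.iKm + Xs),
    )


def apparent_sd(params: InterfacialParams, S0: float) -> tuple[float, float]:
    """Closed-form apparent (Vmax, Km) of a surface-dilution experiment at fixed S0."""
    return params.Vmax, params.iKm * (params.Ks + S0) / S0


def activity_rate_ratio(
    params_a: InterfacialParams,
    params_b: InterfacialParams,
    Xs: float,
    S0: float,
) -> float:
    """Velocity ratio of two enzyme forms at a shared (Xs, S0) condition.

    Maps where the activity differential between, e.g., phosphorylated and
    unphosphorylated enzyme is large (it concentrates at low substrate when
    the forms differ mainly in membrane affinity Ks).
    """
    va = interfacial_velocity(params_a, Xs, S0)
    vb = interfacial_velocity(params_b, Xs, S0)
    if vb == 0:
        raise DomainError("denominator velocity is zero; ratio undefined")
    return va / vb
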