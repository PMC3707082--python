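"""Soluble-substrate Michaelis-Menten, linear-efficiency and IC50 analysis.

Short-chain (diC6) PIP3 is water-soluble, so the ordinary Michaelis-Menten
rate law V = kcat*ET*S/(Km + S) applies.  Phospho-tail autoinhibited enzyme
forms may not saturate within an experimentally accessible substrate range;
for those the catalytic efficiency kcat/Km is estimated instead as the slope
of the sub-saturating linear regime (V = (kcat/Km)*ET*S for S << Km).

Trans inhibition by the phosphorylated C-tail peptide is quantified with a
single-site dose-response model, activity = bottom + (top-bottom)/(1+[I]/IC50),
Hill coefficient fixed at 1 unless explicitly freed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from lmfit import Model
from scipy import stats

from .exceptions import CurvatureError, DesignError, DomainError, FitError, NoSaturationError
from .interfacial import VelocityDataset


@dataclass(frozen=True)
class MMParams:
    """Michaelis-Menten parameters: kcat (min^-1), Km (µM), with SEs.

    ``cov`` is the fitted kcat/Km covariance used by the delta method when
    propagating the efficiency uncertainty.
    """

    kcat: float
    Km: float
    se_kcat: float
    se_Km: float
    cov: float = 0.0

    def __post_init__(self):
        if self.kcat <= 0 or self.Km <= 0:
            raise FitError(f"kcat and Km must be positive (kcat={self.kcat}, Km={self.Km})")

    @property
    def efficiency(self) -> float:
        """Catalytic efficiency kcat/Km, min^-1 µM^-1."""
        return self.kcat / self.Km


@dataclass(frozen=True)
class DoseResponseFit:
    """Single-site inhibition fit.  IC50 in µM; hill fixed at 1 by default.

    ``inhibition_detected`` is False when activity shows no significant
    concentration-dependent decrease (e.g. the unphosphorylated peptide);
    the other fields then describe the flat fit, with IC50 = inf.
    """

    IC50: float
    top: float
    bottom: float
    hill: float = 1.0
    se_IC50: Optional[float] = None
    inhibition_detected: bool = True

    def __post_init__(self):
        if self.inhibition_detected and not self.IC50 > 0:
            raise FitError(f"IC50 must be positive, got {self.IC50}")
        if self.bottom > self.top + 1e-12:
            raise FitError("bottom must not exceed top")

    def predict(self, I):
        I = np.asarray(I, dtype=float)
        return self.bottom + (self.top - self.bottom) / (1.0 + (I / self.IC50) ** self.hill)


def _mm_model(S, kcat, Km, ET):
    return kcat * ET * S / (Km + S)


def fit_michaelis_menten(ds: VelocityDataset) -> MMParams:
    """Fit V = kcat*ET*S/(Km + S) to a soluble-substrate dataset.

    Raises :class:`NoSaturationError` when the Km estimate exceeds five times
    the largest assayed substrate concentration, in which case only the
    efficiency is identifiable and :func:`fit_linear_efficiency` should be
    used.  Warns when the substrate range does not straddle the Km estimate.
    """
    if ds.design != "soluble":
        raise DesignError("fit_michaelis_menten requires a soluble-design dataset")
    S = ds.varied()
    V = ds.velocities()
    if len(np.unique(S)) < 4:
        raise DesignError("need >= 4 distinct substrate concentrations")

    model = Model(_mm_model, independent_vars=["S"])
    params = model.make_params(
        kcat=dict(value=max(V.max() / ds.ET, 1e-9), min=1e-12),
        Km=dict(value=float(np.median(S[S > 0])) if np.any(S > 0) else 1.0, min=1e-12),
        ET=dict(value=ds.ET, vary=False),
    )
    result = model.fit(V, params, S=S)
    if not result.success:
        raise FitError(f"Michaelis-Menten fit failed: {result.message}")
    kcat = result.params["kcat"].value
    Km = result.params["Km"].value
    if Km > 5.0 * S.max():
        raise NoSaturationError(
            f"Km estimate ({Km:.3g} µM) exceeds 5x the maximum substrate "
            f"concentration ({S.max():.3g} µM); only kcat/Km is identifiable - "
            "use fit_linear_efficiency"
        )
    if not (S.min() < Km < S.max()):
        warnings.warn(
            f"substrate range [{S.min():g}, {S.max():g}] µM does not straddle the "
            f"Km estimate {Km:.3g} µM; parameters may be poorly constrained",
            stacklevel=2,
        )
    se_k = result.params["kcat"].stderr or 0.0
    se_K = result.params["Km"].stderr or 0.0
    cov = 0.0
    if result.covar is not None:
        names = [p for p in result.params if result.params[p].vary]
        ik, iK = names.index("kcat"), names.index("Km")
        cov = float(result.covar[ik, iK])
    return MMParams(kcat=float(kcat), Km=float(Km), se_kcat=float(se_k), se_Km=float(se_K), cov=cov)


def fit_linear_efficiency(ds: VelocityDataset, alpha: float = 0.05) -> tuple[float, float]:
    """Catalytic efficiency kcat/Km from the sub-saturating linear regime.

    Fits a line through the origin to V vs S with 1/S^2 weighting
    (equivalently, averages the per-point ratios V/S) and divides the slope
    by ET; this weighting matches the multiplicative error structure of the
    assays and is least biased by residual curvature.  Valid only while the
    data are statistically linear: an F-test compares the one-parameter line
    against the two-parameter Michaelis-Menten hyperbola and rejects the
    linear analysis when curvature is significant at level ``alpha``.
    Returns (efficiency, standard error), min^-1 µM^-1.
    """
    if ds.design != "soluble":
        raise DesignError("fit_linear_efficiency requires a soluble-design dataset")
    S = ds.varied()
    V = ds.velocities()
    if len(np.unique(S[S > 0])) < 3:
        raise DesignError("need >= 3 distinct nonzero substrate concentrations")
    pos = S > 0
    ratios = V[pos] / S[pos]
    slope = float(np.mean(ratios))
    if slope <= 0:
        raise FitError(f"non-positive velocity slope ({slope:.3g}); no activity detectable")
    if np.corrcoef(S[pos], V[pos])[0, 1] < 0:
        raise FitError("velocity decreases with substrate; not a sub-saturating linear regime")
    n = int(pos.sum())
    ssr_lin = float(np.sum((ratios - slope) ** 2))  # weighted (1/S^2) residuals

    # curvature test: line-through-origin (1 parameter) vs MM hyperbola (2)
    if n >= 4:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mm = fit_michaelis_menten(ds)
            ssr_mm = float(
                np.sum(((V[pos] - _mm_model(S[pos], mm.kcat, mm.Km, ds.ET)) / S[pos]) ** 2)
            )
        except (NoSaturationError, FitError):
            ssr_mm = None
        if ssr_mm is not None and ssr_mm < ssr_lin and n > 2:
            f = (ssr_lin - ssr_mm) / 1.0 / (ssr_mm / (n - 2))
            p = stats.f.sf(f, 1, n - 2)
            if p < alpha:
                raise CurvatureError(
                    f"significant curvature (F-test p={p:.3g} < {alpha}); "
                    "the data saturate - use fit_michaelis_menten"
                )
    se_slope = float(np.std(ratios, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return slope / ds.ET, se_slope / ds.ET


def catalytic_efficiency(mm: MMParams) -> tuple[float, float]:
    """kcat/Km (min^-1 µM^-1) with a delta-method standard error."""
    eff = mm.efficiency
    rel_var = (
        (mm.se_kcat / mm.kcat) ** 2
        + (mm.se_Km / mm.Km) ** 2
        - 2.0 * mm.cov / (mm.kcat * mm.Km)
    )
    return eff, eff * math.sqrt(max(rel_var, 0.0))


def fold_change(eff_a: float, eff_b: float) -> float:
    """Ratio of two catalytic efficiencies (or any two positive rates)."""
    if eff_b == 0:
        raise DomainError("zero denominator in fold change")
    if eff_a <= 0 or eff_b <= 0:
        raise DomainError("fold change requires strictly positive inputs")
    return eff_a / eff_b


def _logistic(I, top, bottom, IC50, hill):
    return bottom + (top - bottom) / (1.0 + (I / IC50) ** hill)


def fit_ic50(
    dose_response: pd.DataFrame,
    free_hill: bool = False,
    anchor_top: bool = True,
    alpha: float = 0.05,
) -> DoseResponseFit:
    """Fit a single-site inhibition curve to (inhibitor µM, activity) data.

    Requires >= 5 inhibitor concentrations spanning >= 2 log units and
    including zero.  ``top`` is anchored to the mean uninhibited activity
    unless ``anchor_top=False``; ``bottom`` is constrained >= 0; the Hill
    coefficient is fixed at 1 unless ``free_hill=True``.

    A response with no significant concentration-dependent decrease (F-test
    of the logistic against a flat mean at level ``alpha``) is reported as a
    non-inhibition result, not raised as an error.
    """
    df = dose_response
    for col in ("I_uM", "activity"):
        if col not in df.columns:
            raise DesignError(f"dose-response table must have column {col!r}")
    I = df["I_uM"].to_numpy(dtype=float)
    A = df["activity"].to_numpy(dtype=float)
    conc = np.unique(I)
    if len(conc) < 5:
        raise DesignError("need >= 5 distinct inhibitor concentrations")
    if 0.0 not in conc:
        raise DesignError("dose-response design must include a zero-inhibitor control")
    pos = conc[conc > 0]
    if np.log10(pos.max() / pos.min()) < 2.0:
        raise DesignError("inhibitor concentrations must span >= 2 log units")

    top0 = float(A[I == 0].mean())
    model = Model(_logistic, independent_vars=["I"])
    params = model.make_params(
        top=dict(value=top0, vary=not anchor_top),
        bottom=dict(value=max(float(A[I == I.max()].mean()), 0.0), min=0.0),
        IC50=dict(value=float(np.median(pos)), min=1e-9),
        hill=dict(value=1.0, vary=free_hill, min=0.1),
    )
    result = model.fit(A, params, I=I)
    ssr_fit = float(np.sum(result.residual**2))
    ssr_flat = float(np.sum((A - A.mean()) ** 2))
    n = len(A)
    k_extra = 2 + int(free_hill) + int(not anchor_top)
    dof = n - 1 - k_extra
    detected = False
    if ssr_fit < ssr_flat and dof > 0:
        f = (ssr_flat - ssr_fit) / k_extra / (ssr_fit / dof)
        detected = stats.f.sf(f, k_extra, dof) < alpha
    # inhibition must also be a *decrease*
    detected = detected and result.params["bottom"].value < result.params["top"].value

    if not detected:
        return DoseResponseFit(
            IC50=math.inf,
            top=float(A.mean()),
            bottom=float(A.mean()),
            hill=1.0,
            se_IC50=None,
            inhibition_detected=False,
        )
    return DoseResponseFit(
        IC50=float(result.params["IC50"].value),
        top=float(result.params["top"].value),
        bottom=float(result.params["bottom"].value),
        hill=float(result.params["hill"].value),
        se_IC50=result.params["IC50"].stderr,
        inhibition_detected=True,
    )
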