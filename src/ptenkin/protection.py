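"""Phosphatase-protection kinetics and conformational-equilibrium inference.

A promiscuous probe phosphatase (calf intestinal alkaline phosphatase, CIP)
removes tail phosphates only when the phospho-tail is solvent exposed.  The
loss of the phospho signal therefore follows pseudo-first-order kinetics,
F(t) = F0 * exp(-k*t), where k is proportional both to the probe
concentration and to the fraction of time the tail is exposed (open).

Comparing the concentration-normalized rate of a folded, autoinhibited
protein with that of a fully exposed reference (denatured protein, or a
destabilized mutant) gives the protection factor

    r = k_open / k_native.

Under the rapid-exchange occupancy model k_native = f_open * k_open, the
open fraction is f_open = 1/r and the closed:open equilibrium constant is
(r-1):1.  The field's headline convention quotes the rate ratio itself as
"closed:open r:1", accurate for r >> 1; both conventions are reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from lmfit import Model

from .exceptions import DesignError, DomainError, FitError

_K_LOWER_BOUND = 1e-6  # min^-1; fits pinned here are flagged "no decay"


@dataclass
class DecayTimecourse:
    """One dephosphorylation time course.

    times in minutes (nonnegative, increasing); fraction_phospho is the
    band-intensity ratio relative to t=0 (so the first point should sit near
    1; values in [0.8, 1.2] are accepted to absorb blot-loading variation).
    """

    times: np.ndarray
    fraction_phospho: np.ndarray
    CIP_conc: float
    condition: str = "native"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.fraction_phospho = np.asarray(self.fraction_phospho, dtype=float)
        if self.times.shape != self.fraction_phospho.shape:
            raise DesignError("times and fraction_phospho must have equal length")
        if np.any(self.times < 0) or np.any(np.diff(self.times) <= 0):
            raise DomainError("times must be nonnegative and strictly increasing")
        if not (self.CIP_conc > 0):
            raise DomainError(f"CIP concentration must be positive, got {self.CIP_conc}")
        if self.times[0] == 0 and not (0.8 <= self.fraction_phospho[0] <= 1.2):
            raise DomainError(
                f"fraction at t=0 is {self.fraction_phospho[0]:.3g}; expected within "
                "[0.8, 1.2] - normalize intensities to the t=0 band first"
            )


@dataclass(frozen=True)
class DecayFit:
    """First-order decay fit: rate k (min^-1), half-life ln2/k (min)."""

    k: float
    t_half: float
    se_k: float
    CIP_conc: float
    condition: str = ""
    no_decay: bool = False

    def __post_init__(self):
        if not self.k > 0:
            raise FitError(f"rate must be positive, got {self.k}")


@dataclass(frozen=True)
class EquilibriumEstimate:
    """Closed:open equilibrium inferred from a protection-rate differential.

    rate_ratio r = k_open/k_native (concentration-normalized);
    closed_to_open_paper = r (the r:1 headline convention);
    closed_to_open_exact = r-1 (occupancy model k_native = f_open*k_open);
    f_open = 1/r.  ``destabilized`` marks r < 1, where the "native" state is
    in fact more exposed than the reference.
    """

    rate_ratio: float
    closed_to_open_paper: float
    closed_to_open_exact: float
    f_open: float
    destabilized: bool = False


def fit_first_order_decay(tc: DecayTimecourse) -> DecayFit:
    """Least-squares fit of F(t) = F0 * exp(-k t).

    F0 is a free parameter bounded to [0.8, 1.2] to absorb loading variation.
    Non-decaying data leave k pinned at its lower bound and are flagged
    ``no_decay``; a time span shorter than half a fitted half-life triggers a
    wide-confidence-interval warning.
    """
    t = tc.times
    F = tc.fraction_phospho
    if len(t) < 4:
        raise DesignError(f"need >= 4 time points, got {len(t)}")

    def decay(t, F0, k):
        return F0 * np.exp(-k * t)

    # log-linear initial guess on the positive points
    pos = F > 0
    k0 = 0.01
    if pos.sum() >= 2:
        slope = np.polyfit(t[pos], np.log(F[pos]), 1)[0]
        k0 = max(-slope, _K_LOWER_BOUND * 10)
    model = Model(decay)
    params = model.make_params(
        F0=dict(value=float(np.clip(F[0], 0.8, 1.2)), min=0.8, max=1.2),
        k=dict(value=k0, min=_K_LOWER_BOUND),
    )
    result = model.fit(F, params, t=t)
    if not result.success:
        raise FitError(f"decay fit failed: {result.message}")
    k = float(result.params["k"].value)
    # flag fits where less than ~5% of the signal decays over the window
    no_decay = k <= 2 * _K_LOWER_BOUND or k * t.max() < 0.05
    t_half = math.log(2) / k
    if not no_decay and t.max() < 0.5 * t_half:
        warnings.warn(
            f"time span {t.max():g} min covers less than half the fitted half-life "
            f"({t_half:.3g} min); the rate is poorly constrained",
            stacklevel=2,
        )
    return DecayFit(
        k=k,
        t_half=t_half,
        se_k=float(result.params["k"].stderr or np.nan),
        CIP_conc=tc.CIP_conc,
        condition=tc.condition,
        no_decay=no_decay,
    )


def normalize_rate(fit: DecayFit, ref_conc: float) -> float:
    """Scale a pseudo-first-order rate to a reference probe concentration.

    k is linear in the probe (alkaline phosphatase) concentration, so
    k_norm = k * ref_conc / CIP_conc.
    """
    if not (ref_conc > 0 and fit.CIP_conc > 0):
        raise DomainError("concentrations must be positive")
    return fit.k * ref_conc / fit.CIP_conc


def infer_closed_open(k_native_norm: float, k_open_norm: float) -> EquilibriumEstimate:
    """Closed:open equilibrium from the normalized protection-rate pair.

    ``k_open_norm`` is the fully exposed reference (denatured protein);
    ``k_native_norm`` the folded state.  r < 1 (state more exposed than the
    reference) is returned with the ``destabilized`` flag, not raised.
    """
    if not (k_native_norm > 0 and k_open_norm > 0):
        raise DomainError("both rates must be positive")
    r = k_open_norm / k_native_norm
    return EquilibriumEstimate(
        rate_ratio=r,
        closed_to_open_paper=r,
        closed_to_open_exact=r - 1.0,
        f_open=1.0 / r,
        destabilized=r < 1.0,
    )
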