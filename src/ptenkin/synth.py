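"""Seeded synthetic-data generators.

The assays this package analyzes were published without deposited raw data,
so every analysis stage ships with a generator that emulates the matching
experiment's design and noise structure: hyperbolic velocity surfaces with
optional apparent substrate inhibition at high surface mol%, soluble
Michaelis-Menten curves, logistic dose-response tables, exponential
protection decays, saturable co-sedimentation series, and analytic
sphere/dumbbell scattering curves.

Conventions
-----------
* Every generator is a pure function of its parameters and a mandatory seed
  carried by :class:`NoiseModel`; there is no global random state.
* Zero-noise outputs lie exactly on the corresponding forward model.
* Default replicate structure is three experiments performed in duplicate,
  matching the published assay design.
* Default noise is multiplicative Gaussian with a 5% coefficient of
  variation, a typical precision for these assays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .binding import BindingPoint, BindingSeries
from .exceptions import DesignError, DomainError
from .interfacial import InterfacialParams, VelocityDataset, VelocityPoint, interfacial_velocity
from .protection import DecayTimecourse
from .saxs import ScatteringCurve

DEFAULT_CV = 0.05
DEFAULT_REPLICATES = 2
DEFAULT_EXPERIMENTS = 3


@dataclass(frozen=True)
class NoiseModel:
    """Noise specification: multiplicative (cv) or additive (sd) Gaussian."""

    kind: Literal["multiplicative_gaussian", "additive_gaussian"]
    cv_or_sd: float
    seed: int

    def __post_init__(self):
        if self.cv_or_sd < 0:
            raise DomainError("noise level must be >= 0")
        if self.kind not in ("multiplicative_gaussian", "additive_gaussian"):
            raise DomainError(f"unknown noise kind {self.kind!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.cv_or_sd == 0:
            return values.copy()
        z = rng.standard_normal(values.shape)
        if self.kind == "multiplicative_gaussian":
            return values * (1.0 + self.cv_or_sd * z)
        return values + self.cv_or_sd * z


def quiet(seed: int = 0) -> NoiseModel:
    """Zero-noise model (exact forward-model values)."""
    return NoiseModel("multiplicative_gaussian", 0.0, seed)


def default_noise(seed: int, cv: float = DEFAULT_CV) -> NoiseModel:
    return NoiseModel("multiplicative_gaussian", cv, seed)


def _replicate_ids(n_experiments: int, replicates: int):
    return [f"e{e + 1}r{r + 1}" for e in range(n_experiments) for r in range(replicates)]


def gen_interfacial(
    params: InterfacialParams,
    design: Literal["bulk_dilution", "surface_dilution"],
    levels: Sequence[float],
    noise: NoiseModel,
    fixed_value: Optional[float] = None,
    replicates: int = DEFAULT_REPLICATES,
    n_experiments: int = DEFAULT_EXPERIMENTS,
    substrate_inhibition: bool = False,
    sample: str = "synthetic",
) -> VelocityDataset:
    """Simulate a bulk- or surface-dilution velocity dataset.

    Defaults mirror the published designs: bulk dilution at a fixed 1 mol%
    surface concentration, surface dilution at a fixed 50 µM bulk
    concentration.  ``substrate_inhibition`` multiplies high-Xs velocities
    by a decreasing artifact factor (no effect on the four lowest levels) to
    emulate the apparent inhibition limb of surface-dilution curves.
    """
    levels = np.asarray(list(levels), dtype=float)
    if levels.size == 0:
        raise DesignError("levels must be non-empty")
    if fixed_value is None:
        fixed_value = 1.0 if design == "bulk_dilution" else 50.0
    rng = noise.rng()
    if design == "bulk_dilution":
        Xs = np.full_like(levels, fixed_value)
        S0 = levels
    elif design == "surface_dilution":
        Xs = levels
        S0 = np.full_like(levels, fixed_value)
    else:
        raise DesignError(f"design must be bulk_dilution or surface_dilution, got {design!r}")
    v_true = interfacial_velocity(params, Xs, S0)
    if substrate_inhibition:
        if design != "surface_dilution":
            raise DesignError("the substrate-inhibition artifact applies to surface dilution")
        x0 = np.sort(np.unique(levels))[min(3, len(np.unique(levels)) - 1)]
        factor = 1.0 / (1.0 + (np.clip(Xs - x0, 0.0, None) / x0) ** 2)
        v_true = v_true * factor
    points = []
    for rid in _replicate_ids(n_experiments, replicates):
        v = np.clip(noise.apply(v_true, rng), 0.0, None)
        points.extend(
            VelocityPoint(S0=float(s), Xs=float(x), V0=float(vv), replicate_id=rid)
            for s, x, vv in zip(S0, Xs, v)
        )
    return VelocityDataset(
        points=points, design=design, ET=params.ET, fixed_value=fixed_value, sample=sample
    )


def gen_mm(
    kcat: float,
    Km: float,
    ET: float,
    S_levels: Sequence[float],
    noise: NoiseModel,
    replicates: int = DEFAULT_REPLICATES,
    n_experiments: int = DEFAULT_EXPERIMENTS,
    sample: str = "synthetic",
) -> VelocityDataset:
    """Simulate a soluble-substrate Michaelis-Menten dataset."""
    S = np.asarray(list(S_levels), dtype=float)
    if S.size == 0:
        raise DesignError("S_levels must be non-empty")
    rng = noise.rng()
    v_true = kcat * ET * S / (Km + S)
    points = []
    for rid in _replicate_ids(n_experiments, replicates):
        v = np.clip(noise.apply(v_true, rng), 0.0, None)
        points.extend(
            VelocityPoint(S0=float(s), Xs=0.0, V0=float(vv), replicate_id=rid)
            for s, vv in zip(S, v)
        )
    return VelocityDataset(points=points, design="soluble", ET=ET, sample=sample)


def gen_dose_response(
    IC50: float,
    top: float,
    bottom: float,
    I_levels: Sequence[float],
    noise: NoiseModel,
    hill: float = 1.0,
    replicates: int = DEFAULT_REPLICATES,
    n_experiments: int = DEFAULT_EXPERIMENTS,
    sample: str = "synthetic",
) -> pd.DataFrame:
    """Simulate a (inhibitor µM, activity) dose-response table."""
    I = np.asarray(list(I_levels), dtype=float)
    if I.size == 0:
        raise DesignError("I_levels must be non-empty")
    rng = noise.rng()
    with np.errstate(divide="ignore"):
        a_true = bottom + (top - bottom) / (1.0 + (I / IC50) ** hill)
    rows = []
    for rid in _replicate_ids(n_experiments, replicates):
        a = noise.apply(a_true, rng)
        rows.extend(
            {"sample": sample, "I_uM": float(i), "activity": float(av), "replicate": rid}
            for i, av in zip(I, a)
        )
    return pd.DataFrame(rows)


def gen_decay(
    k: float,
    CIP_conc: float,
    t_levels: Sequence[float],
    noise: NoiseModel,
    F0: float = 1.0,
    condition: str = "native",
) -> DecayTimecourse:
    """Simulate a pseudo-first-order dephosphorylation time course."""
    t = np.asarray(list(t_levels), dtype=float)
    if t.size == 0:
        raise DesignError("t_levels must be non-empty")
    rng = noise.rng()
    f_true = F0 * np.exp(-k * t)
    f = np.clip(noise.apply(f_true, rng), 0.0, None)
    if t[0] == 0:
        f[0] = np.clip(f[0], 0.8, 1.2)
    return DecayTimecourse(times=t, fraction_phospho=f, CIP_conc=CIP_conc, condition=condition)


def gen_binding(
    c50: float,
    fmax: float,
    molpct_levels: Sequence[float],
    noise: NoiseModel,
    total_intensity: float = 1000.0,
    lipid: Literal["PIP2", "PS"] = "PIP2",
    sample: str = "synthetic",
) -> BindingSeries:
    """Simulate a co-sedimentation series: saturable bound fraction rendered
    as pellet/supernatant band intensities with independent noise on each."""
    c = np.asarray(list(molpct_levels), dtype=float)
    if c.size == 0:
        raise DesignError("molpct_levels must be non-empty")
    rng = noise.rng()
    f_true = fmax * c / (c50 + c)
    pellet = np.clip(noise.apply(total_intensity * f_true, rng), 0.0, None)
    sup = np.clip(noise.apply(total_intensity * (1.0 - f_true), rng), 0.0, None)
    points = [
        BindingPoint(anionic_molpct=float(cc), pellet_intensity=float(p), supernatant_intensity=float(s))
        for cc, p, s in zip(c, pellet, sup)
    ]
    return BindingSeries(sample=sample, lipid=lipid, points=points)


def sphere_intensity(q: np.ndarray, R: float) -> np.ndarray:
    """Form-factor intensity of a uniform sphere of radius R, I(0)=1."""
    q = np.asarray(q, dtype=float)
    qR = q * R
    F = np.ones_like(qR)
    nz = qR != 0
    F[nz] = 3.0 * (np.sin(qR[nz]) - qR[nz] * np.cos(qR[nz])) / qR[nz] ** 3
    return F**2


def two_sphere_intensity(q: np.ndarray, d: float, R: float) -> np.ndarray:
    """Debye intensity of two identical spheres with centers d apart, I(0)=1."""
    q = np.asarray(q, dtype=float)
    qd = q * d
    cross = np.ones_like(qd)
    nz = qd != 0
    cross[nz] = np.sin(qd[nz]) / qd[nz]
    return sphere_intensity(q, R) * (1.0 + cross) / 2.0


def gen_scattering(
    body: Literal["sphere", "two_sphere"],
    q_grid: Sequence[float],
    noise: NoiseModel,
    R: float = 30.0,
    d: float = 40.0,
) -> ScatteringCurve:
    """Simulate a scattering curve from an analytic body.

    ``sphere``: uniform sphere of radius R (Rg = sqrt(3/5) R, Dmax = 2R).
    ``two_sphere``: dumbbell of two R-spheres with centers d apart
    (Dmax = d + 2R).  Noise is Poisson-like, sigma proportional to sqrt(I);
    at zero noise the intensities are exact and sigma reports a nominal 1%
    scale so downstream chi^2 weighting remains defined.
    """
    q = np.asarray(list(q_grid), dtype=float)
    if body == "sphere":
        I_true = sphere_intensity(q, R)
    elif body == "two_sphere":
        I_true = two_sphere_intensity(q, d, R)
    else:
        raise DesignError(f"unknown body {body!r}")
    rng = noise.rng()
    level = noise.cv_or_sd if noise.cv_or_sd > 0 else 0.01
    sigma = level * np.sqrt(np.clip(I_true, 1e-12, None))
    if noise.cv_or_sd > 0:
        I = I_true + sigma * rng.standard_normal(I_true.shape)
    else:
        I = I_true.copy()
    return ScatteringCurve(q=q, I=I, sigma=sigma)
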