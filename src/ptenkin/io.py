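"""CSV / .dat readers and writers for the analysis stages.

Schemas (column names are exact):

* ``velocities.csv`` — sample, design{bulk_dilution|surface_dilution|soluble},
  S0_uM, Xs_molpct, ET_uM, V0_uM_per_min, replicate.  An optional ``Xs_unit``
  column (``molpct`` or ``molfrac``) lets mole-fraction data be loaded; it is
  converted to mol% on ingest.
* ``soluble.csv`` — sample, S_uM, ET_uM, V0_uM_per_min, replicate.
* ``doseresponse.csv`` — sample, inhibitor, I_uM, activity, replicate.
* ``decay.csv`` — sample, condition, CIP_uM, time_min, fraction_phospho, replicate.
* ``binding.csv`` — sample, lipid, anionic_molpct, pellet_intensity,
  supernatant_intensity, replicate.
* scattering ``.dat`` — 3 columns (q, I, sigma), whitespace or comma
  separated, ``#`` comments.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .binding import BindingPoint, BindingSeries
from .exceptions import DesignError
from .interfacial import VelocityDataset, VelocityPoint
from .protection import DecayTimecourse
from .saxs import ScatteringCurve

PathLike = Union[str, Path]


def _require(df: pd.DataFrame, cols: tuple[str, ...], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DesignError(f"{what} is missing required columns {missing}")


def load_velocities(path: PathLike) -> dict[tuple[str, str], VelocityDataset]:
    """Load velocities.csv into datasets keyed by (sample, design)."""
    df = pd.read_csv(path)
    _require(
        df,
        ("sample", "design", "S0_uM", "Xs_molpct", "ET_uM", "V0_uM_per_min", "replicate"),
        "velocities table",
    )
    if "Xs_unit" in df.columns:
        frac = df["Xs_unit"].astype(str).str.lower().eq("molfrac")
        df.loc[frac, "Xs_molpct"] = df.loc[frac, "Xs_molpct"] * 100.0
    out = {}
    for (sample, design), grp in df.groupby(["sample", "design"], sort=False):
        et = grp["ET_uM"].unique()
        if len(et) != 1:
            raise DesignError(f"{sample}/{design}: ET must be constant within a dataset")
        points = [
            VelocityPoint(S0=row.S0_uM, Xs=row.Xs_molpct, V0=row.V0_uM_per_min,
                          replicate_id=str(row.replicate))
            for row in grp.itertuples()
        ]
        out[(sample, design)] = VelocityDataset(
            points=points, design=design, ET=float(et[0]), sample=sample
        )
    return out


def write_velocities(datasets, path: PathLike) -> None:
    rows = []
    for ds in datasets:
        for p in ds.points:
            rows.append(
                {
                    "sample": ds.sample,
                    "design": ds.design,
                    "S0_uM": p.S0,
                    "Xs_molpct": p.Xs,
                    "ET_uM": ds.ET,
                    "V0_uM_per_min": p.V0,
                    "replicate": p.replicate_id,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_soluble(path: PathLike) -> dict[str, VelocityDataset]:
    """Load soluble.csv into soluble-design datasets keyed by sample."""
    df = pd.read_csv(path)
    _require(df, ("sample", "S_uM", "ET_uM", "V0_uM_per_min", "replicate"), "soluble table")
    out = {}
    for sample, grp in df.groupby("sample", sort=False):
        et = grp["ET_uM"].unique()
        if len(et) != 1:
            raise DesignError(f"{sample}: ET must be constant within a dataset")
        points = [
            VelocityPoint(S0=row.S_uM, Xs=0.0, V0=row.V0_uM_per_min, replicate_id=str(row.replicate))
            for row in grp.itertuples()
        ]
        out[sample] = VelocityDataset(points=points, design="soluble", ET=float(et[0]), sample=sample)
    return out


def load_dose_response(path: PathLike) -> dict[tuple[str, str], pd.DataFrame]:
    """Load doseresponse.csv, keyed by (sample, inhibitor)."""
    df = pd.read_csv(path)
    _require(df, ("sample", "inhibitor", "I_uM", "activity", "replicate"), "dose-response table")
    return {key: grp.reset_index(drop=True) for key, grp in df.groupby(["sample", "inhibitor"], sort=False)}


def load_decay(path: PathLike) -> dict[tuple[str, str], DecayTimecourse]:
    """Load decay.csv, keyed by (sample, condition).

    Replicates at the same time point are averaged into one trace.
    """
    df = pd.read_csv(path)
    _require(
        df, ("sample", "condition", "CIP_uM", "time_min", "fraction_phospho", "replicate"), "decay table"
    )
    out = {}
    for (sample, condition), grp in df.groupby(["sample", "condition"], sort=False):
        conc = grp["CIP_uM"].unique()
        if len(conc) != 1:
            raise DesignError(f"{sample}/{condition}: CIP concentration must be constant")
        mean = grp.groupby("time_min", sort=True)["fraction_phospho"].mean()
        out[(sample, condition)] = DecayTimecourse(
            times=mean.index.to_numpy(dtype=float),
            fraction_phospho=mean.to_numpy(dtype=float),
            CIP_conc=float(conc[0]),
            condition=str(condition),
        )
    return out


def load_binding(path: PathLike) -> dict[tuple[str, str], BindingSeries]:
    """Load binding.csv, keyed by (sample, lipid).

    Replicate band intensities at the same mol% are averaged per replicate
    fraction convention: the point's fraction is the mean of per-replicate
    fractions, carried through as averaged intensities with matched total.
    """
    df = pd.read_csv(path)
    _require(
        df,
        ("sample", "lipid", "anionic_molpct", "pellet_intensity", "supernatant_intensity", "replicate"),
        "binding table",
    )
    out = {}
    for (sample, lipid), grp in df.groupby(["sample", "lipid"], sort=False):
        pts = []
        for molpct, g in grp.groupby("anionic_molpct", sort=True):
            fr = (g["pellet_intensity"] / (g["pellet_intensity"] + g["supernatant_intensity"])).mean()
            pts.append(
                BindingPoint(
                    anionic_molpct=float(molpct),
                    pellet_intensity=float(fr),
                    supernatant_intensity=float(1.0 - fr),
                )
            )
        out[(sample, lipid)] = BindingSeries(sample=sample, lipid=lipid, points=pts)
    return out


def load_scattering(path: PathLike) -> ScatteringCurve:
    """Load a 3-column (q, I, sigma) scattering file; 2 columns -> no sigma."""
    path = Path(path)
    try:
        arr = np.loadtxt(path, comments="#")
    except ValueError:
        arr = np.loadtxt(path, comments="#", delimiter=",")
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise DesignError(f"{path} is not a 2- or 3-column scattering file")
    sigma = arr[:, 2] if arr.shape[1] >= 3 else None
    return ScatteringCurve(q=arr[:, 0], I=arr[:, 1], sigma=sigma)


def write_scattering(curve: ScatteringCurve, path: PathLike) -> None:
    sigma = curve.sigma if curve.sigma is not None else np.zeros_like(curve.q)
    np.savetxt(
        path,
        np.column_stack([curve.q, curve.I, sigma]),
        header="q_invA I sigma",
        fmt="%.8g",
    )


def write_pofr(result, path: PathLike) -> None:
    pd.DataFrame({"r_A": result.r, "P_r": result.Pr}).to_csv(path, index=False)
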