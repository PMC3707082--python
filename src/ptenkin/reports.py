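"""Stage runners and summary tables tying the fits into one pipeline.

Each ``run_*`` function loads one stage's CSV input (per the schemas in
:mod:`ptenkin.io`), applies the module's analysis and returns a tidy summary
DataFrame with units in the column names.  :func:`run_all` executes every
stage present in the config, writes per-stage CSVs plus a machine-readable
JSON report, and records a run manifest (versions, seed, options).
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io, saxs
from .binding import fit_binding_curve
from .config import RunConfig
from .exceptions import DesignError, NoSaturationError, PtenkinError
from .interfacial import combine_interfacial, fit_apparent_mm, truncate_substrate_inhibition
from .protection import fit_first_order_decay, infer_closed_open, normalize_rate
from .soluble import catalytic_efficiency, fit_ic50, fit_linear_efficiency, fit_michaelis_menten

logger = logging.getLogger(__name__)


def run_interfacial(config: RunConfig) -> pd.DataFrame:
    """Interfacial summary: per-sample kcat, iKm, Ks with SEs.

    Pairs each sample's bulk-dilution and surface-dilution datasets,
    truncates the SD limb to ``config.n_keep`` surface concentrations, fits
    both apparent hyperbolas and combines them.
    """
    datasets = io.load_velocities(config.inputs["interfacial"])
    samples = sorted({s for s, _ in datasets})
    rows = []
    for sample in samples:
        bd_ds = datasets.get((sample, "bulk_dilution"))
        sd_ds = datasets.get((sample, "surface_dilution"))
        if bd_ds is None or sd_ds is None:
            logger.warning("sample %s lacks a BD/SD pair; skipped", sample)
            continue
        if sd_ds.n_distinct() > config.n_keep:
            sd_ds = truncate_substrate_inhibition(sd_ds, config.n_keep)
        bd = fit_apparent_mm(bd_ds)
        sd = fit_apparent_mm(sd_ds)
        params = combine_interfacial(bd, sd, Xs_fixed=bd_ds.fixed_value, ET=bd_ds.ET)
        rows.append(
            {
                "sample": sample,
                "kcat_per_min": params.kcat,
                "se_kcat": params.se_kcat,
                "iKm_molpct": params.iKm,
                "se_iKm": params.se_iKm,
                "Ks_uM": params.Ks,
                "se_Ks": params.se_Ks,
                "n_keep": config.n_keep,
            }
        )
    if not rows:
        raise DesignError("no sample had both bulk- and surface-dilution data")
    return pd.DataFrame(rows)


def run_soluble(config: RunConfig) -> pd.DataFrame:
    """Soluble-substrate summary: kcat, Km and efficiency per sample.

    Samples without detectable saturation fall back to the linear-efficiency
    analysis and report efficiency only.
    """
    datasets = io.load_soluble(config.inputs["soluble"])
    rows = []
    for sample, ds in datasets.items():
        try:
            mm = fit_michaelis_menten(ds)
            eff, se_eff = catalytic_efficiency(mm)
            rows.append(
                {
                    "sample": sample,
                    "kcat_per_min": mm.kcat,
                    "se_kcat": mm.se_kcat,
                    "Km_uM": mm.Km,
                    "se_Km": mm.se_Km,
                    "efficiency_per_min_per_uM": eff,
                    "se_efficiency": se_eff,
                    "analysis": "michaelis_menten",
                }
            )
        except NoSaturationError:
            eff, se_eff = fit_linear_efficiency(ds)
            rows.append(
                {
                    "sample": sample,
                    "kcat_per_min": np.nan,
                    "se_kcat": np.nan,
                    "Km_uM": np.nan,
                    "se_Km": np.nan,
                    "efficiency_per_min_per_uM": eff,
                    "se_efficiency": se_eff,
                    "analysis": "linear_efficiency",
                }
            )
    return pd.DataFrame(rows)


def run_ic50(config: RunConfig) -> pd.DataFrame:
    """Dose-response summary: IC50 per (sample, inhibitor)."""
    tables = io.load_dose_response(config.inputs["doseresponse"])
    rows = []
    for (sample, inhibitor), df in tables.items():
        fit = fit_ic50(df)
        rows.append(
            {
                "sample": sample,
                "inhibitor": inhibitor,
                "IC50_uM": fit.IC50,
                "se_IC50": fit.se_IC50,
                "top": fit.top,
                "bottom": fit.bottom,
                "inhibition_detected": fit.inhibition_detected,
            }
        )
    return pd.DataFrame(rows)


def run_conformational(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Protection-kinetics summary.

    Returns (decay fits, equilibrium estimates).  Rates are normalized to
    ``config.ref_cip_uM`` (default: the highest probe concentration in the
    table); the open reference for equilibrium inference is the condition
    named ``denatured`` when present, else the fastest normalized rate.
    """
    courses = io.load_decay(config.inputs["decay"])
    fits = {key: fit_first_order_decay(tc) for key, tc in courses.items()}
    ref_conc = config.ref_cip_uM or max(f.CIP_conc for f in fits.values())
    norm = {key: normalize_rate(f, ref_conc) for key, f in fits.items()}

    decay_rows = [
        {
            "sample": s,
            "condition": c,
            "k_per_min": f.k,
            "se_k": f.se_k,
            "t_half_min": f.t_half,
            "CIP_uM": f.CIP_conc,
            "k_norm_per_min": norm[(s, c)],
            "ref_CIP_uM": ref_conc,
            "no_decay": f.no_decay,
        }
        for (s, c), f in fits.items()
    ]

    eq_rows = []
    for sample in sorted({s for s, _ in fits}):
        conds = {c: norm[(sample, c)] for (s, c) in fits if s == sample}
        if len(conds) < 2:
            continue
        if "denatured" in conds:
            open_cond = "denatured"
        else:
            open_cond = max(conds, key=conds.get)
        for cond, k_norm in conds.items():
            if cond == open_cond:
                continue
            est = infer_closed_open(k_norm, conds[open_cond])
            eq_rows.append(
                {
                    "sample": sample,
                    "condition": cond,
                    "open_reference": open_cond,
                    "rate_ratio": est.rate_ratio,
                    "closed_to_open_paper": est.closed_to_open_paper,
                    "closed_to_open_exact": est.closed_to_open_exact,
                    "f_open": est.f_open,
                    "destabilized": est.destabilized,
                }
            )
    return pd.DataFrame(decay_rows), pd.DataFrame(eq_rows)


def run_binding(config: RunConfig) -> pd.DataFrame:
    """Co-sedimentation summary: fitted c50 / fmax per (sample, lipid)."""
    series = io.load_binding(config.inputs["binding"])
    rows = []
    for (sample, lipid), s in series.items():
        fit = fit_binding_curve(s)
        rows.append(
            {
                "sample": sample,
                "lipid": lipid,
                "c50_molpct": fit.c50,
                "se_c50": fit.se_c50,
                "fmax": fit.fmax,
                "se_fmax": fit.se_fmax,
                "poor_fit": fit.poor_fit,
            }
        )
    return pd.DataFrame(rows)


def run_saxs(config: RunConfig, outdir: Path | None = None) -> pd.DataFrame:
    """SAXS descriptor summary: Guinier Rg, Dmax, real-space Rg, shoulder.

    The saxs input is a mapping of sample name to scattering file (or a
    single path, reported as sample "saxs").  Writes each P(r) table next to
    the summary when ``outdir`` is given.
    """
    entry = config.inputs["saxs"]
    files = entry if isinstance(entry, dict) else {"saxs": entry}
    rows = []
    for sample, path in files.items():
        curve = io.load_scattering(path)
        g = saxs.guinier_fit(curve, qRg_limit=config.qRg_limit)
        scan = saxs.estimate_dmax(curve, r_scan=config.dmax_scan, alpha=config.alpha)
        pofr = saxs.pair_distribution(curve, Dmax=scan.Dmax, alpha=config.alpha)
        if outdir is not None:
            io.write_pofr(pofr, Path(outdir) / f"pofr_{sample}.csv")
        rows.append(
            {
                "sample": sample,
                "Rg_guinier_A": g.Rg,
                "I0": g.I0,
                "qRg_max": g.qRg_max,
                "Dmax_A": pofr.Dmax,
                "Rg_real_A": pofr.Rg_real,
                "shoulder_fraction": saxs.shoulder_fraction(pofr),
                "alpha": pofr.alpha,
            }
        )
    return pd.DataFrame(rows)


_STAGE_RUNNERS = {
    "interfacial": run_interfacial,
    "soluble": run_soluble,
    "doseresponse": run_ic50,
    "binding": run_binding,
}


def run_all(config: RunConfig) -> dict:
    """Execute every stage present in the config.

    Writes one CSV per summary table, a combined ``report.json`` and a
    ``manifest.json`` (package/library versions, seed, options) under
    ``config.outdir``.  Returns the report as a dict of records.
    """
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {}

    for stage, runner in _STAGE_RUNNERS.items():
        if stage in config.inputs:
            df = runner(config)
            df.to_csv(outdir / f"{stage}_summary.csv", index=False)
            report[stage] = df.to_dict(orient="records")
    if "decay" in config.inputs:
        decay_df, eq_df = run_conformational(config)
        decay_df.to_csv(outdir / "decay_summary.csv", index=False)
        eq_df.to_csv(outdir / "equilibrium_summary.csv", index=False)
        report["decay"] = decay_df.to_dict(orient="records")
        report["equilibrium"] = eq_df.to_dict(orient="records")
    if "saxs" in config.inputs:
        df = run_saxs(config, outdir=outdir)
        df.to_csv(outdir / "saxs_summary.csv", index=False)
        report["saxs"] = df.to_dict(orient="records")

    manifest = {
        "ptenkin_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "python_version": platform.python_version(),
        "seed": config.seed,
        "options": {
            "n_keep": config.n_keep,
            "qRg_limit": config.qRg_limit,
            "alpha": config.alpha,
            "noise_cv": config.noise_cv,
            "dmax_scan": list(config.dmax_scan),
        },
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("wrote report for stages %s to %s", sorted(report), outdir)
    return report
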