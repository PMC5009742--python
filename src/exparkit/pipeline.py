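"""End-to-end orchestration: simulate -> analyze -> calibrate -> quantify -> report.

``run_pipeline`` ties the stages together deterministically under one seed:
a calibration dilution plate, per-well POI extraction, (piecewise) calibration
fitting, inverse quantitation of unknowns, a let-7-family specificity plate
with its cross-reactivity table, melt-curve Tm calls, and a paired
method-comparison table with RE/RSD columns.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import curves as _curves
from . import synthetic
from .design import LET7_FAMILY, cross_reactivity_report
from .errors import ConfigError, ExparError
from .io import RunConfig, write_results_csv
from .quant import fit_calibration, invert_poi
from .synthetic import CalibrationTruth, CurveModel, PlateSpec, WellSpec

__all__ = [
    "DEFAULT_CROSS_REACTIVITY",
    "analyze_plate",
    "run_pipeline",
]

#: Default per-species cross-reaction fractions of the specificity plate.
#: The target reacts fully; siblings with more central mismatches react at
#: fractions spanning ~1e-1 down to ~1e-4, the scale separation an
#: asymmetric-template assay is designed to resolve.
DEFAULT_CROSS_REACTIVITY = {
    "let-7a": 1.0,
    "let-7e": 0.0993,
    "let-7d": 0.00044,
    "let-7f": 0.00023,
    "let-7b": 0.0001,
    "let-7c": 0.0001,
    "let-7g": 0.00005,
    "let-7i": 0.00005,
}

#: Melt-transition truths per template variant: the symmetric template shows
#: one duplex transition; the biotin-tagged template splits it in two (the
#: destabilised 5' duplex melting ~10 degC lower); the toehold hairpin adds a
#: high-Tm stem.
MELT_TRUTHS = {
    "standard": (64.3,),
    "biotin": (59.9, 51.5),
    "toehold_biotin": (66.61,),
}


def analyze_plate(curve_list, smooth_window: int = 7, poly_order: int = 2) -> pd.DataFrame:
    """POI-call every amplification curve; one row per well."""
    rows = []
    for c in curve_list:
        res = _curves.extract_poi(c, smooth_window=smooth_window, poly_order=poly_order)
        rows.append(
            {
                "well": c.well,
                "poi": res.poi,
                "max_slope": res.max_slope,
                "amplified": res.amplified,
                "qc_notes": ";".join(res.qc_notes),
            }
        )
    return pd.DataFrame(rows)


def _dilution_wells(cfg: RunConfig) -> list[WellSpec]:
    lo = math.ceil(math.log10(cfg.range_min))
    hi = math.floor(math.log10(cfg.range_max))
    wells = []
    for d in range(lo, hi + 1):
        for r in range(1, cfg.replicates + 1):
            wells.append(
                WellSpec(f"C{d:02d}r{r}", "let-7a", 10.0 ** d, cfg.template_kind, r)
            )
    return wells


def _specificity_wells(cfg: RunConfig, input_copies: float) -> list[WellSpec]:
    return [
        WellSpec(f"S_{name}", name, input_copies, cfg.template_kind, 1)
        for name in LET7_FAMILY
    ]


def _stage(name):
    """Decorator-free stage guard: re-raise with the failing stage named."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"stage '{name}' failed: {exc}") from exc
            return False

    return _Ctx()


class _StageError(ExparError):
    pass


def run_pipeline(
    cfg: RunConfig,
    mode: str = "simulate+analyze",
    plate_curves=None,
    outdir: str | Path | None = None,
    unknown_levels=(4.05e6, 0.418e6, 3.98e6),
    specificity_input: float = 6.02e9,
    cross_reactivity: dict | None = None,
    curve_model: CurveModel | None = None,
) -> dict:
    """Run the full desk pipeline and return (and optionally write) a report.

    In ``simulate+analyze`` mode every input is generated from ``cfg.seed``;
    in ``analyze-only`` mode ``plate_curves`` (as read from CSV) are POI-called
    and calibration/quantitation stages are skipped.  The report is a plain
    JSON-serialisable dict; when ``outdir`` is given, CSV/JSON artefacts are
    written there and the report carries a content hash for determinism checks.
    """
    if mode not in ("simulate+analyze", "analyze-only"):
        raise ConfigError(f"unknown mode '{mode}'")
    report: dict = {"seed": cfg.seed, "mode": mode, "template_kind": cfg.template_kind}
    truth = CalibrationTruth(cfg.calibration_a, cfg.calibration_b, (cfg.range_min, cfg.range_max))
    curve_defaults = curve_model if curve_model is not None else CurveModel()
    artefacts: dict[str, pd.DataFrame] = {}

    if mode == "analyze-only":
        if plate_curves is None:
            raise ConfigError("analyze-only mode requires plate_curves")
        with _stage("analyze"):
            per_well = analyze_plate(plate_curves, cfg.smooth_window, cfg.poly_order)
        report["per_well"] = per_well.to_dict(orient="records")
        artefacts["per_well"] = per_well
    else:
        with _stage("simulate-calibration-plate"):
            plate = synthetic.generate_plate(
                PlateSpec(_dilution_wells(cfg), cfg.read_interval, cfg.duration, cfg.seed),
                truth,
                curve_defaults,
                amplification_floor=cfg.amplification_floor,
            )
        with _stage("analyze"):
            per_well = analyze_plate(plate.curves, cfg.smooth_window, cfg.poly_order)
            per_well = per_well.merge(plate.truth[["well", "copies", "poi_true"]], on="well")
        report["per_well"] = per_well.round(6).to_dict(orient="records")
        artefacts["per_well"] = per_well

        with _stage("calibrate"):
            ok = per_well[per_well["amplified"]]
            fit = fit_calibration(ok[["copies", "poi"]].to_numpy())
        report["calibration"] = {
            "intercept": fit.intercept,
            "slope": fit.slope,
            "r": fit.r,
            "n_points": fit.n_points,
            "copies_range": list(fit.copies_range),
        }

        with _stage("quantify"):
            # unknowns: fresh wells at the requested levels, quantified back
            # through the fitted line (inverse prediction)
            wells = [
                WellSpec(f"U{i + 1}", "let-7a", lvl, cfg.template_kind, 1)
                for i, lvl in enumerate(unknown_levels)
            ]
            uplate = synthetic.generate_plate(
                PlateSpec(tuple(wells), cfg.read_interval, cfg.duration, cfg.seed + 1),
                truth,
                curve_defaults,
                amplification_floor=cfg.amplification_floor,
            )
            u_results = analyze_plate(uplate.curves, cfg.smooth_window, cfg.poly_order)
            u_results["true_copies"] = [w.copies for w in wells]
            u_results["estimated_copies"] = [
                invert_poi(fit, p) if a else 0.0
                for p, a in zip(u_results["poi"], u_results["amplified"])
            ]
        report["quantified_unknowns"] = u_results.to_dict(orient="records")
        artefacts["quantified_unknowns"] = u_results

        with _stage("specificity"):
            splate = synthetic.generate_plate(
                PlateSpec(
                    _specificity_wells(cfg, specificity_input),
                    cfg.read_interval,
                    cfg.duration,
                    cfg.seed + 2,
                ),
                truth,
                curve_defaults,
                cross_reactivity=cross_reactivity or DEFAULT_CROSS_REACTIVITY,
                amplification_floor=cfg.amplification_floor,
            )
            s_results = analyze_plate(splate.curves, cfg.smooth_window, cfg.poly_order)
            s_results = s_results.merge(splate.truth[["well", "species"]], on="well")
            xr_table = cross_reactivity_report(s_results, fit, specificity_input)
        report["cross_reactivity"] = xr_table.to_dict(orient="records")
        artefacts["cross_reactivity"] = xr_table

        with _stage("melt"):
            tms_true = MELT_TRUTHS[cfg.template_kind]
            T_grid = np.arange(45.0, 95.0 + 1e-9, 0.25)
            melt = synthetic.generate_melt_curve(
                tms_true, 1.5, 1000.0, T_grid, seed=cfg.seed + 3, noise_sd=2.0
            )
            called = _curves.call_tm(melt, min_prominence=cfg.melt_prominence)
        report["melt"] = {"true_tms": list(tms_true), "called_tms": called}

        with _stage("method-comparison"):
            mc = synthetic.generate_method_comparison(
                true_levels=[4.05, 0.418, 3.98, 0.406, 4.30],  # x1e6 copies/uL scale
                cv_ref=10.0,
                cv_test=5.0,
                n_reps=cfg.replicates,
                seed=cfg.seed + 4,
            )
        report["method_comparison"] = mc.to_dict(orient="records")
        artefacts["method_comparison"] = mc

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in artefacts.items():
            write_results_csv(df, outdir / f"{name}.csv")
        payload = json.dumps(report, sort_keys=True, default=float)
        report["report_sha256"] = hashlib.sha256(payload.encode()).hexdigest()
        (outdir / "report.json").write_text(json.dumps(report, sort_keys=True, indent=2, default=float))
    return report
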