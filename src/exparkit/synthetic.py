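"""Instrument-like synthetic data: amplification plates, melt curves, method tables.

Real-time EXPAR traces are sigmoidal: a flat baseline, an exponential rise
once amplification outruns the dye background, and a plateau set by reagent
exhaustion.  The generator uses a logistic in time for that shape — its
midpoint is exactly the point of maximum slope, so the ground-truth POI of a
well is a model parameter rather than a derived quantity.  Well POIs follow
a log-linear calibration POI = a - b * lg(copies), the behaviour the
downstream fitting stage assumes.

Melt curves are sums of two-state (logistic in temperature) transitions, and
method-comparison tables carry multiplicative lognormal noise, mimicking
paired quantitation of the same samples by a reference and a test method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .curves import AMPLIFICATION, MELT, FluorescenceCurve
from .errors import ConfigError, DomainError
from .quant import relative_error, rsd

__all__ = [
    "CurveModel",
    "CalibrationTruth",
    "WellSpec",
    "PlateSpec",
    "PlateRun",
    "generate_curve",
    "generate_plate",
    "generate_melt_curve",
    "generate_method_comparison",
]

TEMPLATE_KINDS = ("standard", "biotin", "toehold_biotin")


@dataclass(frozen=True)
class CurveModel:
    """Phenomenological sigmoid for one amplification trace.

    RFU(t) = baseline + drift*t + amplitude / (1 + exp(-k*(t - poi_true)))
             + Gaussian(0, noise_sd)

    Defaults emulate a plate-reader channel with a 100-RFU background,
    1000-RFU signal swing, a 2-3 minute rise (k = 1.5 /min) and noise at
    2% of the amplitude.
    """

    baseline: float = 100.0
    amplitude: float = 1000.0
    steepness: float = 1.5
    poi_true: float = 15.0
    noise_sd: float = 20.0
    drift: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise DomainError("amplitude must be non-negative")
        if self.steepness <= 0:
            raise DomainError("steepness must be positive")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be non-negative")


@dataclass(frozen=True)
class CalibrationTruth:
    """Ground-truth log-linear calibration POI = a - b * lg(copies).

    Note the sign convention: ``slope_b`` is the positive coefficient of the
    decreasing relation (the OLS fit of the same line has slope ``-b``).
    """

    intercept_a: float = 28.3
    slope_b: float = 2.09
    valid_range: tuple[float, float] = (0.602, 6.02e11)

    def __post_init__(self) -> None:
        if self.slope_b == 0:
            raise DomainError("slope_b must be non-zero")
        lo, hi = self.valid_range
        if not lo < hi:
            raise DomainError("valid_range must satisfy min < max")

    def poi_of(self, copies: float) -> float:
        return self.intercept_a - self.slope_b * math.log10(copies)


@dataclass(frozen=True)
class WellSpec:
    well: str
    species: str
    copies: float
    template_kind: str = "biotin"
    replicate: int = 1


@dataclass(frozen=True)
class PlateSpec:
    """Layout and acquisition settings of a simulated plate run."""

    wells: tuple
    read_interval: float = 1.0  # minutes between reads
    duration: float = 60.0  # minutes
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "wells", tuple(self.wells))
        ids = [w.well for w in self.wells]
        if len(set(ids)) != len(ids):
            raise ConfigError("well ids must be unique")
        for w in self.wells:
            if w.copies < 0:
                raise ConfigError(f"well {w.well}: copies must be non-negative")
            if w.template_kind not in TEMPLATE_KINDS:
                raise ConfigError(f"well {w.well}: unknown template kind '{w.template_kind}'")

    def t_grid(self) -> np.ndarray:
        n = int(math.floor(self.duration / self.read_interval)) + 1
        return np.arange(n) * self.read_interval


@dataclass(frozen=True)
class PlateRun:
    """Simulated (or ingested) plate: curves plus a ground-truth sidecar."""

    curves: tuple
    truth: pd.DataFrame

    def curve(self, well: str) -> FluorescenceCurve:
        for c in self.curves:
            if c.well == well:
                return c
        raise KeyError(well)


def generate_curve(model: CurveModel, t_grid, seed: int = 0) -> FluorescenceCurve:
    """One sigmoidal amplification trace on ``t_grid`` (minutes)."""
    t = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise DomainError("t_grid must be strictly increasing")
    rng = np.random.default_rng(seed)
    clean = (
        model.baseline
        + model.drift * t
        + model.amplitude / (1.0 + np.exp(-model.steepness * (t - model.poi_true)))
    )
    noise = rng.normal(0.0, model.noise_sd, size=t.shape) if model.noise_sd > 0 else 0.0
    return FluorescenceCurve(well="sim", times=t, rfu=clean + noise, kind=AMPLIFICATION)


def generate_plate(
    spec: PlateSpec,
    truth: CalibrationTruth,
    curve_defaults: CurveModel | None = None,
    cross_reactivity: dict[str, float] | None = None,
    amplification_floor: float = 0.1,
) -> PlateRun:
    """Simulate a whole plate with known per-well truth.

    Each well's effective input is ``copies * cross_reactivity[species]``
    (the target species carries fraction 1.0).  Its true POI follows the
    calibration line, clipped to the run duration.  Wells whose effective
    input falls below ``amplification_floor`` copies stay flat; between the
    floor and one molecule, Poisson presence sampling decides whether the
    single-molecule well fires at all.
    """
    if curve_defaults is None:
        curve_defaults = CurveModel()
    if cross_reactivity is None:
        cross_reactivity = {w.species: 1.0 for w in spec.wells}
    for w in spec.wells:
        if w.species not in cross_reactivity:
            raise ConfigError(f"species '{w.species}' missing from cross_reactivity map")

    t = spec.t_grid()
    seeds = np.random.SeedSequence(spec.seed).generate_state(2 * len(spec.wells))
    curves: list[FluorescenceCurve] = []
    rows: list[dict] = []
    for i, w in enumerate(spec.wells):
        curve_seed = int(seeds[2 * i])
        presence_seed = int(seeds[2 * i + 1])
        effective = w.copies * cross_reactivity[w.species]
        amplifying = effective >= amplification_floor
        if amplifying and effective < 1.0:
            # sub-single-molecule regime: the well fires only if at least
            # one molecule is actually present (Poisson occupancy)
            p_present = 1.0 - math.exp(-effective)
            amplifying = np.random.default_rng(presence_seed).random() < p_present
        if amplifying:
            poi_true = float(np.clip(truth.poi_of(effective), 0.0, spec.duration))
            model = replace(curve_defaults, poi_true=poi_true)
        else:
            poi_true = float("nan")
            model = replace(curve_defaults, amplitude=0.0)
        curve = replace(generate_curve(model, t, seed=curve_seed), well=w.well)
        curves.append(curve)
        rows.append(
            {
                "well": w.well,
                "species": w.species,
                "copies": w.copies,
                "template_kind": w.template_kind,
                "replicate": w.replicate,
                "effective_copies": effective,
                "poi_true": poi_true,
                "amplifying": amplifying,
                "seed": spec.seed,
            }
        )
    return PlateRun(curves=tuple(curves), truth=pd.DataFrame(rows))


def generate_melt_curve(
    tms,
    widths,
    amplitudes,
    T_grid,
    seed: int = 0,
    baseline: float = 100.0,
    noise_sd: float = 0.0,
) -> FluorescenceCurve:
    """Melt trace as a sum of two-state transitions.

    Each transition contributes amplitude_i / (1 + exp((T - Tm_i)/width_i)):
    fluorescence falls as the duplex melts, so -dRFU/dT peaks near each Tm.
    ``widths`` and ``amplitudes`` may be scalars (broadcast) or sequences
    matching ``tms``.
    """
    T = np.asarray(T_grid, dtype=float)
    if np.any(np.diff(T) <= 0):
        raise DomainError("T_grid must be strictly increasing")
    tms = np.atleast_1d(np.asarray(tms, dtype=float))
    widths = np.broadcast_to(np.asarray(widths, dtype=float), tms.shape)
    amplitudes = np.broadcast_to(np.asarray(amplitudes, dtype=float), tms.shape)
    if np.any(widths <= 0):
        raise DomainError("transition widths must be positive")
    rng = np.random.default_rng(seed)
    rfu = np.full_like(T, baseline)
    for tm, w, a in zip(tms, widths, amplitudes):
        rfu = rfu + a / (1.0 + np.exp((T - tm) / w))
    if noise_sd > 0:
        rfu = rfu + rng.normal(0.0, noise_sd, size=T.shape)
    return FluorescenceCurve(well="melt", times=T, rfu=rfu, kind=MELT)


def generate_method_comparison(
    true_levels,
    cv_ref: float,
    cv_test: float,
    n_reps: int = 3,
    seed: int = 0,
    sample_names=None,
) -> pd.DataFrame:
    """Paired reference-vs-test quantitation table with lognormal noise.

    ``cv_ref`` / ``cv_test`` are coefficients of variation in percent.  Each
    sample is measured ``n_reps`` times by both methods; replicates are the
    true level times mean-one lognormal multiplicative noise.  The output
    mirrors an inter-method accuracy table: per-sample means, RSDs and the
    relative error of the test mean against the reference mean.
    """
    if cv_ref < 0 or cv_test < 0:
        raise DomainError("coefficients of variation must be non-negative")
    if n_reps < 2:
        raise DomainError("need at least 2 replicates per sample")
    levels = np.asarray(true_levels, dtype=float)
    if sample_names is None:
        sample_names = [f"sample {i + 1}" for i in range(len(levels))]
    rng = np.random.default_rng(seed)

    def draw(level: float, cv_percent: float) -> np.ndarray:
        if cv_percent == 0:
            return np.full(n_reps, level)
        sigma = math.sqrt(math.log(1.0 + (cv_percent / 100.0) ** 2))
        return level * rng.lognormal(-sigma * sigma / 2.0, sigma, size=n_reps)

    rows = []
    for name, level in zip(sample_names, levels):
        ref = draw(level, cv_ref)
        test = draw(level, cv_test)
        ref_mean, test_mean = float(np.mean(ref)), float(np.mean(test))
        rows.append(
            {
                "sample": name,
                "true_level": level,
                "ref_mean": ref_mean,
                "ref_rsd_pct": rsd(ref) if np.ptp(ref) > 0 or ref_mean != 0 else 0.0,
                "test_mean": test_mean,
                "test_rsd_pct": rsd(test) if np.ptp(test) > 0 or test_mean != 0 else 0.0,
                "re_pct": relative_error(test_mean, ref_mean),
            }
        )
    return pd.DataFrame(rows)
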