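"""Calibration and quantitation for POI-based amplification assays.

A calibration line relates the point of inflection (POI, minutes) of a
real-time amplification curve to the decadic log of input copy number,
POI = a + b * lg(copies) with b < 0 for a well-behaved assay (earlier
inflection at higher input).  Unknowns are quantified by inverse prediction
on that line.  Accuracy versus a reference method is summarised by the
relative error RE and the relative standard deviation RSD across replicates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError, IngestError

__all__ = [
    "AVOGADRO",
    "CalibrationFit",
    "PiecewiseFit",
    "fit_calibration",
    "fit_piecewise",
    "invert_poi",
    "predict_poi",
    "copies_from_amount",
    "amount_from_copies",
    "estimate_phi_from_quench",
    "relative_error",
    "rsd",
    "lod_lowest_point",
    "lod_three_sigma",
]

#: Avogadro constant to 4 significant figures; matches printed copy-number
#: conversions of the form 10 fmol -> 6.02e9 copies at their precision.
AVOGADRO = 6.022e23


@dataclass(frozen=True)
class CalibrationFit:
    """Ordinary least-squares line POI = intercept + slope * lg(copies).

    ``r`` is the Pearson correlation of POI with lg(copies); it is NaN and
    ``degenerate`` is True when all POIs coincide (slope 0, r undefined).
    ``copies_range`` is the (min, max) input range the fit covers.
    """

    intercept: float
    slope: float
    r: float
    copies_range: tuple[float, float]
    n_points: int
    degenerate: bool = False


@dataclass(frozen=True)
class PiecewiseFit:
    """Two abutting calibration segments split at ``breakpoint`` (lg copies)."""

    lower: CalibrationFit
    upper: CalibrationFit
    breakpoint: float
    degenerate: bool = False


def _as_points(points) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise IngestError("points must be (copies, poi) pairs")
    copies, poi = arr[:, 0], arr[:, 1]
    if np.any(copies <= 0):
        raise IngestError("all copy numbers must be positive")
    return copies, poi


def fit_calibration(points) -> CalibrationFit:
    """Fit POI against lg(copies) by ordinary least squares.

    ``points`` is an iterable of (copies, poi) pairs; at least 3 are
    required.  The sign convention is the raw OLS slope: a calibration
    reported in the field as POI = 28.3 - 2.09 lg(copies) comes back as
    intercept 28.3, slope -2.09.
    """
    copies, poi = _as_points(points)
    if len(copies) < 3:
        raise IngestError("calibration needs at least 3 points")
    lg = np.log10(copies)
    rng = (float(np.min(copies)), float(np.max(copies)))
    if np.ptp(poi) == 0:
        return CalibrationFit(
            intercept=float(poi[0]), slope=0.0, r=float("nan"),
            copies_range=rng, n_points=len(copies), degenerate=True,
        )
    res = stats.linregress(lg, poi)
    return CalibrationFit(
        intercept=float(res.intercept), slope=float(res.slope),
        r=float(res.rvalue), copies_range=rng, n_points=len(copies),
    )


def _segment_rss(fit: CalibrationFit, lg: np.ndarray, poi: np.ndarray) -> float:
    resid = poi - (fit.intercept + fit.slope * lg)
    return float(np.dot(resid, resid))


def fit_piecewise(points, min_segment: int = 3, slope_tol: float = 1e-6) -> PiecewiseFit:
    """Two-segment linear calibration with a data-driven breakpoint.

    Candidate breakpoints are every interior abscissa plus the midpoints
    between consecutive distinct abscissas (in lg space); the split
    minimising the total residual sum of squares wins, with each segment
    holding at least ``min_segment`` points.  Requires >= 6 points spanning
    at least 4 decades.  When the two recovered slopes agree to
    ``slope_tol`` the fit is flagged degenerate (a single line suffices).
    """
    copies, poi = _as_points(points)
    if len(copies) < 2 * min_segment:
        raise IngestError(f"piecewise calibration needs at least {2 * min_segment} points")
    lg = np.log10(copies)
    if np.ptp(lg) < 4.0:
        raise IngestError("piecewise calibration needs a span of at least 4 decades")

    order = np.argsort(lg)
    lg, poi, copies = lg[order], poi[order], copies[order]
    uniq = np.unique(lg)
    candidates = np.concatenate([uniq[1:-1], (uniq[:-1] + uniq[1:]) / 2.0])

    best: tuple[float, float, CalibrationFit, CalibrationFit] | None = None
    for bp in np.sort(candidates):
        left = lg <= bp
        right = ~left
        if left.sum() < min_segment or right.sum() < min_segment:
            continue
        lo = fit_calibration(np.column_stack([copies[left], poi[left]]))
        hi = fit_calibration(np.column_stack([copies[right], poi[right]]))
        rss = _segment_rss(lo, lg[left], poi[left]) + _segment_rss(hi, lg[right], poi[right])
        if best is None or rss < best[0] - 1e-12:
            best = (rss, float(bp), lo, hi)
    if best is None:
        raise IngestError("no admissible breakpoint: segments too small")
    _, bp, lo, hi = best
    degenerate = abs(lo.slope - hi.slope) <= slope_tol
    return PiecewiseFit(lower=lo, upper=hi, breakpoint=bp, degenerate=degenerate)


def predict_poi(fit: CalibrationFit, copies: float) -> float:
    """Forward prediction POI(copies) on the calibration line."""
    if copies <= 0:
        raise DomainError("copies must be positive")
    return fit.intercept + fit.slope * math.log10(copies)


def invert_poi(fit: CalibrationFit, poi: float) -> float:
    """Inverse prediction: copy number from an observed POI.

    copies = 10 ** ((poi - intercept) / slope).  Emits a warning when the
    result falls outside the copy range the calibration was fitted on.
    """
    if fit.slope == 0:
        raise DomainError("cannot invert a calibration with zero slope")
    copies = 10.0 ** ((poi - fit.intercept) / fit.slope)
    lo, hi = fit.copies_range
    if not lo <= copies <= hi:
        warnings.warn(
            f"inverse prediction {copies:.3g} copies outside calibrated range [{lo:.3g}, {hi:.3g}]",
            stacklevel=2,
        )
    return copies


def copies_from_amount(amount_mol: float) -> float:
    """Convert an amount of substance (moles) to molecule copies."""
    if amount_mol < 0:
        raise DomainError("amount must be non-negative")
    return amount_mol * AVOGADRO


def amount_from_copies(copies: float) -> float:
    """Convert molecule copies to an amount of substance (moles)."""
    if copies < 0:
        raise DomainError("copies must be non-negative")
    return copies / AVOGADRO


def estimate_phi_from_quench(drop_3prime: float, drop_5prime: float) -> float:
    """Estimate phi from a two-fluorophore quench partition experiment.

    A template end-labelled with distinct fluorophores at its 3' and 5'
    termini, hybridised with quencher-tagged trigger, loses fluorescence at
    each end in proportion to how much trigger annealed there.  The fraction
    annealed at the productive 3' copy is then

        phi = drop_3' / (drop_3' + drop_5')

    with both drops given in percent of the initial intensity.
    """
    for name, d in (("drop_3prime", drop_3prime), ("drop_5prime", drop_5prime)):
        if not 0.0 <= d <= 100.0:
            raise DomainError(f"{name} must lie in [0, 100] percent")
    total = drop_3prime + drop_5prime
    if total == 0:
        raise DomainError("both quench drops are zero; phi is undefined")
    return drop_3prime / total


def relative_error(measured: float, reference: float) -> float:
    """Signed relative error of a measurement versus a reference value, in %."""
    if reference <= 0:
        raise DomainError("reference must be positive")
    return (measured - reference) / reference * 100.0


def rsd(values) -> float:
    """Relative standard deviation: sample SD (n-1) over the mean, in %."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise DomainError("RSD needs at least 2 values")
    mean = float(np.mean(arr))
    if mean == 0:
        raise DomainError("RSD undefined for zero mean")
    return float(np.std(arr, ddof=1)) / mean * 100.0


def lod_lowest_point(fit: CalibrationFit) -> float:
    """Limit of detection as the lowest calibrated input (copies)."""
    return fit.copies_range[0]


def lod_three_sigma(fit: CalibrationFit, ntc_pois) -> float:
    """Limit of detection by the 3-SD convention (copies).

    The detection threshold is the mean no-template-control POI minus three
    of its standard deviations (earlier POI = more signal); the LOD is the
    copy number whose predicted POI sits at that threshold.
    """
    ntc = np.asarray(ntc_pois, dtype=float)
    if ntc.size < 2:
        raise DomainError("need at least 2 no-template-control POIs")
    threshold = float(np.mean(ntc) - 3.0 * np.std(ntc, ddof=1))
    return invert_poi(fit, threshold)
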