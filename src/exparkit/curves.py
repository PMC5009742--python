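"""Curve-level measurands: amplification POI and melt-curve Tm.

The point of inflection (POI) of a real-time sigmoidal amplification trace —
the time of maximum slope — is the isothermal analogue of qPCR's Cq and the
single number a calibration curve is built on.  Melting temperatures are read
as peaks of the negative derivative -dF/dT of a dye-based melt trace.

Derivatives are estimated by Savitzky-Golay local least-squares smoothing
followed by finite differencing on the (possibly non-uniform) grid; peak
positions are refined by quadratic interpolation around the grid maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .errors import DomainError, IngestError

__all__ = [
    "FluorescenceCurve",
    "PoiResult",
    "extract_poi",
    "call_tm",
    "baseline_correct",
]

AMPLIFICATION = "amplification"
MELT = "melt"


@dataclass(frozen=True)
class FluorescenceCurve:
    """One well's time- or temperature-ordered fluorescence series.

    ``times`` carries minutes for amplification curves and degrees Celsius
    for melt curves; ``rfu`` is relative fluorescence units.
    """

    well: str
    times: np.ndarray
    rfu: np.ndarray
    kind: str = AMPLIFICATION

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        rfu = np.asarray(self.rfu, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "rfu", rfu)
        if self.kind not in (AMPLIFICATION, MELT):
            raise IngestError(f"unknown curve kind '{self.kind}'")
        if times.ndim != 1 or times.shape != rfu.shape:
            raise IngestError("times and rfu must be 1-D arrays of equal length")
        if len(times) < 10:
            raise IngestError(f"curve '{self.well}' has {len(times)} points; at least 10 required")
        if np.any(np.diff(times) <= 0):
            raise IngestError(f"curve '{self.well}': times must be strictly increasing")
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(rfu))):
            raise IngestError(f"curve '{self.well}' contains non-finite values")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class PoiResult:
    """POI call for one amplification curve.

    ``poi`` is NaN when the well did not amplify (``amplified`` False).
    """

    well: str
    poi: float
    max_slope: float
    amplified: bool
    qc_notes: tuple = field(default_factory=tuple)


def _smoothed_derivative(x: np.ndarray, y: np.ndarray, window: int, order: int) -> np.ndarray:
    """Savitzky-Golay smooth, then d/dx by central differences on the grid."""
    window = min(window, len(y) if len(y) % 2 == 1 else len(y) - 1)
    smooth = savgol_filter(y, window_length=window, polyorder=order)
    return np.gradient(smooth, x)


def _quadratic_refine(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Vertex of the parabola through points i-1, i, i+1; falls back to x[i]."""
    if i == 0 or i == len(x) - 1:
        return float(x[i])
    a, b, _ = np.polyfit(x[i - 1 : i + 2], y[i - 1 : i + 2], 2)
    if a >= 0:  # not concave at a maximum; keep the grid point
        return float(x[i])
    vertex = -b / (2.0 * a)
    return float(np.clip(vertex, x[i - 1], x[i + 1]))


def extract_poi(
    curve: FluorescenceCurve,
    smooth_window: int = 7,
    poly_order: int = 2,
    min_slope: float | None = None,
) -> PoiResult:
    """Locate the point of inflection: the time of maximum slope.

    The first derivative is estimated by local least-squares polynomial
    smoothing (``smooth_window`` points, degree ``poly_order``); the argmax
    is refined by quadratic interpolation around the grid maximum, with ties
    broken toward the earliest time.

    ``min_slope`` (RFU/min) separates amplifying from flat wells.  When left
    ``None`` it defaults to 5 times the baseline-noise level of the
    derivative, estimated robustly (scaled median absolute deviation around
    the median) so that a rise anywhere on the trace — even in the first few
    reads — does not inflate the threshold.  Because the estimate scales
    with the fluorescence, the call is invariant under positive affine
    transforms of the RFU axis.
    """
    if curve.kind != AMPLIFICATION:
        raise DomainError("extract_poi requires an amplification curve")
    if smooth_window % 2 == 0 or smooth_window < poly_order + 2:
        raise DomainError("smooth_window must be odd and at least poly_order + 2")

    t, y = curve.times, curve.rfu
    deriv = _smoothed_derivative(t, y, smooth_window, poly_order)

    if min_slope is None:
        mad = float(np.median(np.abs(deriv - np.median(deriv))))
        # the 1e-12 floor keeps round-off on perfectly flat traces below threshold
        min_slope = max(5.0 * 1.4826 * mad, 1e-12 * max(1.0, float(np.max(np.abs(y)))))

    i_max = int(np.argmax(deriv))  # argmax returns the earliest tie
    max_slope = float(deriv[i_max])
    notes: list[str] = []
    if max_slope <= min_slope:
        return PoiResult(curve.well, float("nan"), max_slope, False, ("below min_slope",))

    poi = _quadratic_refine(t, deriv, i_max)
    poi = float(np.clip(poi, t[0], t[-1]))
    if i_max in (0, len(t) - 1):
        notes.append("maximum slope at grid boundary")
    return PoiResult(curve.well, poi, max_slope, True, tuple(notes))


def _windowed_quadratic_refine(x: np.ndarray, y: np.ndarray, i: int, half: int) -> float:
    """Parabola vertex fitted over +/- ``half`` points around index ``i``."""
    lo, hi = max(0, i - half), min(len(x), i + half + 1)
    if hi - lo < 3:
        return float(x[i])
    a, b, _ = np.polyfit(x[lo:hi], y[lo:hi], 2)
    if a >= 0:
        return float(x[i])
    return float(np.clip(-b / (2.0 * a), x[lo], x[hi - 1]))


def call_tm(
    curve: FluorescenceCurve,
    smooth_window: int | None = None,
    min_prominence: float = 0.1,
) -> list[float]:
    """Call melting temperatures as peaks of -dF/dT.

    The derivative is estimated by Savitzky-Golay filtering; when
    ``smooth_window`` is None an odd window spanning about 5 degC is chosen
    from the grid step, which averages out instrument noise while keeping
    transitions a few degrees apart resolvable.  Peaks with prominence below
    ``min_prominence`` times the global maximum of -dF/dT are discarded.
    Returned Tm values are refined by a parabola fitted across roughly a
    third of the smoothing window, sorted by prominence (most prominent
    first); an empty list means no transition qualified.
    """
    if curve.kind != MELT:
        raise DomainError("call_tm requires a melt curve")
    T, y = curve.times, curve.rfu
    if np.ptp(y) == 0:
        return []
    steps = np.diff(T)
    step = float(np.median(steps))
    if smooth_window is None:
        smooth_window = int(round(5.0 / step))
        smooth_window = max(7, smooth_window + (smooth_window % 2 == 0))
    smooth_window = min(smooth_window, len(T) if len(T) % 2 == 1 else len(T) - 1)

    if np.allclose(steps, step, rtol=1e-6):
        neg_deriv = -savgol_filter(y, smooth_window, 2, deriv=1, delta=step)
    else:
        neg_deriv = -_smoothed_derivative(T, y, smooth_window, 2)
    top = float(np.max(neg_deriv))
    if top <= 0:
        return []
    peaks, props = find_peaks(neg_deriv, prominence=min_prominence * top)
    if len(peaks) == 0:
        return []
    half = max(1, smooth_window // 3)
    order = np.argsort(props["prominences"])[::-1]
    return [_windowed_quadratic_refine(T, neg_deriv, int(peaks[i]), half) for i in order]


def baseline_correct(curve: FluorescenceCurve, smooth_window: int = 7) -> FluorescenceCurve:
    """Subtract a line fitted to the initial flat (pre-amplification) region.

    The baseline region is the longest prefix over which the smoothed
    derivative stays below an amplification threshold (5 times the SD of the
    derivative over the first points, or 5% of the global maximum slope,
    whichever is larger).  If the curve never amplifies the fit spans the
    whole trace, so pure drift is removed entirely.  Idempotent on curves
    whose baseline is already flat at zero.
    """
    t, y = curve.times, curve.rfu
    deriv = _smoothed_derivative(t, y, smooth_window, 2)
    n0 = max(5, smooth_window)
    thr = max(5.0 * float(np.std(deriv[:n0])), 0.05 * float(np.max(deriv)), 0.0)
    above = np.nonzero(deriv > thr)[0]
    k = int(above[0]) if len(above) else len(t)
    k = max(k, 5)
    coef = np.polyfit(t[:k], y[:k], 1)
    corrected = y - np.polyval(coef, t)
    return replace(curve, rfu=corrected)
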