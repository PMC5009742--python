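"""Calibration fitting, inverse prediction, conversions, phi estimation, RE/RSD."""

import math

import numpy as np
import pytest

from exparkit import (
    DomainError,
    IngestError,
    amount_from_copies,
    copies_from_amount,
    estimate_phi_from_quench,
    fit_calibration,
    fit_piecewise,
    invert_poi,
    predict_poi,
    relative_error,
    rsd,
)
from exparkit.quant import lod_lowest_point, lod_three_sigma

# the four published-style calibration coefficient sets (intercept, OLS slope)
CALIBRATIONS = [
    (28.3, -2.09),   # biotin template, single wide linear range
    (35.1, -1.39),   # standard template, low segment
    (72.2, -5.51),   # standard template, high segment
    (-29.7, 1.99),   # toehold/biotin template (positive slope as printed)
]


def line_points(intercept, slope, lgs):
    return [(10.0**x, intercept + slope * x) for x in lgs]


class TestFitCalibration:
    @pytest.mark.parametrize("intercept,slope", CALIBRATIONS)
    def test_exact_recovery(self, intercept, slope):
        fit = fit_calibration(line_points(intercept, slope, range(0, 12)))
        assert fit.intercept == pytest.approx(intercept, rel=1e-10, abs=1e-10)
        assert fit.slope == pytest.approx(slope, rel=1e-10)
        assert abs(fit.r) == pytest.approx(1.0, abs=1e-12)
        assert not fit.degenerate

    def test_identical_pois_flagged_degenerate(self):
        fit = fit_calibration([(1e2, 12.0), (1e4, 12.0), (1e6, 12.0)])
        assert fit.degenerate
        assert fit.slope == 0.0
        assert math.isnan(fit.r)

    def test_too_few_points_rejected(self):
        with pytest.raises(IngestError):
            fit_calibration([(1e2, 10.0), (1e4, 8.0)])

    def test_non_positive_copies_rejected(self):
        with pytest.raises(IngestError):
            fit_calibration([(0.0, 10.0), (1e4, 8.0), (1e6, 6.0)])


class TestFitPiecewise:
    def test_two_segment_recovery_with_breakpoint(self):
        lgs_lo = np.arange(2.0, 8.79, 0.848)
        lgs_hi = np.arange(9.0, 11.79, 0.7)
        pts = line_points(35.1, -1.39, lgs_lo) + line_points(72.2, -5.51, lgs_hi)
        pw = fit_piecewise(pts)
        assert pw.lower.slope == pytest.approx(-1.39, rel=1e-9)
        assert pw.upper.slope == pytest.approx(-5.51, rel=1e-9)
        assert abs(pw.breakpoint - math.log10(6.02e8)) <= 0.5
        assert not pw.degenerate

    def test_single_line_flagged_degenerate(self):
        pw = fit_piecewise(line_points(28.3, -2.09, np.arange(0.0, 11.0)))
        assert pw.degenerate
        assert pw.lower.slope == pytest.approx(pw.upper.slope, abs=1e-9)

    def test_noisy_slope_recovery(self):
        rng_master = np.random.default_rng(2024)
        lgs_lo = np.arange(2.0, 8.8, 0.7)
        lgs_hi = np.arange(9.0, 11.8, 0.7)
        lo_err, hi_err = [], []
        for _ in range(50):
            pts = []
            for x in lgs_lo:
                pts.append((10.0**x, 35.1 - 1.39 * x + rng_master.normal(0, 0.3)))
            for x in lgs_hi:
                pts.append((10.0**x, 72.2 - 5.51 * x + rng_master.normal(0, 0.3)))
            pw = fit_piecewise(pts)
            lo_err.append(abs(pw.lower.slope - (-1.39)) / 1.39)
            hi_err.append(abs(pw.upper.slope - (-5.51)) / 5.51)
        assert np.mean(lo_err) < 0.10
        assert np.mean(hi_err) < 0.10

    def test_insufficient_span_rejected(self):
        with pytest.raises(IngestError):
            fit_piecewise(line_points(28.3, -2.09, np.linspace(2.0, 4.0, 8)))


class TestInversePrediction:
    def test_intercept_maps_to_single_copy(self):
        fit = fit_calibration(line_points(28.3, -2.09, range(0, 12)))
        assert invert_poi(fit, 28.3) == pytest.approx(1.0, rel=1e-9)

    def test_ten_decades_down_the_line(self):
        fit = fit_calibration(line_points(28.3, -2.09, range(0, 12)))
        assert invert_poi(fit, 7.4) == pytest.approx(1e10, rel=1e-9)

    @pytest.mark.parametrize("copies", [1.0, 4.7e3, 6.02e9, 9.9e10])
    def test_round_trip_identity(self, copies):
        fit = fit_calibration(line_points(28.3, -2.09, range(0, 12)))
        assert invert_poi(fit, predict_poi(fit, copies)) == pytest.approx(copies, rel=1e-9)

    def test_zero_slope_rejected(self):
        fit = fit_calibration([(1e2, 12.0), (1e4, 12.0), (1e6, 12.0)])
        with pytest.raises(DomainError):
            invert_poi(fit, 12.0)

    def test_out_of_range_warns(self):
        fit = fit_calibration(line_points(28.3, -2.09, range(2, 8)))
        with pytest.warns(UserWarning):
            invert_poi(fit, 28.3)  # 1 copy, below the fitted range


class TestCopyMoleConversion:
    def test_femtomole_scale(self):
        assert copies_from_amount(10e-15) == pytest.approx(6.02e9, rel=5e-3)

    def test_zeptomole_scale(self):
        assert copies_from_amount(1e-23) == pytest.approx(6.02, rel=5e-3)

    def test_zero(self):
        assert copies_from_amount(0.0) == 0.0

    def test_inverse_consistency(self):
        for copies in (1.0, 6.02e9, 3.3e20):
            assert amount_from_copies(copies_from_amount(amount_from_copies(copies))) == pytest.approx(
                amount_from_copies(copies), rel=1e-12
            )

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            copies_from_amount(-1e-15)
        with pytest.raises(DomainError):
            amount_from_copies(-5.0)


class TestPhiFromQuench:
    def test_symmetric_template_near_half(self):
        phi = estimate_phi_from_quench(51.0, 54.0)
        assert phi == pytest.approx(0.486, abs=0.001)

    def test_asymmetric_template(self):
        phi = estimate_phi_from_quench(93.1, 36.8)
        assert phi == pytest.approx(0.717, abs=0.001)

    @pytest.mark.parametrize("d3", [1.0, 50.0, 100.0])
    def test_no_5prime_loss_gives_unity(self, d3):
        assert estimate_phi_from_quench(d3, 0.0) == 1.0

    def test_both_zero_rejected(self):
        with pytest.raises(DomainError):
            estimate_phi_from_quench(0.0, 0.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            estimate_phi_from_quench(120.0, 10.0)


# (measured, reference, printed RE %) for the inter-method comparison table;
# the one ambiguous-sign row is excluded
TABLE_RE_CELLS = [
    (4.33, 4.05, 6.91),
    (4.17, 4.05, 2.96),
    (0.373, 0.418, -10.8),
    (0.361, 0.418, -13.6),
    (4.33, 3.98, 8.79),
    (4.09, 3.98, 2.76),
    (4.09, 4.30, -4.88),
    (4.87, 4.30, 13.3),
]


class TestAccuracyMetrics:
    @pytest.mark.parametrize("measured,reference,printed", TABLE_RE_CELLS)
    def test_relative_error_matches_printed_cells(self, measured, reference, printed):
        assert relative_error(measured, reference) == pytest.approx(printed, abs=0.05)

    def test_relative_error_zero_at_equality(self):
        assert relative_error(3.14, 3.14) == 0.0

    def test_relative_error_needs_positive_reference(self):
        with pytest.raises(DomainError):
            relative_error(1.0, 0.0)

    @pytest.mark.parametrize(
        "values,expected",
        [([5.0, 5.0, 5.0], 0.0), ([1.0, 2.0, 3.0], 50.0), ([9.0, 10.0, 11.0], 10.0)],
    )
    def test_rsd(self, values, expected):
        assert rsd(values) == pytest.approx(expected, rel=1e-12)

    def test_rsd_needs_two_values(self):
        with pytest.raises(DomainError):
            rsd([4.2])


class TestLod:
    def test_lowest_point_convention(self):
        fit = fit_calibration(line_points(28.3, -2.09, range(1, 12)))
        assert lod_lowest_point(fit) == pytest.approx(10.0)

    def test_three_sigma_convention_is_more_conservative(self):
        fit = fit_calibration(line_points(28.3, -2.09, range(0, 12)))
        # no-template controls inflect late with some spread
        lod = lod_three_sigma(fit, [27.0, 27.5, 26.8, 27.2])
        assert lod > 1.0  # stricter than the single-copy lowest point
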