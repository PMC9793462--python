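import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import nanodiss as nd
from nanodiss.crystallinity import (
    DEFAULT_CELL_DIAMETER,
    solve_cell_diameter,
)


class TestUnitCell:
    def test_cubic_cell(self):
        v = nd.unit_cell_volume(10e-10, 10e-10, 10e-10, *(math.pi / 2,) * 3)
        assert v == pytest.approx(1000e-30, rel=1e-12)

    def test_monoclinic_cell(self):
        # abc sin(beta) for alpha = gamma = 90 deg
        v = nd.unit_cell_volume(
            10e-10, 8e-10, 12e-10, math.pi / 2, math.radians(104.5), math.pi / 2
        )
        assert v == pytest.approx(929.4e-30, rel=1e-3)

    def test_degenerate_angles_rejected(self):
        with pytest.raises(nd.GeometryError):
            nd.unit_cell_volume(1e-9, 1e-9, 1e-9, 0.0, 0.0, 0.0)

    def test_unit_cell_object_effective_diameter(self):
        cell = nd.UnitCell(a=10e-10, b=10e-10, c=10e-10)
        assert cell.effective_diameter == pytest.approx(
            (6 * 1000e-30 / math.pi) ** (1 / 3), rel=1e-12
        )


class TestCoreShellAmorphicity:
    # printed single-size amorphicity table; D_cell solved from the
    # 20 nm / one-layer entry (28.5%)
    TABLE = [
        (20e-9, 1, 28.5), (20e-9, 2, 51.0), (20e-9, 3, 68.1),
        (50e-9, 1, 12.2), (50e-9, 2, 23.3), (100e-9, 1, 6.2),
        (100e-9, 3, 17.8), (200e-9, 2, 6.2), (1000e-9, 3, 1.9),
    ]

    def test_solved_cell_diameter(self):
        d = solve_cell_diameter(20e-9, 1, 28.5)
        assert d == pytest.approx(1.058e-9, abs=1e-12 * 1e3)
        assert d == pytest.approx(DEFAULT_CELL_DIAMETER, rel=1e-3)

    @pytest.mark.parametrize("x,z,expected", TABLE)
    def test_reproduces_printed_table(self, x, z, expected):
        d = solve_cell_diameter(20e-9, 1, 28.5)
        assert nd.core_shell_amorphicity(x, z, d) == pytest.approx(expected, abs=0.1)

    def test_no_shell_means_crystalline(self):
        assert nd.core_shell_amorphicity(100e-9, 0) == 0.0

    def test_fully_amorphous_below_shell_size(self):
        assert nd.core_shell_amorphicity(2e-9, 3) == 100.0

    @given(
        st.floats(min_value=5e-9, max_value=1e-5),
        st.integers(min_value=0, max_value=5),
    )
    def test_bounded_and_monotone(self, x, z):
        am = nd.core_shell_amorphicity(x, z)
        assert 0.0 <= am <= 100.0
        assert nd.core_shell_amorphicity(x, z + 1) >= am
        assert nd.core_shell_amorphicity(x * 2, z) <= am

    def test_negative_layer_count_rejected(self):
        with pytest.raises(nd.ValidationError):
            nd.core_shell_amorphicity(100e-9, -1)


class TestPSDAmorphicity:
    def test_monodisperse_limit(self):
        dpsd = nd.DiscretePSD(
            class_sizes=np.array([100e-9]), volume_fractions=np.array([1.0])
        )
        assert nd.psd_amorphicity(dpsd, 1) == pytest.approx(
            nd.core_shell_amorphicity(100e-9, 1), rel=1e-12
        )

    def test_single_layer_contribution_of_111nm_batch(self):
        # whole-PSD value printed as 6.3% for the 111 nm batch
        dpsd = nd.discretize(nd.LogNormalPSD(111e-9, 0.513), 999)
        assert nd.psd_amorphicity(dpsd, 1) == pytest.approx(6.3, abs=0.5)

    def test_lies_between_classwise_extremes(self):
        dpsd = nd.discretize(nd.LogNormalPSD(79e-9, 0.402), 99)
        per_class = nd.core_shell_amorphicity(dpsd.class_sizes, 2)
        value = nd.psd_amorphicity(dpsd, 2)
        assert per_class.min() <= value <= per_class.max()


class TestScherrer:
    def test_reference_peak(self):
        # 0.28 deg FWHM at 13.7 deg 2-theta, Cu K-alpha, K = 0.9
        tau = nd.scherrer_size(math.radians(0.28), 13.7)
        assert tau == pytest.approx(285.8e-10, rel=1e-3)

    def test_proportional_to_shape_factor(self):
        t1 = nd.scherrer_size(5e-3, 13.7, shape_factor=0.9)
        t2 = nd.scherrer_size(5e-3, 13.7, shape_factor=1.8)
        assert t2 == pytest.approx(2 * t1, rel=1e-12)

    def test_monotone_decreasing_in_width(self):
        widths = np.linspace(1e-3, 1e-1, 50)
        taus = [nd.scherrer_size(w, 13.7) for w in widths]
        assert all(a > b for a, b in zip(taus, taus[1:]))

    def test_zero_width_rejected(self):
        with pytest.raises(nd.DomainError):
            nd.scherrer_size(0.0, 13.7)


class TestXRPDCalibration:
    LINE = [(0.0, 100.0), (25.0, 350.0), (50.0, 600.0), (100.0, 1100.0)]

    def test_exact_line_inverts_exactly(self):
        cal = nd.fit_xrpd_calibration(self.LINE)
        assert cal.slope == pytest.approx(10.0, rel=1e-12)
        assert cal.residual_sd == pytest.approx(0.0, abs=1e-9)
        w, half = nd.predict_crystallinity(cal, 600.0)
        assert w == pytest.approx(50.0, rel=1e-12)
        assert half == pytest.approx(0.0, abs=1e-6)

    def test_amorphous_content_bookkeeping(self):
        assert nd.amorphous_content(92.0) == pytest.approx(8.0)
        batch_mean = np.mean([nd.amorphous_content(77.0), nd.amorphous_content(80.0)])
        assert batch_mean == pytest.approx(21.5)

    def test_prediction_interval_covers_calibration_points(self):
        rng = np.random.default_rng(7)
        pts = [(w, 10.0 * w + 100.0 + rng.normal(0, 5.0)) for w in (0, 20, 40, 60, 80, 100)]
        cal = nd.fit_xrpd_calibration(pts)
        for w_true, intensity in pts:
            w_hat, half = nd.predict_crystallinity(cal, intensity)
            assert abs(w_hat - w_true) <= max(half, 3 * cal.residual_sd / abs(cal.slope))

    def test_degenerate_points_rejected(self):
        with pytest.raises(nd.RegressionError):
            nd.fit_xrpd_calibration([(50.0, 100.0), (50.0, 200.0)])
        with pytest.raises(nd.RegressionError):
            nd.fit_xrpd_calibration([(50.0, 100.0)])


class TestDetectionLimit:
    def test_two_point_constructed_root(self):
        # line through (50 nm, 0) and (500 nm, 100): root at exactly 50 nm
        pts = [(50e-9, 0.0), (500e-9, 100.0)]
        assert nd.detection_limit_size(pts) == pytest.approx(50e-9, rel=1e-9)

    def test_reference_peak_table_by_ols(self):
        # four printed (size, intensity) pairs; frozen OLS oracle 25.79 nm
        pts = [(2443e-9, 2114.0), (93e-9, 618.0), (90e-9, 563.0), (79e-9, 516.0)]
        assert nd.detection_limit_size(pts) == pytest.approx(25.79e-9, rel=1e-3)

    def test_duplicate_point_changes_weighting_predictably(self):
        pts = [(50e-9, 0.0), (500e-9, 100.0)]
        with_dup = pts + [(500e-9, 100.0)]
        # both lines pass exactly through the same two loci -> same root
        assert nd.detection_limit_size(with_dup) == pytest.approx(
            nd.detection_limit_size(pts), rel=1e-9
        )

    def test_negative_slope_rejected(self):
        with pytest.raises(nd.RegressionError):
            nd.detection_limit_size([(50e-9, 100.0), (500e-9, 0.0)])
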