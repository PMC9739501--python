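"""Size-class binning, NBSS construction, fitting and box-tier comparison."""

import math

import numpy as np
import pytest

from fishspectra.errors import DegenerateInputError, EmptyCommunityError
from fishspectra.size_spectrum import (
    CurvatureDifference,
    FitModel,
    SizeSpectrum,
    assign_size_classes,
    build_nbss,
    compare_curvatures,
    fit_spectrum,
)
from fishspectra.synthetic_data import generate_spectrum_points


class TestAssignSizeClasses:
    def test_hand_evaluated_indices(self):
        scheme, classes = assign_size_classes([1.0, 1.9, 2.0, 7.9], V_override=1.0)
        assert scheme.V == 1.0
        assert list(classes) == [1, 1, 2, 3]

    def test_weight_at_lower_boundary_is_class_1(self):
        _, classes = assign_size_classes([3.7])
        assert list(classes) == [1]

    def test_class_widths_double(self):
        scheme, _ = assign_size_classes([0.8, 100.0])
        widths = [scheme.width(k) for k in range(1, 8)]
        assert np.allclose(np.diff(np.log2(widths)), 1.0)

    def test_override_above_minimum_rejected(self):
        with pytest.raises(ValueError):
            assign_size_classes([1.0, 2.0], V_override=1.5)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            assign_size_classes([1.0, -2.0])


class TestBuildNbss:
    def test_single_gram_fish(self):
        spectrum = build_nbss([1.0], area=1.0)
        assert spectrum.x == pytest.approx([1.0])
        assert spectrum.y == pytest.approx([0.0])

    def test_doubling_area_shifts_y_down_by_one(self):
        weights = [1.0, 1.5, 3.0, 9.0, 20.0]
        s1 = build_nbss(weights, area=1.0)
        s2 = build_nbss(weights, area=2.0)
        assert s2.x == pytest.approx(s1.x)
        assert s2.y == pytest.approx(s1.y - 1.0)

    def test_equal_biomass_per_octave_has_slope_minus_one(self):
        # 1024 g in each of 10 doubling classes starting at V = 1 g
        weights = []
        for k in range(1, 11):
            w = 2.0 ** (k - 1)
            weights.extend([w] * int(1024 / w))
        spectrum = build_nbss(weights, area=1.0)
        assert spectrum.n_classes == 10
        fit = fit_spectrum(spectrum, FitModel.LINEAR)
        assert fit.slope == pytest.approx(-1.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        quad = fit_spectrum(spectrum, FitModel.QUADRATIC)
        assert quad.curvature == pytest.approx(0.0, abs=1e-9)

    def test_empty_community_rejected(self):
        with pytest.raises(EmptyCommunityError):
            build_nbss([])

    def test_empty_interior_classes_are_omitted(self):
        spectrum = build_nbss([1.0, 1.0, 40.0])
        assert spectrum.n_classes == 2
        assert spectrum.x == pytest.approx([1.0, 6.0])


class TestFitSpectrum:
    def test_exact_parabola_recovered(self):
        spectrum = generate_spectrum_points(-0.2, 3.0, -5.0, n_points=8)
        fit = fit_spectrum(spectrum)
        assert fit.coefficients == pytest.approx((-0.2, 3.0, -5.0), abs=1e-9)
        assert fit.curvature == pytest.approx(-0.2)
        assert fit.r_squared == pytest.approx(1.0)

    def test_exact_line_recovered(self):
        spectrum = SizeSpectrum(
            x=np.arange(1.0, 7.0), y=-1.0 * np.arange(1.0, 7.0) + 9.0
        )
        fit = fit_spectrum(spectrum, FitModel.LINEAR)
        assert fit.slope == pytest.approx(-1.0)
        assert fit.intercept == pytest.approx(9.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_apex_of_dome_fit(self):
        # apex = -b/2a, e.g. a=-0.6241, b=8.93 -> 7.154
        spectrum = generate_spectrum_points(-0.6241, 8.93, -24.06, n_points=10)
        fit = fit_spectrum(spectrum)
        assert fit.apex_x == pytest.approx(8.93 / (2 * 0.6241), abs=1e-6)
        assert fit.apex_x == pytest.approx(7.154, abs=1e-3)

    def test_upward_parabola_has_no_apex(self):
        fit = fit_spectrum(generate_spectrum_points(0.3, -1.0, 2.0, n_points=6))
        assert fit.apex_x is None

    def test_too_few_points_rejected(self):
        spectrum = SizeSpectrum(x=np.array([1.0, 2.0]), y=np.array([3.0, 1.0]))
        with pytest.raises(DegenerateInputError):
            fit_spectrum(spectrum, FitModel.QUADRATIC)

    def test_constant_y_rejected(self):
        spectrum = SizeSpectrum(x=np.arange(4.0), y=np.ones(4))
        with pytest.raises(DegenerateInputError):
            fit_spectrum(spectrum, FitModel.LINEAR)

    def test_monte_carlo_curvature_recovery(self):
        """500 noisy spectra (sigma = 0.1): mean fitted curvature within
        2 SE of the generating coefficient."""
        a = -0.15
        fits = [
            fit_spectrum(
                generate_spectrum_points(a, 3.0, -5.0, n_points=10,
                                         noise_sd=0.1, seed=seed)
            ).curvature
            for seed in range(500)
        ]
        fits = np.asarray(fits)
        se = fits.std(ddof=1) / math.sqrt(len(fits))
        assert abs(fits.mean() - a) < 2 * se


class TestInvariances:
    weights = [0.8, 1.1, 2.4, 2.9, 7.3, 15.0, 31.0, 64.0, 130.0, 200.0]

    def _curv_slope(self, weights, area=1.0):
        s = build_nbss(weights, area=area)
        return (
            fit_spectrum(s, FitModel.QUADRATIC).curvature,
            fit_spectrum(s, FitModel.LINEAR).slope,
        )

    def test_area_changes_only_the_intercept(self):
        c1, s1 = self._curv_slope(self.weights, area=1.0)
        c2, s2 = self._curv_slope(self.weights, area=37.5)
        assert c1 == pytest.approx(c2, abs=1e-12)
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_replicating_every_fish_shifts_only_the_intercept(self):
        """Scaling each class's biomass by a constant (here by doubling
        every fish) leaves curvature and slope unchanged."""
        c1, s1 = self._curv_slope(self.weights)
        c2, s2 = self._curv_slope(self.weights * 2)
        assert c1 == pytest.approx(c2, abs=1e-12)
        assert s1 == pytest.approx(s2, abs=1e-12)


class TestCompareCurvatures:
    def test_disjoint_boxes_very_significant(self):
        verdict, *_ = compare_curvatures(
            [-0.05, -0.06, -0.07], [-0.20, -0.21, -0.22]
        )
        assert verdict is CurvatureDifference.VERY_SIGNIFICANT

    def test_identical_groups_not_significant(self):
        group = [-0.1, -0.2, -0.3, -0.4]
        verdict, box_a, box_b = compare_curvatures(group, group)
        assert verdict is CurvatureDifference.NOT_SIGNIFICANT
        assert box_a == box_b

    def test_overlapping_boxes_with_mutually_outside_medians(self):
        # boxes [0.5, 1.5] and [1.4, 1.7] overlap but each median is
        # outside the other group's box
        a = [0.0, 0.5, 0.6, 1.5, 2.0]
        b = [1.0, 1.4, 1.6, 1.7, 2.2]
        verdict, box_a, box_b = compare_curvatures(a, b)
        assert box_a.q3 >= box_b.q1  # overlap, so not very significant
        assert verdict is CurvatureDifference.SIGNIFICANT

    def test_one_median_inside_other_box_not_significant(self):
        a = [0.0, 0.5, 1.0, 1.5, 2.0]
        b = [0.9, 1.4, 1.5, 1.6, 2.0]  # median of a (1.0) inside b? no:
        # b's box is [1.4, 1.6]; a's box [0.5, 1.5] contains b's median 1.5
        verdict, *_ = compare_curvatures(a, b)
        assert verdict is CurvatureDifference.NOT_SIGNIFICANT

    def test_small_group_rejected(self):
        with pytest.raises(DegenerateInputError):
            compare_curvatures([-0.1, -0.2], [-0.3, -0.4, -0.5])
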