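"""Peak detection, FWHM areas, stoichiometry, occupancy, MW calibration."""

import numpy as np
import pytest

from dipms.peaks import (
    Peak,
    PeakGroup,
    apparent_mw,
    group_peaks,
    mw_calibration,
    occupancy,
    peak_metrics,
    pick_peaks,
    stoichiometry,
    trapezoid_between,
)


def gaussian(n, apex, sigma, amplitude=1.0):
    grid = np.arange(1, n + 1, dtype=float)
    return amplitude * np.exp(-0.5 * ((grid - apex) / sigma) ** 2)


class TestPickPeaks:
    def test_single_gaussian_one_peak_at_apex(self):
        profile = gaussian(40, apex=20, sigma=2)
        peaks = pick_peaks(profile)
        assert len(peaks) == 1
        assert peaks[0].apex_fraction == 20

    def test_width_one_spike_rejected(self):
        profile = np.zeros(20)
        profile[10] = 1.0
        assert pick_peaks(profile) == []

    def test_width_two_bump_rejected(self):
        profile = np.zeros(20)
        profile[10:12] = 1.0
        assert pick_peaks(profile) == []

    def test_low_bump_rejected(self):
        profile = np.zeros(30) + gaussian(30, apex=15, sigma=2, amplitude=0.15)
        assert pick_peaks(profile, min_height=0.2) == []

    def test_triangle_peak_accepted_with_halfmax_bounds(self):
        profile = np.array([0, 0.5, 1.0, 0.5, 0])
        peaks = pick_peaks(profile)
        assert len(peaks) == 1
        peak = peaks[0]
        assert peak.apex_fraction == 3
        assert peak.left == pytest.approx(2.0)
        assert peak.right == pytest.approx(4.0)

    def test_mirrored_profile_has_mirrored_apexes(self):
        profile = gaussian(50, apex=15, sigma=2) + gaussian(50, apex=35, sigma=3, amplitude=0.8)
        forward = [p.apex_fraction for p in pick_peaks(profile)]
        backward = [51 - p.apex_fraction for p in pick_peaks(profile[::-1])]
        assert sorted(forward) == sorted(backward)

    def test_two_separated_gaussians_found(self):
        profile = gaussian(60, 15, 2) + gaussian(60, 45, 2, amplitude=0.7)
        apexes = sorted(p.apex_fraction for p in pick_peaks(profile))
        assert apexes == [15, 45]


class TestPeakMetrics:
    def test_rectangular_pulse_area_over_the_pulse(self):
        profile = np.zeros(11)
        profile[3:8] = 1.0  # fractions 4..8 at height 1
        peak = Peak("P", apex_fraction=6, left=4.0, right=8.0, height=1.0)
        out = peak_metrics(profile, peak)
        assert out.fwhm_area == pytest.approx(4.0)

    def test_triangle_fwhm_area(self):
        profile = np.array([0, 0.5, 1.0, 0.5, 0])
        (peak,) = pick_peaks(profile)
        out = peak_metrics(profile, peak)
        # trapezoid of (0.5, 1, 0.5) over two unit intervals
        assert out.fwhm_area == pytest.approx(1.5)

    @pytest.mark.parametrize("sigma", [2.0, 3.0, 4.0])
    def test_gaussian_area_matches_fine_grid_oracle(self, sigma):
        n, apex = 60, 30
        profile = gaussian(n, apex, sigma)
        (peak,) = pick_peaks(profile)
        out = peak_metrics(profile, peak)
        fine = np.linspace(peak.left, peak.right, 20001)
        oracle = np.trapezoid(np.exp(-0.5 * ((fine - apex) / sigma) ** 2), fine)
        assert out.fwhm_area == pytest.approx(oracle, rel=0.05)

    def test_bounds_clipped_with_warning(self):
        profile = gaussian(20, 3, 2)
        peak = Peak("P", apex_fraction=3, left=-2.0, right=8.0, height=1.0)
        with pytest.warns(UserWarning, match="clip"):
            out = peak_metrics(profile, peak)
        assert out.left == 1.0


class TestStoichiometry:
    def make_group(self, areas):
        peaks = [
            Peak(f"P{i}", apex_fraction=10, left=8, right=12, height=1, fwhm_area=a)
            for i, a in enumerate(areas)
        ]
        return PeakGroup(peaks=peaks, apex_fraction=10)

    def test_equal_areas_all_unit(self):
        ratios = stoichiometry(self.make_group([5.0, 5.0, 5.0]))
        assert all(v == pytest.approx(1.0) for v in ratios.values())

    def test_two_to_one(self):
        ratios = stoichiometry(self.make_group([10.0, 5.0]))
        assert ratios["P0"] == pytest.approx(2.0)
        assert ratios["P1"] == pytest.approx(1.0)

    def test_scale_invariance(self):
        a = stoichiometry(self.make_group([8.0, 2.0, 4.0]))
        b = stoichiometry(self.make_group([80.0, 20.0, 40.0]))
        assert a == pytest.approx(b)

    def test_zero_area_member_excluded(self):
        with pytest.warns(UserWarning, match="zero-area"):
            ratios = stoichiometry(self.make_group([6.0, 0.0, 3.0]))
        assert set(ratios) == {"P0", "P2"}

    def test_too_few_members(self):
        with pytest.raises(ValueError):
            stoichiometry(self.make_group([5.0]))


class TestOccupancy:
    def test_full_span_is_one(self):
        profile = gaussian(40, 20, 3)
        assert occupancy(profile, (1, 40)) == pytest.approx(1.0)

    def test_symmetric_profile_half_per_side(self):
        profile = gaussian(41, 21, 3)
        assert occupancy(profile, (1, 21)) == pytest.approx(0.5, abs=1e-6)

    def test_disjoint_bounds_sum_to_one(self):
        rng = np.random.default_rng(31)
        profile = rng.random(30)
        cuts = [1, 7.3, 14.8, 22.1, 30]
        total = sum(
            occupancy(profile, (lo, hi)) for lo, hi in zip(cuts[:-1], cuts[1:])
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_zero_signal_errors(self):
        with pytest.raises(ValueError):
            occupancy(np.zeros(10), (1, 5))


class TestTrapezoidBetween:
    def test_partial_end_segments(self):
        profile = np.array([0.0, 1.0, 1.0, 0.0])
        # integral over [1.5, 3.5]: half rising segment (0.375... no: profile
        # linear 0->1 on [1,2]; value at 1.5 = 0.5; area [1.5,2] = 0.375;
        # [2,3] = 1.0; [3,3.5]: 1->0 at 3.5 value 0.5 -> 0.375
        assert trapezoid_between(profile, 1.5, 3.5) == pytest.approx(1.75)

    def test_empty_interval(self):
        assert trapezoid_between(np.ones(5), 3.0, 3.0) == 0.0


class TestMWCalibration:
    def test_two_standards_exact(self):
        curve = mw_calibration([(10, 1000.0), (50, 10.0)])
        assert apparent_mw(curve, 10) == pytest.approx(1000.0)
        assert apparent_mw(curve, 50) == pytest.approx(10.0)

    def test_noisy_loglinear_slope_recovered(self):
        rng = np.random.default_rng(32)
        slope, intercept = -0.05, 3.5
        fractions = np.arange(5, 90, 7)
        log_mw = slope * fractions + intercept + rng.normal(0, 0.02, len(fractions))
        curve = mw_calibration(list(zip(fractions, 10**log_mw)))
        assert curve.slope == pytest.approx(slope, rel=0.05)

    def test_leave_one_out_middle_standard(self):
        rng = np.random.default_rng(33)
        slope, intercept = -0.04, 3.2
        fractions = np.arange(5, 90, 7)
        log_mw = slope * fractions + intercept + rng.normal(0, 0.02, len(fractions))
        mids = len(fractions) // 2
        held_f, held_mw = fractions[mids], 10 ** log_mw[mids]
        rest = [
            (f, 10**lm) for i, (f, lm) in enumerate(zip(fractions, log_mw)) if i != mids
        ]
        curve = mw_calibration(rest)
        assert apparent_mw(curve, held_f) == pytest.approx(held_mw, rel=0.10)

    def test_duplicate_fractions_rejected(self):
        with pytest.raises(ValueError):
            mw_calibration([(10, 100.0), (10, 50.0)])

    def test_extrapolation_warns(self):
        curve = mw_calibration([(10, 1000.0), (50, 10.0)])
        with pytest.warns(UserWarning, match="extrapolat"):
            apparent_mw(curve, 70)


class TestGroupPeaks:
    def test_coapexing_peaks_grouped(self):
        peaks = [
            Peak("A", 10.0, 8, 12, 1, 5.0),
            Peak("B", 10.5, 8, 12, 1, 5.0),
            Peak("C", 30.0, 28, 32, 1, 5.0),
        ]
        groups = group_peaks(peaks, apex_tolerance=1.0)
        members = sorted(sorted(g.members) for g in groups)
        assert members == [["A", "B"], ["C"]]

    def test_same_protein_two_apexes_in_two_groups(self):
        peaks = [Peak("A", 10.0, 8, 12, 1, 5.0), Peak("A", 30.0, 28, 32, 1, 2.0)]
        groups = group_peaks(peaks)
        assert len(groups) == 2
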