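"""Profile-curve extraction and width metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.ndimage import gaussian_filter1d

import phantomiq as pq
from phantomiq.profiles import (
    LumenMetrics,
    ProfileCurve,
    extract_profile,
    make_cpr,
    measure_stent_lumen,
    measure_vessel_profile,
    percent_error,
    round_half_away,
    width_at_threshold,
)

PITCH = 0.02
POS = np.arange(-300, 301) * PITCH


def rect_profile(width, hi=424.0, lo=40.0):
    return ProfileCurve(POS, np.where(np.abs(POS) <= width / 2, hi, lo), PITCH)


def blurred_rect(width, sigma, hi=424.0, lo=40.0):
    vals = gaussian_filter1d(np.where(np.abs(POS) <= width / 2, hi, lo), sigma / PITCH)
    return ProfileCurve(POS, vals, PITCH)


class TestWidthAtThreshold:
    @pytest.mark.parametrize("fraction", [0.1, 0.5, 0.9, 0.99])
    def test_rectangle_width_recovered(self, fraction):
        p = rect_profile(3.2)
        # crossings of a discontinuous step interpolate within one sample
        assert width_at_threshold(p, 424.0, fraction) == pytest.approx(3.2, abs=2 * PITCH)

    def test_unreached_threshold_gives_zero(self):
        p = blurred_rect(0.4, 0.5)  # heavy blur: peak far below 90%
        assert width_at_threshold(p, 424.0, 0.90) == 0.0

    def test_blurred_widths_bracket_true_width(self):
        p = blurred_rect(3.2, 0.4)
        w10 = width_at_threshold(p, 424.0, 0.10)
        w90 = width_at_threshold(p, 424.0, 0.90)
        assert w90 <= 3.2 <= w10

    def test_monotone_in_blur(self):
        # dense 1-D convolution oracle: w10 grows, w90 shrinks with blur
        w10s, w90s = [], []
        for sigma in (0.1, 0.25, 0.4, 0.6):
            p = blurred_rect(3.2, sigma)
            w10s.append(width_at_threshold(p, 424.0, 0.10))
            w90s.append(width_at_threshold(p, 424.0, 0.90))
        assert all(a <= b + 1e-9 for a, b in zip(w10s, w10s[1:]))
        assert all(a >= b - 1e-9 for a, b in zip(w90s, w90s[1:]))

    def test_central_peak_preferred_over_bright_neighbour(self):
        # a brighter structure at the profile end must not shift the peak
        vals = np.where(np.abs(POS) <= 1.6, 400.0, 40.0)
        vals[POS > 5.0] = 424.0
        p = ProfileCurve(POS, vals, PITCH)
        assert width_at_threshold(p, 424.0, 0.5) == pytest.approx(3.2, abs=2 * PITCH)

    @settings(max_examples=30, deadline=None)
    @given(
        width=st.floats(0.8, 4.0),
        sigma=st.floats(0.05, 0.8),
        frac=st.floats(0.05, 0.95),
    )
    def test_w90_never_exceeds_w10(self, width, sigma, frac):
        p = blurred_rect(width, sigma)
        w_lo = width_at_threshold(p, 424.0, min(frac, 0.9))
        w_hi = width_at_threshold(p, 424.0, max(frac, 0.1))
        assert width_at_threshold(p, 424.0, 0.9) <= width_at_threshold(p, 424.0, 0.1)
        assert w_hi <= w_lo + 1e-9


class TestPercentError:
    @pytest.mark.parametrize(
        "measured, truth, expected",
        [
            (409.5, 424.0, -3.4),
            (191.9, 423.6, -54.7),
            (190.7, 423.6, -55.0),
            (236.0, 423.6, -44.3),
            (5.0, 5.0, 0.0),
        ],
    )
    def test_reference_readings(self, measured, truth, expected):
        err = percent_error(measured, truth)
        assert round_half_away(err, 1) == pytest.approx(expected)

    def test_zero_truth_is_undefined(self):
        assert percent_error(1.0, 0.0) is None

    def test_round_half_away_from_zero(self):
        assert round_half_away(-33.95, 1) == -34.0
        assert round_half_away(0.05, 1) == 0.1


class TestVesselMetrics:
    def test_measured_equals_model_gives_zero_errors(self):
        p = blurred_rect(3.2, 0.1)
        m = measure_vessel_profile(p, p)
        assert m.errors["peak_ct"] == pytest.approx(0.0, abs=1e-9)
        assert m.errors["w10"] == pytest.approx(0.0, abs=1e-9)
        assert m.w10 == m.model_w10

    def test_model_resampled_when_pitch_differs(self):
        p = blurred_rect(3.2, 0.2)
        coarse = ProfileCurve(POS[::4], p.values[::4], 4 * PITCH)
        m = measure_vessel_profile(p, coarse)
        assert m.model_peak == pytest.approx(p.central_peak(), rel=1e-3)


class TestStentLumen:
    def stent_profile(self, gap, strut_height=700.0):
        vals = np.full_like(POS, 424.0)
        vals[np.abs(POS) > gap / 2 + 0.4] = 40.0
        bump = strut_height * np.exp(-((np.abs(POS) - (gap / 2 + 0.2)) ** 2) / (2 * 0.1**2))
        return ProfileCurve(POS, vals + bump, PITCH)

    def test_synthetic_struts_give_gap_width(self):
        model = rect_profile(3.0)
        prof = self.stent_profile(2.0)
        m = measure_stent_lumen(prof, model)
        thr = 1.10 * 424.0
        # oracle: first positions around 0 where profile exceeds the threshold
        above = prof.values > thr
        i0 = np.argmax(above[300:]) + 300
        i1 = 300 - np.argmax(above[:301][::-1])
        expected = POS[i0 - 1] - POS[i1 + 1]
        assert m.w_lumen == pytest.approx(expected, abs=2 * PITCH)
        assert m.threshold == pytest.approx(thr)

    def test_bloomed_lumen_reads_zero(self):
        model = rect_profile(3.0)
        vals = np.full_like(POS, 500.0)  # everything above 110% threshold
        vals += 300 * np.exp(-((np.abs(POS) - 1.2) ** 2) / (2 * 0.1**2))
        m = measure_stent_lumen(ProfileCurve(POS, vals, PITCH), model)
        assert m.w_lumen == 0.0
        assert m.error == -100.0

    def test_w_truth_is_model_fwhm(self):
        model = rect_profile(3.0)
        m = measure_stent_lumen(self.stent_profile(2.0), model)
        assert m.w_truth == pytest.approx(3.0, abs=2 * PITCH)

    def test_profile_without_struts_rejected(self):
        model = rect_profile(3.0)
        with pytest.raises(ValueError, match="strut"):
            measure_stent_lumen(blurred_rect(3.0, 0.3), model)


class TestExtraction:
    def test_straight_vessel_profile_symmetric(self, mini_phantom):
        spec, grid, vol, truth = mini_phantom
        prof = extract_profile(vol, truth, "normal-3.2", 8.0)
        assert prof.positions[0] == pytest.approx(-prof.positions[-1])
        assert prof.central_peak() == pytest.approx(424.0, abs=1.0)
        mid = prof.values[np.abs(prof.positions) < 1.0]
        assert np.all(mid > 380)

    def test_profile_pitch_quarter_pixel(self, mini_phantom):
        spec, grid, vol, truth = mini_phantom
        prof = extract_profile(vol, truth, "normal-3.2", 8.0)
        assert prof.pitch == pytest.approx(grid.spacing[0] / 4.0)

    def test_arc_length_outside_vessel_rejected(self, mini_phantom):
        spec, grid, vol, truth = mini_phantom
        with pytest.raises(ValueError):
            extract_profile(vol, truth, "normal-3.2", 99.0)

    def test_cpr_arc_axis_matches_chord_sum(self, mini_phantom):
        spec, grid, vol, truth = mini_phantom
        geom = truth.vessels["curved-4.0"]
        img, s_axis, offs = make_cpr(vol, truth, "curved-4.0", s_pitch=0.5)
        chord = np.sum(np.linalg.norm(np.diff(geom.points, axis=0), axis=1))
        assert geom.length == pytest.approx(chord, rel=1e-9)
        assert s_axis[-1] <= chord + 1e-9
        assert chord - s_axis[-1] < 0.5  # one s-pitch
        # the straightened vessel stays centred: the offset-0 column is as
        # bright as any column (the lumen plateau)
        centre = img[:, np.argmin(np.abs(offs))].mean()
        assert centre >= img.mean(axis=0).max() - 1.0

    def test_cpr_of_straight_vessel_equals_planar_reformation(self, mini_phantom):
        spec, grid, vol, truth = mini_phantom
        img, s_axis, offs = make_cpr(vol, truth, "normal-3.2", s_pitch=1.0)
        # every row equals the orthogonal profile at that arc length
        for i in (0, len(s_axis) // 2, len(s_axis) - 1):
            prof = extract_profile(vol, truth, "normal-3.2", float(s_axis[i]),
                                   pitch=offs[1] - offs[0],
                                   min_extent_mm=offs[-1] * 2)
            common = min(len(prof.values), img.shape[1])
            a = img[i][:common]
            b = np.interp(offs[:common], prof.positions, prof.values)
            assert np.allclose(a, b, atol=1e-6)
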