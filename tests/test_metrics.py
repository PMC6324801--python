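"""Profile/PDD metric tests on analytic fixtures with closed-form values."""
import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from linacmc import metrics
from linacmc.scoring import ScanCurve
from linacmc.synthetic import (ERF_PENUMBRA_FACTOR, PRESETS,
                               SyntheticBeamModel, generate_reference)


def clean(preset: str) -> dict:
    model = dataclasses.replace(PRESETS[preset], noise_pct=0.0)
    return generate_reference(model, seed=1)


@pytest.fixture(scope="module")
def fff10():
    return clean("fff10")


@pytest.fixture(scope="module")
def flat10():
    return clean("flat10")


def triangle_profile(gradient=0.4, half_width=60.0, center=0.0,
                     step=1.0) -> ScanCurve:
    """Straight-line cone: 100 - g|x - c|, positions in mm."""
    x = np.arange(-half_width - 20.0, half_width + 20.0 + step / 2, step)
    v = np.maximum(100.0 - gradient * np.abs(x - center), 0.0)
    return ScanCurve(x, v, "lateral", "cax")


# ---------------------------------------------------------------------- #
# depth-dose metrics
# ---------------------------------------------------------------------- #
class TestD20D10:
    def test_constant_curve_gives_unity(self):
        z = np.arange(0.0, 301.0, 1.0)
        c = ScanCurve(z, np.full(z.size, 50.0), "depth", "dmax")
        assert metrics.d20_d10(c) == pytest.approx(1.0)

    def test_pure_exponential_closed_form(self):
        z = np.arange(0.0, 301.0, 1.0)
        c = ScanCurve(z, 100 * np.exp(-0.05 * z / 10.0), "depth", "dmax")
        assert metrics.d20_d10(c) == pytest.approx(np.exp(-0.5), abs=1e-6)

    def test_shallow_curve_raises(self):
        z = np.arange(0.0, 150.0, 5.0)
        c = ScanCurve(z, 100 * np.exp(-0.004 * z), "depth", "dmax")
        with pytest.raises(metrics.MetricError):
            metrics.d20_d10(c)


# ---------------------------------------------------------------------- #
# penumbra
# ---------------------------------------------------------------------- #
class TestPenumbra:
    def test_erf_edge_closed_form(self, flat10):
        # flat-top profile with erf edges of sigma 4 mm
        prof = flat10["profile_10cm"]
        expected = ERF_PENUMBRA_FACTOR * 4.0
        for side in ("left", "right"):
            # interpolation error well under a tenth of the 1 mm step
            assert metrics.penumbra(prof, side) == pytest.approx(
                expected, abs=0.1)

    def test_position_scaling_doubles_penumbra(self, flat10):
        prof = flat10["profile_10cm"]
        doubled = ScanCurve(prof.positions * 2, prof.values, "lateral", "cax")
        assert metrics.penumbra(doubled, "left") == pytest.approx(
            2 * metrics.penumbra(prof, "left"), rel=1e-6)

    def test_uncrossed_level_raises(self):
        x = np.arange(-50.0, 51.0, 1.0)
        c = ScanCurve(x, np.full(x.size, 60.0), "lateral", "cax")
        with pytest.raises(metrics.MetricError):
            metrics.penumbra(c, "left")


# ---------------------------------------------------------------------- #
# field size and inflection points
# ---------------------------------------------------------------------- #
class TestFieldSize:
    def test_synthetic_field_size_within_half_step(self, fff10):
        prof = metrics.renormalize_fff(fff10["profile_10cm"])
        # geometric scaling: 100 mm field projected to 10 cm depth
        assert metrics.dosimetric_field_size(prof) == pytest.approx(
            110.0, abs=0.6)

    def test_translation_equivariance(self, flat10):
        prof = flat10["profile_10cm"]
        shifted = ScanCurve(prof.positions + 7.0, prof.values, "lateral",
                            "cax")
        i_l, i_r = metrics.inflection_points(prof)
        j_l, j_r = metrics.inflection_points(shifted)
        assert j_l - i_l == pytest.approx(7.0, abs=0.05)
        assert j_r - i_r == pytest.approx(7.0, abs=0.05)

    def test_differs_from_half_maximum_width_when_asymmetric(self):
        # regression guard: inflection-based size is not the 50% width
        model = dataclasses.replace(PRESETS["fff10"], noise_pct=0.0,
                                    asymmetry_per_mm=4e-4)
        prof = generate_reference(model, 3)["profile_10cm"]
        rn = metrics.renormalize_fff(prof)
        fs = metrics.dosimetric_field_size(rn)
        from linacmc.metrics import _level_crossing
        x50l = _level_crossing(rn.positions, rn.values, 50.0, rising=True)
        x50r = _level_crossing(rn.positions, rn.values, 50.0, rising=False)
        assert fs != pytest.approx(x50r - x50l, abs=0.2)


# ---------------------------------------------------------------------- #
# FFF renormalisation
# ---------------------------------------------------------------------- #
class TestRenormalizeFFF:
    def test_idempotent(self, fff10):
        once = metrics.renormalize_fff(fff10["profile_10cm"])
        twice = metrics.renormalize_fff(once)
        np.testing.assert_allclose(once.values, twice.values)

    def test_shoulder_dose_reads_100_after_renormalisation(self, fff10):
        rn = metrics.renormalize_fff(fff10["profile_10cm"])
        xl, xr = rn.meta["shoulder_positions_mm"]
        shoulder = 0.5 * (rn.interp(xl) + rn.interp(xr))
        assert shoulder == pytest.approx(100.0, abs=1e-9)

    def test_scale_factor_is_100_over_shoulder_value(self, fff10):
        raw = fff10["profile_10cm"]
        rn = metrics.renormalize_fff(raw)
        xl, xr = rn.meta["shoulder_positions_mm"]
        v = 0.5 * (raw.interp(xl) + raw.interp(xr))
        assert rn.meta["shoulder_scale"] == pytest.approx(100.0 / v)

    def test_input_scale_invariance(self, fff10):
        raw = fff10["profile_10cm"]
        scaled = ScanCurve(raw.positions, raw.values * 3.7, "lateral", "cax")
        a = metrics.renormalize_fff(raw)
        b = metrics.renormalize_fff(scaled)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-9)

    def test_flat_profile_raises(self):
        x = np.arange(-60.0, 61.0, 1.0)
        c = ScanCurve(x, np.full(x.size, 100.0), "lateral", "cax")
        with pytest.raises(metrics.MetricError):
            metrics.renormalize_fff(c)


# ---------------------------------------------------------------------- #
# unflatness, slope, peak position, symmetry
# ---------------------------------------------------------------------- #
class TestUnflatness:
    def test_flat_profile_near_unity(self, flat10):
        prof = flat10["profile_10cm"].normalized("cax")
        assert metrics.unflatness(prof) == pytest.approx(1.0, abs=0.02)

    def test_fff_cone_matches_analytic_ratio(self, fff10):
        model = dataclasses.replace(PRESETS["fff10"], noise_pct=0.0)
        rn = metrics.renormalize_fff(fff10["profile_10cm"])
        fs = metrics.dosimetric_field_size(rn)
        x80 = 0.8 * fs / 2.0
        expected = (model.profile_analytic(0.0, 10.0)
                    / np.mean(model.profile_analytic([-x80, x80], 10.0)))
        assert metrics.unflatness(rn, fs) == pytest.approx(
            float(expected), rel=0.01)


class TestSlope:
    def test_linear_cone_recovers_gradient_exactly(self):
        prof = triangle_profile(gradient=0.4)
        assert metrics.slope(prof, field_size_mm=120.0) == pytest.approx(
            0.4, rel=1e-9)

    def test_flat_profile_gives_zero(self):
        x = np.arange(-80.0, 81.0, 1.0)
        c = ScanCurve(x, np.full(x.size, 100.0), "lateral", "cax")
        assert metrics.slope(c, field_size_mm=120.0) == 0.0


class TestPeakPosition:
    def test_centered_cone_gives_zero(self):
        prof = triangle_profile(center=0.0)
        assert metrics.peak_position(prof, field_size_mm=120.0) \
            == pytest.approx(0.0, abs=1e-9)

    def test_translated_cone_recovers_shift(self):
        prof = triangle_profile(center=1.0)
        assert metrics.peak_position(prof, field_size_mm=120.0) \
            == pytest.approx(1.0, abs=0.05)

    def test_degenerate_equal_slopes_raise(self):
        x = np.arange(-80.0, 81.0, 1.0)
        c = ScanCurve(x, 100.0 - 0.2 * x, "lateral", "cax")
        with pytest.raises(metrics.MetricError):
            metrics.peak_position(c, field_size_mm=120.0)


class TestSymmetry:
    def test_even_profile_gives_zero(self, fff10):
        assert metrics.symmetry(
            metrics.renormalize_fff(fff10["profile_10cm"])) \
            == pytest.approx(0.0, abs=1e-9)

    def test_side_scaled_fixture(self):
        x = np.arange(-80.0, 81.0, 1.0)
        v = np.where(np.abs(x) < 60, 100.0, 20.0).astype(float)
        v[x > 0] *= 1.02
        c = ScanCurve(x, v, "lateral", "cax")
        assert metrics.symmetry(c, field_size_mm=120.0) == pytest.approx(
            2.0, abs=0.05)


class TestCompareCurves:
    def test_curve_vs_itself_is_zero(self, fff10):
        maxd, diffs = metrics.compare_curves(fff10["pdd"], fff10["pdd"])
        assert maxd == 0.0 and np.all(diffs == 0.0)

    def test_constant_offset_is_recovered(self, fff10):
        pdd = fff10["pdd"]
        shifted = ScanCurve(pdd.positions, pdd.values + 1.0, "depth", "dmax")
        maxd, _ = metrics.compare_curves(shifted, pdd)
        assert maxd == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_ranges_raise(self):
        a = ScanCurve(np.arange(0.0, 10.0), np.ones(10), "depth", "dmax")
        b = ScanCurve(np.arange(50.0, 60.0), np.ones(10), "depth", "dmax")
        with pytest.raises(metrics.MetricError):
            metrics.compare_curves(a, b)


# ---------------------------------------------------------------------- #
# invariance properties
# ---------------------------------------------------------------------- #
@settings(max_examples=25, deadline=None, derandomize=True)
@given(scale=st.floats(0.1, 50.0), shift=st.floats(-20.0, 20.0))
def test_metrics_invariant_under_raw_rescaling_and_translation(scale, shift):
    """Uniform rescaling of raw dose leaves all metrics unchanged; position
    translation shifts the edge positions but not widths."""
    base = clean("fff10")["profile_10cm"]
    transformed = ScanCurve(base.positions + shift, base.values * scale,
                            "lateral", "raw")
    a = metrics.renormalize_fff(base)
    b = metrics.renormalize_fff(transformed)
    fs_a = metrics.dosimetric_field_size(a)
    fs_b = metrics.dosimetric_field_size(b)
    assert fs_b == pytest.approx(fs_a, abs=0.05)
    assert metrics.penumbra(b, "left") == pytest.approx(
        metrics.penumbra(a, "left"), abs=0.05)
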