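"""Waveform-feature formulas: closed-form examples, oracles, recovery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgposture.core import EcgSignal
from ecgposture.features import (
    FEATURE_NAMES,
    SELECTED_FEATURES,
    aggregate_epoch,
    angle_qsr,
    beat_feature_table,
    corrected_area,
    qtc,
    s_over_r,
    slope,
    stable_point,
    wave_height,
)
from ecgposture.synthetic import truth_fiducials

FS = 200.0


class TestStablePoint:
    def test_constant_tp(self):
        sig = EcgSignal(np.full(100, 0.3), FS)
        est = stable_point(sig, 10, 60)
        assert est.stable == pytest.approx(0.3)
        assert np.mean(est.tp_points) == pytest.approx(est.stable)

    def test_linear_ramp_gives_midpoint(self):
        n = 120
        ramp = np.linspace(0.0, 1.0, n)
        est = stable_point(EcgSignal(ramp, FS), 0, n)
        midpoint = ramp[n // 2]
        assert abs(est.stable - midpoint) <= (ramp[1] - ramp[0]) * 1.5

    def test_too_short_segment_rejected(self):
        sig = EcgSignal(np.zeros(50) + 0.1, FS)
        with pytest.raises(ValueError):
            stable_point(sig, 10, 15)


class TestScalarOps:
    def test_wave_height(self):
        assert wave_height(2.0, 0.2) == pytest.approx(1.8)
        assert wave_height(-0.4, 0.1, depth=True) == pytest.approx(0.5)
        assert wave_height(0.2, 0.2) == 0.0

    def test_slope(self):
        assert slope(100, 2.0, 400, 0.8) == pytest.approx(0.004)
        assert slope(0, 1.0, 10, 1.0) == 0.0
        assert slope(400, 0.8, 100, 2.0) == pytest.approx(0.004)  # symmetric
        assert math.isnan(slope(5, 1.0, 5, 2.0))

    def test_qtc(self):
        assert qtc(400.0, 200, FS) == pytest.approx(400.0)  # RR = 1 s
        assert qtc(400.0, 128, FS) == pytest.approx(500.0)  # RR = 0.64 s
        assert math.isnan(qtc(400.0, 0, FS))

    def test_s_over_r(self):
        assert s_over_r(0.1, 1.1, 0.1) == 0.0
        assert s_over_r(-0.9, 1.1, 0.1) == pytest.approx(1.0)
        assert s_over_r(-0.265, 1.1, 0.1) == pytest.approx(0.365)
        assert math.isnan(s_over_r(0.0, 0.1, 0.1))

    def test_angle_qsr_known_triangles(self):
        # equilateral (aspect 1 keeps coordinates as given)
        assert angle_qsr((0, 0), (1, math.sqrt(3)), (2, 0), aspect=1.0) \
            == pytest.approx(60.0)
        # 3-4-5 right triangle, right angle at S
        assert angle_qsr((0, 3), (4, 0), (0, 0), aspect=1.0) == pytest.approx(90.0)
        # QS=RS=1, QR=1.9 -> obtuse angle at S
        q, s, r = (0.0, 0.0), (0.95, -math.sqrt(1 - 0.95**2)), (1.9, 0.0)
        assert angle_qsr(q, r, s, aspect=1.0) == pytest.approx(
            math.degrees(math.acos((1 + 1 - 1.9**2) / 2.0)), abs=0.1)

    def test_angle_qsr_degenerate(self):
        assert math.isnan(angle_qsr((0, 0), (1, 1), (0, 0)))


class TestCorrectedArea:
    def test_baseline_endpoints(self):
        rel = np.array([0.0, 2.0, 4.0, 2.0, 0.0])
        assert corrected_area(rel, 0, 4, FS) == pytest.approx(40.0)

    def test_offset_endpoints_chord_subtracted(self):
        rel = np.array([-2.0, 1.0, 4.0, 1.0, -2.0])
        assert corrected_area(rel, 0, 4, FS) == pytest.approx(60.0)

    def test_straight_line_zero(self):
        rel = np.linspace(-1.0, 3.0, 9)
        assert corrected_area(rel, 0, 8, FS) == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_span_missing(self):
        assert math.isnan(corrected_area(np.zeros(10), 3, 4, FS))

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.integers(min_value=-9, max_value=9), min_size=3, max_size=30))
    def test_matches_bruteforce_chord_subtraction(self, values):
        rel = np.array(values, dtype=float)
        a, b = 0, len(rel) - 1
        # independent oracle: explicit loop over the chord definition
        total = 0.0
        for k in range(a, b + 1):
            chord = rel[a] + (rel[b] - rel[a]) * (k - a) / (b - a)
            total += rel[k] - chord
        assert corrected_area(rel, a, b, FS) == pytest.approx(
            abs(total) * 1000.0 / FS)


@pytest.fixture(scope="module")
def clean_table(clean_recording):
    beats = truth_fiducials(clean_recording)
    return beat_feature_table(clean_recording.signal, beats)


class TestExtractFeatures:
    def test_intervals_match_truth(self, clean_recording, clean_table):
        truth = clean_recording.truth
        ms = 1000.0 / clean_recording.signal.fs
        qt_true = (truth["T_end"] - truth["Q"]).to_numpy() * ms
        ok = np.isfinite(clean_table["QT"].to_numpy())
        assert ok.sum() > 100
        np.testing.assert_allclose(clean_table["QT"].to_numpy()[ok],
                                   qt_true[ok], atol=1e-9)
        rr_err = (clean_table["RR"] - truth["rr_ms"]).abs().dropna()
        assert rr_err.max() < 1e-9

    def test_heights_match_truth(self, clean_recording, clean_table):
        truth = clean_recording.truth
        for feat, col in [("P_peak", "p_height"), ("R_peak", "r_height"),
                          ("T_peak", "t_height"), ("S_peak", "s_depth")]:
            rel = ((clean_table[feat] - truth[col]) / truth[col]).abs().dropna()
            assert rel.max() < 0.01, feat

    def test_internal_identities(self, clean_table):
        tab = clean_table.dropna(subset=["QRS_area", "T_area", "R_peak", "T_peak"])
        np.testing.assert_allclose(
            tab["QRSa_minus_Ta"], tab["QRS_area"] - tab["T_area"], atol=1e-12)
        np.testing.assert_allclose(
            tab["Ta_over_QRSa"], tab["T_area"] / tab["QRS_area"], rtol=1e-12)
        np.testing.assert_allclose(
            tab["T_over_R"], tab["T_peak"] / tab["R_peak"], rtol=1e-12)
        np.testing.assert_allclose(
            tab["RpTp_y"], tab["R_peak"] - tab["T_peak"], atol=1e-12)
        # magnitude convention: RS = R height + S depth (not QR - depth diff)
        np.testing.assert_allclose(
            tab["RS"], tab["R_peak"] + tab["S_peak"], atol=1e-12)
        assert (tab["QR"] > tab["R_peak"]).all()  # Q depth adds, never subtracts

    def test_selected_features_are_subset(self):
        assert set(SELECTED_FEATURES) <= set(FEATURE_NAMES)
        assert len(FEATURE_NAMES) == 30


class TestAggregateEpoch:
    def test_identical_vectors_unchanged(self):
        v = {name: float(i) for i, name in enumerate(FEATURE_NAMES)}
        agg = aggregate_epoch([dict(v) for _ in range(12)], min_beats=10)
        assert agg == v

    def test_median_robust_to_outlier(self):
        vectors = [{"QT": 400.0} for _ in range(29)] + [{"QT": 4000.0}]
        agg = aggregate_epoch(vectors, min_beats=10)
        assert agg["QT"] == 400.0

    def test_min_beats_rule(self):
        vectors = [{"QT": 400.0} for _ in range(9)]
        assert math.isnan(aggregate_epoch(vectors, min_beats=10)["QT"])
        assert math.isnan(aggregate_epoch([], min_beats=10)["QT"])
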