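"""R detection and landmark delineation against generator ground truth."""

import numpy as np
import pytest

from ecgposture.core import FIDUCIAL_NAMES, BeatFiducials, EcgSignal
from ecgposture.delineate import (
    DelineationConfig,
    area_increment_boundary,
    delineate_all,
    detect_r_peaks,
    validate_beats,
)
from ecgposture.pipeline import PipelineConfig, preprocess_signal

FS = 200.0

PEAK_NAMES = ("P_peak", "Q", "R", "S", "T_peak")
BOUNDARY_NAMES = ("P_on", "P_end", "QRS_on", "J", "T_on", "T_end")


def match_errors(beats, truth, names):
    """Per-landmark absolute errors (samples) for truth-matched beats."""
    truth_r = truth["R"].to_numpy()
    errors = {n: [] for n in names}
    for b in beats:
        j = int(np.argmin(np.abs(truth_r - b.R)))
        for n in names:
            if b.get(n) is not None:
                errors[n].append(abs(b.get(n) - truth.iloc[j][n]))
    return {n: np.array(v) for n, v in errors.items()}


class TestDetectRPeaks:
    def test_clean_60bpm_count_and_timing(self, clean_recording):
        sig = clean_recording.signal
        truth_r = clean_recording.truth["R"].to_numpy()
        peaks = detect_r_peaks(sig)
        assert abs(peaks.size - truth_r.size) <= 1
        d = np.abs(peaks[:, None] - truth_r[None, :]).min(axis=1)
        assert np.all(d <= 2)  # within 10 ms at 200 Hz

    def test_all_zero_signal_empty(self):
        assert detect_r_peaks(EcgSignal(np.zeros(4000), FS)).size == 0

    def test_noisy_recall_precision(self, noisy_recording):
        cfg = PipelineConfig()
        clean, _ = preprocess_signal(noisy_recording.signal, cfg)
        truth_r = noisy_recording.truth["R"].to_numpy()
        peaks = detect_r_peaks(clean)
        d_pred = np.abs(peaks[:, None] - truth_r[None, :]).min(axis=1)
        d_true = np.abs(truth_r[:, None] - peaks[None, :]).min(axis=1)
        assert np.mean(d_pred <= 3) >= 0.99  # precision
        assert np.mean(d_true <= 3) >= 0.99  # recall

    def test_sorted_unique(self, noisy_recording):
        peaks = detect_r_peaks(noisy_recording.signal)
        assert np.all(np.diff(peaks) > 0)


class TestAreaIncrementBoundary:
    def bump_signal(self, half_width=8):
        x = np.zeros(400)
        i = np.arange(200 - half_width, 200 + half_width + 1)
        x[i] = np.cos(np.pi * (i - 200) / (2 * half_width)) ** 2
        return EcgSignal(x, FS)

    def test_symmetric_bump_symmetric_boundaries(self):
        sig = self.bump_signal()
        cfg = DelineationConfig(area_theta=0.05)
        left = area_increment_boundary(sig, 200, "left", 0.0, cfg)
        right = area_increment_boundary(sig, 200, "right", 0.0, cfg)
        assert abs((200 - left) - (right - 200)) <= 1

    def test_flat_after_peak_immediate(self):
        x = np.zeros(100)
        x[50] = 1.0
        cfg = DelineationConfig(area_theta=0.05, area_window=10)
        idx = area_increment_boundary(EcgSignal(x, FS), 50, "right", 0.0, cfg)
        assert idx == 51

    def test_bump_end_recovered(self):
        # 40 ms half-width bump: boundary within 20 ms of the true end
        half_width = 8  # samples = 40 ms
        sig = self.bump_signal(half_width)
        cfg = DelineationConfig(area_theta=0.05, area_window=10)
        right = area_increment_boundary(sig, 200, "right", 0.0, cfg)
        assert abs(right - (200 + half_width)) <= 4

    def test_peak_outside_signal_rejected(self):
        with pytest.raises(ValueError):
            area_increment_boundary(EcgSignal(np.zeros(100), FS), 500, "right")


class TestDelineateBeat:
    def test_clean_landmark_accuracy(self, clean_recording):
        sig = clean_recording.signal
        beats = delineate_all(sig)
        assert len(beats) == len(clean_recording.truth)
        errs = match_errors(beats, clean_recording.truth, FIDUCIAL_NAMES)
        for n in PEAK_NAMES:
            assert errs[n].size == len(beats)
            assert errs[n].max() <= 2, n  # peaks within 10 ms
        for n in BOUNDARY_NAMES:
            assert errs[n].max() <= 4, n  # boundaries within 20 ms

    def test_absent_p_wave_marked_missing(self):
        from ecgposture.synthetic import (
            SubjectProfile, make_position_schedule, synthesize_recording)
        profile = SubjectProfile(
            subject_id="X", seed=1,
            amp_factors={"P": 1e-6, "Q": 1, "R": 1, "S": 1, "T": 1},
        ).noiseless()
        rec = synthesize_recording(
            profile, make_position_schedule(2, positions={"supine": 1.0}, seed=0))
        beats = delineate_all(rec.signal)
        assert len(beats) > 10
        assert all(b.P_peak is None for b in beats)
        assert all(b.T_peak is not None for b in beats)

    def test_ordering_invariant_all_beats(self, noisy_recording):
        beats = delineate_all(noisy_recording.signal)
        assert all(b.ordering_ok() for b in beats)
        n = len(noisy_recording.signal)
        for b in beats:
            idx = [b.get(name) for name in FIDUCIAL_NAMES if b.get(name) is not None]
            assert min(idx) >= 0 and max(idx) < n

    def test_r_out_of_range_rejected(self, clean_recording):
        from ecgposture.delineate import delineate_beat
        with pytest.raises(ValueError):
            delineate_beat(clean_recording.signal, len(clean_recording.signal) + 5,
                           1000.0)


class TestValidateBeats:
    def test_clean_recording_mostly_valid(self, clean_recording):
        sig = clean_recording.signal
        beats = validate_beats(delineate_all(sig), sig)
        assert np.mean([b.valid for b in beats]) >= 0.95

    def test_short_rr_flagged(self, clean_recording):
        sig = clean_recording.signal
        beats = delineate_all(sig)[:3]
        # force a 300 ms RR between the first two beats
        beats[1] = BeatFiducials(R=beats[0].R + int(0.3 * FS))
        flagged = validate_beats(sorted(beats, key=lambda b: b.R), sig)
        assert "rr_range" in flagged[0].qc_flags

    def test_empty_list(self, clean_recording):
        assert validate_beats([], clean_recording.signal) == []

    def test_nothing_deleted(self, noisy_recording):
        sig = noisy_recording.signal
        beats = delineate_all(sig)
        assert len(validate_beats(beats, sig)) == len(beats)
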