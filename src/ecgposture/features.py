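"""The 30 waveform-morphology features and their beat-to-epoch aggregation.

All amplitudes are measured against the "stable point": the mean of five
smoothed samples taken at equal intervals inside the TP segment, the
electrically quiet interval that anchors the isoelectric level. Features
come in three orientation classes — time-limit (horizontal, ms),
amplitude (vertical, mV) and double-direction (areas in mV*ms, slopes in
mV/ms, the QRS-triangle angle in degrees).

Conventions
-----------
* Q and S are reported as depths (positive magnitudes) and S/R as the
  positive ratio |S - stable| / (R - stable): the ratio of S-wave depth
  to R-wave height.
* Wave areas are chord-corrected: the straight line joining the interval
  endpoints is subtracted before summing, which removes the offset left
  by unequal Q/S (or T onset/end) depths; the result is a magnitude.
* The QRS-triangle angle mixes a time axis (ms) and a voltage axis (mV);
  the single free geometric parameter is ``aspect``, the number of ms one
  mV is worth, 10 by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BeatFiducials, EcgSignal
from .preprocess import moving_average

__all__ = [
    "FEATURE_NAMES",
    "FEATURE_ORIENTATION",
    "SELECTED_FEATURES",
    "BaselineEstimate",
    "stable_point",
    "wave_height",
    "slope",
    "corrected_area",
    "qtc",
    "s_over_r",
    "angle_qsr",
    "extract_features",
    "aggregate_epoch",
    "beat_feature_table",
]

#: All 30 features in canonical order.
FEATURE_NAMES = (
    "QT", "RR", "PR_inter", "PR_segment", "ST_inter", "ST_segment",
    "RT_slope", "P_wide", "QS_wide", "T_wide", "TP_segment",
    "P_peak", "R_peak", "T_peak", "T_area", "RpTp_x", "RpTp_y", "Tp_Te",
    "QR", "RS", "QRS_area", "S_peak", "RS_slope", "S_over_R", "T_over_R",
    "Ta_over_QRSa", "QRSa_minus_Ta", "ST_slope", "QTc", "angle_QSR",
)

FEATURE_ORIENTATION = {
    "QT": "horizontal", "RR": "horizontal", "PR_inter": "horizontal",
    "PR_segment": "horizontal", "ST_inter": "horizontal",
    "ST_segment": "horizontal", "RT_slope": "double", "P_wide": "horizontal",
    "QS_wide": "horizontal", "T_wide": "horizontal", "TP_segment": "horizontal",
    "P_peak": "vertical", "R_peak": "vertical", "T_peak": "vertical",
    "T_area": "double", "RpTp_x": "horizontal", "RpTp_y": "vertical",
    "Tp_Te": "horizontal", "QR": "vertical", "RS": "vertical",
    "QRS_area": "double", "S_peak": "vertical", "RS_slope": "double",
    "S_over_R": "vertical", "T_over_R": "vertical", "Ta_over_QRSa": "double",
    "QRSa_minus_Ta": "double", "ST_slope": "double", "QTc": "horizontal",
    "angle_QSR": "double",
}

#: The 12-feature subset used for classification (adopted verbatim from the
#: significance analysis, not re-derived).
SELECTED_FEATURES = (
    "QT", "RR", "TP_segment", "angle_QSR", "S_over_R", "QR",
    "P_peak", "R_peak", "T_peak", "T_area", "QRS_area", "Ta_over_QRSa",
)

DEFAULT_ASPECT = 10.0  # ms per mV in the QRS-triangle plane


@dataclass(frozen=True)
class BaselineEstimate:
    """Isoelectric level of one beat: the stable point and its 5 TP picks."""

    stable: float
    tp_points: tuple[float, ...]


def stable_point(sig: EcgSignal, tp_start: int, tp_end: int,
                 smooth_width: int = 5) -> BaselineEstimate:
    """Estimate the isoelectric level from one TP segment [tp_start, tp_end).

    The segment is smoothed with a width-5 mean filter, five points are
    sampled at the interior fractions 1/6 .. 5/6 of the segment (avoiding
    the T-end and P-onset boundaries), and their mean is the stable point.
    """
    if tp_end - tp_start < 7:
        raise ValueError("TP segment too short for a stable-point estimate")
    seg = moving_average(sig.samples[tp_start:tp_end], smooth_width)
    n = seg.size
    picks = tuple(float(seg[int(round(i / 6.0 * (n - 1)))]) for i in range(1, 6))
    return BaselineEstimate(stable=float(np.mean(picks)), tp_points=picks)


def wave_height(peak_amp: float, stable: float, depth: bool = False) -> float:
    """Wave height above the stable point; ``depth=True`` (Q, S waves)
    returns the magnitude of the deflection instead."""
    if not (np.isfinite(peak_amp) and np.isfinite(stable)):
        return math.nan
    h = peak_amp - stable
    return abs(h) if depth else h


def slope(x1: float, y1: float, x2: float, y2: float) -> float:
    """|dy/dx| between two (ms, mV) points; NaN for a vertical segment."""
    if x1 == x2 or not all(np.isfinite(v) for v in (x1, y1, x2, y2)):
        return math.nan
    return abs((y1 - y2) / (x1 - x2))


def corrected_area(rel: np.ndarray, a: int, b: int, fs: float) -> float:
    """Chord-corrected wave area over samples a..b inclusive, in mV*ms.

    ``rel`` is the signal relative to the stable point. The straight line
    joining rel[a] and rel[b] is subtracted from every sample in the span
    and the residuals summed, scaled by the sample period in ms; the
    result is returned as a magnitude. With both endpoints on the
    baseline the chord vanishes and this is the plain area; with equal
    sub-baseline endpoints it reproduces the triangle-subtraction rule.
    """
    rel = np.asarray(rel, dtype=float)
    if not 0 <= a < b - 1 < rel.size - 1:
        return math.nan
    span = rel[a:b + 1]
    chord = np.linspace(span[0], span[-1], span.size)
    return abs(float(np.sum(span - chord))) * (1000.0 / fs)


def qtc(qt: float, rri: float, fs: float) -> float:
    """Bazett heart-rate-corrected QT: QT / sqrt(RR in seconds)."""
    if not (np.isfinite(qt) and np.isfinite(rri)) or rri <= 0:
        return math.nan
    return qt / math.sqrt(rri / fs)


def s_over_r(s_amp: float, r_amp: float, stable: float) -> float:
    """Ratio of S-wave depth to R-wave height: |S - stable| / (R - stable)."""
    if not all(np.isfinite(v) for v in (s_amp, r_amp, stable)):
        return math.nan
    if r_amp == stable:
        return math.nan
    return abs(s_amp - stable) / (r_amp - stable)


def angle_qsr(
    q: tuple[float, float],
    r: tuple[float, float],
    s: tuple[float, float],
    aspect: float = DEFAULT_ASPECT,
) -> float:
    """Interior angle at S of the Q-R-S triangle, in degrees.

    Points are (ms, mV); voltages are scaled by ``aspect`` ms/mV before
    the side lengths and the law of cosines are applied. Returns NaN for
    a degenerate (zero-length-side) triangle; the cosine is clamped so the
    result always lies in [0, 180].
    """
    pts = [(x, y * aspect) for x, y in (q, r, s)]
    if not all(np.isfinite(v) for p in pts for v in p):
        return math.nan
    (qx, qy), (rx, ry), (sx, sy) = pts
    qs = math.hypot(sx - qx, sy - qy)
    rs = math.hypot(sx - rx, sy - ry)
    qr = math.hypot(rx - qx, ry - qy)
    if qs == 0 or rs == 0:
        return math.nan
    cos_s = (qs * qs + rs * rs - qr * qr) / (2.0 * qs * rs)
    return math.degrees(math.acos(min(1.0, max(-1.0, cos_s))))


def _idx_ms(beat: BeatFiducials, name: str, fs: float) -> float:
    idx = beat.get(name)
    return math.nan if idx is None else idx * 1000.0 / fs


def extract_features(
    sig: EcgSignal,
    beat: BeatFiducials,
    next_beat: BeatFiducials | None,
    baseline: BaselineEstimate | None,
    aspect: float = DEFAULT_ASPECT,
) -> dict[str, float]:
    """Compute all 30 features for one delineated beat.

    ``next_beat`` supplies the RR interval and the TP-segment end; missing
    landmarks (or a missing baseline) propagate to NaN in every feature
    that needs them. An invalid beat yields all-NaN.
    """
    out = {name: math.nan for name in FEATURE_NAMES}
    if not beat.valid or baseline is None:
        return out
    x = sig.samples
    fs = sig.fs
    stable = baseline.stable

    def t(name: str) -> float:  # landmark time in ms
        return _idx_ms(beat, name, fs)

    def amp(name: str) -> float:  # raw landmark amplitude in mV
        idx = beat.get(name)
        return math.nan if idx is None else float(x[idx])

    p_h = wave_height(amp("P_peak"), stable)
    r_h = wave_height(amp("R"), stable)
    t_h = wave_height(amp("T_peak"), stable)
    q_d = wave_height(amp("Q"), stable, depth=True)
    s_d = wave_height(amp("S"), stable, depth=True)

    out["QT"] = t("T_end") - t("Q")
    if next_beat is not None:
        rr_samples = next_beat.R - beat.R
        out["RR"] = rr_samples * 1000.0 / fs
        out["QTc"] = qtc(out["QT"], rr_samples, fs)
        if next_beat.P_on is not None and beat.T_end is not None:
            out["TP_segment"] = (next_beat.P_on - beat.T_end) * 1000.0 / fs
    out["PR_inter"] = t("QRS_on") - t("P_on")
    out["PR_segment"] = t("QRS_on") - t("P_end")
    out["ST_inter"] = t("T_end") - t("J")
    out["ST_segment"] = t("T_on") - t("J")
    out["P_wide"] = t("P_end") - t("P_on")
    out["QS_wide"] = t("S") - t("Q")
    out["T_wide"] = t("T_end") - t("T_on")
    out["RpTp_x"] = t("T_peak") - t("R")
    out["Tp_Te"] = t("T_end") - t("T_peak")

    out["P_peak"] = p_h
    out["R_peak"] = r_h
    out["T_peak"] = t_h
    out["S_peak"] = s_d
    out["QR"] = r_h + q_d
    out["RS"] = r_h + s_d
    out["RpTp_y"] = r_h - t_h

    out["RT_slope"] = slope(t("R"), r_h, t("T_peak"), t_h)
    out["RS_slope"] = slope(t("R"), r_h, t("S"), -s_d if np.isfinite(s_d) else math.nan)
    if beat.J is not None and beat.T_on is not None and beat.J != beat.T_on:
        # signed: an ST trending downward gives a negative slope
        out["ST_slope"] = (float(x[beat.T_on]) - float(x[beat.J])) / (
            (beat.T_on - beat.J) * 1000.0 / fs)

    rel = x - stable
    if beat.Q is not None and beat.S is not None:
        out["QRS_area"] = corrected_area(rel, beat.Q, beat.S, fs)
    if beat.T_on is not None and beat.T_end is not None:
        out["T_area"] = corrected_area(rel, beat.T_on, beat.T_end, fs)
    if np.isfinite(out["QRS_area"]) and np.isfinite(out["T_area"]):
        out["QRSa_minus_Ta"] = out["QRS_area"] - out["T_area"]
        if out["QRS_area"] > 0:
            out["Ta_over_QRSa"] = out["T_area"] / out["QRS_area"]

    out["S_over_R"] = s_over_r(amp("S"), amp("R"), stable)
    if np.isfinite(r_h) and r_h != 0 and np.isfinite(t_h):
        out["T_over_R"] = t_h / r_h

    if all(beat.get(n) is not None for n in ("Q", "R", "S")):
        out["angle_QSR"] = angle_qsr(
            (t("Q"), wave_height(amp("Q"), stable)),
            (t("R"), r_h),
            (t("S"), wave_height(amp("S"), stable)),
            aspect=aspect,
        )
    return out


def aggregate_epoch(
    vectors: list[dict[str, float]],
    min_beats: int = 10,
) -> dict[str, float]:
    """Aggregate beat-level vectors to one epoch-level vector.

    The per-feature median over the epoch's beats with a non-missing value
    is used (robust to an occasional mis-delineated beat); a feature with
    fewer than ``min_beats`` contributing beats is missing.
    """
    out = {name: math.nan for name in FEATURE_NAMES}
    if not vectors:
        return out
    for name in FEATURE_NAMES:
        vals = np.array([v.get(name, math.nan) for v in vectors], dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size >= min_beats:
            out[name] = float(np.median(vals))
    return out


def beat_feature_table(
    sig: EcgSignal,
    beats: list[BeatFiducials],
    aspect: float = DEFAULT_ASPECT,
    smooth_width: int = 5,
) -> pd.DataFrame:
    """Per-beat feature table for a delineated recording.

    Beat i's stable point comes from the TP segment between its own T end
    and beat i+1's P onset (the quiet interval that follows the beat it
    baselines). The last beat has no TP segment or RR and yields NaNs.
    Columns: r_index, stable, the 30 features.
    """
    rows = []
    for i, beat in enumerate(beats):
        nxt = beats[i + 1] if i + 1 < len(beats) else None
        baseline = None
        if (nxt is not None and beat.T_end is not None and nxt.P_on is not None
                and nxt.P_on - beat.T_end >= 7):
            try:
                baseline = stable_point(sig, beat.T_end, nxt.P_on, smooth_width)
            except ValueError:
                baseline = None
        feats = extract_features(sig, beat, nxt, baseline, aspect=aspect)
        row = {"r_index": beat.R,
               "stable": math.nan if baseline is None else baseline.stable}
        row.update(feats)
        rows.append(row)
    return pd.DataFrame(rows, columns=["r_index", "stable", *FEATURE_NAMES])
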