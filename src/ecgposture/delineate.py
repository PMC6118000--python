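"""Beat detection and fiducial-point delineation.

R peaks are found from a smoothed derivative-energy envelope with an
adaptive (running-median) threshold, a 250 ms refractory period and a
search-back pass for missed beats. The remaining landmarks are placed
relative to each R peak: Q and S as the opposite-sign extrema in short
windows, P and T peaks as the dominant extrema in their physiologic
windows, and every wave onset/end (P on/end, QRS onset, J point, T
on/end) with an area-increment boundary rule — walking away from the
peak, the boundary is the first sample whose look-ahead window holds less
than a fraction theta of the area held by the window at the peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .core import FIDUCIAL_NAMES, BeatFiducials, EcgSignal
from .preprocess import moving_average

__all__ = [
    "DelineationConfig",
    "detect_r_peaks",
    "area_increment_boundary",
    "delineate_beat",
    "delineate_all",
    "validate_beats",
]


@dataclass(frozen=True)
class DelineationConfig:
    """Search windows (ms relative to the R peak, half-open) and area rule.

    ``area_window`` (w, samples) and ``area_theta`` parameterize the
    area-increment boundary rule; ``min_wave_amp`` is the smallest
    peak-to-local-baseline deflection accepted as a real P or T wave.
    """

    q_window: tuple[float, float] = (-60.0, 0.0)
    s_window: tuple[float, float] = (0.0, 60.0)
    p_window: tuple[float, float] = (-250.0, -80.0)
    t_window_start: float = 80.0
    t_window_end_cap: float = 400.0
    t_window_rr_frac: float = 0.6
    refractory_ms: float = 250.0
    area_window: int = 10
    area_theta: float = 0.01
    boundary_span_ms: float = 160.0  # generic max walk distance from a peak
    p_span_ms: float = 80.0  # physiologic half-width caps used when the
    t_span_ms: float = 160.0  # area criterion never fires (noisy signals)
    qrs_span_ms: float = 30.0
    j_fallback_ms: float = 20.0
    min_wave_amp: float = 0.05  # mV
    envelope_smooth_ms: float = 30.0
    threshold_factor: float = 8.0
    threshold_block_s: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.area_theta < 1:
            raise ValueError("area_theta must lie in (0, 1)")
        if self.area_window < 1:
            raise ValueError("area_window must be >= 1")


def _envelope(x: np.ndarray, fs: float, cfg: DelineationConfig) -> np.ndarray:
    d = np.gradient(x)
    energy = d * d
    width = max(1, int(round(cfg.envelope_smooth_ms * fs / 1000.0)))
    return moving_average(energy, width)


def _blockwise_threshold(env: np.ndarray, fs: float, cfg: DelineationConfig) -> np.ndarray:
    """Adaptive threshold: per-block running median times a fixed factor."""
    block = max(1, int(round(cfg.threshold_block_s * fs)))
    n_blocks = max(1, int(np.ceil(env.size / block)))
    centers = np.empty(n_blocks)
    medians = np.empty(n_blocks)
    tops = np.empty(n_blocks)
    for b in range(n_blocks):
        lo, hi = b * block, min((b + 1) * block, env.size)
        centers[b] = (lo + hi - 1) / 2.0
        medians[b] = np.median(env[lo:hi])
        tops[b] = np.percentile(env[lo:hi], 99)
    if n_blocks == 1:
        med = np.full(env.size, medians[0])
        top = np.full(env.size, tops[0])
    else:
        idx = np.arange(env.size)
        med = np.interp(idx, centers, medians)
        top = np.interp(idx, centers, tops)
    # the median term tracks the noise floor; the percentile term rejects
    # P/T-wave envelope lobes, which carry orders of magnitude less
    # derivative energy than the QRS
    return np.maximum(cfg.threshold_factor * med, 0.2 * top) + 1e-9


def detect_r_peaks(sig: EcgSignal, cfg: DelineationConfig | None = None) -> np.ndarray:
    """Detect R peaks; returns a sorted array of sample indices.

    Candidate beats are envelope peaks above the adaptive threshold with a
    250 ms refractory distance; each is refined to the signal maximum
    within +/-40 ms. A search-back pass re-scans abnormally long RR gaps
    (> 1.66 x median RR) at 40 % of the threshold.
    """
    cfg = cfg or DelineationConfig()
    x = sig.samples
    env = _envelope(x, sig.fs, cfg)
    thr = _blockwise_threshold(env, sig.fs, cfg)
    refractory = max(1, int(round(cfg.refractory_ms * sig.fs / 1000.0)))
    cand, _ = find_peaks(env, height=thr, distance=refractory)

    half = max(1, int(round(0.040 * sig.fs)))

    def refine(idx: np.ndarray) -> np.ndarray:
        out = []
        for c in idx:
            lo, hi = max(0, c - half), min(x.size, c + half + 1)
            out.append(lo + int(np.argmax(x[lo:hi])))
        return np.array(sorted(set(out)), dtype=int)

    peaks = refine(cand)
    if peaks.size >= 3:
        rr = np.diff(peaks)
        med_rr = np.median(rr)
        extra: list[int] = []
        for i, gap in enumerate(rr):
            if gap > 1.66 * med_rr:
                lo = peaks[i] + refractory
                hi = peaks[i + 1] - refractory
                if hi <= lo:
                    continue
                seg_cand, _ = find_peaks(
                    env[lo:hi], height=0.4 * thr[lo:hi], distance=refractory)
                extra.extend((lo + seg_cand).tolist())
        if extra:
            peaks = refine(np.concatenate([peaks, np.array(extra, dtype=int)]))
            # enforce refractory after the merge, keeping the taller peak
            keep: list[int] = []
            for p in peaks:
                if keep and p - keep[-1] < refractory:
                    if x[p] > x[keep[-1]]:
                        keep[-1] = int(p)
                else:
                    keep.append(int(p))
            peaks = np.array(keep, dtype=int)
    return peaks


def _area_boundary(
    sig: EcgSignal,
    peak: int,
    direction: str,
    baseline: float,
    cfg: DelineationConfig,
    limit: int,
) -> tuple[int, bool]:
    """Area-increment walk; returns (index, criterion_met)."""
    x = sig.samples
    if not 0 <= peak < x.size:
        raise ValueError(f"peak index {peak} outside signal")
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    w = cfg.area_window
    step = 1 if direction == "right" else -1
    edge = peak + step * limit
    edge = min(max(edge, 0), x.size - 1)

    def window_area(k: int) -> float:
        if step > 0:
            lo, hi = k, min(k + w, x.size)
        else:
            lo, hi = max(k - w + 1, 0), k + 1
        return abs(float(np.sum(x[lo:hi] - baseline)))

    a_peak = window_area(peak)
    if a_peak == 0.0:
        return min(max(peak + step, 0), x.size - 1), True
    k = peak + step
    while (k - edge) * step <= 0:
        if window_area(k) < cfg.area_theta * a_peak:
            return k, True
        k += step
    return edge, False


def area_increment_boundary(
    sig: EcgSignal,
    peak: int,
    direction: str,
    baseline: float = 0.0,
    cfg: DelineationConfig | None = None,
    limit: int | None = None,
) -> int:
    """Locate a wave onset or end by the area-increment rule.

    Walking sample-by-sample from ``peak`` in ``direction``, the detector
    evaluates A(k) = |sum over the w-sample window extending from k away
    from the peak of (sample - baseline)| and returns the first k with
    A(k) < theta * A(peak). If the criterion is never met the search-window
    edge is returned.
    """
    cfg = cfg or DelineationConfig()
    if limit is None:
        limit = int(round(cfg.boundary_span_ms * sig.fs / 1000.0))
    idx, _ = _area_boundary(sig, peak, direction, baseline, cfg, limit)
    return idx


def _extremum(x: np.ndarray, lo: int, hi: int, mode: str) -> int | None:
    """Index of the extremum of x on [lo, hi); None if the window is empty."""
    lo, hi = max(lo, 0), min(hi, x.size)
    if hi <= lo:
        return None
    seg = x[lo:hi]
    return lo + int(np.argmin(seg) if mode == "min" else np.argmax(seg))


def delineate_beat(
    sig: EcgSignal,
    r: int,
    rr_ms: float,
    cfg: DelineationConfig | None = None,
) -> BeatFiducials:
    """Delineate one beat around a detected R peak.

    Q and S are the minima (sign opposite to the upright R) of short
    windows flanking R; P and T peaks are the dominant maxima in their
    windows; onsets/ends come from :func:`area_increment_boundary`, with
    the search bounded by neighbouring landmarks so the temporal ordering
    cannot be violated. Waves whose deflection from the local baseline is
    below ``min_wave_amp`` are marked missing; a failed J search falls back
    to S + 20 ms.
    """
    cfg = cfg or DelineationConfig()
    x = sig.samples
    if not 0 <= r < x.size:
        raise ValueError(f"R index {r} outside signal")
    sp = sig.fs / 1000.0  # samples per ms

    def ms(v: float) -> int:
        return int(round(v * sp))

    # local baseline: median over the beat's neighbourhood (TP dominates)
    lo = max(0, r - ms(0.35 * rr_ms))
    hi = min(x.size, r + ms(0.75 * rr_ms))
    baseline = float(np.median(x[lo:hi]))

    q = _extremum(x, r + ms(cfg.q_window[0]), r + ms(cfg.q_window[1]), "min")
    s = _extremum(x, r + ms(cfg.s_window[0]) + 1, r + ms(cfg.s_window[1]) + 1, "min")
    p_peak = _extremum(x, r + ms(cfg.p_window[0]), r + ms(cfg.p_window[1]) + 1, "max")
    t_hi = min(cfg.t_window_end_cap, cfg.t_window_rr_frac * rr_ms)
    t_peak = _extremum(x, r + ms(cfg.t_window_start), r + ms(t_hi) + 1, "max")

    if p_peak is not None and x[p_peak] - baseline < cfg.min_wave_amp:
        p_peak = None
    if t_peak is not None and x[t_peak] - baseline < cfg.min_wave_amp:
        t_peak = None

    beat = BeatFiducials(R=r, Q=q, S=s, P_peak=p_peak, T_peak=t_peak)

    def bound(peak: int | None, direction: str, span_ms: float,
              lo: int | None, hi: int | None) -> tuple[int | None, bool]:
        """Boundary from ``peak``, clamped into the open interval (lo, hi)."""
        if peak is None:
            return None, False
        idx, met = _area_boundary(sig, peak, direction, baseline, cfg, ms(span_ms))
        if lo is not None:
            idx = max(idx, lo + 1)
        if hi is not None:
            idx = min(idx, hi - 1)
        return idx, met

    if p_peak is not None:
        beat.P_on, _ = bound(p_peak, "left", cfg.p_span_ms, None, p_peak)
        beat.P_end, _ = bound(p_peak, "right", cfg.p_span_ms, p_peak,
                              q if q is not None else r)
    beat.QRS_on, _ = bound(q, "left", cfg.qrs_span_ms, beat.P_end, q)
    beat.J, j_met = bound(s, "right", cfg.boundary_span_ms, s, t_peak)
    if s is not None and not j_met:
        beat.J = min(s + ms(cfg.j_fallback_ms), x.size - 1)  # fallback: S + 20 ms
        if t_peak is not None:
            beat.J = min(beat.J, t_peak - 1)
    if t_peak is not None:
        beat.T_on, _ = bound(t_peak, "left", cfg.t_span_ms, beat.J, t_peak)
        beat.T_end, _ = bound(t_peak, "right", cfg.t_span_ms, t_peak, None)

    # enforce strict ordering: drop any non-R landmark that breaks it
    # (the clamps above make this a no-op except in pathological geometry)
    prev = -1
    for name in FIDUCIAL_NAMES:
        idx = beat.get(name)
        if idx is None:
            continue
        if idx <= prev:
            if name == "R":
                prev = idx  # R always kept
            else:
                setattr(beat, name, None)
        else:
            prev = idx
    return beat


def delineate_all(
    sig: EcgSignal,
    r_peaks: np.ndarray | None = None,
    cfg: DelineationConfig | None = None,
) -> list[BeatFiducials]:
    """Detect (if needed) and delineate every beat of a recording."""
    cfg = cfg or DelineationConfig()
    if r_peaks is None:
        r_peaks = detect_r_peaks(sig, cfg)
    r_peaks = np.asarray(r_peaks, dtype=int)
    beats: list[BeatFiducials] = []
    for i, r in enumerate(r_peaks):
        if i + 1 < r_peaks.size:
            rr_ms = (r_peaks[i + 1] - r) * 1000.0 / sig.fs
        elif i > 0:
            rr_ms = (r - r_peaks[i - 1]) * 1000.0 / sig.fs
        else:
            rr_ms = 1000.0
        beats.append(delineate_beat(sig, int(r), rr_ms, cfg))
    return beats


#: Landmarks a beat must have to be usable for the 30-feature vector.
REQUIRED_POINTS = FIDUCIAL_NAMES

RR_RANGE_MS = (400.0, 2000.0)
R_HEIGHT_RANGE_MV = (0.2, 6.0)


def validate_beats(
    beats: list[BeatFiducials],
    sig: EcgSignal,
    stable: np.ndarray | None = None,
) -> list[BeatFiducials]:
    """Automatic beat QC (replaces manual waveform checking).

    A beat is flagged invalid — never deleted — when any required landmark
    is missing, its RR to the next beat is outside [400, 2000] ms, its R
    height above the local baseline is outside [0.2, 6] mV, or the
    landmark ordering is violated. ``stable`` optionally supplies a
    per-beat baseline estimate (mV); otherwise the signal median is used.
    """
    x = sig.samples
    fallback = float(np.median(x)) if len(beats) else 0.0
    out: list[BeatFiducials] = []
    for i, beat in enumerate(beats):
        flags: list[str] = []
        missing = [n for n in REQUIRED_POINTS if beat.get(n) is None]
        if missing:
            flags.append("missing:" + ",".join(missing))
        if not beat.ordering_ok():
            flags.append("ordering")
        if i + 1 < len(beats):
            rr = (beats[i + 1].R - beat.R) * 1000.0 / sig.fs
            if not RR_RANGE_MS[0] <= rr <= RR_RANGE_MS[1]:
                flags.append("rr_range")
        base = fallback if stable is None or not np.isfinite(stable[i]) else float(stable[i])
        r_height = float(x[beat.R]) - base
        if not R_HEIGHT_RANGE_MV[0] <= r_height <= R_HEIGHT_RANGE_MV[1]:
            flags.append("r_height")
        beat.qc_flags = flags
        beat.valid = not flags
        out.append(beat)
    return out
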