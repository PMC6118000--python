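"""ECG denoising: mains removal, EMG-band wavelet suppression and
baseline-drift removal.

The pipeline order is fixed: mains comb filter first, then a three-level
dyadic wavelet shrinkage of the high-frequency (EMG-band) detail, and
finally subtraction of a smooth baseline fitted through per-beat
isoelectric anchor points. Baseline removal needs anchors from the TP
segments and therefore runs after a coarse R detection (two-pass scheme).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.interpolate import CubicSpline

from .core import EcgSignal

__all__ = ["FilterConfig", "mains_filter", "wavelet_denoise", "remove_baseline"]


@dataclass(frozen=True)
class FilterConfig:
    """Denoising configuration.

    mains_freq : 50 or 60 Hz.
    wavelet_name : any discrete PyWavelets family; db4 by default (close to
        the spline wavelets customary in ECG work).
    levels : dyadic decomposition depth (3 by default).
    baseline_fit : "spline" (cubic, the default) or "polynomial".
    smooth_width : width of the TP-segment smoothing mean filter, samples.
    """

    mains_freq: float = 50.0
    wavelet_name: str = "db4"
    levels: int = 3
    threshold_mode: str = "hard"
    shrink_levels: int = 2  # how many of the finest detail bands to shrink
    cycle_shifts: int = 8  # translation-invariant averaging shifts
    baseline_fit: str = "spline"
    smooth_width: int = 5

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.mains_freq not in (50.0, 60.0, 50, 60):
            raise ValueError("mains_freq must be 50 or 60 Hz")


def moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Length-preserving, zero-phase moving average with mirror padding.

    For an even ``width`` the kernel spans width+1 taps with half weights
    at the ends — still total weight ``width`` per period, so the comb
    nulls are preserved, but without the half-sample phase shift a plain
    even-length average would introduce.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    x = np.asarray(x, dtype=float)
    if width == 1:
        return x.copy()
    if width % 2 == 1:
        kernel = np.full(width, 1.0 / width)
    else:
        kernel = np.full(width + 1, 1.0 / width)
        kernel[0] = kernel[-1] = 0.5 / width
    half = kernel.size // 2
    padded = np.pad(x, (half, half), mode="reflect")
    return np.convolve(padded, kernel, mode="valid")


def mains_filter(sig: EcgSignal, mains_freq: float = 50.0) -> EcgSignal:
    """Remove powerline interference with a one-period moving average.

    The window is ``round(fs / mains_freq)`` samples — a comb filter with an
    exact null at the mains frequency when fs is a multiple of it (e.g. a
    4-sample mean at 200 Hz nulls 50 Hz) while leaving the sub-10-Hz ECG
    band essentially untouched. Edges are mirrored, so length is preserved.
    """
    if sig.fs <= 2 * mains_freq:
        raise ValueError(
            f"fs={sig.fs} Hz too low to mean-filter {mains_freq} Hz mains")
    width = int(round(sig.fs / mains_freq))
    if width < 2:
        raise ValueError("mains window shorter than 2 samples")
    return sig.copy_with(moving_average(sig.samples, width))


def wavelet_denoise(sig: EcgSignal, cfg: FilterConfig | None = None) -> EcgSignal:
    """Suppress EMG-band noise by translation-invariant wavelet shrinkage.

    A 3-level dyadic decomposition is taken; the two finest detail bands
    are thresholded at the universal threshold ``sigma * sqrt(2 ln n)``
    with sigma estimated from the median absolute deviation of the finest
    band. Hard thresholding averaged over ``cycle_shifts`` circular shifts
    (cycle spinning) is used: it removes the sub-threshold noise as well
    as soft shrinkage does without biasing the large QRS coefficients, and
    the shift averaging suppresses the blocking artifacts plain hard
    thresholding leaves. Coarser bands are untouched, so a clean beat
    passes through almost unchanged; on a clean signal the estimated noise
    floor — and hence the threshold — is near zero.
    """
    cfg = cfg or FilterConfig()
    x = sig.samples
    wavelet = pywt.Wavelet(cfg.wavelet_name)
    if x.size < 2**cfg.levels or x.size < wavelet.dec_len:
        raise ValueError("signal shorter than the wavelet filter support")
    n_shrunk = min(cfg.shrink_levels, cfg.levels)
    shifts = range(max(1, cfg.cycle_shifts))
    out = np.zeros_like(x)
    threshold = None
    for shift in shifts:
        xs = np.roll(x, shift)
        coeffs = pywt.wavedec(xs, wavelet, level=cfg.levels, mode="symmetric")
        # coeffs = [approx, detail_level_L, ..., detail_level_1]
        if threshold is None:
            d1 = coeffs[-1]
            sigma = np.median(np.abs(d1 - np.median(d1))) / 0.6745
            threshold = sigma * np.sqrt(2.0 * np.log(x.size))
        if threshold > 0:
            for k in range(1, n_shrunk + 1):
                coeffs[-k] = pywt.threshold(coeffs[-k], threshold,
                                            mode=cfg.threshold_mode)
        rec = pywt.waverec(coeffs, wavelet, mode="symmetric")[: x.size]
        out += np.roll(rec, -shift)
    return sig.copy_with(out / len(shifts))


def remove_baseline(
    sig: EcgSignal,
    anchors: np.ndarray,
    fit: str = "spline",
) -> EcgSignal:
    """Subtract a smooth baseline fitted through isoelectric anchor points.

    ``anchors`` is an (n, 2) array of (sample_index, amplitude) pairs, one
    per beat, taken on the TP segments where the trace should sit at the
    isoelectric level. A cubic spline (or, for "polynomial" / fewer than 4
    anchors, a polynomial of degree ``min(3, n-1)``) is fitted through them
    and subtracted; outside the anchor range the fit is held constant so
    edge extrapolation cannot blow up.
    """
    anchors = np.asarray(anchors, dtype=float)
    if anchors.ndim != 2 or anchors.shape[1] != 2 or anchors.shape[0] < 2:
        raise ValueError("need at least 2 (index, amplitude) anchors")
    order = np.argsort(anchors[:, 0])
    xa, ya = anchors[order, 0], anchors[order, 1]
    xa, keep = np.unique(xa, return_index=True)
    ya = ya[keep]
    if xa.size < 2:
        raise ValueError("need at least 2 distinct anchor indices")

    x = np.arange(sig.samples.size, dtype=float)
    if fit == "spline" and xa.size >= 4:
        spline = CubicSpline(xa, ya, bc_type="natural")
        inner = np.clip(x, xa[0], xa[-1])
        baseline = spline(inner)
    else:
        degree = min(3, xa.size - 1)
        coefs = np.polyfit(xa, ya, degree)
        inner = np.clip(x, xa[0], xa[-1])
        baseline = np.polyval(coefs, inner)
    return sig.copy_with(sig.samples - baseline)
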