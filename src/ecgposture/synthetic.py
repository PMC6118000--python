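"""Seeded synthetic overnight sleep-ECG generator with position-dependent
beat morphology.

The generator exists so that every downstream stage — denoising,
delineation, waveform features, position statistics and classification —
can be exercised against known ground truth. One heartbeat is modelled as
a sum of five smooth, unimodal, compact-support bumps (P, Q, R, S, T) on a
flat baseline, so every landmark point (wave onset, peak, end) has an
exact closed-form location and the TP segment is exactly isoelectric.

Lying position modulates the beat template multiplicatively (wave
amplitudes) and additively (QT and RR), in the directions reported for
real sleep ECG: on the left side the P, R and T waves shrink, the S wave
deepens, S/R rises and the QRS triangle narrows; the right side is nearly
indistinguishable from supine apart from a slightly smaller T wave.
Between-subject variability is modelled as per-wave multiplicative
offsets, which is what defeats subject-independent classification without
per-subject normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    CLASS_ORDER,
    EPOCH_SECONDS,
    FIDUCIAL_NAMES,
    POSITIONS,
    SLEEP_STAGES,
    EcgSignal,
)

__all__ = [
    "WaveComponent",
    "BeatMorphology",
    "PositionParams",
    "PositionEffect",
    "SubjectProfile",
    "PositionSchedule",
    "SyntheticRecording",
    "default_morphology",
    "default_position_effects",
    "identity_position_effects",
    "make_position_schedule",
    "make_subject_profile",
    "synthesize_recording",
    "truth_fiducials",
    "template_features",
    "sample_feature_table",
]

#: Sleep-stage prior (wake, REM, light, deep) — carried as metadata only.
SLEEP_STAGE_PRIOR = (0.10, 0.14, 0.67, 0.09)

#: Default position prior: left-dominant night with rare prone epochs.
POSITION_PRIOR = {"left": 0.46, "supine": 0.16, "right": 0.34, "prone": 0.04}


@dataclass(frozen=True)
class WaveComponent:
    """One wave of the beat template.

    ``center`` is the time offset from the R peak in ms, ``width`` the
    half-width of the compact support in ms, ``amplitude`` the signed peak
    deflection in mV. The bump is a raised cosine:
    ``a * cos^2(pi (t - c) / (2 w))`` for ``|t - c| <= w``, zero outside.
    """

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("wave width must be positive")
        if abs(self.amplitude) > 10:
            raise ValueError("wave amplitude exceeds 10 mV")

    @property
    def onset(self) -> float:
        return self.center - self.width

    @property
    def end(self) -> float:
        return self.center + self.width

    @property
    def area(self) -> float:
        """Unsigned area of the bump in mV*ms (integral of cos^2 = width)."""
        return abs(self.amplitude) * self.width


@dataclass(frozen=True)
class BeatMorphology:
    """Beat template: one wave component per P, Q, R, S, T plus rhythm."""

    P: WaveComponent
    Q: WaveComponent
    R: WaveComponent
    S: WaveComponent
    T: WaveComponent
    rr_mean: float = 1000.0  # ms
    rr_sd: float = 25.0  # ms

    def __post_init__(self) -> None:
        centers = [self.P.center, self.Q.center, self.R.center, self.S.center, self.T.center]
        if not all(a < b for a, b in zip(centers, centers[1:])):
            raise ValueError("wave centers must be strictly ordered P < Q < R < S < T")
        if not 400 <= self.rr_mean <= 2000:
            raise ValueError("rr_mean must lie in [400, 2000] ms")

    @property
    def qt(self) -> float:
        """QT interval implied by the geometry: Q peak to T end (ms)."""
        return self.T.end - self.Q.center

    @property
    def pr(self) -> float:
        """PR interval implied by the geometry: P onset to QRS onset (ms)."""
        return self.Q.onset - self.P.onset

    def waves(self) -> dict[str, WaveComponent]:
        return {"P": self.P, "Q": self.Q, "R": self.R, "S": self.S, "T": self.T}


def default_morphology() -> BeatMorphology:
    """Lead-II-like template: wave offsets are multiples of 5 ms so that at
    200 Hz every landmark falls exactly on the sample grid."""
    return BeatMorphology(
        P=WaveComponent(center=-160.0, width=55.0, amplitude=0.15),
        Q=WaveComponent(center=-30.0, width=15.0, amplitude=-0.10),
        R=WaveComponent(center=0.0, width=15.0, amplitude=1.20),
        S=WaveComponent(center=30.0, width=15.0, amplitude=-0.25),
        T=WaveComponent(center=300.0, width=130.0, amplitude=0.35),
    )


@dataclass(frozen=True)
class PositionParams:
    """Template modulation for one lying position.

    Multiplicative amplitude factors for P, R, S, T, a width factor for T,
    and additive offsets for QT (shifts the T wave) and mean RR, both ms.
    """

    p_amp: float = 1.0
    r_amp: float = 1.0
    s_amp: float = 1.0
    t_amp: float = 1.0
    t_width: float = 1.0
    qt_offset: float = 0.0
    rr_offset: float = 0.0

    def __post_init__(self) -> None:
        for f in (self.p_amp, self.r_amp, self.s_amp, self.t_amp, self.t_width):
            if f <= 0:
                raise ValueError("position amplitude/width factors must be positive")


#: Mapping position name -> PositionParams.
PositionEffect = dict[str, PositionParams]


def default_position_effects() -> PositionEffect:
    """Default per-position modulation.

    Directions follow the reported left-vs-supine contrasts (smaller P, R
    and T, deeper S, longer QT and RR on the left; right almost equal to
    supine except a slightly smaller T). Magnitudes are generator defaults,
    chosen to give pooled per-position feature contrasts of realistic
    relative size; they are configurable and carry no empirical claim.
    """
    return {
        "left": PositionParams(p_amp=0.60, r_amp=0.75, s_amp=1.25, t_amp=0.70,
                               qt_offset=7.0, rr_offset=40.0),
        "supine": PositionParams(),
        "right": PositionParams(t_amp=0.90),
        "prone": PositionParams(p_amp=0.70, r_amp=0.65, s_amp=0.90, t_amp=0.75,
                                qt_offset=-5.0),
    }


def identity_position_effects() -> PositionEffect:
    """Null effect: every position shares the same template (for calibration)."""
    return {p: PositionParams() for p in POSITIONS}


@dataclass(frozen=True)
class SubjectProfile:
    """One synthetic subject: template, per-wave offsets and noise levels.

    ``amp_factors`` are multiplicative per-wave morphology offsets (the
    between-subject variability); noise defaults give a visibly dirty but
    easily recoverable signal. The same seed always reproduces the same
    recording.
    """

    subject_id: str
    morphology: BeatMorphology = field(default_factory=default_morphology)
    amp_factors: dict[str, float] = field(
        default_factory=lambda: {w: 1.0 for w in "PQRST"})
    rr_subject_offset: float = 0.0  # ms
    qt_subject_offset: float = 0.0  # ms, shifts the T wave
    wander_amp: float = 0.15  # mV baseline wander
    wander_freq: float = 0.25  # Hz
    emg_sd: float = 0.03  # mV white high-frequency noise
    mains_amp: float = 0.02  # mV
    mains_freq: float = 50.0  # Hz
    seed: int = 0

    def noiseless(self) -> "SubjectProfile":
        return replace(self, wander_amp=0.0, emg_sd=0.0, mains_amp=0.0)


def make_subject_profile(
    subject_id: str,
    rng: np.random.Generator,
    between_sd: float = 0.40,
    rr_between_sd: float = 60.0,
    qt_between_sd: float = 40.0,
    **noise_overrides,
) -> SubjectProfile:
    """Draw a subject: log-normal per-wave amplitude offsets plus Gaussian
    RR and QT offsets (between-subject variability spans both amplitude and
    time features, which is what defeats raw cross-subject transfer)."""
    factors = {w: float(np.exp(rng.normal(0.0, between_sd))) for w in "PQRST"}
    return SubjectProfile(
        subject_id=subject_id,
        amp_factors=factors,
        rr_subject_offset=float(rng.normal(0.0, rr_between_sd)),
        qt_subject_offset=float(rng.normal(0.0, qt_between_sd)),
        seed=int(rng.integers(0, 2**31 - 1)),
        **noise_overrides,
    )


@dataclass(frozen=True)
class PositionSchedule:
    """Ordered run-length encoding of per-epoch lying positions."""

    runs: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.runs:
            raise ValueError("schedule must contain at least one run")
        for pos, n in self.runs:
            if pos not in POSITIONS:
                raise ValueError(f"unknown position {pos!r}")
            if n < 1:
                raise ValueError("run length must be >= 1 epoch")
        if self.total_epochs * EPOCH_SECONDS > 12 * 3600:
            raise ValueError("schedule exceeds 12 h")

    @property
    def total_epochs(self) -> int:
        return sum(n for _, n in self.runs)

    def epoch_positions(self) -> list[str]:
        out: list[str] = []
        for pos, n in self.runs:
            out.extend([pos] * n)
        return out


def make_position_schedule(
    total_epochs: int,
    mean_run: float = 30.0,
    positions: dict[str, float] | None = None,
    seed: int | np.random.Generator = 0,
) -> PositionSchedule:
    """Draw a night of position runs.

    Run lengths are geometric with mean ``mean_run`` epochs; run positions
    are drawn from the ``positions`` prior (name -> probability, defaults to
    a left-dominant night with rare prone epochs), never repeating the
    previous run's position when more than one position has mass.
    """
    if total_epochs < 1:
        raise ValueError("total_epochs must be >= 1")
    if mean_run < 1:
        raise ValueError("mean_run must be >= 1")
    prior = dict(positions) if positions is not None else dict(POSITION_PRIOR)
    if not prior:
        raise ValueError("position set must not be empty")
    names = list(prior)
    probs = np.array([prior[n] for n in names], dtype=float)
    if np.any(probs < 0) or probs.sum() <= 0:
        raise ValueError("position prior must be non-negative with positive mass")
    probs = probs / probs.sum()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    runs: list[tuple[str, int]] = []
    remaining = total_epochs
    prev: str | None = None
    while remaining > 0:
        p = probs.copy()
        if prev is not None and len(names) > 1:
            p[names.index(prev)] = 0.0
            if p.sum() <= 0:  # prior put all mass on one position
                p = probs.copy()
            else:
                p = p / p.sum()
        pos = str(rng.choice(names, p=p))
        length = min(int(rng.geometric(1.0 / mean_run)), remaining)
        runs.append((pos, length))
        remaining -= length
        prev = pos
    return PositionSchedule(runs=tuple(runs))


def draw_sleep_stages(n_epochs: int, rng: np.random.Generator) -> list[str]:
    """i.i.d. sleep-stage labels with a realistic stage mix (metadata only)."""
    return [str(s) for s in rng.choice(SLEEP_STAGES, size=n_epochs, p=SLEEP_STAGE_PRIOR)]


@dataclass
class SyntheticRecording:
    """A generated recording plus its pre-noise ground truth.

    ``truth`` has one row per beat: the 11 landmark sample indices, the
    realized RR to the next beat (ms, NaN for the last beat), the true
    P/R/S/T heights and Q depth (mV, relative to the flat baseline), the
    epoch index and position of the beat.
    ``labels`` has one row per epoch: epoch_index, start_s, position,
    sleep_stage.
    """

    signal: EcgSignal
    truth: pd.DataFrame
    labels: pd.DataFrame
    profile: SubjectProfile
    schedule: PositionSchedule


def _scaled_waves(
    morph: BeatMorphology,
    params: PositionParams,
    amp_factors: dict[str, float],
    qt_shift: float = 0.0,
) -> dict[str, WaveComponent]:
    """Apply subject and position modulation to the template waves."""
    pos_amp = {"P": params.p_amp, "Q": 1.0, "R": params.r_amp,
               "S": params.s_amp, "T": params.t_amp}
    out: dict[str, WaveComponent] = {}
    for name, w in morph.waves().items():
        amp = w.amplitude * amp_factors.get(name, 1.0) * pos_amp[name]
        center = w.center + (params.qt_offset + qt_shift if name == "T" else 0.0)
        width = w.width * (params.t_width if name == "T" else 1.0)
        out[name] = WaveComponent(center=center, width=width, amplitude=amp)
    return out


def _add_bump(samples: np.ndarray, c_idx: int, hw_samples: float, amp: float) -> None:
    lo = max(0, int(math.ceil(c_idx - hw_samples)))
    hi = min(samples.size - 1, int(math.floor(c_idx + hw_samples)))
    if hi < lo:
        return
    i = np.arange(lo, hi + 1)
    samples[i] += amp * np.cos(np.pi * (i - c_idx) / (2.0 * hw_samples)) ** 2


def synthesize_recording(
    profile: SubjectProfile,
    schedule: PositionSchedule,
    effects: PositionEffect | None = None,
    fs: float = 200.0,
) -> SyntheticRecording:
    """Generate one recording from a subject profile and a position schedule.

    Beats are laid down sequentially; each beat takes the position of the
    epoch containing its R peak, the position's :class:`PositionParams`
    modulate the template, and noise (baseline wander, EMG-band white
    noise, mains) is added after the ground truth is recorded.
    """
    if fs < 100:
        raise ValueError("sampling rate must be >= 100 Hz")
    if effects is None:
        effects = default_position_effects()
    positions = schedule.epoch_positions()
    for pos in set(positions):
        if pos not in effects:
            raise ValueError(f"schedule position {pos!r} missing from effects")

    rng = np.random.default_rng(profile.seed)
    n_epochs = schedule.total_epochs
    n_samples = int(round(n_epochs * EPOCH_SECONDS * fs))
    samples = np.zeros(n_samples, dtype=float)
    ms_per_sample = 1000.0 / fs

    labels = pd.DataFrame({
        "epoch_index": np.arange(n_epochs),
        "start_s": np.arange(n_epochs) * EPOCH_SECONDS,
        "position": positions,
        "sleep_stage": draw_sleep_stages(n_epochs, rng),
    })

    morph = profile.morphology
    rows: list[dict] = []
    # first R far enough in that the full beat template fits
    t_ms = -morph.P.onset + 50.0
    r_indices: list[int] = []
    while True:
        r_idx = int(round(t_ms / ms_per_sample))
        epoch = int(r_idx / (EPOCH_SECONDS * fs))
        if epoch >= n_epochs:
            break
        params = effects[positions[epoch]]
        waves = _scaled_waves(morph, params, profile.amp_factors,
                              profile.qt_subject_offset)
        if (r_idx + waves["T"].end / ms_per_sample) >= n_samples:
            break
        row: dict = {"epoch_index": epoch, "position": positions[epoch]}
        for name, w in waves.items():
            c_idx = r_idx + int(round(w.center / ms_per_sample))
            hw = w.width / ms_per_sample
            _add_bump(samples, c_idx, hw, w.amplitude)
            on = int(round(c_idx - hw))
            end = int(round(c_idx + hw))
            if name == "P":
                row.update(P_on=on, P_peak=c_idx, P_end=end)
            elif name == "Q":
                row.update(QRS_on=on, Q=c_idx)
            elif name == "R":
                row.update(R=c_idx)
            elif name == "S":
                row.update(S=c_idx, J=end)
            else:
                row.update(T_on=on, T_peak=c_idx, T_end=end)
        row.update(
            p_height=waves["P"].amplitude,
            q_depth=abs(waves["Q"].amplitude),
            r_height=waves["R"].amplitude,
            s_depth=abs(waves["S"].amplitude),
            t_height=waves["T"].amplitude,
        )
        rows.append(row)
        r_indices.append(r_idx)
        rr = (morph.rr_mean + profile.rr_subject_offset + params.rr_offset
              + rng.normal(0.0, morph.rr_sd))
        rr = max(400.0, rr)
        t_ms += rr

    truth = pd.DataFrame(rows)
    if len(truth):
        r = truth["R"].to_numpy(dtype=float)
        truth["rr_ms"] = np.append(np.diff(r) * ms_per_sample, np.nan)

    if profile.wander_amp > 0:
        t = np.arange(n_samples) / fs
        samples += profile.wander_amp * np.sin(
            2 * np.pi * profile.wander_freq * t + rng.uniform(0, 2 * np.pi))
    if profile.emg_sd > 0:
        samples += rng.normal(0.0, profile.emg_sd, size=n_samples)
    if profile.mains_amp > 0:
        t = np.arange(n_samples) / fs
        samples += profile.mains_amp * np.sin(
            2 * np.pi * profile.mains_freq * t + rng.uniform(0, 2 * np.pi))

    return SyntheticRecording(
        signal=EcgSignal(samples=samples, fs=fs),
        truth=truth,
        labels=labels,
        profile=profile,
        schedule=schedule,
    )


def truth_fiducials(recording: SyntheticRecording) -> list:
    """Ground-truth landmark rows as :class:`~ecgposture.core.BeatFiducials`
    (for testing downstream stages against perfect delineation)."""
    from .core import FIDUCIAL_NAMES, BeatFiducials

    beats = []
    for _, row in recording.truth.iterrows():
        kwargs = {n: int(row[n]) for n in FIDUCIAL_NAMES}
        beats.append(BeatFiducials(**kwargs))
    return beats


# ---------------------------------------------------------------------------
# Feature-level shortcut


def template_features(
    morph: BeatMorphology,
    params: PositionParams,
    amp_factors: dict[str, float] | None = None,
    rr_subject_offset: float = 0.0,
    qt_subject_offset: float = 0.0,
    aspect: float = 10.0,
) -> dict[str, float]:
    """Closed-form values of the 12 selected waveform features implied by a
    (subject- and position-modulated) beat template.

    ``aspect`` is the voltage-to-time scaling used for the QRS-triangle
    angle (ms of x-axis per mV of y-axis), matching the features module.
    """
    if amp_factors is None:
        amp_factors = {w: 1.0 for w in "PQRST"}
    w = _scaled_waves(morph, params, amp_factors, qt_subject_offset)
    rr = morph.rr_mean + rr_subject_offset + params.rr_offset
    h_p, h_r, h_t = w["P"].amplitude, w["R"].amplitude, w["T"].amplitude
    d_q, d_s = abs(w["Q"].amplitude), abs(w["S"].amplitude)

    qx, rx, sx = w["Q"].center, w["R"].center, w["S"].center
    qy, ry, sy = -d_q * aspect, h_r * aspect, -d_s * aspect
    qs = math.hypot(sx - qx, sy - qy)
    rs = math.hypot(sx - rx, sy - ry)
    qr = math.hypot(rx - qx, ry - qy)
    cos_s = (qs**2 + rs**2 - qr**2) / (2 * qs * rs)
    angle = math.degrees(math.acos(min(1.0, max(-1.0, cos_s))))

    # chord-corrected areas of the continuous template (mV*ms)
    t_area = h_t * w["T"].width
    qrs_signed = (h_r * w["R"].width - d_q * w["Q"].width / 2.0
                  - d_s * w["S"].width / 2.0)
    chord = -(d_q + d_s) / 2.0 * (sx - qx)
    qrs_area = abs(qrs_signed - chord)

    return {
        "QT": w["T"].end - qx,
        "RR": rr,
        "TP_segment": rr - (w["T"].end - w["P"].onset),
        "angle_QSR": angle,
        "S_over_R": d_s / h_r,
        "QR": h_r + d_q,
        "P_peak": h_p,
        "R_peak": h_r,
        "T_peak": h_t,
        "T_area": t_area,
        "QRS_area": qrs_area,
        "Ta_over_QRSa": t_area / qrs_area,
    }


def sample_feature_table(
    n_subjects: int = 9,
    epochs_per_position: int = 100,
    effects: PositionEffect | None = None,
    within_sd: float = 0.04,
    seed: int = 0,
    positions: tuple[str, ...] = CLASS_ORDER,
    between_sd: float = 0.40,
    morphology: BeatMorphology | None = None,
) -> pd.DataFrame:
    """Draw an epoch-level feature table directly, skipping signal synthesis.

    Each subject gets log-normal per-wave amplitude offsets; each position's
    mean feature vector is the closed-form template value; epoch rows add
    independent Gaussian noise of relative scale ``within_sd`` (fraction of
    the position-mean magnitude). Columns: subject/epoch metadata plus the
    12 selected features.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if epochs_per_position < 1:
        raise ValueError("epochs_per_position must be >= 1")
    if within_sd < 0:
        raise ValueError("within_sd must be non-negative")
    if effects is None:
        effects = default_position_effects()
    if morphology is None:
        morphology = default_morphology()
    rng = np.random.default_rng(seed)

    frames: list[pd.DataFrame] = []
    for s in range(n_subjects):
        prof = make_subject_profile(f"S{s + 1:02d}", rng, between_sd=between_sd)
        epoch = 0
        for pos in positions:
            mean = template_features(
                morphology, effects[pos], prof.amp_factors,
                prof.rr_subject_offset, prof.qt_subject_offset)
            names = list(mean)
            mu = np.array([mean[k] for k in names])
            noise = rng.normal(0.0, 1.0, size=(epochs_per_position, len(names)))
            values = mu + within_sd * np.abs(mu) * noise
            df = pd.DataFrame(values, columns=names)
            df.insert(0, "subject_id", prof.subject_id)
            df.insert(1, "epoch_index", np.arange(epoch, epoch + epochs_per_position))
            df.insert(2, "position", pos)
            df.insert(3, "sleep_stage", draw_sleep_stages(epochs_per_position, rng))
            epoch += epochs_per_position
            frames.append(df)
    return pd.concat(frames, ignore_index=True)
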