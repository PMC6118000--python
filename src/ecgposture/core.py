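"""Shared domain types for the sleep-position ECG pipeline.

The pipeline works on a single-lead (lead II) voltage trace sampled
uniformly, typically at 200 Hz, with the night divided into 30-s scoring
epochs that each carry one lying-position label (left lateral, supine,
right lateral or prone) and optionally one sleep-stage label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical class order used everywhere (confusion matrices, priors, plots).
POSITIONS = ("left", "supine", "right", "prone")

#: The three classes actually used for classification (prone is excluded
#: because overnight prone epochs are too rare to train on).
CLASS_ORDER = ("left", "supine", "right")

SLEEP_STAGES = ("wake", "REM", "light", "deep")

#: Scoring-epoch length in seconds.
EPOCH_SECONDS = 30.0


@dataclass
class EcgSignal:
    """Uniformly sampled single-lead ECG voltage trace.

    Parameters
    ----------
    samples : ndarray
        Voltage in millivolts.
    fs : float
        Sampling rate in Hz.
    start_time : float
        Time of the first sample in seconds (defaults to 0).
    """

    samples: np.ndarray
    fs: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("signal must be a 1-d array with at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("signal contains non-finite samples")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.fs

    def copy_with(self, samples: np.ndarray) -> "EcgSignal":
        return EcgSignal(samples=samples, fs=self.fs, start_time=self.start_time)


#: Landmark-point names in temporal order within one beat.
FIDUCIAL_NAMES = (
    "P_on", "P_peak", "P_end", "QRS_on", "Q", "R", "S", "J",
    "T_on", "T_peak", "T_end",
)

MISSING = -1  # sentinel for an absent landmark in integer index arrays


@dataclass
class BeatFiducials:
    """0-based sample indices of the delineated landmarks of one beat.

    Any landmark except R may be missing (``None``). When all are present
    they are strictly increasing in the order of :data:`FIDUCIAL_NAMES`.
    """

    P_on: int | None = None
    P_peak: int | None = None
    P_end: int | None = None
    QRS_on: int | None = None
    Q: int | None = None
    R: int = 0
    S: int | None = None
    J: int | None = None
    T_on: int | None = None
    T_peak: int | None = None
    T_end: int | None = None
    valid: bool = True
    qc_flags: list[str] = field(default_factory=list)

    def get(self, name: str) -> int | None:
        return getattr(self, name)

    def as_array(self) -> np.ndarray:
        """All 11 landmark indices in order, ``MISSING`` for absent ones."""
        return np.array(
            [MISSING if self.get(n) is None else int(self.get(n)) for n in FIDUCIAL_NAMES],
            dtype=int,
        )

    def present(self) -> list[str]:
        return [n for n in FIDUCIAL_NAMES if self.get(n) is not None]

    def ordering_ok(self) -> bool:
        """True when the present landmarks are strictly increasing."""
        idx = [self.get(n) for n in FIDUCIAL_NAMES if self.get(n) is not None]
        return all(a < b for a, b in zip(idx, idx[1:]))
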