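"""Benchmark confusion matrices from a published sleep lying-position
classification study (single-lead sleep ECG, 9 healthy subjects, random
forest on 12 waveform features).

These pooled test-set matrices — one per classification scheme — serve as
worked examples: feeding them through :mod:`ecgposture.evaluate` must
reproduce the accuracy and kappa levels the study reports (subject
specific ~97 % / kappa ~0.9; subject independent ~45 % / ~0.09 raw,
~64 % / ~0.32 with per-subject quantile normalization). Rows are the
output (predicted) position, columns the target (true) position, in
order left / supine / right.
"""

from __future__ import annotations

import numpy as np

from .core import CLASS_ORDER
from .evaluate import ConfusionMatrix

__all__ = ["REFERENCE_CONFUSION_MATRICES", "reference_matrix"]

REFERENCE_CONFUSION_MATRICES: dict[str, list[list[int]]] = {
    # subject-specific scheme (20 % train / 80 % test, pooled over subjects)
    "subject_specific": [
        [1868, 39, 7],
        [8, 603, 9],
        [14, 15, 1336],
    ],
    # leave-one-subject-out, raw features
    "subject_independent_raw": [
        [1492, 458, 247],
        [716, 203, 1068],
        [79, 166, 378],
    ],
    # leave-one-subject-out, per-subject 5/95 % quantile normalization
    "subject_independent_normalized": [
        [1757, 261, 334],
        [288, 377, 459],
        [312, 176, 892],
    ],
}


def reference_matrix(scheme: str) -> ConfusionMatrix:
    """The pooled benchmark matrix for one scheme as a ConfusionMatrix."""
    return ConfusionMatrix(
        np.array(REFERENCE_CONFUSION_MATRICES[scheme], dtype=int), CLASS_ORDER)
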