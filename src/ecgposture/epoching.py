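"""Segmentation into 30-s labelled epochs and the exclusion rules.

Beats are assigned to the epoch whose half-open 30-s interval contains
their R peak. Downstream analysis drops (a) epochs inside same-position
runs lasting no more than 1 min (two epochs) — too close to a position
change, (b) epochs with too few valid beats — the automatic surrogate for
signal disturbed while the sleeper turns over, and (c), for
classification only, the rare prone epochs, leaving the three-class
problem left / supine / right.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CLASS_ORDER, EPOCH_SECONDS, BeatFiducials, EcgSignal
from .features import FEATURE_NAMES, aggregate_epoch, beat_feature_table

__all__ = ["EpochRecord", "segment_and_label", "apply_exclusions", "records_to_frame"]

#: Metadata columns of the epoch-level feature table.
META_COLUMNS = ("subject_id", "epoch_index", "start_s", "position",
                "sleep_stage", "n_valid_beats")


@dataclass
class EpochRecord:
    """One labelled 30-s epoch with its aggregated feature vector."""

    subject_id: str
    epoch_index: int
    start_s: float
    position: str
    sleep_stage: str
    features: dict[str, float]
    n_valid_beats: int
    qc_flags: list[str] = field(default_factory=list)


def segment_and_label(
    sig: EcgSignal,
    beats: list[BeatFiducials],
    labels: pd.DataFrame,
    subject_id: str = "S01",
    min_beats: int = 10,
    beat_features: pd.DataFrame | None = None,
) -> list[EpochRecord]:
    """Build one EpochRecord per labelled epoch.

    ``labels`` needs columns epoch_index, position and (optionally)
    sleep_stage; epochs missing from it are labelled unknown. Beat-level
    features are computed here unless a precomputed ``beat_features``
    table (from :func:`beat_feature_table`) is passed.
    """
    if beat_features is None:
        beat_features = beat_feature_table(sig, beats)
    n_epochs = int(math.ceil(sig.duration / EPOCH_SECONDS))
    samples_per_epoch = EPOCH_SECONDS * sig.fs

    label_map: dict[int, tuple[str, str]] = {}
    for _, row in labels.iterrows():
        stage = row["sleep_stage"] if "sleep_stage" in labels.columns else "unknown"
        label_map[int(row["epoch_index"])] = (str(row["position"]), str(stage))

    by_epoch: dict[int, list[int]] = {}
    for i, beat in enumerate(beats):
        epoch = int(beat.R // samples_per_epoch)
        by_epoch.setdefault(epoch, []).append(i)

    records: list[EpochRecord] = []
    for e in range(n_epochs):
        position, stage = label_map.get(e, ("unknown", "unknown"))
        idx = by_epoch.get(e, [])
        valid_idx = [i for i in idx if beats[i].valid]
        vectors = [beat_features.iloc[i][list(FEATURE_NAMES)].to_dict()
                   for i in valid_idx]
        feats = aggregate_epoch(vectors, min_beats=min_beats)
        flags = []
        if position == "unknown":
            flags.append("unlabelled")
        if len(valid_idx) < min_beats:
            flags.append("too_few_beats")
        records.append(EpochRecord(
            subject_id=subject_id,
            epoch_index=e,
            start_s=e * EPOCH_SECONDS,
            position=position,
            sleep_stage=stage,
            features=feats,
            n_valid_beats=len(valid_idx),
            qc_flags=flags,
        ))
    return records


def _run_lengths(positions: list[str]) -> list[int]:
    """Length of the same-position run each epoch belongs to."""
    out = [0] * len(positions)
    i = 0
    while i < len(positions):
        j = i
        while j < len(positions) and positions[j] == positions[i]:
            j += 1
        for k in range(i, j):
            out[k] = j - i
        i = j
    return out


def apply_exclusions(
    records: list[EpochRecord],
    for_classification: bool = False,
    min_beats: int = 10,
    max_short_run: int = 2,
) -> list[EpochRecord]:
    """Drop epochs per the exclusion rules; idempotent.

    Removed: unlabelled epochs; epochs with fewer than ``min_beats`` valid
    beats; when ``for_classification``, prone epochs (so the surviving
    class set is left/supine/right); and finally epochs in same-position
    runs of length <= ``max_short_run`` (1 min at 30 s/epoch). The
    pointwise rules run before the run-length rule, which makes the whole
    operation idempotent: removals can only merge neighbouring runs, never
    split them. Records from several subjects may be mixed; runs are
    computed within each subject.
    """
    records = sorted(records, key=lambda r: (r.subject_id, r.epoch_index))
    kept = [
        r for r in records
        if r.position != "unknown"
        and r.n_valid_beats >= min_beats
        and not (for_classification and r.position not in CLASS_ORDER)
    ]
    out: list[EpochRecord] = []
    subjects = dict.fromkeys(r.subject_id for r in kept)
    for subject in subjects:
        sub = [r for r in kept if r.subject_id == subject]
        runs = _run_lengths([r.position for r in sub])
        out.extend(rec for rec, run in zip(sub, runs) if run > max_short_run)
    return out


def records_to_frame(records: list[EpochRecord]) -> pd.DataFrame:
    """Epoch records as a tidy table: metadata columns + 30 feature columns."""
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "epoch_index": r.epoch_index,
            "start_s": r.start_s,
            "position": r.position,
            "sleep_stage": r.sleep_stage,
            "n_valid_beats": r.n_valid_beats,
        }
        row.update({k: r.features.get(k, np.nan) for k in FEATURE_NAMES})
        rows.append(row)
    return pd.DataFrame(rows, columns=[*META_COLUMNS, *FEATURE_NAMES])
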