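"""Plain-text file formats of the pipeline.

Everything is CSV plus, for signals, a JSON sidecar carrying the sampling
rate and units. Formats:

signal CSV      header ``sample_index,ecg_mV``; sidecar ``<name>.json``
                with ``{fs_hz, units, lead, subject_id, seed}``.
labels CSV      ``epoch_index,start_s,position,sleep_stage``.
fiducials CSV   one row per beat, the 11 landmark columns (sample
                indices, -1 for missing) plus a ``valid`` flag.
feature CSV     one row per epoch: metadata + the 30 feature columns,
                missing encoded as an empty field.

Every writer stamps a provenance comment line (``# provenance: ...``)
with the package version and the seed/config hash when supplied.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import FIDUCIAL_NAMES, MISSING, BeatFiducials, EcgSignal

__all__ = [
    "read_signal", "write_signal",
    "read_labels", "write_labels",
    "read_fiducials", "write_fiducials",
    "read_feature_table", "write_feature_table",
]


def _provenance(seed: int | None = None, config: dict | None = None) -> str:
    parts = [f"ecgposture={__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]
        parts.append(f"config_sha={digest}")
    return "# provenance: " + " ".join(parts) + "\n"


def write_signal(
    path: str | Path,
    sig: EcgSignal,
    subject_id: str = "",
    seed: int | None = None,
    lead: str = "II",
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_provenance(seed))
        fh.write("sample_index,ecg_mV\n")
        for i, v in enumerate(sig.samples):
            fh.write(f"{i},{v:.9f}\n")
    sidecar = {
        "fs_hz": sig.fs,
        "units": "mV",
        "lead": lead,
        "subject_id": subject_id,
        "seed": seed,
        "start_time_s": sig.start_time,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_signal(path: str | Path) -> EcgSignal:
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing JSON sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    df = pd.read_csv(path, comment="#")
    expected = ["sample_index", "ecg_mV"]
    if list(df.columns) != expected:
        bad = [c for c in df.columns if c not in expected] or list(df.columns)
        raise ValueError(f"malformed signal header: unexpected column(s) {bad}")
    idx = df["sample_index"].to_numpy()
    if np.any(np.diff(idx) <= 0):
        raise ValueError("sample_index must be strictly increasing")
    samples = df["ecg_mV"].to_numpy(dtype=float)
    if np.isnan(samples).any():
        raise ValueError("signal contains NaN samples")
    return EcgSignal(samples=samples, fs=float(sidecar["fs_hz"]),
                     start_time=float(sidecar.get("start_time_s", 0.0)))


def write_labels(path: str | Path, labels: pd.DataFrame,
                 seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(seed))
        labels.to_csv(fh, index=False)


def read_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    required = {"epoch_index", "position"}
    if not required <= set(df.columns):
        raise ValueError(f"labels file missing columns {sorted(required - set(df.columns))}")
    return df


def write_fiducials(path: str | Path, beats: list[BeatFiducials],
                    seed: int | None = None) -> None:
    rows = []
    for b in beats:
        row = {n: (MISSING if b.get(n) is None else int(b.get(n)))
               for n in FIDUCIAL_NAMES}
        row["valid"] = int(b.valid)
        rows.append(row)
    df = pd.DataFrame(rows, columns=[*FIDUCIAL_NAMES, "valid"])
    with open(path, "w") as fh:
        fh.write(_provenance(seed))
        df.to_csv(fh, index=False)


def read_fiducials(path: str | Path) -> list[BeatFiducials]:
    df = pd.read_csv(path, comment="#")
    beats = []
    for _, row in df.iterrows():
        kwargs = {n: (None if int(row[n]) == MISSING else int(row[n]))
                  for n in FIDUCIAL_NAMES if n != "R"}
        beats.append(BeatFiducials(R=int(row["R"]),
                                   valid=bool(row.get("valid", 1)), **kwargs))
    return beats


def write_feature_table(path: str | Path, table: pd.DataFrame,
                        seed: int | None = None, config: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(seed, config))
        table.to_csv(fh, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
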