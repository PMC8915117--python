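"""Readers and writers for records, fiducials and feature tables.

Records travel as single-column (or multi-column) CSV of millivolt samples;
fiducial tables and feature tables are CSV with stable headers.  All formats
round-trip losslessly up to float formatting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, FeatureVector
from .fiducials import LANDMARK_NAMES, BeatFiducials

__all__ = [
    "RecordSource",
    "read_record",
    "write_record",
    "write_fiducials",
    "read_fiducials",
    "write_features",
    "read_features",
]


@dataclass(frozen=True)
class RecordSource:
    """A sample file plus how to interpret it."""

    path: str | Path
    fs: float
    channel: int = 0
    fmt: str = "csv"

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("declared sampling rate must be positive")
        if self.fmt != "csv":
            raise ValueError(f"unsupported record format {self.fmt!r} (CSV only)")


def read_record(source: RecordSource) -> tuple[np.ndarray, float]:
    """Load one channel of a CSV record; returns (samples, fs)."""
    path = Path(source.path)
    if not path.exists():
        raise FileNotFoundError(f"record file not found: {path}")
    try:
        df = pd.read_csv(path, header=None, comment="#")
    except Exception as exc:  # malformed file
        raise IOError(f"could not parse record {path}: {exc}") from exc
    if source.channel >= df.shape[1]:
        raise IOError(
            f"record {path} has {df.shape[1]} channel(s); channel "
            f"{source.channel} requested"
        )
    col = df.iloc[:, source.channel]
    # tolerate a header row
    samples = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
    if np.isnan(samples[0]) and len(samples) > 1:
        samples = samples[1:]
    if np.any(np.isnan(samples)):
        raise IOError(f"record {path} contains non-numeric samples")
    return samples, float(source.fs)


def write_record(path: str | Path, samples: np.ndarray) -> None:
    np.savetxt(path, np.asarray(samples, dtype=float), fmt="%.6f")


def write_fiducials(path: str | Path, fiducials: Sequence[BeatFiducials]) -> None:
    """CSV: beat_id, nine index columns, nine amplitude columns, fs."""
    rows = []
    for i, f in enumerate(fiducials):
        row: dict = {"beat_id": i}
        row.update({f"idx_{n}": getattr(f, n) for n in LANDMARK_NAMES})
        row.update({f"amp_{n}": f.amplitudes.get(n, np.nan) for n in LANDMARK_NAMES})
        row["fs"] = f.fs
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_fiducials(path: str | Path) -> list[BeatFiducials]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(
            BeatFiducials(
                **{n: int(row[f"idx_{n}"]) for n in LANDMARK_NAMES},
                amplitudes={n: float(row[f"amp_{n}"]) for n in LANDMARK_NAMES},
                fs=float(row["fs"]),
            )
        )
    return out


def write_features(path: str | Path, features: Sequence[FeatureVector]) -> None:
    from .features import features_to_frame

    features_to_frame(features).to_csv(path, index=False)


def read_features(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Returns (X, y) from a feature CSV written by :func:`write_features`."""
    df = pd.read_csv(path)
    missing = set(FEATURE_NAMES) - set(df.columns)
    if missing or "subject" not in df.columns:
        raise IOError(f"feature file {path} lacks columns: {sorted(missing) or ['subject']}")
    X = df[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = df["subject"].to_numpy()
    return X, y
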