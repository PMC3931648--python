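"""Domain types for accelerometer time series and CSV reading/writing.

The interchange format is deliberately minimal: comma-separated, one header
row, ``.`` decimal mark, UTF-8, with columns ``time,x,y,z[,label]``.
Coordinates are accelerations in g.  Timestamps are metadata only — the
classifier uses (x, y, z) alone — so the ``time`` column may be omitted on
input and is then reconstructed from the sample rate and row index.
No resampling, filtering or calibration is performed on ingest: the method
operates on raw acceleration values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LabeledSample",
    "Dataset",
    "FormatError",
    "read_accel_csv",
    "write_accel_csv",
]


class FormatError(ValueError):
    """Raised when a CSV file violates the accelerometer interchange format."""


@dataclass(frozen=True)
class LabeledSample:
    """One timestamped tri-axial acceleration reading, in g.

    Parameters
    ----------
    t : float
        Time in seconds, non-negative.
    x, y, z : float
        Acceleration along the three orthogonal device axes, in g.
    label : str, optional
        Behaviour name; ``None`` for unlabelled samples.
    """

    t: float
    x: float
    y: float
    z: float
    label: str | None = None

    def __post_init__(self) -> None:
        for name in ("x", "y", "z"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"coordinate {name} must be finite, got {v!r}")
        if self.t < 0 or not math.isfinite(self.t):
            raise ValueError(f"time must be a finite non-negative real, got {self.t!r}")
        if self.label is not None and self.label == "":
            raise ValueError("label, when present, must be a non-empty string")

    @property
    def xyz(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass(frozen=True)
class Dataset:
    """An ordered collection of samples with a common sample rate.

    Training sets must be fully labelled; test sets may be unlabelled or
    carry held-out labels for verification.
    """

    samples: tuple[LabeledSample, ...]
    sample_rate: float
    fully_labeled: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.sample_rate <= 0 or not math.isfinite(self.sample_rate):
            raise ValueError(f"sample_rate must be a positive real, got {self.sample_rate!r}")
        object.__setattr__(self, "samples", tuple(self.samples))
        ts = [s.t for s in self.samples]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ValueError("timestamps must be non-decreasing")
        object.__setattr__(
            self, "fully_labeled", all(s.label is not None for s in self.samples)
        )

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def __getitem__(self, i: int) -> LabeledSample:
        return self.samples[i]

    def coords(self) -> np.ndarray:
        """(n, 3) array of raw accelerations, in g, in row order."""
        return np.array([[s.x, s.y, s.z] for s in self.samples], dtype=float).reshape(-1, 3)

    def labels(self) -> tuple[str | None, ...]:
        return tuple(s.label for s in self.samples)

    def to_frame(self, include_labels: bool = True) -> pd.DataFrame:
        data = {
            "time": [s.t for s in self.samples],
            "x": [s.x for s in self.samples],
            "y": [s.y for s in self.samples],
            "z": [s.z for s in self.samples],
        }
        if include_labels:
            data["label"] = [s.label for s in self.samples]
        return pd.DataFrame(data)


def read_accel_csv(path: str | Path, has_labels: bool, sample_rate: float) -> Dataset:
    """Read an accelerometer CSV into a :class:`Dataset`, preserving row order.

    Parameters
    ----------
    path : path
        CSV file with header ``time,x,y,z[,label]``; ``time`` may be absent,
        in which case timestamps are reconstructed as ``row / sample_rate``.
    has_labels : bool
        Whether to require and read a ``label`` column.
    sample_rate : float
        Sampling frequency in Hz.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    FormatError
        If a required column is missing or a coordinate does not parse as a
        number (the error names the offending data row, 1-based).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("x", "y", "z"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if has_labels and "label" not in df.columns:
        raise FormatError(f"{path}: has_labels=True but no 'label' column present")

    coords = {}
    for col in ("x", "y", "z"):
        raw = df[col]
        vals = np.empty(len(raw), dtype=float)
        for i, s in enumerate(raw):
            # float() round-trips repr-printed values exactly, unlike the
            # default pandas parser
            try:
                v = float(s)
            except (TypeError, ValueError):
                v = math.nan
            if not math.isfinite(v):
                raise FormatError(
                    f"{path}: non-numeric or missing value {s!r} "
                    f"in column {col!r} at data row {i + 1}"
                )
            vals[i] = v
        coords[col] = vals

    n = len(df)
    if "time" in df.columns:
        tvals = pd.to_numeric(df["time"], errors="coerce")
        bad = tvals.index[tvals.isna()]
        if len(bad) > 0:
            raise FormatError(
                f"{path}: non-numeric time value at data row {int(bad[0]) + 1}"
            )
        times = tvals.to_numpy(dtype=float)
    else:
        times = np.arange(n, dtype=float) / sample_rate

    if has_labels:
        rawlab = df["label"]
        missing = rawlab.index[rawlab.isna() | (rawlab.str.strip() == "")]
        if len(missing) > 0:
            raise FormatError(
                f"{path}: empty label at data row {int(missing[0]) + 1}"
            )
        labels: Sequence[str | None] = [str(v).strip() for v in rawlab]
    else:
        labels = [None] * n

    samples = tuple(
        LabeledSample(t=float(times[i]), x=float(coords["x"][i]),
                      y=float(coords["y"][i]), z=float(coords["z"][i]),
                      label=labels[i])
        for i in range(n)
    )
    return Dataset(samples=samples, sample_rate=sample_rate)


def write_accel_csv(dataset: Dataset, path: str | Path, include_labels: bool) -> Path:
    """Write a :class:`Dataset` to CSV; round-trips coordinates and labels.

    Coordinates are written at full float precision so that
    ``read(write(d))`` reproduces them bit-for-bit.

    Raises
    ------
    ValueError
        If the dataset is empty, or ``include_labels`` is requested on a
        partially labelled dataset.
    """
    if len(dataset) == 0:
        raise ValueError("refusing to write an empty dataset")
    if include_labels and not dataset.fully_labeled:
        raise ValueError("include_labels=True requires a fully labelled dataset")
    path = Path(path)
    df = dataset.to_frame(include_labels=include_labels)
    # repr-precision floats guarantee a lossless round trip
    df.to_csv(path, index=False, float_format=None)
    return path
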