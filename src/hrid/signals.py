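"""Sampled exercise-test records and their canonical on-disk format.

A record is one open-loop identification test: a uniformly sampled pair of
time series — input ``u`` (treadmill speed in m/s, or cycle-ergometer work
rate in W) and output ``y`` (heart rate in bpm) — at a fixed sample period
(5 s by default).  On disk a record is a plain CSV with header
``time_s,u,y`` plus a YAML sidecar ``<stem>.meta.yaml`` carrying subject,
test index, modality, units and any preprocessing state (stored means,
detrend coefficients).  The time column is redundant (it is implied by the
sample period) but is required on read for validation of the grid.

Each participant performs two identical tests; :func:`pair_records` groups
records into the pairs used for counterbalanced cross-validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, FormatError, SamplingError

__all__ = [
    "SignalRecord",
    "RecordPair",
    "PairingResult",
    "MODALITIES",
    "read_record",
    "write_record",
    "pair_records",
    "sidecar_path",
]

MODALITIES = ("TM", "CE")
_UNITS = {"TM": "m/s", "CE": "W"}

#: relative tolerance on the uniformity of the time grid
_GRID_RTOL = 1e-6


@dataclass
class SignalRecord:
    """One test's uniformly sampled (u, y) time series with metadata.

    ``u_mean``/``y_mean`` are populated when the record has been put into
    deviation form (means subtracted); ``extras`` carries auxiliary
    preprocessing metadata such as detrend coefficients and round-trips
    through the sidecar file.
    """

    subject_id: str
    test_index: int
    modality: str
    sample_period: float
    u: np.ndarray
    y: np.ndarray
    u_mean: float | None = None
    y_mean: float | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.modality not in MODALITIES:
            raise DataError(f"modality must be one of {MODALITIES}, "
                            f"got {self.modality!r}")
        if self.test_index not in (1, 2):
            raise DataError(f"test_index must be 1 or 2, got {self.test_index}")
        if self.u.ndim != 1 or self.y.ndim != 1:
            raise DataError("u and y must be one-dimensional")
        if len(self.u) != len(self.y):
            raise DataError(f"u and y lengths differ: {len(self.u)} vs {len(self.y)}")
        if len(self.u) < 2:
            raise DataError("a record needs at least 2 samples")
        if self.sample_period <= 0:
            raise DataError("sample_period must be > 0")
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.y))):
            raise DataError("u and y must be finite (no NaN/inf samples)")

    @property
    def n_samples(self) -> int:
        return len(self.u)

    @property
    def duration(self) -> float:
        """Test duration in seconds (n_samples * sample_period)."""
        return self.n_samples * self.sample_period

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.sample_period

    @property
    def input_units(self) -> str:
        return _UNITS[self.modality]

    @property
    def centered(self) -> bool:
        """True when the record is in deviation form (means removed)."""
        return self.u_mean is not None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalRecord):
            return NotImplemented
        return (self.subject_id == other.subject_id
                and self.test_index == other.test_index
                and self.modality == other.modality
                and self.sample_period == other.sample_period
                and np.array_equal(self.u, other.u)
                and np.array_equal(self.y, other.y)
                and self.u_mean == other.u_mean
                and self.y_mean == other.y_mean
                and self.extras == other.extras)


@dataclass(frozen=True)
class RecordPair:
    """A subject's two replicate tests, for counterbalanced cross-validation."""

    subject_id: str
    first: SignalRecord
    second: SignalRecord

    def __post_init__(self) -> None:
        a, b = self.first, self.second
        if a.subject_id != b.subject_id or a.subject_id != self.subject_id:
            raise DataError("pair members must share subject_id")
        if a.modality != b.modality:
            raise DataError(f"pair members of {self.subject_id} differ in modality")
        if a.sample_period != b.sample_period:
            raise DataError(f"pair members of {self.subject_id} differ in "
                            "sample_period")
        if (a.test_index, b.test_index) != (1, 2):
            raise DataError("first must be test 1 and second test 2")

    @property
    def modality(self) -> str:
        return self.first.modality

    @property
    def records(self) -> tuple[SignalRecord, SignalRecord]:
        return (self.first, self.second)


@dataclass(frozen=True)
class PairingResult:
    """Pairs formed from a record collection, plus subjects left unpaired."""

    pairs: tuple[RecordPair, ...]
    unpaired: tuple[str, ...]


def sidecar_path(path: str | Path) -> Path:
    """Path of the YAML metadata sidecar belonging to a record CSV."""
    path = Path(path)
    return path.with_name(path.stem + ".meta.yaml")


def read_record(path: str | Path) -> SignalRecord:
    """Read a record from its CSV + sidecar.

    Raises :class:`FormatError` for missing columns or sidecar keys,
    :class:`SamplingError` for a non-uniform time grid, and
    :class:`DataError` for NaN samples.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - normalise parser failures
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if list(frame.columns) != ["time_s", "u", "y"]:
        raise FormatError(f"{path} must have header 'time_s,u,y', "
                          f"got {list(frame.columns)}")
    if len(frame) < 2:
        raise DataError(f"{path}: a record needs at least 2 samples")

    meta_file = sidecar_path(path)
    if not meta_file.exists():
        raise FormatError(f"missing sidecar {meta_file}")
    meta = yaml.safe_load(meta_file.read_text())
    for key in ("subject_id", "test_index", "modality", "units"):
        if key not in meta:
            raise FormatError(f"{meta_file} lacks required key {key!r}")

    t = frame["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    sample_period = float(meta.get("sample_period_s", dt[0] if len(dt) else 0.0))
    if sample_period <= 0:
        raise SamplingError(f"{path}: non-positive sample period")
    if np.any(np.abs(dt - sample_period) > _GRID_RTOL * sample_period) or \
            abs(t[0]) > _GRID_RTOL * sample_period:
        raise SamplingError(f"{path}: time grid is not uniform at "
                            f"{sample_period} s")

    u = frame["u"].to_numpy(dtype=float)
    y = frame["y"].to_numpy(dtype=float)
    if np.any(~np.isfinite(u)) or np.any(~np.isfinite(y)):
        raise DataError(f"{path}: NaN or infinite samples")

    modality = str(meta["modality"])
    if modality in _UNITS and str(meta["units"]) != _UNITS[modality]:
        raise FormatError(f"{meta_file}: units {meta['units']!r} inconsistent "
                          f"with modality {modality} ({_UNITS.get(modality)})")
    return SignalRecord(
        subject_id=str(meta["subject_id"]),
        test_index=int(meta["test_index"]),
        modality=modality,
        sample_period=sample_period,
        u=u,
        y=y,
        u_mean=None if meta.get("u_mean") is None else float(meta["u_mean"]),
        y_mean=None if meta.get("y_mean") is None else float(meta["y_mean"]),
        extras=dict(meta.get("extras", {})),
    )


def write_record(record: SignalRecord, path: str | Path) -> Path:
    """Write a record as CSV + YAML sidecar such that reading inverts it.

    Floats are written in shortest round-trip representation, so
    ``read_record(write_record(r)) == r`` bit-exactly.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("time_s,u,y\n")
        for t, u, y in zip(record.time, record.u, record.y):
            fh.write(f"{float(t)!r},{float(u)!r},{float(y)!r}\n")
    meta = {
        "subject_id": record.subject_id,
        "test_index": record.test_index,
        "modality": record.modality,
        "units": record.input_units,
        "sample_period_s": record.sample_period,
        "u_mean": record.u_mean,
        "y_mean": record.y_mean,
        "extras": record.extras,
    }
    sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def pair_records(records: Iterable[SignalRecord]) -> PairingResult:
    """Group records into per-subject pairs (test 1, test 2).

    Subjects with exactly one test are excluded and listed in
    ``PairingResult.unpaired``; a duplicate (subject, test_index)
    combination raises :class:`DataError`.
    """
    by_subject: dict[str, dict[int, SignalRecord]] = {}
    order: list[str] = []
    for rec in records:
        tests = by_subject.setdefault(rec.subject_id, {})
        if rec.subject_id not in order:
            order.append(rec.subject_id)
        if rec.test_index in tests:
            raise DataError(f"duplicate record for subject {rec.subject_id} "
                            f"test {rec.test_index}")
        tests[rec.test_index] = rec
    pairs: list[RecordPair] = []
    unpaired: list[str] = []
    for sid in order:
        tests = by_subject[sid]
        if len(tests) == 2:
            pairs.append(RecordPair(sid, tests[1], tests[2]))
        else:
            unpaired.append(sid)
    return PairingResult(tuple(pairs), tuple(unpaired))
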