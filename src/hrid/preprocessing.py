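"""Deviation form, transient trimming and linear detrending of records.

Heart-rate responses are analysed as deviations around mean levels.  Two
optional steps address the slow drift visible during the first minutes of
a test: dropping an initial segment before evaluation, and removing a
least-squares straight line from the heart-rate trace.  The default
profile (:data:`REPLICATION_PROFILE`) centres only; the recommended
profile additionally skips the first 300 s, which covers the observed
drift time scales of roughly 140-180 s.

The pipeline applies steps in the order trim -> centre -> detrend, so
means are always recomputed over the retained evaluation period.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import DataError, DomainError, StateError
from .signals import SignalRecord

__all__ = [
    "PreprocessConfig",
    "REPLICATION_PROFILE",
    "RECOMMENDED_PROFILE",
    "to_deviations",
    "from_deviations",
    "trim_transient",
    "detrend_linear",
    "preprocess",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    """What to do to a record before estimation.

    center : subtract the means of u and y (deviation form)
    skip_initial : seconds to drop from the start of the evaluation period
    detrend : remove a least-squares straight line from y
    """

    center: bool = True
    skip_initial: float = 0.0
    detrend: bool = False

    def __post_init__(self) -> None:
        if self.skip_initial < 0:
            raise DomainError("skip_initial must be >= 0")


#: centre only — the analysis pipeline as originally run
REPLICATION_PROFILE = PreprocessConfig()
#: additionally skip the first 5 minutes, covering the initial drift
RECOMMENDED_PROFILE = PreprocessConfig(skip_initial=300.0)


def to_deviations(record: SignalRecord) -> SignalRecord:
    """Subtract the means of u and y, storing them for inversion."""
    if record.centered:
        raise StateError("record is already in deviation form")
    u_mean = float(np.mean(record.u))
    y_mean = float(np.mean(record.y))
    return replace(record, u=record.u - u_mean, y=record.y - y_mean,
                   u_mean=u_mean, y_mean=y_mean, extras=dict(record.extras))


def from_deviations(record: SignalRecord) -> SignalRecord:
    """Restore absolute units by adding the stored means back."""
    if not record.centered:
        raise StateError("record is not in deviation form")
    return replace(record, u=record.u + record.u_mean,
                   y=record.y + record.y_mean,
                   u_mean=None, y_mean=None, extras=dict(record.extras))


def trim_transient(record: SignalRecord, skip_initial: float) -> SignalRecord:
    """Drop the first ``skip_initial`` seconds from both u and y.

    A skip that is not a multiple of the sample period is rounded up to
    the next sample instant (logged).  Raises :class:`DomainError` when
    nothing (or fewer than 2 samples) would remain.
    """
    if skip_initial < 0:
        raise DomainError("skip_initial must be >= 0")
    if skip_initial == 0:
        return record
    h = record.sample_period
    n_skip = int(math.ceil(skip_initial / h - 1e-9))
    if abs(n_skip * h - skip_initial) > 1e-9 * h:
        log.info("skip_initial %.3f s rounded up to %d samples (%.3f s)",
                 skip_initial, n_skip, n_skip * h)
    if n_skip > record.n_samples - 2:
        raise DomainError(f"skip_initial {skip_initial} s leaves fewer than "
                          f"2 of {record.n_samples} samples")
    extras = dict(record.extras)
    extras["skipped_initial_s"] = float(extras.get("skipped_initial_s", 0.0)
                                        + n_skip * h)
    return replace(record, u=record.u[n_skip:], y=record.y[n_skip:],
                   extras=extras)


def detrend_linear(record: SignalRecord) -> SignalRecord:
    """Remove the least-squares straight line from y.

    The fitted slope (bpm/s) and intercept (bpm) are logged in
    ``extras['detrend']``.  Idempotent up to round-off.  The input u is
    left untouched.
    """
    if record.n_samples < 3:
        raise DataError("detrending needs at least 3 samples")
    t = record.time
    slope, intercept = np.polyfit(t, record.y, 1)
    extras = dict(record.extras)
    extras["detrend"] = {"slope_bpm_per_s": float(slope),
                         "intercept_bpm": float(intercept)}
    return replace(record, y=record.y - (slope * t + intercept), extras=extras)


def preprocess(record: SignalRecord, config: PreprocessConfig) -> SignalRecord:
    """Apply trim -> centre -> detrend as configured.

    Centring always happens after trimming so the stored means refer to
    the retained evaluation period.
    """
    out = record
    if config.skip_initial > 0:
        out = trim_transient(out, config.skip_initial)
    if config.center:
        out = to_deviations(out)
    if config.detrend:
        out = detrend_linear(out)
    return out
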