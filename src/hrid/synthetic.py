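"""Synthetic PRBS exercise tests with a known ground-truth response.

The generator emulates the open-loop identification experiments the
analysis assumes: a pseudo-random binary sequence (PRBS) switches the
exercise intensity between two levels to excite the relevant modes of
heart-rate dynamics, and each simulated participant performs two
identical tests so that counterbalanced cross-validation is possible.

Ground truth follows the two-phase reading of the measured responses: a
parallel connection of a small-gain, slow, undelayed first-order branch
(the initial drift) and a dominant delayed first-order branch (the true
dynamic response), plus white Gaussian measurement noise at the 5 s
sample level.  Cohort truth parameters are drawn around the estimates
obtained on the real treadmill and cycle-ergometer cohorts (fast branch
~20.2 bpm/(m/s), tau ~34.3 s, dead time ~17.9 s for TM; ~0.35 bpm/W,
~37.9 s, ~17.1 s for CE; drift branch gains ~7.0 bpm/(m/s) / ~0.09 bpm/W
with time constants ~141.5 s / ~180.7 s) with +/-20 % uniform jitter.

Everything is reproducible from integer seeds; a pair's two tests share
the truth (and the input sequence) but not the measurement noise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .errors import ConfigurationError, DomainError
from .estimation import ParameterBounds
from .models import PARALLEL, ProcessModel, make_model, simulate
from .signals import RecordPair, SignalRecord

__all__ = [
    "PRBSConfig",
    "SyntheticTruth",
    "Cohort",
    "TRUTH_CENTRES",
    "generate_prbs",
    "generate_record",
    "generate_cohort",
    "write_truth_manifest",
    "read_truth_manifest",
]

log = logging.getLogger(__name__)

#: maximal-length LFSR feedback taps (Fibonacci form, 1-based bit indices)
_LFSR_TAPS = {
    3: (3, 2), 4: (4, 3), 5: (5, 3), 6: (6, 5), 7: (7, 6),
    8: (8, 6, 5, 4), 9: (9, 5), 10: (10, 7), 11: (11, 9),
    12: (12, 11, 10, 4), 13: (13, 12, 11, 8), 14: (14, 13, 12, 2),
    15: (15, 14), 16: (16, 15, 13, 4),
}

#: per-modality truth centres for the parallel two-phase model, input
#: levels, and baseline heart rate used by :func:`generate_cohort`
TRUTH_CENTRES: dict[str, dict] = {
    "TM": {
        "params": {"kp1": 7.0, "taup1": 141.5,
                   "kp2": 20.2, "taup2": 34.3, "Td": 17.9},
        "levels": (1.2, 2.0),        # treadmill speed, m/s
        "baseline_hr": 140.0,
    },
    "CE": {
        "params": {"kp1": 0.09, "taup1": 180.7,
                   "kp2": 0.35, "taup2": 37.9, "Td": 17.1},
        "levels": (75.0, 125.0),     # work rate, W
        "baseline_hr": 120.0,
    },
}


@dataclass(frozen=True)
class PRBSConfig:
    """Design of the binary excitation.

    The shift register advances every ``clock_period`` seconds (which
    must be a whole number of sample periods); the full m-sequence period
    is ``2**register_length - 1`` clock ticks, truncated or repeated to
    fill ``duration``.  The defaults (30 s clock, order 7, 1800 s) put
    the excitation bandwidth around the 30-180 s time constants of
    heart-rate response.
    """

    low_level: float
    high_level: float
    clock_period: float = 30.0
    register_length: int = 7
    sample_period: float = 5.0
    duration: float = 1800.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.register_length not in _LFSR_TAPS:
            raise DomainError("register_length must be in [3, 16]")
        if self.sample_period <= 0 or self.clock_period <= 0:
            raise DomainError("periods must be > 0")
        ratio = self.clock_period / self.sample_period
        if abs(ratio - round(ratio)) > 1e-9:
            raise DomainError("clock_period must be a whole number of "
                              "sample periods")
        if self.duration < self.clock_period:
            raise DomainError("duration must cover at least one clock period")
        if self.low_level > self.high_level:
            raise DomainError("low_level must be <= high_level")
        if self.low_level == self.high_level:
            log.warning("degenerate PRBS: both levels equal %.3g "
                        "(constant input)", self.low_level)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration / self.sample_period))


def _lfsr_bits(register_length: int, n_ticks: int, seed: int) -> np.ndarray:
    """Maximal-length shift-register bit stream; seed picks the initial
    (never all-zero) register state."""
    taps = _LFSR_TAPS[register_length]
    rng = np.random.default_rng(seed)
    state = list(rng.integers(0, 2, size=register_length))
    if not any(state):
        state[0] = 1
    bits = np.empty(n_ticks, dtype=int)
    for t in range(n_ticks):
        bits[t] = state[-1]
        fb = 0
        for tap in taps:
            fb ^= state[tap - 1]
        state = [fb] + state[:-1]
    return bits


def generate_prbs(config: PRBSConfig) -> np.ndarray:
    """Sampled two-level PRBS input, held for each clock period.

    Deterministic given ``config.seed``; the sequence repeats after
    ``2**register_length - 1`` clock ticks.
    """
    spt = int(round(config.clock_period / config.sample_period))
    n = config.n_samples
    n_ticks = -(-n // spt)
    bits = _lfsr_bits(config.register_length, n_ticks, config.seed)
    levels = np.where(bits > 0, config.high_level, config.low_level)
    return np.repeat(levels, spt)[:n].astype(float)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one synthetic subject.

    ``truth_model`` is typically the parallel two-phase structure with a
    small-gain slow drift branch and a delayed fast branch.  An optional
    additive linear ramp (bpm/min) is available to stress the detrending
    stage; it is exogenous, i.e. not part of the input response.
    """

    subject_id: str
    truth_model: ProcessModel
    modality: str
    baseline_hr: float
    noise_sd: float = 2.0
    seed: int = 0
    drift_ramp_bpm_per_min: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be >= 0")


def generate_record(truth: SyntheticTruth, prbs: PRBSConfig,
                    test_index: int,
                    bounds: ParameterBounds | None = None) -> SignalRecord:
    """One synthetic test in absolute units.

    ``y = baseline_hr + response(truth_model, u - mean(u)) + noise``; the
    noise stream is seeded by ``(truth.seed, test_index)`` so the two
    tests of a pair share truth and input but not noise.  Raises
    :class:`ConfigurationError` when the truth model falls outside the
    estimation bounds (which would make recovery experiments ill-posed).
    """
    check = bounds or ParameterBounds.default(truth.modality)
    if not check.contains(truth.truth_model):
        raise ConfigurationError(
            f"truth model for {truth.subject_id} lies outside the "
            f"estimation bounds: {truth.truth_model.free_values()}")
    u = generate_prbs(prbs)
    h = prbs.sample_period
    y = truth.baseline_hr + simulate(truth.truth_model, u - u.mean(), h)
    if truth.drift_ramp_bpm_per_min:
        y = y + truth.drift_ramp_bpm_per_min * np.arange(len(u)) * h / 60.0
    if truth.noise_sd > 0:
        rng = np.random.default_rng([truth.seed, test_index])
        y = y + rng.normal(0.0, truth.noise_sd, size=len(u))
    return SignalRecord(subject_id=truth.subject_id, test_index=test_index,
                        modality=truth.modality, sample_period=h,
                        u=u, y=y)


@dataclass(frozen=True)
class Cohort:
    """A generated cohort: record pairs plus the truth behind each subject."""

    pairs: tuple[RecordPair, ...]
    truths: dict[str, SyntheticTruth] = field(default_factory=dict)
    prbs: dict[str, PRBSConfig] = field(default_factory=dict)

    @property
    def records(self) -> list[SignalRecord]:
        out: list[SignalRecord] = []
        for pair in self.pairs:
            out.extend(pair.records)
        return out


def generate_cohort(n_subjects: int, modality: str = "TM", seed: int = 0,
                    noise_sd: float = 2.0, jitter: float = 0.2,
                    prbs: PRBSConfig | None = None) -> Cohort:
    """A cohort of paired tests with per-subject jittered truth.

    Each subject's parallel-model truth is drawn with independent uniform
    ``+/- jitter`` (default 20 %) factors around the modality's centres in
    :data:`TRUTH_CENTRES`; two records per subject share input and truth
    but have independent measurement noise.  Fully reproducible from
    ``seed``.
    """
    if n_subjects < 1:
        raise DomainError("n_subjects must be >= 1")
    if modality not in TRUTH_CENTRES:
        raise DomainError(f"modality must be one of {list(TRUTH_CENTRES)}")
    centre = TRUTH_CENTRES[modality]
    base_prbs = prbs or PRBSConfig(low_level=centre["levels"][0],
                                   high_level=centre["levels"][1])
    pairs: list[RecordPair] = []
    truths: dict[str, SyntheticTruth] = {}
    prbs_map: dict[str, PRBSConfig] = {}
    for i in range(n_subjects):
        rng = np.random.default_rng([seed, i])
        params = {name: value * rng.uniform(1.0 - jitter, 1.0 + jitter)
                  for name, value in centre["params"].items()}
        truth = SyntheticTruth(
            subject_id=f"{modality}{i + 1:02d}",
            truth_model=make_model(PARALLEL, params),
            modality=modality,
            baseline_hr=centre["baseline_hr"],
            noise_sd=noise_sd,
            seed=int(rng.integers(2**31 - 1)),
        )
        subj_prbs = replace(base_prbs, seed=int(rng.integers(2**31 - 1)))
        rec1 = generate_record(truth, subj_prbs, 1)
        rec2 = generate_record(truth, subj_prbs, 2)
        pairs.append(RecordPair(truth.subject_id, rec1, rec2))
        truths[truth.subject_id] = truth
        prbs_map[truth.subject_id] = subj_prbs
    return Cohort(tuple(pairs), truths, prbs_map)


# ---------------------------------------------------------------------------
# truth manifests (for recovery scoring of serialized cohorts)
# ---------------------------------------------------------------------------

def write_truth_manifest(truths: Mapping[str, SyntheticTruth],
                         path: str | Path) -> Path:
    path = Path(path)
    payload = {
        sid: {
            "structure": t.truth_model.structure,
            "parameters": {k: float(v)
                           for k, v in t.truth_model.free_values().items()},
            "modality": t.modality,
            "baseline_hr": float(t.baseline_hr),
            "noise_sd": float(t.noise_sd),
            "seed": int(t.seed),
            "drift_ramp_bpm_per_min": float(t.drift_ramp_bpm_per_min),
        }
        for sid, t in truths.items()
    }
    path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return path


def read_truth_manifest(path: str | Path) -> dict[str, SyntheticTruth]:
    payload = yaml.safe_load(Path(path).read_text())
    out: dict[str, SyntheticTruth] = {}
    for sid, entry in payload.items():
        out[sid] = SyntheticTruth(
            subject_id=sid,
            truth_model=make_model(entry["structure"], entry["parameters"]),
            modality=entry["modality"],
            baseline_hr=float(entry["baseline_hr"]),
            noise_sd=float(entry["noise_sd"]),
            seed=int(entry["seed"]),
            drift_ramp_bpm_per_min=float(
                entry.get("drift_ramp_bpm_per_min", 0.0)),
        )
    return out
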