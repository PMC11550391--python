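"""Bounded least-squares estimation of process models from exercise records.

The free parameters of a chosen structure are estimated by minimising the
sum of squared differences between the measured heart-rate deviations and
the simulated model output, subject to box constraints that keep the
search in physiologically plausible ranges.  Dead time is a continuous
decision variable inside the search (not a grid over whole-sample
delays); the resulting local minima are mitigated by a multi-start
scheme: one start at the midpoint of the bounds plus seeded random draws
(log-uniform for time constants and dead time, uniform for gains and the
zero).

Goodness of fit is the NRMSE-based percentage

    fit = 100 * (1 - ||y - ysim||_2 / ||y - mean(y)||_2)

so 100 % is a perfect reproduction, 0 % is no better than the mean, and
negative values are worse than the mean.  A sum-of-squares variant is
available via ``fit_formula="ssq"``.

Counterbalanced cross-validation pairs a subject's two replicate tests:
the model estimated on one test is simulated against the other test's
input and scored against its measured output, and vice versa.

The central object is :class:`ProcessModelRegressor`, a scikit-learn
style estimator (``fit``/``predict``/``score``, ``get_params``); the
module-level functions :func:`fit_model` and :func:`cross_validate` are
thin wrappers over it operating on :class:`~hrid.signals.SignalRecord`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .errors import (ConvergenceError, DomainError, ExcitationError,
                     StateError)
from .models import (PARALLEL, STRUCTURES, ProcessModel, make_model,
                     n_states, simulate)
from .signals import RecordPair, SignalRecord

__all__ = [
    "ParameterBounds",
    "OptimizerOptions",
    "FitResult",
    "ProcessModelRegressor",
    "compute_fit",
    "fit_model",
    "cross_validate",
]

#: default physiologically plausible ranges; gains depend on modality
_DEFAULT_RANGES = {
    "tau": (1.0, 600.0),
    "Td": (0.0, 60.0),
    "Tz": (-120.0, 120.0),
    "gain": {"TM": (0.0, 100.0), "CE": (0.0, 2.0)},
}
_GAIN_PARAMS = ("k", "kp1", "kp2")
_TAU_PARAMS = ("tau1", "tau2", "taup1", "taup2")


@dataclass(frozen=True)
class ParameterBounds:
    """Per-parameter box constraints in physical units."""

    bounds: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise DomainError(f"bound for {name}: lower {lo} must be "
                                  f"< upper {hi}")

    @classmethod
    def default(cls, modality: str = "TM") -> "ParameterBounds":
        """Defaults: tau in [1, 600] s, Td in [0, 60] s, Tz in [-120, 120] s,
        gains in [0, 100] bpm/(m/s) for TM or [0, 2] bpm/W for CE."""
        gain = _DEFAULT_RANGES["gain"][modality]
        b: dict[str, tuple[float, float]] = {}
        for p in _GAIN_PARAMS:
            b[p] = gain
        for p in _TAU_PARAMS:
            b[p] = _DEFAULT_RANGES["tau"]
        b["Td"] = _DEFAULT_RANGES["Td"]
        b["Tz"] = _DEFAULT_RANGES["Tz"]
        return cls(b)

    @classmethod
    def from_dict(cls, mapping: Mapping[str, Sequence[float]],
                  modality: str = "TM") -> "ParameterBounds":
        """Defaults for ``modality`` overridden by the given entries."""
        base = dict(cls.default(modality).bounds)
        for name, pair in mapping.items():
            base[name] = (float(pair[0]), float(pair[1]))
        return cls(base)

    def arrays(self, names: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.bounds[n][0] for n in names])
        hi = np.array([self.bounds[n][1] for n in names])
        return lo, hi

    def contains(self, model: ProcessModel) -> bool:
        for name, value in model.free_values().items():
            lo, hi = self.bounds[name]
            if not lo <= value <= hi:
                return False
        return True


@dataclass(frozen=True)
class OptimizerOptions:
    """Multi-start bounded least-squares settings.

    ``max_nfev`` caps objective evaluations per start; ``ftol`` is the
    relative decrease tolerance on the objective.  ``estimate_x0`` adds
    the simulator's initial modal states as extra free parameters
    (default off: estimation runs on deviation-form data from rest).
    """

    n_starts: int = 10
    seed: int = 0
    max_nfev: int = 500
    ftol: float = 1e-10
    fit_formula: str = "rms"
    estimate_x0: bool = False

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise DomainError("n_starts must be >= 1")
        if self.fit_formula not in ("rms", "ssq"):
            raise DomainError("fit_formula must be 'rms' or 'ssq'")


@dataclass
class FitResult:
    """Outcome of estimating one structure on one record."""

    model: ProcessModel
    fit_estimation: float
    residuals: np.ndarray
    n_starts_converged: int
    objective: float
    ysim: np.ndarray
    ybar: float
    N: int
    seed: int
    fit_validation: float | None = None
    initial_state: np.ndarray | None = None
    record_id: str | None = None
    modality: str | None = None

    @property
    def structure(self) -> str:
        return self.model.structure

    def to_dict(self) -> dict:
        """JSON-serialisable summary with full provenance."""
        return {
            "structure": self.structure,
            "parameters": {k: float(v)
                           for k, v in self.model.free_values().items()},
            "fit_estimation_pct": float(self.fit_estimation),
            "fit_validation_pct": (None if self.fit_validation is None
                                   else float(self.fit_validation)),
            "objective_ssr": float(self.objective),
            "n_starts_converged": int(self.n_starts_converged),
            "N": int(self.N),
            "seed": int(self.seed),
            "record_id": self.record_id,
            "modality": self.modality,
            "initial_state": (None if self.initial_state is None
                              else [float(v) for v in self.initial_state]),
        }


def compute_fit(y: Sequence[float], ysim: Sequence[float],
                formula: str = "rms") -> float:
    """NRMSE-based fit percentage.

    ``rms`` (default): ``100 * (1 - ||y-ysim|| / ||y-ybar||)``;
    ``ssq``: the same with both norms squared.  Raises
    :class:`DomainError` when y is constant (the normaliser vanishes).
    """
    y = np.asarray(y, dtype=float)
    ysim = np.asarray(ysim, dtype=float)
    if y.shape != ysim.shape or y.ndim != 1:
        raise DomainError("y and ysim must be 1-d arrays of equal length")
    if len(y) < 2:
        raise DomainError("fit needs at least 2 samples")
    denom = float(np.linalg.norm(y - y.mean()))
    if denom == 0.0:
        raise DomainError("fit is undefined for constant y")
    err = float(np.linalg.norm(y - ysim))
    if formula == "rms":
        return 100.0 * (1.0 - err / denom)
    if formula == "ssq":
        return 100.0 * (1.0 - (err / denom) ** 2)
    raise DomainError(f"unknown fit formula {formula!r}")


def _canonicalize(model: ProcessModel) -> ProcessModel:
    """Report exchangeable pole pairs with tau1 <= tau2."""
    if "tau2" in model.free_parameters and model.tau1 > model.tau2:
        return replace(model, tau1=model.tau2, tau2=model.tau1)
    return model


class ProcessModelRegressor(RegressorMixin, BaseEstimator):
    """Scikit-learn style estimator for one process-model structure.

    ``X`` is the exercise-intensity input as a single-column array (or a
    1-d array) sampled at ``sample_period``; ``y`` is the heart rate at
    the same instants.  Both are expected in deviation (zero-mean) form.
    After ``fit``, the estimated :class:`~hrid.models.ProcessModel` is in
    ``model_`` and the NRMSE fit percentage in ``fit_percent_``.

    Parameters
    ----------
    structure : one of P1, P1D, P2, P2D, P2Z, P2ZD, P1parP1D
    sample_period : seconds between samples (default 5.0)
    bounds : ParameterBounds or None (defaults for ``modality``)
    modality : "TM" or "CE"; selects default gain bounds
    n_starts, seed, max_nfev, ftol, fit_formula, estimate_x0 :
        see :class:`OptimizerOptions`
    center_sim : express the simulated output as deviations around its
        own mean over the evaluation period before comparing with the
        (deviation-form) data.  This matches the deviation representation
        of the measurements and makes the estimate invariant to output
        offsets; on by default.
    extra_starts : optional list of name->value maps used as additional
        deterministic starting points (e.g. a nested structure's solution)
    """

    def __init__(self, structure: str = "P1D", sample_period: float = 5.0,
                 bounds: ParameterBounds | None = None, modality: str = "TM",
                 n_starts: int = 10, seed: int = 0, max_nfev: int = 500,
                 ftol: float = 1e-10, fit_formula: str = "rms",
                 estimate_x0: bool = False, center_sim: bool = True,
                 extra_starts: Sequence[Mapping[str, float]] | None = None):
        self.structure = structure
        self.sample_period = sample_period
        self.bounds = bounds
        self.modality = modality
        self.n_starts = n_starts
        self.seed = seed
        self.max_nfev = max_nfev
        self.ftol = ftol
        self.fit_formula = fit_formula
        self.estimate_x0 = estimate_x0
        self.center_sim = center_sim
        self.extra_starts = extra_starts

    # -- internal helpers ---------------------------------------------------

    def _validate_u(self, X) -> np.ndarray:
        X = check_array(np.asarray(X, dtype=float).reshape(-1, 1)
                        if np.ndim(X) == 1 else X, ensure_2d=True)
        if X.shape[1] != 1:
            raise DomainError("X must have exactly one column (the input u)")
        return X[:, 0]

    def _start_points(self, names, lo, hi, n_extra_states):
        rng = np.random.default_rng(self.seed)
        starts = [0.5 * (lo + hi)]
        for params in (self.extra_starts or ()):
            theta = np.array([float(params[n]) for n in names[:len(names)
                                                             - n_extra_states]])
            if n_extra_states:
                theta = np.concatenate([theta, np.zeros(n_extra_states)])
            starts.append(np.clip(theta, lo, hi))
        while len(starts) < self.n_starts + len(self.extra_starts or ()):
            theta = np.empty(len(names))
            for i, name in enumerate(names):
                if name in _TAU_PARAMS or name == "Td":
                    lo_pos = max(lo[i], 0.5)
                    theta[i] = math.exp(rng.uniform(math.log(lo_pos),
                                                    math.log(hi[i])))
                    theta[i] = min(max(theta[i], lo[i]), hi[i])
                else:
                    theta[i] = rng.uniform(lo[i], hi[i])
            starts.append(theta)
        return starts

    # -- scikit-learn API ---------------------------------------------------

    def fit(self, X, y) -> "ProcessModelRegressor":
        if self.structure not in STRUCTURES:
            raise DomainError(f"unknown structure {self.structure!r}")
        u = self._validate_u(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != len(u):
            raise DomainError("X and y lengths differ")
        if len(y) < 2:
            raise DomainError("need at least 2 samples")
        if np.ptp(u) == 0.0:
            raise ExcitationError("input u is constant: no excitation to "
                                  "identify dynamics from")

        names = list(STRUCTURES[self.structure].free_parameters)
        bounds = self.bounds or ParameterBounds.default(self.modality)
        lo, hi = bounds.arrays(names)
        h = float(self.sample_period)

        nx = 0
        if self.estimate_x0:
            # number of modal states at a representative (all-poles-active)
            # parameter point of this structure
            nx = 2 if ("tau2" in names or self.structure == PARALLEL) else 1
            span = 2.0 * float(np.max(np.abs(u))) + 1.0
            names = names + [f"x0_{i}" for i in range(nx)]
            lo = np.concatenate([lo, -span * np.ones(nx)])
            hi = np.concatenate([hi, span * np.ones(nx)])

        n_par = len(names) - nx

        def build(theta):
            model = make_model(self.structure,
                               dict(zip(names[:n_par], theta[:n_par])))
            x0 = theta[n_par:] if nx else None
            if x0 is not None and len(x0) != n_states(model):
                x0 = x0[:n_states(model)]
            return model, x0

        def sim_out(model, x0):
            ysim = simulate(model, u, h, initial_state=x0)
            return ysim - ysim.mean() if self.center_sim else ysim

        def residual(theta):
            model, x0 = build(theta)
            return sim_out(model, x0) - y

        best = None
        n_converged = 0
        for theta0 in self._start_points(names, lo, hi, nx):
            try:
                sol = least_squares(residual, theta0, bounds=(lo, hi),
                                    method="trf", ftol=self.ftol,
                                    xtol=1e-12, gtol=1e-12,
                                    max_nfev=self.max_nfev,
                                    x_scale=np.maximum(hi - lo, 1.0) / 10.0)
            except Exception:  # noqa: BLE001 - a failed start is not fatal
                continue
            if sol.status > 0:
                n_converged += 1
            ssr = float(2.0 * sol.cost)
            if best is None or ssr < best[0]:
                best = (ssr, sol)
        if best is None or n_converged == 0:
            raise ConvergenceError(
                f"no start converged for {self.structure} "
                f"({self.n_starts} starts, max_nfev={self.max_nfev})")

        ssr, sol = best
        model, x0 = build(sol.x)
        model = _canonicalize(model)
        ysim = sim_out(model, x0)
        self.model_ = model
        self.params_ = model.free_values()
        self.initial_state_ = None if x0 is None else np.asarray(x0)
        self.fit_percent_ = compute_fit(y, ysim, self.fit_formula)
        self.result_ = FitResult(
            model=model,
            fit_estimation=self.fit_percent_,
            residuals=y - ysim,
            n_starts_converged=n_converged,
            objective=float(np.sum((y - ysim) ** 2)),
            ysim=ysim,
            ybar=float(np.mean(y)),
            N=len(y),
            seed=self.seed,
            initial_state=self.initial_state_,
        )
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        u = self._validate_u(X)
        ysim = simulate(self.model_, u, float(self.sample_period))
        return ysim - ysim.mean() if self.center_sim else ysim

    def score(self, X, y, sample_weight=None) -> float:
        """NRMSE fit as a fraction (1.0 = perfect), overriding R^2."""
        return compute_fit(np.asarray(y, dtype=float).ravel(),
                           self.predict(X), self.fit_formula) / 100.0


# ---------------------------------------------------------------------------
# record-level wrappers
# ---------------------------------------------------------------------------

def _record_id(record: SignalRecord) -> str:
    return f"{record.subject_id}/t{record.test_index}"


def fit_model(record: SignalRecord, structure_name: str,
              bounds: ParameterBounds | None = None,
              options: OptimizerOptions | None = None,
              extra_starts: Sequence[Mapping[str, float]] | None = None
              ) -> FitResult:
    """Estimate one structure's parameters from a deviation-form record."""
    if not record.centered:
        raise StateError("record must be preprocessed to deviation form "
                         "before estimation (see hrid.preprocessing)")
    opts = options or OptimizerOptions()
    reg = ProcessModelRegressor(
        structure=structure_name, sample_period=record.sample_period,
        bounds=bounds, modality=record.modality, n_starts=opts.n_starts,
        seed=opts.seed, max_nfev=opts.max_nfev, ftol=opts.ftol,
        fit_formula=opts.fit_formula, estimate_x0=opts.estimate_x0,
        extra_starts=extra_starts)
    reg.fit(record.u.reshape(-1, 1), record.y)
    result = reg.result_
    result.record_id = _record_id(record)
    result.modality = record.modality
    return result


def cross_validate(pair: RecordPair, structure_name: str,
                   bounds: ParameterBounds | None = None,
                   options: OptimizerOptions | None = None
                   ) -> tuple[FitResult, FitResult]:
    """Counterbalanced cross-validation over a subject's two tests.

    The model estimated on the first record is simulated against the
    second record's input and scored against its measured output (that
    model's ``fit_validation``), and vice versa.  Estimation failures are
    annotated with the record that caused them.
    """
    opts = options or OptimizerOptions()
    results = []
    for train, test in ((pair.first, pair.second), (pair.second, pair.first)):
        if not test.centered:
            raise StateError(f"record {_record_id(test)} must be in "
                             "deviation form")
        try:
            res = fit_model(train, structure_name, bounds, opts)
        except ConvergenceError as exc:
            raise ConvergenceError(
                f"estimation failed on record {_record_id(train)}: {exc}"
            ) from exc
        ysim_val = simulate(res.model, test.u, test.sample_period)
        # deviation representation: compare the simulated output as
        # deviations around its own mean, like the measured data
        ysim_val = ysim_val - ysim_val.mean()
        res.fit_validation = compute_fit(test.y, ysim_val, opts.fit_formula)
        results.append(res)
    return results[0], results[1]
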