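"""Continuous-time process models of heart-rate response to exercise intensity.

The transfer-function family is

    Po(s) = k (Tz s + 1) / ((tau1 s + 1)(tau2 s + 1)) * exp(-Td s)

with steady-state gain ``k`` (bpm per m/s on a treadmill, bpm per W on a
cycle ergometer), real poles at ``-1/tau1`` and ``-1/tau2``, an optional
zero at ``-1/Tz`` (sign-free) and a pure dead time ``Td``.  Constraining
subsets of the parameters to zero yields the six nested structures P1,
P1D, P2, P2D, P2Z and P2ZD; the seventh structure, ``P1parP1D``, is the
classical two-phase form: a parallel connection of an undelayed
first-order branch (slow, low-gain "drift"/Phase-I surrogate) and a
delayed first-order branch (the dominant Phase-II response).

Simulation is exact for zero-order-hold inputs: the held input's switch
times, shifted by the dead time, partition each sampling interval into at
most two constant-input sub-intervals, and the state is propagated across
each sub-interval with closed-form (scalar or Jordan-block) matrix
exponentials.  The zero is realised through the modal output map, never by
differentiating the sampled signal, and a repeated pole pair uses the
analytic repeated-root propagator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import lfilter

from .errors import DomainError, ParameterError

__all__ = [
    "ModelStructure",
    "ProcessModel",
    "STRUCTURES",
    "STRUCTURE_ORDER",
    "PARALLEL",
    "make_model",
    "simulate",
    "step_response",
    "dc_gain",
    "n_states",
]

#: relative tolerance below which a pole pair is treated as repeated
_TIE_REL_TOL = 1e-9
#: absolute tolerance (in units of one sample period) for snapping the
#: fractional part of the dead time onto the sampling grid
_GRID_SNAP = 1e-9


@dataclass(frozen=True)
class ModelStructure:
    """A named model structure and its ordered free parameters."""

    name: str
    free_parameters: tuple[str, ...]


PARALLEL = "P1parP1D"

STRUCTURE_ORDER: tuple[str, ...] = (
    "P1", "P1D", "P2", "P2D", "P2Z", "P2ZD", PARALLEL,
)

STRUCTURES: dict[str, ModelStructure] = {
    "P1": ModelStructure("P1", ("k", "tau1")),
    "P1D": ModelStructure("P1D", ("k", "tau1", "Td")),
    "P2": ModelStructure("P2", ("k", "tau1", "tau2")),
    "P2D": ModelStructure("P2D", ("k", "tau1", "tau2", "Td")),
    "P2Z": ModelStructure("P2Z", ("k", "tau1", "tau2", "Tz")),
    "P2ZD": ModelStructure("P2ZD", ("k", "tau1", "tau2", "Tz", "Td")),
    PARALLEL: ModelStructure(PARALLEL, ("kp1", "taup1", "kp2", "taup2", "Td")),
}

_NONNEGATIVE = ("tau1", "tau2", "taup1", "taup2", "Td")


@dataclass(frozen=True)
class ProcessModel:
    """A structure identifier plus concrete parameter values.

    Parameters not free in the structure are held at zero (their
    constraint value).  Time constants and the dead time are in seconds;
    gains are in output units per input unit.  ``Tz`` may be negative
    (non-minimum-phase response).
    """

    structure: str
    k: float = 0.0
    tau1: float = 0.0
    tau2: float = 0.0
    Tz: float = 0.0
    Td: float = 0.0
    kp1: float = 0.0
    taup1: float = 0.0
    kp2: float = 0.0
    taup2: float = 0.0

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise ParameterError(f"unknown structure {self.structure!r}")
        for name in _NONNEGATIVE:
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0, got {getattr(self, name)}")

    @property
    def free_parameters(self) -> tuple[str, ...]:
        return STRUCTURES[self.structure].free_parameters

    def free_values(self) -> dict[str, float]:
        """The structure's free parameters as an ordered name->value map."""
        return {p: getattr(self, p) for p in self.free_parameters}


def make_model(structure_name: str, params: Mapping[str, float]) -> ProcessModel:
    """Build a validated :class:`ProcessModel`.

    ``params`` must supply exactly the structure's free parameters; all
    constrained parameters are held at zero.

    Raises
    ------
    ParameterError
        for an unknown structure or a missing/extra parameter.
    DomainError
        for a negative time constant or dead time.
    """
    if structure_name not in STRUCTURES:
        raise ParameterError(f"unknown structure {structure_name!r}; "
                             f"choose from {sorted(STRUCTURES)}")
    free = STRUCTURES[structure_name].free_parameters
    missing = set(free) - set(params)
    extra = set(params) - set(free)
    if missing or extra:
        raise ParameterError(
            f"{structure_name} takes exactly {free}; "
            f"missing={sorted(missing)} extra={sorted(extra)}")
    return ProcessModel(structure=structure_name,
                        **{p: float(params[p]) for p in free})


def dc_gain(model: ProcessModel) -> float:
    """Steady-state gain: output change per unit sustained input change."""
    if model.structure == PARALLEL:
        return model.kp1 + model.kp2
    return model.k


def n_states(model: ProcessModel) -> int:
    """Number of internal (modal) states of the simulator for this model."""
    if model.structure == PARALLEL:
        return int(model.taup1 > 0) + int(model.taup2 > 0)
    return int(model.tau1 > 0) + int(model.tau2 > 0)


# ---------------------------------------------------------------------------
# exact ZOH simulation
# ---------------------------------------------------------------------------

def _split_delay(Td: float, h: float) -> tuple[int, float]:
    """Dead time as ``m`` whole samples plus a fractional remainder ``r``.

    ``r`` is snapped to 0 when Td falls on the sampling grid to within
    1e-9 of a sample period (avoids spurious sub-intervals).
    """
    m = int(math.floor(Td / h + _GRID_SNAP))
    r = Td - m * h
    if r < _GRID_SNAP * h:
        r = 0.0
    return m, r


def _shift(u: np.ndarray, m: int) -> np.ndarray:
    """The sequence ``u`` delayed by ``m`` whole samples, zero-padded."""
    if m <= 0:
        return u
    out = np.zeros_like(u)
    if m < len(u):
        out[m:] = u[:-m]
    return out


def _first_order_state(tau: float, u: np.ndarray, h: float, m: int, r: float,
                       x0: float = 0.0) -> np.ndarray:
    """State of a unit-DC first-order lag driven by u delayed by m*h + r.

    The state x obeys  tau x' = u_d - x  and is returned at the sample
    instants.  Exact for piecewise-constant u_d; the fractional delay r
    splits each sampling interval into two constant-input pieces.
    """
    b_in = _shift(u, m)
    if r > 0.0:
        a_in = _shift(u, m + 1)
        e_r = math.exp(-r / tau)
        e_hr = math.exp(-(h - r) / tau)
        F = e_r * e_hr
        g1 = e_hr * (1.0 - e_r)     # input active on [jh, jh+r)
        g2 = 1.0 - e_hr             # input active on [jh+r, (j+1)h)
        x = lfilter([0.0, g1], [1.0, -F], a_in)
        x += lfilter([0.0, g2], [1.0, -F], b_in)
    else:
        F = math.exp(-h / tau)
        x = lfilter([0.0, 1.0 - F], [1.0, -F], b_in)
    if x0 != 0.0:
        x += x0 * F ** np.arange(len(u))
    return x


def _jordan_states(tau: float, u: np.ndarray, h: float, m: int, r: float,
                   x0: Sequence[float] | None = None) -> np.ndarray:
    """States of the repeated-pole chain x2 = u_d/(tau s+1), x1 = x2/(tau s+1).

    Uses the analytic repeated-root propagator
    ``exp(A t) = e^(-t/tau) [[1, t/tau], [0, 1]]`` for the Jordan block; no
    eigen-decomposition and no perturbation of the tied poles.  Returns an
    (N, 2) array of [x1, x2] at the sample instants.
    """

    def prop(dt: float) -> tuple[np.ndarray, np.ndarray]:
        e = math.exp(-dt / tau)
        Ad = np.array([[e, e * dt / tau], [0.0, e]])
        Bd = np.array([1.0 - e * (1.0 + dt / tau), 1.0 - e])
        return Ad, Bd

    N = len(u)
    if r > 0.0:
        A1, B1 = prop(r)
        A2, B2 = prop(h - r)
        F = A2 @ A1
        G = np.column_stack([A2 @ B1, B2])
        U = np.stack([_shift(u, m + 1), _shift(u, m)])
    else:
        F, B = prop(h)
        G = B[:, None]
        U = _shift(u, m)[None, :]

    # x[j+1] = F x[j] + G U[:, j]  ->  per-state second-order recursion
    den = np.array([1.0, -(F[0, 0] + F[1, 1]),
                    F[0, 0] * F[1, 1] - F[0, 1] * F[1, 0]])
    x = np.zeros((N, 2))
    for i in range(G.shape[1]):
        g = G[:, i]
        # numerator of C (zI - F)^{-1} g for C = e_row
        # (zI-F)^{-1} = adj/det;  adj = [[z-F11, F01], [F10, z-F00]]
        num1 = np.array([0.0, g[0], F[0, 1] * g[1] - F[1, 1] * g[0]])
        num2 = np.array([0.0, g[1], F[1, 0] * g[0] - F[0, 0] * g[1]])
        x[:, 0] += lfilter(num1, den, U[i])
        x[:, 1] += lfilter(num2, den, U[i])
    if x0 is not None and np.any(np.asarray(x0) != 0.0):
        x0 = np.asarray(x0, dtype=float)
        t = np.arange(N) * h
        decay = np.exp(-t / tau)
        x[:, 0] += decay * (x0[0] + x0[1] * t / tau)
        x[:, 1] += decay * x0[1]
    return x


def _po_response(k: float, tau1: float, tau2: float, Tz: float, Td: float,
                 u: np.ndarray, h: float,
                 x0: Sequence[float] | None = None) -> np.ndarray:
    """Exact sampled response of k(Tz s+1)/((tau1 s+1)(tau2 s+1)) e^(-Td s)."""
    m, r = _split_delay(Td, h)
    ta, tb = sorted((tau1, tau2))
    x0 = None if x0 is None else np.atleast_1d(np.asarray(x0, dtype=float))

    if tb <= 0.0:
        # no poles: static gain (a bare zero would be improper under ZOH)
        if Tz != 0.0:
            raise DomainError("a zero with no poles is improper; "
                              "set Tz=0 when both time constants are 0")
        u_d = _shift(u, m + 1) if r > 0.0 else _shift(u, m)
        return k * u_d

    if ta <= 0.0:
        # single pole tb, possibly with a zero: proper first order
        D = k * Tz / tb
        c = k * (1.0 - Tz / tb)
        x = _first_order_state(tb, u, h, m, r,
                               x0=float(x0[0]) if x0 is not None else 0.0)
        y = c * x
        if D != 0.0:
            u_d = _shift(u, m + 1) if r > 0.0 else _shift(u, m)
            y = y + D * u_d
        return y

    if abs(tb - ta) <= _TIE_REL_TOL * tb:
        # repeated pole: Jordan chain with modal output map
        tau = 0.5 * (ta + tb)
        x = _jordan_states(tau, u, h, m, r, x0=x0)
        C = np.array([k * (1.0 - Tz / tau), k * Tz / tau])
        return x @ C

    # two distinct poles: partial fractions into two scalar modes
    c_a = k * (Tz - ta) / (tb - ta)
    c_b = k * (tb - Tz) / (tb - ta)
    xa0 = float(x0[0]) if x0 is not None else 0.0
    xb0 = float(x0[1]) if x0 is not None else 0.0
    return (c_a * _first_order_state(ta, u, h, m, r, x0=xa0)
            + c_b * _first_order_state(tb, u, h, m, r, x0=xb0))


def simulate(model: ProcessModel, u: Sequence[float], sample_period: float,
             initial_state: Sequence[float] | None = None) -> np.ndarray:
    """Sampled continuous-time response to a zero-order-held input.

    The input ``u`` is held constant over each sampling interval
    ``[j h, (j+1) h)`` and assumed zero before t=0 (deviation form).  The
    returned array is the exact response of the transfer function, delayed
    by the model's dead time, evaluated at the sample instants — computed
    by propagating the modal state across the constant-input sub-intervals
    created when the delayed switch times fall off-grid.

    Parameters
    ----------
    model : ProcessModel
    u : array-like of input samples
    sample_period : seconds between samples (must be > 0)
    initial_state : optional modal state at t=0.  Length must equal
        :func:`n_states`.  Each modal state is the output of a unit-DC
        first-order lag (for a repeated pole pair, the Jordan chain
        [x1, x2]); for the parallel structure, branch-1 state then
        branch-2 state.  ``None`` means rest (all zeros).
    """
    u = np.asarray(u, dtype=float)
    if u.ndim != 1:
        raise DomainError("input u must be one-dimensional")
    if sample_period <= 0:
        raise DomainError("sample_period must be > 0")
    if initial_state is not None:
        initial_state = np.atleast_1d(np.asarray(initial_state, dtype=float))
        if len(initial_state) != n_states(model):
            raise DomainError(
                f"initial_state must have length {n_states(model)} "
                f"for {model.structure}")

    if model.structure == PARALLEL:
        nx1 = int(model.taup1 > 0)
        x0_1 = x0_2 = None
        if initial_state is not None:
            x0_1 = initial_state[:nx1] if nx1 else None
            x0_2 = initial_state[nx1:] if len(initial_state) > nx1 else None
        y1 = _po_response(model.kp1, model.taup1, 0.0, 0.0, 0.0,
                          u, sample_period, x0=x0_1)
        y2 = _po_response(model.kp2, model.taup2, 0.0, 0.0, model.Td,
                          u, sample_period, x0=x0_2)
        return y1 + y2

    return _po_response(model.k, model.tau1, model.tau2, model.Tz, model.Td,
                        u, sample_period, x0=initial_state)


def step_response(model: ProcessModel, amplitude: float, horizon: float,
                  sample_period: float) -> np.ndarray:
    """Response to a step of the given amplitude applied at t=0.

    Convenience over :func:`simulate`; the final value approaches
    ``amplitude * dc_gain(model)`` as the horizon grows.
    """
    if horizon <= 0:
        raise DomainError("horizon must be > 0")
    n = int(math.floor(horizon / sample_period)) + 1
    u = np.full(n, float(amplitude))
    return simulate(model, u, sample_period)
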