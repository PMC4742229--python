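"""Symmetric Steinecke-Herzel (S&H) two-mass vocal fold model.

The vocal fold is represented by two coupled mass-spring-damper oscillators
(a large inferior mass ``m1`` and a small superior mass ``m2``) per fold.
The folds are assumed left-right symmetric, so a single fold is integrated
and mirrored, giving a 4-state system ``(x1, v1, x2, v2)``.  Subglottal
pressure drives the inferior mass through a Bernoulli loading term, and a
smoothed step function switches forces on and off as the glottis opens and
closes.  The model output is the glottal volume velocity ``U(t)``.

Units are the g-cm-ms system throughout: pressures in g/(cm*ms^2), masses in
g, stiffnesses in g/ms^2, damping in g/ms, lengths in cm, flow in cm^3/ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from numba import njit

__all__ = [
    "PARAM_NAMES",
    "NOMINAL_VALUES",
    "RHO_AIR",
    "ParameterSet",
    "SimConfig",
    "StateTrajectory",
    "GlottalFlowSeries",
    "SimResult",
    "smoothed_step",
    "derivatives",
    "glottal_flow",
    "simulate",
    "simulate_flow",
    "flow_to_csv",
]

#: Canonical ordering of the 16 model inputs.
PARAM_NAMES = (
    "P", "m1", "m2", "k1", "k2", "kc", "r1", "r2",
    "d1", "d2", "L", "c1", "c2", "a01", "a02", "x0",
)

#: Nominal parameter values (g-cm-ms unit system).
NOMINAL_VALUES = {
    "P": 0.008,     # subglottal pressure, g/(cm*ms^2)
    "m1": 0.125,    # inferior mass, g
    "m2": 0.025,    # superior mass, g
    "k1": 0.08,     # inferior spring, g/ms^2
    "k2": 0.008,    # superior spring, g/ms^2
    "kc": 0.025,    # coupling spring, g/ms^2
    "r1": 0.02,     # inferior damper, g/ms
    "r2": 0.02,     # superior damper, g/ms
    "d1": 0.25,     # inferior thickness, cm
    "d2": 0.05,     # superior thickness, cm (enters no force/flow term)
    "L": 1.4,       # vocal fold length, cm
    "c1": 0.24,     # inferior collision spring, g/ms^2
    "c2": 0.024,    # superior collision spring, g/ms^2
    "a01": 0.05,    # inferior rest area (model units)
    "a02": 0.05,    # superior rest area (model units)
    "x0": 0.05,     # smoothed-step reference scale, cm
}

#: Air density, g/cm^3.  Fixed constant, not one of the 16 inputs.
RHO_AIR = 0.00113

_IDX = {name: i for i, name in enumerate(PARAM_NAMES)}


@dataclass(frozen=True)
class ParameterSet:
    """The 16 named inputs of the S&H model (g-cm-ms unit system)."""

    P: float = NOMINAL_VALUES["P"]
    m1: float = NOMINAL_VALUES["m1"]
    m2: float = NOMINAL_VALUES["m2"]
    k1: float = NOMINAL_VALUES["k1"]
    k2: float = NOMINAL_VALUES["k2"]
    kc: float = NOMINAL_VALUES["kc"]
    r1: float = NOMINAL_VALUES["r1"]
    r2: float = NOMINAL_VALUES["r2"]
    d1: float = NOMINAL_VALUES["d1"]
    d2: float = NOMINAL_VALUES["d2"]
    L: float = NOMINAL_VALUES["L"]
    c1: float = NOMINAL_VALUES["c1"]
    c2: float = NOMINAL_VALUES["c2"]
    a01: float = NOMINAL_VALUES["a01"]
    a02: float = NOMINAL_VALUES["a02"]
    x0: float = NOMINAL_VALUES["x0"]

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            # P = 0 is the physically meaningful undriven limit; everything
            # else must be strictly positive
            lo_ok = v >= 0 if name == "P" else v > 0
            if not (np.isfinite(v) and lo_ok):
                raise ValueError(f"parameter {name} must be positive and finite, got {v!r}")

    @classmethod
    def nominal(cls) -> "ParameterSet":
        return cls()

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "ParameterSet":
        values = np.asarray(values, dtype=float)
        if values.shape != (16,):
            raise ValueError("expected 16 parameter values")
        return cls(**dict(zip(PARAM_NAMES, values)))

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    def replace(self, **changes: float) -> "ParameterSet":
        return replace(self, **changes)


@dataclass(frozen=True)
class SimConfig:
    """Integration settings: fixed-step RK4 over ``duration`` ms.

    The first ``transient`` ms are discarded before any waveform analysis so
    that measures reflect the steady-state oscillation only.
    """

    dt: float = 0.01          # time step, ms
    duration: float = 1500.0  # total simulated time, ms
    transient: float = 500.0  # discarded initial span, ms
    x_init: tuple[float, float] = (0.01, 0.01)  # initial displacements, cm
    v_init: tuple[float, float] = (0.0, 0.0)    # initial velocities, cm/ms
    rho: float = RHO_AIR      # air density, g/cm^3

    def __post_init__(self) -> None:
        if not (self.dt > 0):
            raise ValueError("dt must be positive")
        if not (self.duration > self.transient >= 0):
            raise ValueError("need duration > transient >= 0")
        if not (self.rho > 0):
            raise ValueError("rho must be positive")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def n_transient(self) -> int:
        return int(round(self.transient / self.dt))


@dataclass
class StateTrajectory:
    """Full state history of one simulation (transient included)."""

    t: np.ndarray    # ms
    x1: np.ndarray   # cm
    v1: np.ndarray   # cm/ms
    x2: np.ndarray   # cm
    v2: np.ndarray   # cm/ms
    a1: np.ndarray   # lower glottal area
    a2: np.ndarray   # upper glottal area
    a_min: np.ndarray


@dataclass
class GlottalFlowSeries:
    """Uniformly sampled glottal volume velocity after transient removal."""

    t: np.ndarray    # ms
    u: np.ndarray    # cm^3/ms
    dt: float        # ms


@dataclass
class SimResult:
    trajectory: StateTrajectory
    flow: GlottalFlowSeries
    diverged: bool


def smoothed_step(y: float, x0: float) -> float:
    """Smoothed Heaviside step: 0 for y <= 0, tanh(50*y/x0) for y > 0.

    ``x0`` is the reference length scale over which the step ramps up.
    """
    if not np.isfinite(y):
        raise ValueError("y must be finite")
    if not (np.isfinite(x0) and x0 > 0):
        raise ValueError("x0 must be positive and finite")
    return _theta(float(y), float(x0))


@njit(cache=True)
def _theta(y: float, x0: float) -> float:
    if y <= 0.0:
        return 0.0
    z = 50.0 * y / x0
    if z >= 20.0:
        # tanh saturates to 1.0 within double precision
        return 1.0
    return math.tanh(z)


@njit(cache=True)
def _derivs(x1, v1, x2, v2,
            P, m1, m2, k1, k2, kc, r1, r2, d1, L, c1, c2, a01, a02, x0):
    a1 = a01 + 2.0 * L * x1
    a2 = a02 + 2.0 * L * x2
    amin = min(a1, a2)

    # aerodynamic driving force on the inferior mass (Bernoulli loading)
    f_aero = 0.0
    if a1 > 0.0:
        ratio = amin / a1
        f_aero = L * d1 * P * (1.0 - _theta(amin, x0) * ratio * ratio) * _theta(a1, x0)

    # collision forces switch on smoothly as each area goes negative
    f_col1 = -_theta(-a1, x0) * c1 * a1 / (2.0 * L)
    f_col2 = -_theta(-a2, x0) * c2 * a2 / (2.0 * L)

    f1 = f_aero - k1 * x1 - r1 * v1 - kc * (x1 - x2) + f_col1
    f2 = -k2 * x2 - r2 * v2 - kc * (x2 - x1) + f_col2
    return v1, f1 / m1, v2, f2 / m2


def derivatives(state: Sequence[float], params: ParameterSet,
                config: SimConfig | None = None) -> np.ndarray:
    """Time derivatives of the 4-state system ``(x1, v1, x2, v2)``."""
    state = np.asarray(state, dtype=float)
    if state.shape != (4,) or not np.all(np.isfinite(state)):
        raise ValueError("state must be a finite 4-vector")
    p = params.to_array()
    out = _derivs(state[0], state[1], state[2], state[3],
                  p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7],
                  p[8], p[10], p[11], p[12], p[13], p[14], p[15])
    return np.array(out)


def glottal_flow(a_min: float, P: float, rho: float = RHO_AIR,
                 x0: float = NOMINAL_VALUES["x0"]) -> float:
    """Bernoulli glottal flow: U = sqrt(2P/rho) * a_min * theta(a_min)."""
    if P < 0:
        raise ValueError("P must be non-negative")
    if not (rho > 0):
        raise ValueError("rho must be positive")
    if a_min <= 0:
        return 0.0
    return math.sqrt(2.0 * P / rho) * a_min * _theta(float(a_min), float(x0))


@njit(cache=True)
def _rk4_kernel(p, rho, dt, n_steps, n_trans, x10, v10, x20, v20, store_states):
    """Fixed-step RK4 integration.

    Returns (status, x1s, v1s, x2s, v2s, u) where status is 0 on success and
    1 on divergence.  State arrays have length n_steps+1 when store_states,
    else length 1; u holds post-transient flow samples (indices n_trans..n_steps).

    In the flow-only mode (store_states False) the integration stops early
    when the fold motion has demonstrably decayed during the transient
    (peak-to-peak x1 excursion below 1e-4 cm and shrinking at least 4-fold
    between consecutive transient windows): such a subject cannot reach a
    sustained oscillation, so u is left zeroed and downstream analysis sees
    the same non-oscillating outcome without integrating the analysis span.
    """
    P = p[0]; m1 = p[1]; m2 = p[2]; k1 = p[3]; k2 = p[4]; kc = p[5]
    r1 = p[6]; r2 = p[7]; d1 = p[8]; L = p[10]; c1 = p[11]; c2 = p[12]
    a01 = p[13]; a02 = p[14]; x0 = p[15]

    n_state = n_steps + 1 if store_states else 1
    x1s = np.empty(n_state)
    v1s = np.empty(n_state)
    x2s = np.empty(n_state)
    v2s = np.empty(n_state)
    u = np.zeros(n_steps - n_trans + 1)
    uc = math.sqrt(2.0 * P / rho)

    x1 = x10; v1 = v10; x2 = x20; v2 = v20
    if store_states:
        x1s[0] = x1; v1s[0] = v1; x2s[0] = x2; v2s[0] = v2
    status = 0
    half = 0.5 * dt
    sixth = dt / 6.0

    # decay-detection windows over the second half of the transient
    w1_start = n_trans // 2
    w2_start = (3 * n_trans) // 4
    w1_lo = w1_hi = w2_lo = w2_hi = 0.0
    check_decay = (not store_states) and n_trans >= 8

    for i in range(n_steps):
        k1a, k1b, k1c, k1d = _derivs(x1, v1, x2, v2, P, m1, m2, k1, k2, kc,
                                     r1, r2, d1, L, c1, c2, a01, a02, x0)
        k2a, k2b, k2c, k2d = _derivs(x1 + half * k1a, v1 + half * k1b,
                                     x2 + half * k1c, v2 + half * k1d,
                                     P, m1, m2, k1, k2, kc, r1, r2, d1, L,
                                     c1, c2, a01, a02, x0)
        k3a, k3b, k3c, k3d = _derivs(x1 + half * k2a, v1 + half * k2b,
                                     x2 + half * k2c, v2 + half * k2d,
                                     P, m1, m2, k1, k2, kc, r1, r2, d1, L,
                                     c1, c2, a01, a02, x0)
        k4a, k4b, k4c, k4d = _derivs(x1 + dt * k3a, v1 + dt * k3b,
                                     x2 + dt * k3c, v2 + dt * k3d,
                                     P, m1, m2, k1, k2, kc, r1, r2, d1, L,
                                     c1, c2, a01, a02, x0)
        x1 += sixth * (k1a + 2.0 * k2a + 2.0 * k3a + k4a)
        v1 += sixth * (k1b + 2.0 * k2b + 2.0 * k3b + k4b)
        x2 += sixth * (k1c + 2.0 * k2c + 2.0 * k3c + k4c)
        v2 += sixth * (k1d + 2.0 * k2d + 2.0 * k3d + k4d)

        if not (abs(x1) < 1e6 and abs(v1) < 1e6 and abs(x2) < 1e6 and abs(v2) < 1e6):
            status = 1
            break

        j = i + 1
        if store_states:
            x1s[j] = x1; v1s[j] = v1; x2s[j] = x2; v2s[j] = v2
        elif check_decay and j >= w1_start and j < n_trans:
            if j < w2_start:
                if j == w1_start:
                    w1_lo = x1; w1_hi = x1
                elif x1 < w1_lo:
                    w1_lo = x1
                elif x1 > w1_hi:
                    w1_hi = x1
            else:
                if j == w2_start:
                    w2_lo = x1; w2_hi = x1
                elif x1 < w2_lo:
                    w2_lo = x1
                elif x1 > w2_hi:
                    w2_hi = x1
                if j == n_trans - 1:
                    pp1 = w1_hi - w1_lo
                    pp2 = w2_hi - w2_lo
                    if pp2 < 1e-4 and pp2 < 0.25 * pp1:
                        break
        if j >= n_trans:
            amin = min(a01 + 2.0 * L * x1, a02 + 2.0 * L * x2)
            if amin > 0.0:
                u[j - n_trans] = uc * amin * _theta(amin, x0)

    return status, x1s, v1s, x2s, v2s, u


def _params_array(params) -> np.ndarray:
    if isinstance(params, ParameterSet):
        return params.to_array()
    arr = np.asarray(params, dtype=float)
    if arr.shape != (16,):
        raise ValueError("expected a ParameterSet or a length-16 array")
    return arr


def simulate(params, config: SimConfig | None = None) -> SimResult:
    """Integrate the model and return full trajectory plus flow series.

    Divergence (non-finite state) is flagged on the result rather than
    raised, so population runs can simply discard the subject.
    """
    config = config or SimConfig()
    p = _params_array(params)
    status, x1, v1, x2, v2, u = _rk4_kernel(
        p, config.rho, config.dt, config.n_steps, config.n_transient,
        config.x_init[0], config.v_init[0], config.x_init[1], config.v_init[1],
        True,
    )
    t = np.arange(config.n_steps + 1) * config.dt
    L, a01, a02 = p[10], p[13], p[14]
    a1 = a01 + 2.0 * L * x1
    a2 = a02 + 2.0 * L * x2
    traj = StateTrajectory(t=t, x1=x1, v1=v1, x2=x2, v2=v2,
                           a1=a1, a2=a2, a_min=np.minimum(a1, a2))
    t_flow = t[config.n_transient:]
    flow = GlottalFlowSeries(t=t_flow, u=u, dt=config.dt)
    return SimResult(trajectory=traj, flow=flow, diverged=bool(status))


def simulate_flow(params, config: SimConfig | None = None) -> tuple[GlottalFlowSeries, bool]:
    """Fast path: integrate and return only the post-transient flow series."""
    config = config or SimConfig()
    p = _params_array(params)
    status, _, _, _, _, u = _rk4_kernel(
        p, config.rho, config.dt, config.n_steps, config.n_transient,
        config.x_init[0], config.v_init[0], config.x_init[1], config.v_init[1],
        False,
    )
    t = (np.arange(u.size) + config.n_transient) * config.dt
    return GlottalFlowSeries(t=t, u=u, dt=config.dt), bool(status)


def flow_to_csv(flow: GlottalFlowSeries, path) -> None:
    """Write a two-column waveform CSV (time_ms, U_cm3_per_ms)."""
    arr = np.column_stack([flow.t, flow.u])
    np.savetxt(path, arr, delimiter=",", header="time_ms,U_cm3_per_ms",
               comments="", fmt="%.10g")
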