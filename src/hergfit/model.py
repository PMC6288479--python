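"""The four-state hERG/IKr Markov gating model and its simulators.

The channel has states open (O), closed (C), inactivated-open (IO) and
inactivated-closed (IC), with conservation [IC] = 1 - ([O] + [C] + [IO])
substituted structurally so only (O, C, IO) are integrated:

    d[O]/dt  = kO(V)·[C]  + kA(V)·[IO] - (kC(V) + kI(V))·[O]
    d[C]/dt  = kC(V)·[O]  + kA(V)·[IC] - (kO(V) + kI(V))·[C]
    d[IO]/dt = kI(V)·[O]  + kO(V)·[IC] - (kA(V) + kC(V))·[IO]

Each transition rate is a two-parameter exponential function of voltage:

    kO = kO1·exp(+kO2·V)    (activation)
    kC = kC1·exp(-kC2·V)    (deactivation)
    kI = kI1·exp(+kI2·V)    (inactivation)
    kA = kA1·exp(-kA2·V)    (recovery)

and the observed current is IKr = GKr·[O]·(V - EK) (GKr in μS, V in mV,
so IKr in nA).  This topology is exactly equivalent to a Hodgkin–Huxley
model with independent activation gate a (a = O + IO) and recovery gate
r (r = O + C): da/dt = kO·(1-a) - kC·a, dr/dt = kA·(1-r) - kI·r, and
O = a·r whenever the initial condition is a product state.  The closed
form at constant voltage is exposed as a test oracle, and the gate
factorisation powers the fast simulation backend used during inference.

Internal units: time ms, voltage mV, rates ms⁻¹, conductance μS, current nA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .errors import ModelEvaluationError, OracleInapplicableError, SimulationError
from .protocol import VoltageProtocol

__all__ = [
    "KINETIC_PARAMETER_NAMES",
    "PARAMETER_NAMES",
    "RateParameters",
    "ModelConstants",
    "RateSet",
    "GatingState",
    "CurrentTrace",
    "AnalyticGateSolution",
    "evaluate_rates",
    "state_derivatives",
    "steady_state",
    "gate_solution",
    "analytic_constant_voltage_solution",
    "simulate",
    "simulate_fast",
]

#: Kinetic parameters in declaration order (prefactor ms⁻¹, sensitivity mV⁻¹).
KINETIC_PARAMETER_NAMES = ("kO1", "kO2", "kC1", "kC2", "kI1", "kI2", "kA1", "kA2")
#: All nine free model parameters.
PARAMETER_NAMES = KINETIC_PARAMETER_NAMES + ("GKr",)

# exp() overflows around 709; clipping beyond this marks the set invalid.
_MAX_EXPONENT = 700.0


@dataclass(frozen=True)
class RateParameters:
    """The nine free scalars of the model.

    Prefactors (kO1, kC1, kI1, kA1) in ms⁻¹, voltage sensitivities
    (kO2, kC2, kI2, kA2) in mV⁻¹, maximal conductance GKr in μS.  All must
    be strictly positive and finite.
    """

    kO1: float
    kO2: float
    kC1: float
    kC2: float
    kI1: float
    kI2: float
    kA1: float
    kA2: float
    GKr: float

    def __post_init__(self):
        for name in PARAMETER_NAMES:
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")

    def as_array(self) -> np.ndarray:
        """Values in :data:`PARAMETER_NAMES` order."""
        return np.array([getattr(self, n) for n in PARAMETER_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values) -> "RateParameters":
        values = np.asarray(values, dtype=float)
        if values.shape != (9,):
            raise ValueError("expected 9 parameter values")
        return cls(**dict(zip(PARAMETER_NAMES, values)))

    def with_conductance(self, GKr: float) -> "RateParameters":
        values = self.as_array()
        values[-1] = GKr
        return RateParameters.from_array(values)


@dataclass(frozen=True)
class ModelConstants:
    """Fixed quantities of the model: the K⁺ reversal potential EK (mV)
    and the unit labels the data binder checks against."""

    EK: float = -88.4
    time_unit: str = "ms"
    voltage_unit: str = "mV"

    def __post_init__(self):
        if not np.isfinite(self.EK):
            raise ValueError("EK must be finite")


@dataclass(frozen=True)
class RateSet:
    """The four transition rates (ms⁻¹) at a single voltage."""

    kO: float
    kC: float
    kI: float
    kA: float

    def __post_init__(self):
        for name in ("kO", "kC", "kI", "kA"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise ValueError(f"rate {name} must be strictly positive and finite, got {value!r}")


@dataclass(frozen=True)
class GatingState:
    """State occupancies; IC is derived so conservation is structural."""

    O: float
    C: float
    IO: float

    def __post_init__(self):
        for name in ("O", "C", "IO", "IC"):
            value = getattr(self, name)
            if not (-1e-12 <= value <= 1.0 + 1e-12):
                raise ValueError(f"occupancy {name}={value!r} outside [0, 1]")

    @property
    def IC(self) -> float:
        return 1.0 - (self.O + self.C + self.IO)

    def as_array(self) -> np.ndarray:
        return np.array([self.O, self.C, self.IO], dtype=float)


@dataclass
class CurrentTrace:
    """Sampled IKr output: times (ms, strictly increasing), currents (nA),
    and optionally the (O, C, IO) state at each sample."""

    times: np.ndarray
    currents: np.ndarray
    states: Optional[np.ndarray] = None
    voltages: Optional[np.ndarray] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.times.shape != self.currents.shape:
            raise ValueError("times and currents must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class AnalyticGateSolution:
    """Steady states and time constants of the two equivalent gates at a
    fixed voltage: activation (a_inf, tau_a) and recovery (r_inf, tau_r)."""

    a_inf: float
    r_inf: float
    tau_a: float
    tau_r: float


def evaluate_rates(params: RateParameters, v: float) -> RateSet:
    """Evaluate the four voltage-dependent rates at membrane potential ``v``.

    Raises :class:`ModelEvaluationError` if any exponent magnitude exceeds
    the overflow guard (the parameter/voltage combination is invalid).
    """
    exponents = (params.kO2 * v, -params.kC2 * v, params.kI2 * v, -params.kA2 * v)
    if any(abs(e) > _MAX_EXPONENT for e in exponents):
        raise ModelEvaluationError(
            f"rate exponent overflow at v={v} mV for parameters {params}"
        )
    return RateSet(
        kO=params.kO1 * math.exp(exponents[0]),
        kC=params.kC1 * math.exp(exponents[1]),
        kI=params.kI1 * math.exp(exponents[2]),
        kA=params.kA1 * math.exp(exponents[3]),
    )


def state_derivatives(state: GatingState, rates: RateSet) -> tuple[float, float, float]:
    """Time derivatives (dO/dt, dC/dt, dIO/dt); dIC/dt is minus their sum."""
    O, C, IO, IC = state.O, state.C, state.IO, state.IC
    dO = rates.kO * C + rates.kA * IO - (rates.kC + rates.kI) * O
    dC = rates.kC * O + rates.kA * IC - (rates.kO + rates.kI) * C
    dIO = rates.kI * O + rates.kO * IC - (rates.kA + rates.kC) * IO
    return (dO, dC, dIO)


def gate_solution(rates: RateSet) -> AnalyticGateSolution:
    """Gate steady states and time constants implied by a rate set."""
    return AnalyticGateSolution(
        a_inf=rates.kO / (rates.kO + rates.kC),
        r_inf=rates.kA / (rates.kA + rates.kI),
        tau_a=1.0 / (rates.kO + rates.kC),
        tau_r=1.0 / (rates.kA + rates.kI),
    )


def steady_state(rates: RateSet) -> GatingState:
    """The unique fixed point of the gating ODEs at constant voltage."""
    g = gate_solution(rates)
    return GatingState(
        O=g.a_inf * g.r_inf,
        C=(1.0 - g.a_inf) * g.r_inf,
        IO=g.a_inf * (1.0 - g.r_inf),
    )


def _factorise(state: GatingState, tol: float = 1e-9) -> tuple[float, float]:
    """Split a product state into gate values (a, r); raises
    :class:`OracleInapplicableError` if the state does not factorise."""
    a = state.O + state.IO
    r = state.O + state.C
    if abs(state.O - a * r) > tol or abs(state.IC - (1.0 - a) * (1.0 - r)) > tol:
        raise OracleInapplicableError(
            "initial state is not a product of activation and recovery gates"
        )
    return a, r


def analytic_constant_voltage_solution(
    params: RateParameters,
    v: float,
    initial: GatingState,
    times: np.ndarray,
) -> np.ndarray:
    """Closed-form (O, C, IO) trajectory at constant voltage.

    Valid when ``initial`` factorises as a product of the two gates (always
    true for a steady state).  Returns an (n, 3) array of occupancies.
    """
    times = np.asarray(times, dtype=float)
    rates = evaluate_rates(params, v)
    g = gate_solution(rates)
    a0, r0 = _factorise(initial)
    a = g.a_inf + (a0 - g.a_inf) * np.exp(-times / g.tau_a)
    r = g.r_inf + (r0 - g.r_inf) * np.exp(-times / g.tau_r)
    return np.column_stack([a * r, (1.0 - a) * r, a * (1.0 - r)])


def _check_times(protocol: VoltageProtocol, times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    if times[0] < 0 or times[-1] > protocol.total_duration + 1e-9:
        raise ValueError(
            f"times [{times[0]}, {times[-1]}] outside protocol duration "
            f"[0, {protocol.total_duration}] ms"
        )
    return times


def _initial_state(params: RateParameters, protocol: VoltageProtocol) -> GatingState:
    """Steady state at the protocol's initial (t = 0) voltage."""
    return steady_state(evaluate_rates(params, protocol.voltage_at(0.0)))


_CONSERVATION_TOL = 1e-8


def _validate_states(states: np.ndarray) -> np.ndarray:
    """Check occupancy bounds along a trajectory; clamp to [0, 1] for output."""
    full = np.column_stack([states, 1.0 - states.sum(axis=1)])
    if not np.all(np.isfinite(full)):
        raise SimulationError("non-finite state encountered during integration")
    if full.min() < -_CONSERVATION_TOL or full.max() > 1.0 + _CONSERVATION_TOL:
        raise SimulationError(
            f"occupancy left [0, 1] beyond tolerance: min={full.min()}, max={full.max()}"
        )
    return np.clip(states, 0.0, 1.0)


def simulate(
    params: RateParameters,
    constants: ModelConstants,
    protocol: VoltageProtocol,
    times: np.ndarray,
    method: str = "LSODA",
    rtol: float = 1e-7,
    atol: float = 1e-9,
    return_states: bool = False,
) -> CurrentTrace:
    """Reference simulator: integrate the (O, C, IO) Markov system with a
    stiff-capable scipy solver, restarting at every segment boundary so
    voltage discontinuities are never smoothed by the stepper.

    The initial condition is the steady state at the protocol's t = 0
    voltage, and IKr = GKr·O·(V - EK) is reported at exactly the requested
    sample times.
    """
    times = _check_times(protocol, times)
    y = _initial_state(params, protocol).as_array()

    states = np.empty((times.size, 3), dtype=float)
    n_segments = len(protocol.segments)
    for i, seg in enumerate(protocol.segments):
        t0 = float(protocol.boundaries[i])
        t1 = float(protocol.boundaries[i + 1])

        def rhs(t, y, seg=seg, t0=t0):
            v = seg.voltage(t - t0)
            kO = params.kO1 * math.exp(params.kO2 * v)
            kC = params.kC1 * math.exp(-params.kC2 * v)
            kI = params.kI1 * math.exp(params.kI2 * v)
            kA = params.kA1 * math.exp(-params.kA2 * v)
            O, C, IO = y
            IC = 1.0 - (O + C + IO)
            return (
                kO * C + kA * IO - (kC + kI) * O,
                kC * O + kA * IC - (kO + kI) * C,
                kI * O + kO * IC - (kA + kC) * IO,
            )

        # Samples owned by this segment (left-closed; the final boundary
        # belongs to the last segment).  ``times`` is sorted, so this is a
        # contiguous slice.
        lo = int(np.searchsorted(times, t0, side="left"))
        if i == n_segments - 1:
            hi = times.size
        else:
            hi = int(np.searchsorted(times, t1, side="left"))
        seg_samples = np.clip(times[lo:hi], t0, t1)
        # Always integrate through t1 so the next segment continues exactly.
        t_eval = np.append(seg_samples, t1) if (seg_samples.size == 0 or seg_samples[-1] < t1) else seg_samples

        sol = solve_ivp(
            rhs,
            (t0, t1),
            y,
            method=method,
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise SimulationError(
                f"ODE integration failed in segment {i} for parameters {params}: {sol.message}"
            )
        states[lo:hi] = sol.y.T[: hi - lo]
        y = sol.y[:, -1]

    states = _validate_states(states)
    voltages = protocol.voltages(times)
    currents = params.GKr * states[:, 0] * (voltages - constants.EK)
    return CurrentTrace(
        times=times,
        currents=currents,
        states=states if return_states else None,
        voltages=voltages,
    )


def simulate_fast(
    params: RateParameters,
    constants: ModelConstants,
    protocol: VoltageProtocol,
    times: np.ndarray,
    dt_smooth: float = 0.05,
    return_states: bool = False,
) -> CurrentTrace:
    """Fast simulator via the Hodgkin–Huxley gate factorisation.

    Propagates the two gates with exact exponential updates on constant
    segments and a second-order exponential-midpoint rule (substep
    ``dt_smooth`` ms, voltage frozen at the substep midpoint) on ramp and
    sine segments.  Agrees with :func:`simulate` to solver tolerance; used
    for the many forward evaluations of inference.
    """
    from ._fastsim import propagate_gates, protocol_plan

    times = _check_times(protocol, times)
    vmin, vmax = protocol.voltage_range()
    # Validates positivity/overflow once; raises for invalid sets.
    evaluate_rates(params, vmin)
    evaluate_rates(params, vmax)

    plan = protocol_plan(protocol)
    init = _initial_state(params, protocol)
    a0, r0 = _factorise(init)
    a, r = propagate_gates(params.as_array(), *plan, times, float(dt_smooth), a0, r0)
    states = np.column_stack([a * r, (1.0 - a) * r, a * (1.0 - r)])
    states = _validate_states(states)
    voltages = protocol.voltages(times)
    currents = params.GKr * states[:, 0] * (voltages - constants.EK)
    return CurrentTrace(
        times=times,
        currents=currents,
        states=states if return_states else None,
        voltages=voltages,
    )
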