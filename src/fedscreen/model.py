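"""Macro-kinetic E. coli growth model with overflow metabolism.

Five coupled ODE states — biomass ``X``, glucose ``S``, acetate ``A``,
dissolved oxygen tension ``DOT`` and polymeric glucose equivalents ``P`` —
plus a broth volume ``V`` that changes only at discrete pulse events
(feeding, sampling, volume balancing).  Glucose uptake splits into an
oxidative and an overflow branch; overflow glucose yields acetate, which is
re-consumed once glucose repression relaxes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from numba import njit
from scipy.integrate import odeint, solve_ivp

from .parameters import ModelParameters

_STATE_NAMES = ("X", "S", "A", "DOT", "P")

#: Default integration tolerances.  The absolute tolerance is per state:
#: DOT lives on a 0-100 % scale, the concentrations on ~0-20 g/L.
DEFAULT_RTOL = 1e-6
DEFAULT_ATOL = (1e-8, 1e-8, 1e-8, 1e-6, 1e-8)


@dataclass
class CultivationState:
    """Broth composition at one time point.

    ``t`` in h; ``X``, ``S``, ``A``, ``P`` in g L^-1; ``DOT`` in % air
    saturation; ``V`` in L.
    """

    t: float
    X: float
    S: float
    A: float
    DOT: float
    P: float = 0.0
    V: float = 0.010

    def validate(self, DOTstar: float = 100.0) -> None:
        for name in ("X", "S", "A", "P", "V"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"state field {name} must be finite and >= 0, got {v!r}")
        if not math.isfinite(self.DOT) or self.DOT < 0 or self.DOT > DOTstar:
            raise ValueError(f"state field DOT must lie in [0, {DOTstar}], got {self.DOT!r}")

    def to_array(self) -> np.ndarray:
        return np.array([self.X, self.S, self.A, self.DOT, self.P], dtype=float)


@dataclass(frozen=True)
class PulseEvent:
    """Instantaneous, perfectly mixed volume change.

    ``kind`` is ``feed`` (volume > 0, carries ``glucose_mass = volume * Si``),
    ``sample`` (volume < 0, concentrations unchanged) or ``balance`` (any
    signed volume, optional glucose mass).  Times are hours from inoculation.
    """

    t: float
    kind: str
    volume: float
    glucose_mass: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("feed", "sample", "balance"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "feed" and self.volume < 0:
            raise ValueError("feed events must have volume >= 0")
        if self.kind == "sample" and (self.volume > 0 or self.glucose_mass != 0):
            raise ValueError("sample events must remove volume and carry no glucose")


class SpecificRates(NamedTuple):
    """Specific conversion rates, g g^-1 h^-1 (``mu`` in h^-1)."""

    qS: float    # total glucose uptake
    qSof: float  # overflow-branch glucose flux
    qSox: float  # oxidative-branch glucose flux
    qAp: float   # acetate production
    qAc: float   # acetate consumption
    mu: float    # specific growth rate
    qO: float    # specific oxygen uptake


def specific_rates(params: ModelParameters, state: CultivationState) -> SpecificRates:
    """Evaluate the kinetic rate expressions at one state.

    Glucose uptake is Monod in glucose and limited multiplicatively by
    oxygen; the overflow branch saturates with total uptake; acetate uptake
    is Monod in acetate and repressed by glucose.
    """
    state.validate(params.DOTstar)
    return SpecificRates(*_rates(params, state.X, state.S, state.A, state.DOT))


def _rates(p: ModelParameters, X: float, S: float, A: float, DOT: float):
    qS = p.qSmax * S / (S + p.Ks) * DOT / (DOT + p.Ko) if S > 0 else 0.0
    qSof = p.pAmax * qS / (qS + p.Kap) if qS > 0 else 0.0
    qSox = qS - qSof
    qAp = p.Yaof * qSof
    qAc = p.qAmax * (A / (A + p.Kaq)) * (p.Ksq / (p.Ksq + S)) if A > 0 else 0.0
    ox = max(qSox - p.qm, 0.0)
    mu = ox * p.Yem + qSof * p.Yofm + qAc * p.Yam
    qO = ox * p.Yosresp + qAc * p.Yaresp
    return qS, qSof, qSox, qAp, qAc, mu, qO


def rhs(params: ModelParameters, state: CultivationState) -> np.ndarray:
    """Time derivatives of (X, S, A, DOT, P) at one state."""
    state.validate(params.DOTstar)
    f = _make_rhs(params)
    return np.asarray(f(state.t, state.to_array()))


def _make_rhs(p: ModelParameters):
    """Closure evaluating the ODE right-hand side on a raw state vector.

    States are clamped at zero inside the rate laws so that solver probes
    marginally below zero see restoring dynamics rather than sign-flipped
    kinetics.
    """
    qSmax, Ks, Ko = p.qSmax, p.Ks, p.Ko
    pAmax, Kap = p.pAmax, p.Kap
    qAmax, Kaq, Ksq = p.qAmax, p.Kaq, p.Ksq
    Yaof, Yem, Yofm, Yam = p.Yaof, p.Yem, p.Yofm, p.Yam
    Yosresp, Yaresp, qm = p.Yosresp, p.Yaresp, p.qm
    kLa, DOTstar, kP = p.kLa, p.DOTstar, p.kP
    H = DOTstar / p.cO2sat  # % DOT per g L^-1 oxygen consumed

    def f(t, y):
        X = y[0] if y[0] > 0.0 else 0.0
        S = y[1] if y[1] > 0.0 else 0.0
        A = y[2] if y[2] > 0.0 else 0.0
        DOT = y[3] if y[3] > 0.0 else 0.0
        P = y[4] if y[4] > 0.0 else 0.0

        qS = qSmax * S / (S + Ks) * DOT / (DOT + Ko) if S > 0.0 else 0.0
        qSof = pAmax * qS / (qS + Kap) if qS > 0.0 else 0.0
        qSox = qS - qSof
        qAc = qAmax * (A / (A + Kaq)) * (Ksq / (Ksq + S)) if A > 0.0 else 0.0
        ox = qSox - qm
        if ox < 0.0:
            ox = 0.0
        mu = ox * Yem + qSof * Yofm + qAc * Yam
        qO = ox * Yosresp + qAc * Yaresp

        return (
            mu * X,
            -qS * X + kP * P,
            (Yaof * qSof - qAc) * X,
            kLa * (DOTstar - DOT) - qO * X * H,
            -kP * P,
        )

    return f


def _pack(p: ModelParameters) -> np.ndarray:
    return np.array([
        p.qSmax, p.Ks, p.Ko, p.pAmax, p.Kap, p.qAmax, p.Kaq, p.Ksq, p.Yaof,
        p.Yem, p.Yofm, p.Yam, p.Yosresp, p.Yaresp, p.qm, p.kLa, p.DOTstar,
        p.kP, p.DOTstar / p.cO2sat,
    ])


@njit(cache=True)
def _rhs_packed(y, t, pv):
    """Compiled right-hand side on a packed parameter vector (odeint order).

    Mirrors the closure from _make_rhs exactly; states clamped at zero."""
    X = y[0] if y[0] > 0.0 else 0.0
    S = y[1] if y[1] > 0.0 else 0.0
    A = y[2] if y[2] > 0.0 else 0.0
    DOT = y[3] if y[3] > 0.0 else 0.0
    P = y[4] if y[4] > 0.0 else 0.0

    qS = pv[0] * S / (S + pv[1]) * DOT / (DOT + pv[2]) if S > 0.0 else 0.0
    qSof = pv[3] * qS / (qS + pv[4]) if qS > 0.0 else 0.0
    qSox = qS - qSof
    qAc = pv[5] * (A / (A + pv[6])) * (pv[7] / (pv[7] + S)) if A > 0.0 else 0.0
    ox = qSox - pv[14]
    if ox < 0.0:
        ox = 0.0
    mu = ox * pv[9] + qSof * pv[10] + qAc * pv[11]
    qO = ox * pv[12] + qAc * pv[13]

    out = np.empty(5)
    out[0] = mu * X
    out[1] = -qS * X + pv[17] * P
    out[2] = (pv[8] * qSof - qAc) * X
    out[3] = pv[15] * (pv[16] - DOT) - qO * X * pv[18]
    out[4] = -pv[17] * P
    return out


def apply_event(state: CultivationState, event: PulseEvent) -> CultivationState:
    """Instantaneous perfectly-mixed update of one event."""
    v = event.volume
    V_old = state.V
    V_new = V_old + v
    if V_new <= 0:
        raise ValueError(f"event at t={event.t} would drive volume to {V_new} L")
    if v > 0:
        # addition: dilute everything, add the carried glucose
        return replace(
            state,
            t=event.t,
            V=V_new,
            X=state.X * V_old / V_new,
            S=(state.S * V_old + event.glucose_mass) / V_new,
            A=state.A * V_old / V_new,
            P=state.P * V_old / V_new,
        )
    # removal: concentrations intact
    return replace(state, t=event.t, V=V_new)


@dataclass
class Trajectory:
    """Simulated states on a reporting grid."""

    t: np.ndarray
    X: np.ndarray
    S: np.ndarray
    A: np.ndarray
    DOT: np.ndarray
    P: np.ndarray
    V: np.ndarray

    def state_at(self, i: int) -> CultivationState:
        return CultivationState(
            t=float(self.t[i]), X=float(self.X[i]), S=float(self.S[i]),
            A=float(self.A[i]), DOT=float(self.DOT[i]), P=float(self.P[i]),
            V=float(self.V[i]),
        )

    def interp(self, variable: str, times: np.ndarray) -> np.ndarray:
        return np.interp(times, self.t, getattr(self, variable))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"t": self.t, "X": self.X, "S": self.S, "A": self.A,
             "DOT": self.DOT, "P": self.P, "V": self.V}
        )


class SimulationError(RuntimeError):
    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last successful time t={last_time:.4f} h)")
        self.last_time = last_time


def simulate(
    params: ModelParameters,
    initial: CultivationState,
    events: Sequence[PulseEvent] = (),
    horizon: float | None = None,
    output_times: Iterable[float] | None = None,
    rtol: float | None = None,
    atol: float | Sequence[float] | None = None,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the model between discrete events.

    Events must be time-sorted; each is applied as an instantaneous mixing
    update.  ``output_times`` (default: a uniform 200-point grid) must lie in
    ``[initial.t, horizon]``; at an event time the reported state is the
    post-event state.
    """
    initial.validate(params.DOTstar)
    rtol = DEFAULT_RTOL if rtol is None else rtol
    atol = np.asarray(DEFAULT_ATOL) if atol is None else atol
    events = [e for e in events if e.t >= initial.t]
    times = [e.t for e in events]
    if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("events must be sorted by time")
    if horizon is None:
        horizon = max([initial.t] + [e.t for e in events])
    if horizon < initial.t:
        raise ValueError("horizon precedes the initial time")
    if output_times is None:
        t_out = np.linspace(initial.t, horizon, 200)
    else:
        t_out = np.asarray(list(output_times), dtype=float)
        if t_out.size and (t_out.min() < initial.t - 1e-12 or t_out.max() > horizon + 1e-12):
            raise ValueError("output_times outside [initial.t, horizon]")

    use_fast = method == "LSODA"
    pv = _pack(params) if use_fast else None
    f = None if use_fast else _make_rhs(params)
    y = initial.to_array()
    t_now = initial.t

    # The broth volume never enters the concentration dynamics, so it is a
    # precomputable step function of time; only events that ADD material
    # (and therefore re-mix concentrations) interrupt the integration.
    # Removals just advance the volume record.
    ev_in = [e for e in events if e.t <= horizon + 1e-12]
    v_times = np.array([e.t for e in ev_in])
    v_cum = initial.V + np.cumsum([e.volume for e in ev_in]) if ev_in else np.empty(0)
    if ev_in and (v_cum <= 0).any():
        bad = ev_in[int(np.argmax(v_cum <= 0))]
        raise ValueError(f"event at t={bad.t} would drive the volume to <= 0 L")

    def V_at(t: float) -> float:
        """Volume at time t; post-event at exact event times."""
        i = int(np.searchsorted(v_times, t, side="right"))
        return initial.V if i == 0 else float(v_cum[i - 1])

    out_t: list[float] = []
    out_y: list[np.ndarray] = []

    def emit(t, yv):
        out_t.append(t)
        out_y.append(np.asarray(yv, dtype=float))

    # pending output times, processed in order
    pending = np.sort(t_out)
    pi = 0

    def integrate_to(t_end, y0, t0):
        nonlocal pi
        # output times strictly inside (t0, t_end); boundaries handled by caller
        wanted = []
        while pi < pending.size and pending[pi] < t_end - 1e-12:
            if pending[pi] <= t0 + 1e-12:
                emit(pending[pi], y0)
            else:
                wanted.append(pending[pi])
            pi += 1
        if t_end <= t0 + 1e-12:
            return np.asarray(y0, dtype=float)
        if use_fast:
            # one LSODA call per segment; interior output times are filled
            # by the solver's dense interpolation in compiled code
            uw, inv = (np.unique(wanted, return_inverse=True)
                       if wanted else (np.empty(0), np.empty(0, dtype=int)))
            ts = np.concatenate([[t0], uw, [t_end]])
            y_out, info = odeint(_rhs_packed, y0, ts, args=(pv,), rtol=rtol, atol=atol,
                                 mxstep=10**6, full_output=True)
            if info["message"] != "Integration successful.":
                raise SimulationError(
                    f"integration failed (lsoda): {info['message']}",
                    float(info["tcur"][-1]),
                )
            for i, tw in enumerate(wanted):
                emit(tw, y_out[1 + inv[i]])
            return y_out[-1]
        t_eval = np.append(np.asarray(wanted, dtype=float), t_end)
        sol = solve_ivp(f, (t0, t_end), y0, method=method, rtol=rtol, atol=atol, t_eval=t_eval)
        if not sol.success:
            raise SimulationError(
                f"integration failed: {sol.message}", sol.t[-1] if sol.t.size else t0
            )
        for k in range(len(wanted)):
            emit(sol.t[k], sol.y[:, k])
        return sol.y[:, -1]

    V_run = initial.V
    for ev in ev_in:
        if ev.volume > 0:
            y = integrate_to(ev.t, y, t_now)
            t_now = ev.t
            # clamp solver-tolerance negatives before the mixing update
            X, S, A, DOT, P = (max(v, 0.0) for v in y)
            DOT = min(DOT, params.DOTstar)
            V_new = V_run + ev.volume
            y = np.array([X * V_run / V_new,
                          (S * V_run + ev.glucose_mass) / V_new,
                          A * V_run / V_new,
                          DOT,
                          P * V_run / V_new])
            V_run = V_new
            # an output time equal to the event time gets the post-event state
            while pi < pending.size and abs(pending[pi] - t_now) <= 1e-12:
                emit(pending[pi], y)
                pi += 1
        else:
            V_run += ev.volume

    y = integrate_to(horizon, y, t_now)
    while pi < pending.size:
        # remaining output times equal to the horizon
        emit(pending[pi], y)
        pi += 1
    out_V = [V_at(t) for t in out_t]

    arr = np.array(out_y) if out_y else np.empty((0, 5))
    return Trajectory(
        t=np.array(out_t),
        X=arr[:, 0] if arr.size else np.array([]),
        S=arr[:, 1] if arr.size else np.array([]),
        A=arr[:, 2] if arr.size else np.array([]),
        DOT=arr[:, 3] if arr.size else np.array([]),
        P=arr[:, 4] if arr.size else np.array([]),
        V=np.array(out_V),
    )


def mu_max(params: ModelParameters) -> float:
    """Maximum specific growth rate: glucose-saturated (S >> Ks),
    acetate-free broth at full oxygen, i.e. the growth law evaluated at
    qS = qSmax * DOTstar / (DOTstar + Ko)."""
    p = params
    qS = p.qSmax * p.DOTstar / (p.DOTstar + p.Ko)
    qSof = p.pAmax * qS / (qS + p.Kap) if qS > 0 else 0.0
    return max(qS - qSof - p.qm, 0.0) * p.Yem + qSof * p.Yofm
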