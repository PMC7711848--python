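"""Batch-end prediction and exponential->constant pulse-feed design.

After the batch phase (glucose and the overflow acetate both consumed),
feeding starts with an exponential profile that holds the specific growth
rate at a setpoint, discretized into fixed-period pulses; once a pulse
would exceed the robot's maximum pipetting volume the schedule switches to
a constant feed at that cap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .estimation import EstimationResult
from .model import CultivationState, PulseEvent, Trajectory, mu_max, simulate
from .parameters import ModelParameters


@dataclass
class FeedSettings:
    """Operating constants of the pulse-feed system.

    ``Si`` g/L feed glucose; ``pulse_period`` h between pulses;
    ``max_pulse_volume`` L robot cap; ``min_pulse_volume`` L minimal
    pipettable volume (smaller pulses are emitted as zero); ``mu_set_fraction``
    of the model's mu_max used as growth setpoint; ``YXS`` design biomass
    yield (None: use the calibrated oxidative yield Yem);
    ``batch_end_threshold`` g/L depletion level; ``acetate_wait_cap`` h
    maximum wait for acetate after glucose depletion; ``horizon`` h.
    """

    Si: float = 400.0
    pulse_period: float = 5.0 / 60.0
    max_pulse_volume: float = 22e-6
    min_pulse_volume: float = 1e-6
    mu_set_fraction: float = 0.5
    YXS: float | None = None
    batch_end_threshold: float = 0.02
    acetate_wait_cap: float = 0.75
    horizon: float = 8.0

    def __post_init__(self) -> None:
        for name in ("Si", "pulse_period", "max_pulse_volume", "batch_end_threshold",
                     "acetate_wait_cap", "horizon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.mu_set_fraction <= 1:
            raise ValueError("mu_set_fraction must lie in (0, 1]")


@dataclass
class FeedSchedule:
    """Timed discrete feed pulses, exponential then constant."""

    feed_start: float
    F0: float  # L/h
    mu_set: float  # 1/h
    pulses: list[PulseEvent] = field(default_factory=list)
    constant_from: float | None = None

    def cumulative_volume(self, t: float) -> float:
        """Total scheduled feed volume up to and including time t, L."""
        return sum(p.volume for p in self.pulses if p.t <= t + 1e-12)

    def future_pulses(self, now: float) -> list[PulseEvent]:
        return [p for p in self.pulses if p.t > now + 1e-12]

    def to_frame(self, reactor_id: str = "") -> pd.DataFrame:
        rows = []
        for p in self.pulses:
            phase = ("constant" if self.constant_from is not None
                     and p.t >= self.constant_from - 1e-12 else "exponential")
            rows.append((reactor_id, p.t, p.volume * 1e6, p.glucose_mass * 1e3, phase))
        return pd.DataFrame(rows, columns=["reactor_id", "t_h", "volume_uL", "glucose_mg", "phase"])

    def to_csv(self, path_or_buf, reactor_id: str = "") -> None:
        self.to_frame(reactor_id).to_csv(path_or_buf, index=False)


class NoBatchEndError(RuntimeError):
    """Raised when glucose is not predicted to deplete within the horizon."""


def predict_batch_end(
    params: ModelParameters,
    state_now: CultivationState,
    horizon: float,
    threshold: float = 0.02,
    acetate_wait_cap: float = 0.75,
    grid: float = 1.0 / 240.0,
    events: Sequence[PulseEvent] = (),
) -> tuple[float, float]:
    """Feed-free forward prediction of (glucose-depletion time, feed start).

    Feeding starts when both glucose and acetate have fallen below the
    threshold, but never later than ``acetate_wait_cap`` after glucose
    depletion.  Times are reported on a grid of resolution ``grid``
    (default 0.25 min).  Non-feed events already committed (sampling,
    balancing) may be passed in.
    """
    if state_now.S < threshold and state_now.A < threshold:
        return state_now.t, state_now.t
    t_out = np.arange(state_now.t, horizon + grid / 2, grid)
    ev = [e for e in events if e.kind != "feed"]
    traj = simulate(params, replace(state_now), ev, horizon=float(t_out[-1]), output_times=t_out)
    below_S = traj.S < threshold
    if not below_S.any():
        raise NoBatchEndError(
            f"glucose not predicted to deplete within horizon {horizon} h "
            f"(min S = {traj.S.min():.3f} g/L)"
        )
    i_dep = int(np.argmax(below_S))
    t_dep = float(traj.t[i_dep])
    both = below_S & (traj.A < threshold)
    if both.any() and float(traj.t[int(np.argmax(both))]) <= t_dep + acetate_wait_cap:
        t_start = float(traj.t[int(np.argmax(both))])
    else:
        t_start = t_dep + acetate_wait_cap
    return t_dep, t_start


def effective_yield(params: ModelParameters, mu_set: float) -> float:
    """Overall biomass-on-glucose design yield at the growth setpoint.

    Inverts the kinetic growth law mu(qS) (acetate-free, fully oxygenated)
    at mu = mu_set and returns mu_set / qS*.  Unlike the oxidative yield
    Yem alone, this accounts for the overflow branch and maintenance, so a
    feed sized with it holds the culture at the setpoint without glucose
    accumulation."""
    from scipy.optimize import brentq

    def mu_of_qS(qS: float) -> float:
        qSof = params.pAmax * qS / (qS + params.Kap) if qS > 0 else 0.0
        return max(qS - qSof - params.qm, 0.0) * params.Yem + qSof * params.Yofm

    qS_sat = params.qSmax * params.DOTstar / (params.DOTstar + params.Ko)
    if mu_set <= 0:
        raise ValueError("mu_set must be positive")
    if mu_of_qS(qS_sat) <= mu_set:
        return mu_of_qS(qS_sat) / qS_sat if qS_sat > 0 else params.Yem
    qS_star = brentq(lambda q: mu_of_qS(q) - mu_set, 1e-12, qS_sat)
    return mu_set / qS_star


def initial_feed_rate(mu_set: float, X0: float, V0: float, YXS: float, Si: float) -> float:
    """Initial volumetric feed rate F0 = mu_set * X0 * V0 / (YXS * Si), L/h,
    for biomass concentration X0 g/L in volume V0 L."""
    if YXS <= 0 or Si <= 0:
        raise ValueError("YXS and Si must be positive")
    if mu_set < 0 or X0 < 0 or V0 <= 0:
        raise ValueError("mu_set and X0 must be >= 0, V0 > 0")
    return mu_set * X0 * V0 / (YXS * Si)


def exponential_pulse_schedule(
    F0: float,
    mu_set: float,
    feed_start: float,
    settings: FeedSettings,
    horizon: float | None = None,
) -> FeedSchedule:
    """Discretize the exponential feed profile V(t) = V0 + (F0/mu_set)
    (e^{mu_set t} - 1) into pulses of one period each; cap at the maximum
    pipetting volume and switch to constant feeding from there on.

    Pulse k (at t_k = feed_start + k*period) carries the profile volume of
    the interval [t_k, t_k + period), so cumulative pulse volume telescopes
    to the closed form exactly.  Pulses below the minimum pipettable volume
    are emitted with zero volume.
    """
    if F0 <= 0:
        raise ValueError("F0 must be positive")
    if mu_set < 0:
        raise ValueError("mu_set must be >= 0")
    horizon = settings.horizon if horizon is None else horizon
    dt = settings.pulse_period
    pulses: list[PulseEvent] = []
    constant_from: float | None = None
    k = 0
    while True:
        t_k = feed_start + k * dt
        if t_k > horizon + 1e-12:
            break
        if constant_from is None:
            tau = t_k - feed_start
            if mu_set > 0:
                # expm1 keeps the mu_set -> 0 limit numerically exact
                v = (F0 / mu_set) * math.exp(mu_set * tau) * math.expm1(mu_set * dt)
            else:  # analytic mu_set -> 0 limit
                v = F0 * dt
            if v > settings.max_pulse_volume:
                v = settings.max_pulse_volume
                constant_from = t_k
        else:
            v = settings.max_pulse_volume
        if v < settings.min_pulse_volume:
            v = 0.0
        pulses.append(PulseEvent(t=t_k, kind="feed", volume=v, glucose_mass=v * settings.Si))
        k += 1
    return FeedSchedule(feed_start=feed_start, F0=F0, mu_set=mu_set,
                        pulses=pulses, constant_from=constant_from)


def design_feed(
    calibration: EstimationResult | ModelParameters,
    state_now: CultivationState,
    settings: FeedSettings,
    committed: FeedSchedule | None = None,
    events: Sequence[PulseEvent] = (),
) -> FeedSchedule:
    """Full clone-specific feed design from the current calibrated model.

    The growth setpoint is ``mu_set_fraction * mu_max(theta_hat)``; batch end
    is predicted by feed-free forward simulation from ``state_now``; biomass
    and volume at feed start are taken from that same event-aware simulation
    (so sampling losses are accounted for); already-executed pulses of a
    previously ``committed`` schedule are kept verbatim and only future
    pulses are replaced.
    """
    params = calibration.theta_hat if isinstance(calibration, EstimationResult) else calibration
    mu_set = settings.mu_set_fraction * mu_max(params)
    YXS = settings.YXS if settings.YXS is not None else effective_yield(params, mu_set)
    now = state_now.t

    if committed is not None and committed.feed_start <= now + 1e-12:
        # Feeding already underway: executed pulses and the start time are
        # immutable.  The profile is re-anchored at the next scheduled pulse
        # with F0 from the current predicted biomass, which continues the
        # exponential law F = mu_set*X*V/(YXS*Si) self-consistently.
        feed_start = committed.feed_start
        future_times = [p.t for p in committed.pulses if p.t > now + 1e-12]
        anchor = min(future_times) if future_times else now
        F0 = initial_feed_rate(mu_set, state_now.X, state_now.V, YXS, settings.Si)
        fresh = exponential_pulse_schedule(F0, mu_set, anchor, settings)
        past = [p for p in committed.pulses if p.t <= now + 1e-12]
        return FeedSchedule(feed_start=feed_start, F0=F0, mu_set=mu_set,
                            pulses=past + fresh.pulses, constant_from=fresh.constant_from)

    _, feed_start = predict_batch_end(
        params, state_now, settings.horizon,
        threshold=settings.batch_end_threshold,
        acetate_wait_cap=settings.acetate_wait_cap,
        events=events,
    )
    # biomass and volume at feed start from the last calibrated model,
    # event-aware so sampling losses are accounted for
    if feed_start > now + 1e-12:
        ev = [e for e in events if e.kind != "feed"]
        traj = simulate(params, replace(state_now), ev, horizon=feed_start,
                        output_times=[feed_start])
        X0, V0 = float(traj.X[-1]), float(traj.V[-1])
    else:
        X0, V0 = state_now.X, state_now.V
    F0 = initial_feed_rate(mu_set, X0, V0, YXS, settings.Si)
    return exponential_pulse_schedule(F0, mu_set, feed_start, settings)


def schedule_from_frame(frame: pd.DataFrame) -> FeedSchedule:
    """Rebuild a schedule from its delimited-text form (single reactor)."""
    pulses = [
        PulseEvent(t=float(r.t_h), kind="feed", volume=float(r.volume_uL) * 1e-6,
                   glucose_mass=float(r.glucose_mg) * 1e-3)
        for r in frame.itertuples()
    ]
    const = frame.loc[frame["phase"] == "constant", "t_h"]
    feed_start = float(frame["t_h"].min()) if len(frame) else 0.0
    return FeedSchedule(feed_start=feed_start, F0=float("nan"), mu_set=float("nan"),
                        pulses=pulses,
                        constant_from=float(const.min()) if len(const) else None)
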