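"""Virtual mini-bioreactor plant: the synthetic stand-in for the robot.

Simulates reactors under their true (hidden) clone parameters with the
facility's measurement schedule: online DOT every 20 s (1440 points over
8 h), at-line biomass/glucose/acetate samples with column-dependent
analysis delays (0.25-1.35 h for biomass, 0.66-2 h for glucose/acetate),
biomass reported through the full OD600 round trip (DCW -> diluted OD ->
path-length correction -> DCW), and relative Gaussian assay noise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .estimation import MeasurementSet, ReactorInput
from .feed_design import FeedSchedule
from .model import CultivationState, PulseEvent, simulate
from .parameters import ESTIMABLE_PARAMETERS, ModelParameters
from .uncertainty import NoiseModel

#: OD600 path-length correction to 1 cm and OD->dry-cell-weight factor.
OD_PATH_FACTOR = 2.62
OD_TO_DCW = 0.33


def _default_biomass_times() -> tuple[float, ...]:
    # 23 at-line biomass samples over the 8-h run (20-min rhythm from 0.4 h)
    return tuple(0.4 + k / 3.0 for k in range(23))


def _default_glc_ace_times() -> tuple[float, ...]:
    # glucose/acetate analytics start later; 20 samples on the same rhythm
    return _default_biomass_times()[3:]


@dataclass
class SamplingPlan:
    """Measurement schedule and analytic conversions of the facility."""

    run_length: float = 8.0
    online_period: float = 20.0 / 3600.0
    biomass_times: tuple[float, ...] = field(default_factory=_default_biomass_times)
    glucose_times: tuple[float, ...] = field(default_factory=_default_glc_ace_times)
    acetate_times: tuple[float, ...] = field(default_factory=_default_glc_ace_times)
    n_columns: int = 6
    biomass_delay_range: tuple[float, float] = (0.25, 1.35)
    glucose_acetate_delay_range: tuple[float, float] = (0.66, 2.0)
    dilution_bounds: tuple[float, float] = (20.0, 100.0)
    sample_volume: float = 150e-6  # L removed per at-line draw

    def __post_init__(self) -> None:
        if self.run_length <= 0 or self.online_period <= 0:
            raise ValueError("run_length and online_period must be positive")
        if self.n_columns < 1:
            raise ValueError("n_columns must be >= 1")

    def online_times(self) -> np.ndarray:
        n = int(round(self.run_length / self.online_period))
        return np.arange(1, n + 1) * self.online_period

    def delay(self, variable: str, column: int) -> float:
        """At-line result delay, linear in the reactor's column index."""
        lo, hi = (self.biomass_delay_range if variable == "biomass"
                  else self.glucose_acetate_delay_range)
        frac = column / (self.n_columns - 1) if self.n_columns > 1 else 0.0
        return lo + (hi - lo) * frac


@dataclass
class CloneSpec:
    """A clone's hidden phenotype and inoculation state."""

    clone_id: str
    true_parameters: ModelParameters
    initial_state: CultivationState


def generate_clone_library(
    base: ModelParameters,
    n_clones: int,
    spread: float,
    seed: int | None = None,
    initial_state: CultivationState | None = None,
) -> list[CloneSpec]:
    """Synthetic clone phenotypes: estimable parameters of ``base`` scaled by
    (1 + eta), eta ~ N(0, spread^2), clipped to bounds.  Clone 0 is the
    unperturbed base."""
    if not 0 <= spread <= 0.5:
        raise ValueError("spread must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    if initial_state is None:
        initial_state = CultivationState(t=0.0, X=1.3, S=5.0, A=0.0, DOT=100.0, P=0.0, V=0.010)
    clones = []
    for i in range(n_clones):
        if i == 0:
            params = base.copy()
        else:
            eta = rng.standard_normal(len(ESTIMABLE_PARAMETERS)) * spread
            values = base.to_array() * (1.0 + eta)
            lo = np.array([base.bounds[n][0] for n in ESTIMABLE_PARAMETERS])
            hi = np.array([base.bounds[n][1] for n in ESTIMABLE_PARAMETERS])
            params = base.with_values(ESTIMABLE_PARAMETERS, np.clip(values, lo, hi))
        clones.append(CloneSpec(
            clone_id=f"clone{i:02d}",
            true_parameters=params,
            initial_state=replace(initial_state),
        ))
    return clones


def od_to_dcw(od_raw: float, dilution: float,
              plan: SamplingPlan | None = None) -> float:
    """Dry cell weight (g/L) from a raw diluted OD600 reading:
    DCW = OD_raw * dilution * 2.62 (path correction) * 0.33."""
    if od_raw < 0:
        raise ValueError("od_raw must be >= 0")
    if plan is not None:
        lo, hi = plan.dilution_bounds
        if not lo <= dilution <= hi:
            warnings.warn(f"dilution {dilution} outside plan bounds [{lo}, {hi}]")
    return od_raw * dilution * OD_PATH_FACTOR * OD_TO_DCW


def _dcw_roundtrip(dcw: float, plan: SamplingPlan) -> float:
    """Send a true DCW through the OD measurement path and back."""
    if dcw <= 0:
        return 0.0
    # dilute so the raw OD reading sits in the linear range (~0.3)
    od_1cm = dcw / OD_TO_DCW
    dilution = float(np.clip(od_1cm / OD_PATH_FACTOR / 0.3, *plan.dilution_bounds))
    od_raw = dcw / (OD_TO_DCW * OD_PATH_FACTOR * dilution)
    return od_to_dcw(od_raw, dilution)


def sampling_events(plan: SamplingPlan) -> list[PulseEvent]:
    """Volume-removal events for every distinct at-line draw."""
    times = sorted(set(plan.biomass_times) | set(plan.glucose_times) | set(plan.acetate_times))
    return [PulseEvent(t=t, kind="sample", volume=-plan.sample_volume) for t in times]


def run_reactor(
    clone: CloneSpec,
    schedule: FeedSchedule | Sequence[PulseEvent] | None,
    plan: SamplingPlan,
    noise: NoiseModel,
    seed: int | None = None,
    reactor_id: str = "R01",
    column: int = 0,
    extra_events: Sequence[PulseEvent] = (),
    until: float | None = None,
) -> MeasurementSet:
    """Run one reactor under its true parameters and emit its measurements.

    ``schedule`` provides the feed pulses (or any explicit event list);
    ``extra_events`` adds protocol events such as the batch top-up pulse.
    ``until`` truncates emission to samples taken up to that time (the full
    event history is still attached, so re-running with a longer ``until``
    extends the record without changing earlier values).  Noise draws are
    positional per record under the given seed, so the emitted values for a
    given sample time are reproducible across calls.
    """
    if isinstance(schedule, FeedSchedule):
        feed_events = list(schedule.pulses)
    else:
        feed_events = list(schedule or [])
    events = sorted(
        [e for e in feed_events + list(extra_events) if e.volume != 0.0 or e.kind != "feed"]
        + sampling_events(plan),
        key=lambda e: e.t,
    )
    events = [e for e in events if e.t <= plan.run_length + 1e-12]
    horizon = plan.run_length
    until = horizon if until is None else min(until, horizon)

    t_online = plan.online_times()
    cut = plan.run_length + 1e-12
    t_b = np.asarray([t for t in plan.biomass_times if t <= cut], dtype=float)
    t_g = np.asarray([t for t in plan.glucose_times if t <= cut], dtype=float)
    t_a = np.asarray([t for t in plan.acetate_times if t <= cut], dtype=float)
    all_t = np.unique(np.concatenate([t_online, t_b, t_g, t_a]))

    traj = simulate(clone.true_parameters, replace(clone.initial_state), events,
                    horizon=horizon, output_times=all_t)
    pos = {t: i for i, t in enumerate(traj.t)}

    rng = np.random.default_rng(seed)
    flags: list[str] = []
    if traj.S.max() > 20.0:
        flags.append(f"overfeeding: glucose reached {traj.S.max():.1f} g/L")
    if traj.X[-1] < clone.initial_state.X * 0.5:
        flags.append("washout: biomass fell below half the inoculum")

    records: list[tuple] = []

    def emit(variable: str, t_sample: np.ndarray, values: np.ndarray, delay: float):
        sigma = noise.sigma_rel.get(variable, 0.0)
        eps = rng.standard_normal(len(t_sample)) * sigma
        noisy = np.clip(values * (1.0 + eps), 0.0, None)
        for t, v in zip(t_sample, noisy):
            if t <= until + 1e-12:
                records.append((reactor_id, clone.clone_id, variable, float(t),
                                float(t + delay), float(v)))

    emit("DOT", t_online, np.array([traj.DOT[pos[t]] for t in t_online]), 0.0)
    x_true = np.array([_dcw_roundtrip(traj.X[pos[t]], plan) for t in t_b])
    emit("biomass", t_b, x_true, plan.delay("biomass", column))
    emit("glucose", t_g, np.array([traj.S[pos[t]] for t in t_g]),
         plan.delay("glucose", column))
    emit("acetate", t_a, np.array([traj.A[pos[t]] for t in t_a]),
         plan.delay("acetate", column))

    u = ReactorInput(initial=replace(clone.initial_state), events=events)
    ms = MeasurementSet.from_records(records, {reactor_id: u})
    ms.flags = flags  # type: ignore[attr-defined]
    ms.trajectory = traj  # type: ignore[attr-defined]
    return ms
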