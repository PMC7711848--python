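"""Closed-loop campaign orchestration.

Per clone, the loop repeats on every arrival of new at-line data: pool all
available measurements of the biological triplicate -> select the
identifiable parameter subset -> re-fit it -> predict batch end -> redesign
the pulse-feed schedule -> commit the future pulses to all replicates.  The
virtual plant stands in for the robotic facility; the controller only ever
sees measurements whose availability time has passed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .estimation import EstimationResult, MeasurementSet, fit, objective
from .feed_design import (
    FeedSchedule,
    FeedSettings,
    NoBatchEndError,
    design_feed,
    predict_batch_end,
)
from .identifiability import SensitivityMatrix, SubsetSelection, select_subset, sensitivity_matrix
from .model import CultivationState, PulseEvent, mu_max, simulate
from .parameters import ModelParameters, initial_guess
from .uncertainty import NoiseModel
from .virtual_plant import CloneSpec, SamplingPlan, run_reactor, sampling_events


@dataclass
class CampaignConfig:
    """Everything needed to run a virtual screening campaign."""

    clones: list[CloneSpec]
    replicates: int = 3
    feed: FeedSettings = field(default_factory=FeedSettings)
    plan: SamplingPlan = field(default_factory=SamplingPlan)
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    initial_parameters: ModelParameters = field(default_factory=initial_guess)
    #: nominal inoculation state assumed by the controller (medium is known;
    #: the biomass belief is corrected from the first at-line measurement)
    nominal_initial: CultivationState = field(
        default_factory=lambda: CultivationState(t=0.0, X=1.3, S=5.0, A=0.0,
                                                 DOT=100.0, P=0.0, V=0.010))
    batch_top_up_time: float = 1.0
    batch_top_up_target: float = 5.0  # g/L glucose after the top-up pulse
    collinearity_threshold: float = 25.0
    fd_step: float = 1e-4
    #: minimum simulated time between calibration cycles of one clone
    min_cycle_gap: float = 0.75
    objective_weighting: str = "relative"
    estimate: bool = True
    redesign: bool = True
    update_initial_biomass: bool = True
    fit_max_nfev: int | None = 60
    sim_rtol: float | None = None
    sim_atol: float | None = None

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.feed.horizon < self.plan.run_length:
            self.feed = replace(self.feed, horizon=self.plan.run_length)


@dataclass
class CalibrationCycleResult:
    """One pass of the calibration cycle for one clone."""

    index: int
    trigger_time: float
    data_counts: dict[str, int]
    selection: SubsetSelection | None
    estimation: EstimationResult
    t_glucose_depleted: float | None
    feed_start: float | None
    schedule: FeedSchedule | None
    mu_set: float | None
    belief_initial: CultivationState
    degraded: bool = False
    message: str = ""


@dataclass
class CloneLog:
    clone_id: str
    reactor_ids: list[str]
    cycles: list[CalibrationCycleResult]
    final_parameters: ModelParameters
    final_schedule: FeedSchedule | None
    measurements: MeasurementSet
    flags: list[str] = field(default_factory=list)

    @property
    def mu_max_sequence(self) -> list[float]:
        return [mu_max(c.estimation.theta_hat) for c in self.cycles]


@dataclass
class CampaignResult:
    config: CampaignConfig
    clones: list[CloneLog]

    def clone(self, clone_id: str) -> CloneLog:
        for log in self.clones:
            if log.clone_id == clone_id:
                return log
        raise KeyError(clone_id)


def _belief_events(schedule: FeedSchedule | None, extra: Sequence[PulseEvent],
                   plan: SamplingPlan) -> list[PulseEvent]:
    """The controller's copy of the committed input history."""
    events = list(extra) + sampling_events(plan)
    if schedule is not None:
        events += [p for p in schedule.pulses if p.volume > 0]
    return sorted(events, key=lambda e: e.t)


def cycle(
    data_now: MeasurementSet,
    previous: CalibrationCycleResult | None,
    config: CampaignConfig,
    trigger_time: float | None = None,
    committed: FeedSchedule | None = None,
    extra_events: Sequence[PulseEvent] = (),
    index: int = 0,
) -> CalibrationCycleResult:
    """One calibration cycle: subset selection -> fit -> feed redesign.

    Parameters outside the selected subset carry over from the previous
    cycle.  With an empty subset the fit is skipped but the feed is still
    recomputed from the carried-over model (degraded mode).  Idempotent on
    unchanged data.
    """
    if trigger_time is None:
        trigger_time = float(data_now.frame["t_available_h"].max()) if len(data_now) else 0.0
    params_prev = (previous.estimation.theta_hat if previous is not None
                   else config.initial_parameters).copy()
    committed = committed if committed is not None else (
        previous.schedule if previous is not None else None)
    belief0 = (previous.belief_initial if previous is not None
               else replace(config.nominal_initial))

    # first cycle: correct the biomass belief from the earliest measurement,
    # back-extrapolated to inoculation at the model's maximum growth rate
    if previous is None and config.update_initial_biomass:
        bio = data_now.frame[data_now.frame["variable"] == "biomass"]
        if len(bio):
            t0 = float(bio["t_sample_h"].min())
            v0 = float(bio.loc[bio["t_sample_h"] == t0, "value"].mean())
            if v0 > 0:
                belief0 = replace(belief0, X=v0 * math.exp(-mu_max(params_prev) * t0))

    degraded = False
    message = ""
    selection: SubsetSelection | None = None
    if config.estimate and len(data_now):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            S = sensitivity_matrix(params_prev, data_now, perturbation=config.fd_step,
                                   rtol=config.sim_rtol, atol=config.sim_atol)
            selection = select_subset(S, threshold=config.collinearity_threshold)
        if selection.selected:
            est = fit(params_prev, selection.selected, data_now,
                      weighting=config.objective_weighting, rtol=config.sim_rtol,
                      atol=config.sim_atol, max_nfev=config.fit_max_nfev)
        else:
            degraded = True
            message = "empty identifiable subset: parameters carried over"
            est = _passthrough(params_prev, data_now, config)
    else:
        est = _passthrough(params_prev, data_now, config)

    # controller belief of the current state under the committed inputs
    events = _belief_events(committed, extra_events, config.plan)
    past = [e for e in events if e.t <= trigger_time + 1e-12]
    traj = simulate(est.theta_hat, replace(belief0), past, horizon=trigger_time,
                    output_times=[trigger_time], rtol=config.sim_rtol, atol=config.sim_atol)
    state_now = traj.state_at(-1)

    mu_set = config.feed.mu_set_fraction * mu_max(est.theta_hat)
    t_dep = feed_start = None
    schedule = committed
    if config.redesign or committed is None:
        future_nonfeed = [e for e in events if e.t > trigger_time and e.kind != "feed"]
        try:
            if committed is None or committed.feed_start > trigger_time:
                t_dep, feed_start = predict_batch_end(
                    est.theta_hat, state_now, config.feed.horizon,
                    threshold=config.feed.batch_end_threshold,
                    acetate_wait_cap=config.feed.acetate_wait_cap,
                    events=future_nonfeed,
                )
            else:
                t_dep = previous.t_glucose_depleted if previous else None
                feed_start = committed.feed_start
            schedule = design_feed(est, state_now, config.feed,
                                   committed=committed, events=future_nonfeed)
        except NoBatchEndError as exc:
            degraded = True
            message = (message + "; " if message else "") + f"feed design deferred: {exc}"
            schedule = committed

    return CalibrationCycleResult(
        index=index, trigger_time=trigger_time, data_counts=data_now.counts(),
        selection=selection, estimation=est, t_glucose_depleted=t_dep,
        feed_start=feed_start, schedule=schedule, mu_set=mu_set,
        belief_initial=belief0, degraded=degraded, message=message,
    )


def _passthrough(params: ModelParameters, data: MeasurementSet,
                 config: CampaignConfig) -> EstimationResult:
    phi = objective(params, data, config.objective_weighting,
                    config.sim_rtol, config.sim_atol) if len(data) else 0.0
    return EstimationResult(
        theta_hat=params.copy(), subset=[], objective=phi,
        per_variable_residuals={}, converged=True, bounds_active={},
        message="estimation skipped",
    )


def _top_up_event(config: CampaignConfig) -> PulseEvent | None:
    """Protocol pulse restoring the batch glucose concentration, sized from
    the controller's prior prediction."""
    t = config.batch_top_up_time
    if t is None or t <= 0:
        return None
    traj = simulate(config.initial_parameters, replace(config.nominal_initial),
                    [], horizon=t, output_times=[t])
    S_pred, V_pred = float(traj.S[-1]), float(traj.V[-1])
    target, Si = config.batch_top_up_target, config.feed.Si
    if S_pred >= target:
        return None
    v = V_pred * (target - S_pred) / (Si - target)
    return PulseEvent(t=t, kind="feed", volume=v, glucose_mass=v * Si)


def _triggers(config: CampaignConfig, columns: Sequence[int]) -> list[float]:
    """Calibration trigger times: at-line availability events, starting at
    the second biomass availability, separated by at least min_cycle_gap."""
    plan = config.plan
    avail: set[float] = set()
    bio_avail: set[float] = set()
    for col in columns:
        for t in plan.biomass_times:
            a = t + plan.delay("biomass", col)
            avail.add(a)
            bio_avail.add(a)
        for t in plan.glucose_times:
            avail.add(t + plan.delay("glucose", col))
        for t in plan.acetate_times:
            avail.add(t + plan.delay("acetate", col))
    avail = sorted(a for a in avail if a <= plan.run_length)
    start = sorted(bio_avail)[1] if len(bio_avail) > 1 else (min(bio_avail) if bio_avail else 0.0)
    out: list[float] = []
    for a in avail:
        if a < start - 1e-12:
            continue
        if not out or a >= out[-1] + config.min_cycle_gap - 1e-12:
            out.append(a)
    return out


def run_campaign(config: CampaignConfig) -> CampaignResult:
    """Run the full closed-loop campaign on the virtual plant.

    Each clone is calibrated against its pooled biological replicates and
    receives one shared feed schedule, applied to all of them.  A clone
    whose cycles keep failing falls back to the last good (or initial-guess)
    schedule and is prominently flagged; the plant never stalls.
    """
    ss = np.random.SeedSequence(config.seed)
    clone_seeds = ss.spawn(len(config.clones))
    logs: list[CloneLog] = []

    for ci, clone in enumerate(config.clones):
        rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in clone_seeds[ci].spawn(config.replicates)]
        reactor_ids = [f"{clone.clone_id}-r{j}" for j in range(config.replicates)]
        columns = [(ci * config.replicates + j) % config.plan.n_columns
                   for j in range(config.replicates)]
        top_up = _top_up_event(config)
        extra = [top_up] if top_up is not None else []

        committed: FeedSchedule | None = None
        prev: CalibrationCycleResult | None = None
        cycles: list[CalibrationCycleResult] = []
        flags: list[str] = []

        def plant_measurements(until: float) -> MeasurementSet:
            ms: MeasurementSet | None = None
            for j in range(config.replicates):
                m = run_reactor(clone, committed, config.plan, config.noise,
                                seed=rep_seeds[j], reactor_id=reactor_ids[j],
                                column=columns[j], extra_events=extra, until=until)
                ms = m if ms is None else ms.merged(m)
                for f in getattr(m, "flags", []):
                    tag = f"{reactor_ids[j]}: {f}"
                    if tag not in flags:
                        flags.append(tag)
            return ms

        for k, t in enumerate(_triggers(config, columns)):
            data_now = plant_measurements(until=t).available_at(t)
            if not len(data_now):
                continue
            try:
                result = cycle(data_now, prev, config, trigger_time=t,
                               committed=committed, extra_events=extra, index=k)
            except Exception as exc:  # noqa: BLE001 - robot-never-stalls contract
                flags.append(f"cycle {k} at t={t:.2f} h failed: {exc}; "
                             "falling back to previous schedule")
                continue
            committed = result.schedule
            prev = result
            cycles.append(result)

        if committed is None:
            # no cycle ever produced a schedule: open-loop initial-guess feed
            flags.append("no successful calibration cycle: initial-guess feeding")
            try:
                committed = design_feed(config.initial_parameters,
                                        replace(config.nominal_initial), config.feed,
                                        events=_belief_events(None, extra, config.plan))
            except NoBatchEndError:
                committed = None

        final_ms = plant_measurements(until=config.plan.run_length)
        logs.append(CloneLog(
            clone_id=clone.clone_id, reactor_ids=reactor_ids, cycles=cycles,
            final_parameters=(prev.estimation.theta_hat if prev is not None
                              else config.initial_parameters.copy()),
            final_schedule=committed, measurements=final_ms, flags=flags,
        ))
    return CampaignResult(config=config, clones=logs)
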