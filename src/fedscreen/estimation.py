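"""Weighted least-squares calibration of the growth model.

The objective pools all measured variables (DOT, biomass, glucose, acetate)
across replicates, normalizing each variable's squared-residual sum by its
number of data points; by default residuals are additionally divided by a
per-variable scale (mean absolute measured value) so %-scale DOT does not
swamp the g/L concentrations.  Only the identifiable parameter subset is
optimized; everything else stays at its incoming value.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model import CultivationState, PulseEvent, simulate
from .parameters import ESTIMABLE_PARAMETERS, ModelParameters

#: Measured variable -> simulated state attribute.
VARIABLE_STATE: dict[str, str] = {
    "DOT": "DOT",
    "biomass": "X",
    "glucose": "S",
    "acetate": "A",
}

VARIABLES = tuple(VARIABLE_STATE)

_COLUMNS = ["reactor_id", "clone_id", "variable", "t_sample_h", "t_available_h", "value", "unit"]

_DEFAULT_UNITS = {"DOT": "%", "biomass": "g/L", "glucose": "g/L", "acetate": "g/L"}

#: Scale floor so an all-zero variable does not produce infinite weights.
SCALE_FLOOR = 1e-3

#: Relative assay noise of the facility's measurement channels.
DEFAULT_SIGMA_REL = {"biomass": 0.15, "glucose": 0.15, "acetate": 0.15, "DOT": 0.05}


@dataclass
class ReactorInput:
    """Applied input history of one reactor: initial state plus all discrete
    feed/sample/balance events (the ``U`` of the estimation problem)."""

    initial: CultivationState
    events: list[PulseEvent] = field(default_factory=list)

    def sorted_events(self) -> list[PulseEvent]:
        return sorted(self.events, key=lambda e: e.t)

    def key(self) -> tuple:
        ini = self.initial
        return (
            (ini.t, ini.X, ini.S, ini.A, ini.DOT, ini.P, ini.V),
            tuple((e.t, e.kind, e.volume, e.glucose_mass) for e in self.sorted_events()),
        )


class MeasurementSet:
    """Observed values with sampling and availability times, plus the applied
    input history per reactor."""

    def __init__(self, frame: pd.DataFrame | None = None,
                 inputs: Mapping[str, ReactorInput] | None = None):
        if frame is None:
            frame = pd.DataFrame(columns=_COLUMNS)
        missing = [c for c in _COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"measurement table missing columns {missing}")
        bad = set(frame["variable"]) - set(VARIABLES)
        if bad:
            raise ValueError(f"unknown measured variables {sorted(bad)}")
        if len(frame) and (frame["t_available_h"] < frame["t_sample_h"] - 1e-12).any():
            raise ValueError("availability time precedes sampling time")
        if len(frame) and not np.isfinite(frame["value"].to_numpy(dtype=float)).all():
            raise ValueError("non-finite measurement values")
        self.frame = frame.reset_index(drop=True)
        self.inputs: dict[str, ReactorInput] = dict(inputs or {})

    def __len__(self) -> int:
        return len(self.frame)

    def counts(self) -> dict[str, int]:
        """Data points per variable (the N_i of the objective)."""
        c = self.frame["variable"].value_counts().to_dict()
        return {v: int(c.get(v, 0)) for v in VARIABLES}

    def available_at(self, t: float) -> "MeasurementSet":
        """Information-causal view: records whose results have arrived by t."""
        return MeasurementSet(self.frame[self.frame["t_available_h"] <= t + 1e-12], self.inputs)

    def for_reactors(self, reactor_ids: Iterable[str]) -> "MeasurementSet":
        ids = set(reactor_ids)
        return MeasurementSet(
            self.frame[self.frame["reactor_id"].isin(ids)],
            {r: u for r, u in self.inputs.items() if r in ids},
        )

    def merged(self, other: "MeasurementSet") -> "MeasurementSet":
        frame = pd.concat([self.frame, other.frame], ignore_index=True)
        inputs = {**self.inputs, **other.inputs}
        return MeasurementSet(frame, inputs)

    def reactor_groups(self) -> dict:
        """Group reactors by identical input history so that replicates
        sharing a feed schedule are simulated once per parameter vector."""
        groups: dict = {}
        for rid in self.frame["reactor_id"].unique():
            if rid not in self.inputs:
                raise KeyError(f"no input history for reactor {rid!r}")
            u = self.inputs[rid]
            key = u.key()
            if key not in groups:
                groups[key] = ([], u.sorted_events(), u.initial)
            groups[key][0].append(rid)
        return groups

    # -- delimited-text round trip -----------------------------------------

    def to_csv(self, path_or_buf) -> None:
        self.frame[_COLUMNS].to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf, inputs: Mapping[str, ReactorInput] | None = None
                 ) -> "MeasurementSet":
        frame = pd.read_csv(path_or_buf)
        return cls(frame, inputs)

    @classmethod
    def from_records(cls, records: Sequence[tuple],
                     inputs: Mapping[str, ReactorInput] | None = None) -> "MeasurementSet":
        """Records as (reactor_id, clone_id, variable, t_sample, t_available,
        value); units filled from the variable defaults."""
        frame = pd.DataFrame(records, columns=_COLUMNS[:-1])
        frame["unit"] = frame["variable"].map(_DEFAULT_UNITS)
        return cls(frame, inputs)


def variable_scales(data: MeasurementSet, scaled: bool = True) -> dict[str, float]:
    """Per-variable residual scale: mean absolute measured value, floored.
    In strict (unscaled) mode every scale is one."""
    if not scaled:
        return {v: 1.0 for v in VARIABLES}
    out = {}
    for v in VARIABLES:
        vals = data.frame.loc[data.frame["variable"] == v, "value"].to_numpy(dtype=float)
        out[v] = max(float(np.mean(np.abs(vals))), SCALE_FLOOR) if vals.size else 1.0
    return out


@dataclass
class EstimationResult:
    theta_hat: ModelParameters
    subset: list[str]
    objective: float
    per_variable_residuals: dict[str, float]
    converged: bool
    bounds_active: dict[str, str]  # parameter -> "lower" | "upper"
    simulation_failed: bool = False
    n_function_evals: int = 0
    message: str = ""


class _CompiledData:
    """Pre-resolved simulation plan for one measurement set: per reactor
    group, the union of needed output times and, per record, where to read
    its value from the resulting trajectory.  Avoids re-doing the pandas
    bookkeeping on every objective evaluation inside a fit."""

    def __init__(self, data: MeasurementSet):
        df = data.frame
        self.n = len(df)
        self.groups = []
        state_idx = {"X": 0, "S": 1, "A": 2, "DOT": 3}
        for _, (reactor_ids, events, initial) in data.reactor_groups().items():
            mask = df["reactor_id"].isin(reactor_ids).to_numpy()
            sub = df.loc[mask]
            t_sample = sub["t_sample_h"].to_numpy(dtype=float)
            t_need = np.unique(t_sample)
            pos = np.searchsorted(t_need, t_sample)
            comp = sub["variable"].map(VARIABLE_STATE).map(state_idx).to_numpy()
            self.groups.append((np.flatnonzero(mask), events, initial,
                                t_need, pos, comp))

    def outputs(self, params: ModelParameters, rtol=None, atol=None) -> np.ndarray:
        out = np.empty(self.n)
        for idx, events, initial, t_need, pos, comp in self.groups:
            horizon = max(float(t_need.max()), initial.t) if t_need.size else initial.t
            traj = simulate(params, replace(initial), events, horizon=horizon,
                            output_times=t_need, rtol=rtol, atol=atol)
            stacked = np.vstack([traj.X, traj.S, traj.A, traj.DOT])
            out[idx] = stacked[comp, pos]
        return out


def _simulated_outputs(params: ModelParameters, data: MeasurementSet,
                       rtol=None, atol=None) -> np.ndarray:
    """Model outputs at every (reactor, variable, t_sample) row of ``data``."""
    return _CompiledData(data).outputs(params, rtol, atol)


#: Finite surrogate residual magnitude used when a simulation fails; keeps
#: the optimizer total while strongly penalizing the parameter point.
_FAILURE_RESIDUAL = 1e6


def residual_weights(data: MeasurementSet, weighting: str = "variable") -> np.ndarray:
    """Per-record residual weights w such that Phi = sum((w*(y-y^m))^2).

    Modes: ``strict`` -- plain per-variable 1/N_i pooling; ``variable`` --
    additionally divides by a per-variable scale (mean absolute measured
    value) so %-scale DOT and g/L concentrations are commensurable;
    ``relative`` -- per-point weights 1/(sigma_rel * |y^m|) matching the
    multiplicative assay-noise model (floored near zero), the maximum-
    likelihood choice for these data."""
    df = data.frame
    counts = data.counts()
    inv_sqrt_n = df["variable"].map(
        {v: 1.0 / np.sqrt(counts[v]) if counts[v] else 0.0 for v in VARIABLES}
    ).to_numpy(dtype=float)
    if weighting == "strict":
        return inv_sqrt_n
    scales = variable_scales(data, True)
    if weighting == "variable":
        return inv_sqrt_n / df["variable"].map(scales).to_numpy(dtype=float)
    if weighting == "relative":
        sigma = df["variable"].map(DEFAULT_SIGMA_REL).to_numpy(dtype=float)
        floor = df["variable"].map(
            {v: max(0.05 * scales[v], SCALE_FLOOR) for v in VARIABLES}
        ).to_numpy(dtype=float)
        y = np.abs(df["value"].to_numpy(dtype=float))
        return inv_sqrt_n / (sigma * np.maximum(y, floor))
    raise ValueError(f"unknown weighting mode {weighting!r}")


def residual_vector(params: ModelParameters, data: MeasurementSet,
                    weighting: str = "variable", rtol: float | None = None, atol: float | None = None,
                    ) -> tuple[np.ndarray, bool]:
    """Weighted residuals r with Phi = sum(r^2); per-variable 1/N_i pooling
    with the ``weighting`` mode's scaling.  Returns (residuals, failed)."""
    df = data.frame
    if not len(df):
        return np.zeros(0), False
    w = residual_weights(data, weighting)
    try:
        y_sim = _simulated_outputs(params, data, rtol, atol)
    except Exception:  # noqa: BLE001 - surrogate keeps the optimizer total
        return np.full(len(df), _FAILURE_RESIDUAL), True
    if not np.isfinite(y_sim).all():
        return np.full(len(df), _FAILURE_RESIDUAL), True
    return (y_sim - df["value"].to_numpy(dtype=float)) * w, False


def objective(params: ModelParameters, data: MeasurementSet, weighting: str = "variable",
              rtol: float | None = None, atol: float | None = None) -> float:
    """Pooled weighted sum-of-squares objective; +inf surrogate on
    simulation failure."""
    r, failed = residual_vector(params, data, weighting, rtol, atol)
    if failed:
        return np.inf
    return float(r @ r)


def _per_variable_residuals(params, data, rtol, atol) -> dict[str, float]:
    df = data.frame
    try:
        y_sim = _simulated_outputs(params, data, rtol, atol)
    except Exception:  # noqa: BLE001
        return {v: np.inf for v in VARIABLES}
    res = y_sim - df["value"].to_numpy(dtype=float)
    out = {}
    for v in VARIABLES:
        mask = (df["variable"] == v).to_numpy()
        out[v] = float(np.sum(res[mask] ** 2))
    return out


def fit(
    params0: ModelParameters,
    subset: Sequence[str],
    data: MeasurementSet,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    weighting: str = "variable",
    rtol: float | None = None,
    atol: float | None = None,
    ftol: float = 1e-10,
    xtol: float = 1e-10,
    diff_step: float = 1e-4,
    max_nfev: int | None = None,
) -> EstimationResult:
    """Bounded local weighted least squares over the identifiable subset.

    Deterministic given inputs and tolerances.  Parameters outside the
    subset keep their incoming values; the result flags any fitted value
    sitting on a bound (a warning sign for the parameter's credibility).
    """
    subset = list(subset)
    unknown = [s for s in subset if s not in ESTIMABLE_PARAMETERS]
    if unknown:
        raise ValueError(f"subset contains non-estimable parameters {unknown}")
    phi0 = objective(params0, data, weighting, rtol, atol)
    if not subset or not len(data):
        return EstimationResult(
            theta_hat=params0.copy(), subset=[], objective=phi0,
            per_variable_residuals=_per_variable_residuals(params0, data, rtol, atol),
            converged=True, bounds_active={}, simulation_failed=not np.isfinite(phi0),
            message="empty subset or no data: parameters unchanged",
        )

    bmap = dict(params0.bounds)
    if bounds:
        bmap.update(bounds)
    lo = np.array([bmap[s][0] for s in subset])
    hi = np.array([bmap[s][1] for s in subset])
    x0 = np.clip(params0.to_array(subset), lo, hi)

    sim_failed = {"flag": False}
    compiled = _CompiledData(data)
    w = residual_weights(data, weighting)
    y_meas = data.frame["value"].to_numpy(dtype=float)

    def fun(x):
        try:
            y_sim = compiled.outputs(params0.with_values(subset, x), rtol, atol)
        except Exception:  # noqa: BLE001 - surrogate keeps the optimizer total
            sim_failed["flag"] = True
            return np.full(compiled.n, _FAILURE_RESIDUAL)
        if not np.isfinite(y_sim).all():
            sim_failed["flag"] = True
            return np.full(compiled.n, _FAILURE_RESIDUAL)
        return (y_sim - y_meas) * w

    # the jacobian step must sit well above the integrator's noise floor,
    # or shallow (sloppy) directions get garbage gradients and the fit stalls
    res = least_squares(
        fun, x0, bounds=(lo, hi), method="trf",
        x_scale=np.maximum(np.abs(x0), 1e-6), diff_step=diff_step,
        ftol=ftol, xtol=xtol, gtol=1e-12, max_nfev=max_nfev,
    )
    theta_hat = params0.with_values(subset, res.x)
    phi_hat = 2.0 * float(res.cost)
    improved = phi_hat <= phi0 + 1e-15
    if not improved:  # optimizer worse than the start: keep params0
        theta_hat, phi_hat = params0.copy(), phi0

    tol = 1e-9
    active = {}
    for s, x, l, h in zip(subset, theta_hat.to_array(subset), lo, hi):
        span = max(h - l, 1e-300)
        if (x - l) / span < tol:
            active[s] = "lower"
        elif (h - x) / span < tol:
            active[s] = "upper"

    return EstimationResult(
        theta_hat=theta_hat,
        subset=subset,
        objective=phi_hat,
        per_variable_residuals=_per_variable_residuals(theta_hat, data, rtol, atol),
        converged=bool(res.status > 0) and improved,
        bounds_active=active,
        simulation_failed=sim_failed["flag"],
        n_function_evals=int(res.nfev),
        message=str(res.message) if improved else "no improvement over starting point",
    )


def estimation_report(result: EstimationResult, cycle_time: float | None = None) -> str:
    """Structured-text provenance record of one fit."""
    buf = io.StringIO()
    if cycle_time is not None:
        buf.write(f"cycle_time_h: {cycle_time:.4f}\n")
    buf.write(f"objective: {result.objective:.8g}\n")
    buf.write(f"converged: {result.converged}\n")
    buf.write(f"subset: {','.join(result.subset) if result.subset else '-'}\n")
    for name in ESTIMABLE_PARAMETERS:
        flag = f" [{result.bounds_active[name]} bound]" if name in result.bounds_active else ""
        buf.write(f"  {name}: {getattr(result.theta_hat, name):.6g}{flag}\n")
    for v, r in result.per_variable_residuals.items():
        buf.write(f"residual_ss[{v}]: {r:.6g}\n")
    return buf.getvalue()
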