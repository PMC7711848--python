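"""Monte Carlo parameter- and predictive-uncertainty analysis.

Parametric bootstrap around the point fit: the measurement set is
repeatedly re-perturbed with the assay noise model (relative Gaussian,
sigma 0.15 for biomass/glucose/acetate and 0.05 for DOT), the identifiable
subset is re-fitted from the point estimate each time, and the best
(lowest-objective) draws form the ensemble used for parameter statistics
and predictive quantile bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .estimation import DEFAULT_SIGMA_REL, EstimationResult, MeasurementSet, fit
from .model import CultivationState, PulseEvent, simulate
from .parameters import ModelParameters

@dataclass
class NoiseModel:
    """Multiplicative Gaussian measurement noise, per variable."""

    sigma_rel: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SIGMA_REL))
    seed: int | None = None

    def __post_init__(self) -> None:
        for v, s in self.sigma_rel.items():
            if s < 0:
                raise ValueError(f"sigma_rel[{v!r}] must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def perturb_dataset(data: MeasurementSet, noise: NoiseModel,
                    rng: np.random.Generator | None = None) -> MeasurementSet:
    """Each value multiplied by (1 + eps), eps ~ N(0, sigma_rel^2); negative
    results clipped to zero.  Deterministic under a fixed seed."""
    rng = noise.rng() if rng is None else rng
    frame = data.frame.copy()
    sigma = frame["variable"].map(lambda v: noise.sigma_rel.get(v, 0.0)).to_numpy(dtype=float)
    eps = rng.standard_normal(len(frame)) * sigma
    frame["value"] = np.clip(frame["value"].to_numpy(dtype=float) * (1.0 + eps), 0.0, None)
    return MeasurementSet(frame, data.inputs)


@dataclass
class MonteCarloEnsemble:
    draws: list[EstimationResult]
    kept: list[int]
    subset: list[str]
    parameter_table: pd.DataFrame  # kept draws x subset parameters
    mean: pd.Series
    sigma: pd.Series        # sigma_theta
    percent_sigma: pd.Series  # 100 * sigma_theta / mean
    correlation: pd.DataFrame
    n_failed: int = 0
    degenerate: bool = False  # all draws identical (e.g. zero noise)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sigma": self.sigma,
                             "percent_sigma": self.percent_sigma})


def monte_carlo(
    data: MeasurementSet,
    theta_hat: ModelParameters,
    subset: Sequence[str],
    n_draws: int = 550,
    n_keep: int = 500,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    weighting: str = "variable",
    max_nfev: int | None = 40,
) -> MonteCarloEnsemble:
    """Bootstrap ensemble of re-fits on re-perturbed data.

    The ``n_keep`` draws with the lowest objective are retained for the
    statistics.  Individual non-convergent draws are dropped and counted;
    above a 20% drop rate a warning is raised.
    """
    if n_keep > n_draws:
        raise ValueError("n_keep must not exceed n_draws")
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    subset = list(subset)

    draws: list[EstimationResult] = []
    n_failed = 0
    for _ in range(n_draws):
        perturbed = perturb_dataset(data, noise, rng)
        result = fit(theta_hat, subset, perturbed, weighting=weighting, max_nfev=max_nfev)
        if result.simulation_failed and not np.isfinite(result.objective):
            n_failed += 1
            continue
        draws.append(result)
    if n_draws and n_failed > 0.2 * n_draws:
        warnings.warn(f"{n_failed}/{n_draws} Monte Carlo draws failed to converge")

    order = np.argsort([d.objective for d in draws], kind="stable")
    kept = list(order[: min(n_keep, len(draws))])

    table = pd.DataFrame(
        [[getattr(draws[i].theta_hat, s) for s in subset] for i in kept],
        columns=subset,
    )
    mean = table.mean()
    sigma = table.std(ddof=1) if len(table) > 1 else pd.Series(0.0, index=subset)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * sigma / mean.where(mean != 0, np.nan)
    degenerate = bool(len(table) > 1 and np.allclose(table.std(ddof=0), 0.0))
    if degenerate or len(table) <= 1:
        corr = pd.DataFrame(np.eye(len(subset)) * 0.0, index=subset, columns=subset)
    else:
        corr = table.corr().fillna(0.0)
        np.fill_diagonal(corr.values, 1.0)
    return MonteCarloEnsemble(
        draws=draws, kept=kept, subset=subset, parameter_table=table,
        mean=mean, sigma=sigma.fillna(0.0), percent_sigma=pct.fillna(0.0),
        correlation=corr, n_failed=n_failed, degenerate=degenerate,
    )


def predictive_band(
    ensemble: MonteCarloEnsemble,
    initial: CultivationState,
    events: Sequence[PulseEvent],
    output_times: Iterable[float],
    quantiles: Sequence[float] = (0.025, 0.5, 0.975),
) -> dict[str, pd.DataFrame]:
    """Pointwise quantile envelopes of X, S, A, DOT over the kept draws.

    Returns variable -> DataFrame indexed by time with one column per
    quantile.  Draws whose simulation fails are dropped (counted in the
    ``n_dropped`` attribute attached to each frame)."""
    if not ensemble.kept:
        raise ValueError("empty ensemble")
    t_out = np.asarray(list(output_times), dtype=float)
    horizon = float(t_out.max())
    trajs = {"X": [], "S": [], "A": [], "DOT": []}
    n_dropped = 0
    from dataclasses import replace

    for i in ensemble.kept:
        theta = ensemble.draws[i].theta_hat
        try:
            tr = simulate(theta, replace(initial), events, horizon=horizon, output_times=t_out)
        except Exception:  # noqa: BLE001 - failed members are dropped, counted
            n_dropped += 1
            continue
        for v in trajs:
            trajs[v].append(getattr(tr, v))
    if not trajs["X"]:
        raise RuntimeError("every ensemble member failed to simulate")
    out = {}
    for v, rows in trajs.items():
        arr = np.vstack(rows)
        frame = pd.DataFrame(
            {f"q{q:g}": np.quantile(arr, q, axis=0) for q in quantiles}, index=t_out
        )
        frame.index.name = "t_h"
        frame.attrs["n_dropped"] = n_dropped
        out[v] = frame
    return out
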