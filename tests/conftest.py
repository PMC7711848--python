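"""Shared fixtures: parameter sets, initial states and synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

from fedscreen import (
    CultivationState,
    FeedSettings,
    MeasurementSet,
    NoiseModel,
    ReactorInput,
    SamplingPlan,
    design_feed,
    initial_guess,
    simulate,
)
from fedscreen.virtual_plant import CloneSpec, generate_clone_library, run_reactor

ZERO_NOISE = {v: 0.0 for v in ("biomass", "glucose", "acetate", "DOT")}


@pytest.fixture(scope="session")
def base_params():
    return initial_guess()


@pytest.fixture()
def batch_state():
    return CultivationState(t=0.0, X=1.3, S=5.0, A=0.0, DOT=100.0, P=0.0, V=0.010)


def make_batch_dataset(params, state, horizon=3.0, n_points=12, reactor_id="R1"):
    """Noise-free batch measurements of all four variables from a simulation."""
    ts = np.linspace(0.25, horizon, n_points)
    traj = simulate(params, state, horizon=horizon, output_times=ts)
    records = []
    for i, t in enumerate(ts):
        records += [
            (reactor_id, "c0", "biomass", t, t, max(traj.X[i], 0.0)),
            (reactor_id, "c0", "glucose", t, t, max(traj.S[i], 0.0)),
            (reactor_id, "c0", "acetate", t, t, max(traj.A[i], 0.0)),
            (reactor_id, "c0", "DOT", t, t, max(traj.DOT[i], 0.0)),
        ]
    return MeasurementSet.from_records(records, {reactor_id: ReactorInput(initial=state)})


@pytest.fixture()
def batch_dataset(base_params, batch_state):
    return make_batch_dataset(base_params, batch_state)


@pytest.fixture(scope="session")
def fed_batch_triplicate(base_params):
    """One perturbed clone, three replicates, full designed fed-batch run at
    the facility's stated assay noise."""
    lib = generate_clone_library(base_params, 2, spread=0.1, seed=424)
    clone = lib[1]
    plan = SamplingPlan()
    schedule = design_feed(clone.true_parameters, clone.initial_state, FeedSettings())
    ms = None
    for j in range(3):
        m = run_reactor(clone, schedule, plan, NoiseModel(), seed=900 + j,
                        reactor_id=f"r{j}", column=j)
        ms = m if ms is None else ms.merged(m)
    return clone, schedule, ms
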