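"""Shared fixtures.

The expensive simulations are session-scoped and shared across test modules:

* ``full_noise_run`` — one full-size network driven by membrane noise alone
  for 500 s; used for the firing-rate, connection-fraction, irregularity and
  PSP-scale checks.
* ``grown_minis`` — three grown desk-scale replay networks (geometry scale
  0.4, 400 excitatory neurons); the replay/training experiments branch off
  these grown states so each condition does not pay for its own growth phase.
* ``main_runs`` — the start-cue experiment on each grown instance.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from lifsorn import Network, LifSornParams, standard_plan, run_experiment
from lifsorn.analysis import firing_rates
from lifsorn.fixtures import FixtureSpec, make_mini_params, replay_fixture_spec

FULL_NOISE_DURATION_S = 500.0
MINI_GROWTH_S = 300.0
MINI_TEST_S = 100.0
MINI_TRAIN_S = 200.0
MINI_RELAX_S = 10.0
REPLAY_SEEDS = (11, 12, 13)


def mini_plan(**kwargs):
    defaults = dict(
        growth_s=MINI_GROWTH_S,
        test_s=MINI_TEST_S,
        train_s=MINI_TRAIN_S,
        relax_s=MINI_RELAX_S,
    )
    defaults.update(kwargs)
    return standard_plan(**defaults)


@pytest.fixture(scope="session")
def full_noise_run():
    """Full-size noise-only run: (network, spike times, ids, CF trace)."""
    net = Network(LifSornParams(), seed=101)
    cf_trace = []
    times, ids = net.run(
        FULL_NOISE_DURATION_S,
        per_second=lambda n, t: cf_trace.append((t, n.connection_fraction)),
    )
    return net, times, ids, np.array(cf_trace)


@pytest.fixture(scope="session")
def grown_minis():
    """Three grown desk-scale networks, keyed by seed."""
    out = {}
    for seed in REPLAY_SEEDS:
        spec = replay_fixture_spec(seed)
        params = make_mini_params(spec)
        net = Network(params, seed=seed)
        net.run(MINI_GROWTH_S, record=False)
        out[seed] = (params, net)
    return out


@pytest.fixture(scope="session")
def main_runs(grown_minis):
    """Start-cue replay experiment branched off each grown instance."""
    runs = {}
    for seed, (params, net) in grown_minis.items():
        res = run_experiment(
            params, mini_plan(cue="start"), seed=seed, network=net.copy()
        )
        runs[seed] = res
    return runs


@pytest.fixture(scope="session")
def mini_noise_run():
    """Small (scale 0.2, 100 E) noise-only run used by cheap dynamics tests."""
    params = make_mini_params(FixtureSpec(seed=5))
    net = Network(params, seed=5)
    cf_trace = []
    times, ids = net.run(
        400.0, per_second=lambda n, t: cf_trace.append((t, n.connection_fraction))
    )
    return net, times, ids, np.array(cf_trace)
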