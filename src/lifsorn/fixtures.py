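"""Deterministic small-scale networks and constructed spike data for testing.

Two kinds of fixtures:

* geometry-scaled mini networks (:func:`make_mini_params` /
  :func:`make_mini_network`) that preserve the full model's dynamical regime
  at a fraction of the cost: every length parameter (grid, wiring kernel,
  stimulus scale, cluster geometry) is multiplied by one scale factor, the
  sweep speed is scaled the same way so the sweep duration and all inter-
  cluster time lags are preserved, and the structural-growth rate is scaled
  by ``(n_exc/1000)^2`` so the per-pair creation rate — and with it the
  connection-fraction equilibrium — is unchanged;

* scripted spike records (:func:`scripted_sequence_spikes`) with known
  ground-truth replay order, replay score, recall speed and transition
  structure, used as exact oracles for the analysis layer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .network import Network
from .params import LifSornParams, GeometryParams, ClusterParams


@dataclass
class FixtureSpec:
    """Recipe for a reduced network instance."""

    n_exc: int = 100
    n_inh: Optional[int] = None    # default n_exc // 5
    scale: float = 0.2             # multiplies every length parameter
    seed: int = 0
    overrides: dict = field(default_factory=dict)  # extra LifSornParams fields

    def __post_init__(self) -> None:
        if self.n_exc < 10:
            raise ValueError("fixture needs at least 10 excitatory neurons")
        if self.scale <= 0:
            raise ValueError("inconsistent scale")


def make_mini_params(spec: FixtureSpec) -> LifSornParams:
    """Scaled-down parameter set; everything not scaled stays at its default."""
    base = LifSornParams()
    s = spec.scale
    n_inh = spec.n_inh if spec.n_inh is not None else spec.n_exc // 5
    geom = GeometryParams(base.geometry.width * s, base.geometry.height * s)
    conn = replace(base.connectivity, sigma_c=base.connectivity.sigma_c * s)
    stim = replace(
        base.stimulus,
        x_start=(base.stimulus.x_start[0] * s, base.stimulus.x_start[1] * s),
        x_goal=(base.stimulus.x_goal[0] * s, base.stimulus.x_goal[1] * s),
        alpha=base.stimulus.alpha * s,
        v_spot=base.stimulus.v_spot * s,
    )
    clus = ClusterParams(radius=base.clusters.radius * s)
    ratio = (spec.n_exc / 1000.0) ** 2
    sp = replace(
        base.sp,
        growth_mean=base.sp.growth_mean * ratio,
        growth_sd=base.sp.growth_sd * ratio,
    )
    kwargs = dict(
        n_exc=spec.n_exc,
        n_inh=n_inh,
        geometry=geom,
        connectivity=conn,
        stimulus=stim,
        clusters=clus,
        sp=sp,
    )
    kwargs.update(spec.overrides)  # explicit overrides win over scaling
    return LifSornParams(**kwargs)


def make_mini_network(spec: FixtureSpec) -> Network:
    return Network(make_mini_params(spec), seed=spec.seed)


def replay_fixture_spec(seed: int = 0) -> FixtureSpec:
    """The desk-scale replay fixture: scale 0.4, 400 excitatory neurons.

    The areal density is 2.5x the full model so each recording cluster holds
    about five neurons — enough pooled spikes for rate curves while keeping
    the simulation roughly an order of magnitude cheaper than full scale.
    """
    return FixtureSpec(n_exc=400, n_inh=80, scale=0.4, seed=seed)


def scripted_sequence_spikes(
    clusters,
    order: Sequence[int],
    separation_ms: float,
    jitter_ms: float = 0.0,
    n_trials: int = 10,
    period_ms: float = 2000.0,
    onset_in_trial_ms: float = 50.0,
    spikes_per_neuron: int = 3,
    phase: str = "test1",
    seed: int = 0,
) -> tuple:
    """Spike record in which cluster bursts follow a prescribed order.

    In every trial, the cluster at rank r of ``order`` emits a synchronous
    burst (``spikes_per_neuron`` spikes from each member) at
    ``onset + onset_in_trial + r * separation + jitter``, with i.i.d. Gaussian
    jitter per cluster and trial.  With zero jitter the ground truth is exact:
    each trial's replay score is the rank correlation of ``order`` against the
    axis, and the recall speed is the cluster spacing over the separation.

    Returns ``(spikes DataFrame, onsets array)`` in the simulator's format.
    """
    if separation_ms <= 0:
        raise ValueError("separation must be positive")
    rng = np.random.default_rng(seed)
    rows_t, rows_i, rows_trial = [], [], []
    onsets = np.arange(n_trials, dtype=float) * period_ms
    for k, onset in enumerate(onsets):
        for r, c in enumerate(order):
            t = onset + onset_in_trial_ms + r * separation_ms
            if jitter_ms > 0:
                t += rng.normal(0.0, jitter_ms)
            for nid in clusters.members[c]:
                for s in range(spikes_per_neuron):
                    rows_t.append(t + s * 1.0)  # 1 ms intra-burst spacing
                    rows_i.append(nid)
                    rows_trial.append(k)
    spikes = pd.DataFrame(
        {
            "time_ms": np.asarray(rows_t),
            "neuron_id": np.asarray(rows_i, dtype=np.int32),
            "phase": phase,
            "trial": np.asarray(rows_trial, dtype=np.int32),
        }
    ).sort_values("time_ms", ignore_index=True)
    return spikes, onsets


def uniform_cluster_positions(
    n_clu: int = 8,
    per_cluster: int = 5,
    spacing: float = 221.428571,
    r_clu: float = 100.0,
    x0: float = 475.0,
    y: float = 500.0,
    seed: int = 0,
) -> tuple:
    """Synthetic excitatory positions with exactly ``per_cluster`` neurons per circle.

    Convenience for analysis-layer tests that need a ClusterSet without
    running the simulator; positions are drawn uniformly inside each circle.
    """
    rng = np.random.default_rng(seed)
    pos = []
    for k in range(n_clu):
        cx = x0 + k * spacing
        r = r_clu * np.sqrt(rng.uniform(0, 0.9, per_cluster))
        th = rng.uniform(0, 2 * np.pi, per_cluster)
        for rr, tt in zip(r, th):
            pos.append((cx + rr * np.cos(tt), y + rr * np.sin(tt)))
    return np.asarray(pos), x0, y
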