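"""Experiment orchestration: phases, recording clusters, annotated spike records.

The main protocol mirrors the sequence-learning experiment: a growth phase in
which the recurrent excitatory connectivity self-organizes under noise, a test
phase with a brief cue flash every two seconds, a short relaxation, a training
phase with the full moving-spot sweep every two seconds, another relaxation,
and a second test phase with the same cue.  Variants swap the training
stimulus (shifted trajectory, bar flash, stationary flash), drop the test
stimulus entirely (spontaneous-activity experiment), or extend the final test
phase (persistence experiment).

Recording is abstracted as eight circular clusters (labelled A-H) of
excitatory neurons placed equidistantly on the start->goal axis; all replay
analyses operate on pooled cluster spikes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .network import Network
from .params import LifSornParams, StimulusParams
from .stimulus import SpotStimulus, BarStimulus, StimulusSchedule

CLUSTER_LABELS = "ABCDEFGH"


@dataclass
class ClusterSet:
    """Labelled neuron groups defined by circles along the stimulus axis."""

    centers: np.ndarray          # (n_clu, 2) um
    radius: float                # um
    members: List[np.ndarray]    # excitatory neuron ids per cluster
    labels: List[str]
    axis_positions: np.ndarray   # distance of each center from the start point
    disjoint: bool

    @property
    def n_clusters(self) -> int:
        return len(self.members)

    def membership_map(self, n_exc: int) -> np.ndarray:
        """Neuron id -> cluster index (-1 outside all clusters)."""
        m = np.full(n_exc, -1, dtype=np.int32)
        for c, ids in enumerate(self.members):
            m[ids] = c
        return m


def build_clusters(
    x_start,
    x_goal,
    n_clu: int,
    r_clu: float,
    positions_exc: np.ndarray,
) -> ClusterSet:
    """Place ``n_clu`` circles equidistantly on the start->goal segment.

    The boundaries of the outermost circles touch the endpoints: center k sits
    at ``x_start + (r + k * step) * unit`` with
    ``step = (|x_goal - x_start| - 2 r) / (n_clu - 1)``.  Membership is every
    excitatory neuron within ``r_clu`` of a center; overlapping circles are
    reported via ``disjoint``.
    """
    if n_clu < 2:
        raise ValueError("need at least two clusters")
    a = np.asarray(x_start, float)
    b = np.asarray(x_goal, float)
    length = float(np.linalg.norm(b - a))
    unit = (b - a) / length
    step = (length - 2.0 * r_clu) / (n_clu - 1)
    offsets = r_clu + step * np.arange(n_clu)
    centers = a + offsets[:, None] * unit
    members = []
    for c in centers:
        d = np.linalg.norm(positions_exc - c, axis=1)
        members.append(np.nonzero(d <= r_clu)[0])
    labels = [CLUSTER_LABELS[k] if k < len(CLUSTER_LABELS) else f"C{k}" for k in range(n_clu)]
    return ClusterSet(
        centers=centers,
        radius=r_clu,
        members=members,
        labels=labels,
        axis_positions=offsets,
        disjoint=bool(step >= 2.0 * r_clu - 1e-9),
    )


@dataclass
class Phase:
    """One protocol phase: a duration and an optional periodic stimulus."""

    name: str
    duration_s: float
    stim: Optional[str] = None          # None | 'cue' | 'sweep' | 'bar' | 'flash'
    cue_where: str = "start"            # for 'cue' and 'flash'
    period_s: float = 2.0               # trial period for periodic stimuli
    reverse: bool = False               # sweep direction
    stim_params: Optional[StimulusParams] = None  # override (training variants)

    @property
    def n_trials(self) -> int:
        if self.stim is None:
            return 0
        n = self.duration_s / self.period_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"phase {self.name}: trial count times period != duration")
        return int(round(n))


@dataclass
class PhasePlan:
    phases: List[Phase] = field(default_factory=list)

    @property
    def total_duration_s(self) -> float:
        return sum(ph.duration_s for ph in self.phases)


def standard_plan(
    cue: str = "start",
    growth_s: float = 400.0,
    test_s: float = 100.0,
    relax_s: float = 10.0,
    train_s: float = 200.0,
    period_s: float = 2.0,
    test2_s: Optional[float] = None,
    train_kind: str = "sweep",
    spontaneous: bool = False,
    train_stim_params: Optional[StimulusParams] = None,
) -> PhasePlan:
    """The main protocol and its variants.

    ``train_kind``: 'sweep' (moving spot), 'bar' (flashed bar), 'flash'
    (stationary spot at the start point) or None (no-training control).
    ``spontaneous=True`` removes the cue from both test phases (input-free
    testing); ``test2_s`` extends the final test phase (persistence).
    """
    test_stim = None if spontaneous else "cue"
    phases = [
        Phase("growth", growth_s),
        Phase("test1", test_s, stim=test_stim, cue_where=cue, period_s=period_s),
        Phase("relax1", relax_s),
    ]
    if train_kind is not None and train_s > 0:
        phases.append(
            Phase("train", train_s, stim=train_kind, period_s=period_s,
                  stim_params=train_stim_params)
        )
    else:
        phases.append(Phase("train", train_s))
    phases += [
        Phase("relax2", relax_s),
        Phase("test2", test2_s if test2_s is not None else test_s,
              stim=test_stim, cue_where=cue, period_s=period_s),
    ]
    return PhasePlan(phases)


def variant_shifted_trajectory(params: LifSornParams, **plan_kwargs) -> tuple:
    """Training trajectory shifted orthogonally to the cluster axis.

    The cluster axis (and the test cues) moves to 30% grid height; the
    training sweep runs parallel at 65% grid height.  At full scale this is
    the quoted y=350 um cluster line and y=650 um training trajectory.
    """
    h = params.geometry.height
    sp = params.stimulus
    base = replace(
        sp,
        x_start=(sp.x_start[0], 0.35 * h),
        x_goal=(sp.x_goal[0], 0.35 * h),
    )
    train = replace(
        sp,
        x_start=(sp.x_start[0], 0.65 * h),
        x_goal=(sp.x_goal[0], 0.65 * h),
    )
    p2 = replace(params, stimulus=base)
    plan = standard_plan(train_stim_params=train, **plan_kwargs)
    return p2, plan


def _phase_schedule(ph: Phase, sp: StimulusParams, t0_ms: float) -> List[object]:
    events: List[object] = []
    if ph.stim is None:
        return events
    spp = ph.stim_params if ph.stim_params is not None else sp
    for k in range(ph.n_trials):
        onset = t0_ms + k * ph.period_s * 1000.0
        if ph.stim == "cue":
            events.append(SpotStimulus.cue(spp, onset, ph.cue_where))
        elif ph.stim == "flash":
            events.append(SpotStimulus.cue(spp, onset, ph.cue_where))
        elif ph.stim == "sweep":
            events.append(SpotStimulus.sweep(spp, onset, reverse=ph.reverse))
        elif ph.stim == "bar":
            events.append(
                BarStimulus(np.asarray(spp.x_start, float),
                            np.asarray(spp.x_goal, float), onset)
            )
        else:
            raise ValueError(f"unknown stimulus kind {ph.stim!r}")
    return events


@dataclass
class ExperimentResult:
    """Annotated spikes, trial bookkeeping and weight snapshots of one run."""

    spikes: pd.DataFrame                     # time_ms, neuron_id, phase, trial
    trial_onsets: Dict[str, np.ndarray]      # phase name -> onset times (ms)
    phase_bounds: Dict[str, tuple]           # phase name -> (t0_ms, t1_ms)
    clusters: ClusterSet
    weight_trace: pd.DataFrame               # per-second forward/backward means
    ee_snapshots: Dict[str, pd.DataFrame]    # phase boundary -> pre/post/weight
    params: LifSornParams
    network: Network


def snapshot_ee(net: Network) -> pd.DataFrame:
    return pd.DataFrame(
        {"pre": net.ee.pre.copy(), "post": net.ee.post.copy(),
         "weight": net.ee.weight.copy()}
    )


def run_experiment(
    params: LifSornParams,
    plan: PhasePlan,
    seed: int = 0,
    network: Optional[Network] = None,
    record_phases: Optional[List[str]] = None,
    trace_weights: bool = True,
) -> ExperimentResult:
    """Execute a phase plan on one network instance.

    A pre-grown ``network`` may be supplied, in which case phases named
    'growth' are skipped (branching several conditions off one grown state)
    and the network's dynamical random streams are re-derived from ``seed``
    so different branches draw independent randomness.  ``record_phases``
    limits spike recording to the named phases (default: everything except
    growth and relaxation).
    """
    from .analysis import adjacent_cluster_weights  # local import, no cycle at load

    if network is not None:
        net = network.reseed(seed)
    else:
        net = Network(params, seed)
    clusters = build_clusters(
        params.stimulus.x_start,
        params.stimulus.x_goal,
        params.clusters.n_clusters,
        params.clusters.radius,
        net.positions[: net.n_exc],
    )
    mmap = clusters.membership_map(net.n_exc)
    if record_phases is None:
        record_phases = [ph.name for ph in plan.phases
                         if not ph.name.startswith(("growth", "relax"))]

    trace_rows: List[tuple] = []

    def tracer(phase_name):
        def cb(n: Network, t_s: float) -> None:
            fwd, bwd = adjacent_cluster_weights(n.ee, mmap, clusters.n_clusters)
            trace_rows.append((t_s, phase_name, fwd, bwd))
        return cb if trace_weights else None

    frames: List[pd.DataFrame] = []
    trial_onsets: Dict[str, np.ndarray] = {}
    phase_bounds: Dict[str, tuple] = {}
    ee_snapshots: Dict[str, pd.DataFrame] = {}
    for ph in plan.phases:
        if ph.name == "growth" and network is not None:
            continue
        t0_ms = net.step * params.neuron.dt
        events = _phase_schedule(ph, params.stimulus, t0_ms)
        schedule = None
        if events:
            schedule = StimulusSchedule(
                events, params.stimulus.n_input, params.stimulus.w_ff
            )
        record = ph.name in record_phases
        times, ids = net.run(
            ph.duration_s, schedule=schedule, record=record,
            per_second=tracer(ph.name),
        )
        t1_ms = net.step * params.neuron.dt
        phase_bounds[ph.name] = (t0_ms, t1_ms)
        onsets = np.array([ev.t0 for ev in events])
        if ph.stim is not None:
            trial_onsets[ph.name] = onsets
        if record and len(times):
            trial = np.full(len(times), -1, dtype=np.int32)
            if len(onsets):
                k = np.floor((times - t0_ms) / (ph.period_s * 1000.0)).astype(np.int64)
                valid = (k >= 0) & (k < len(onsets))
                trial[valid] = k[valid]
            frames.append(
                pd.DataFrame(
                    {"time_ms": times, "neuron_id": ids,
                     "phase": ph.name, "trial": trial}
                )
            )
        ee_snapshots[ph.name] = snapshot_ee(net)

    spikes = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["time_ms", "neuron_id", "phase", "trial"])
    )
    trace = pd.DataFrame(
        trace_rows, columns=["time_s", "phase", "forward", "backward"]
    )
    return ExperimentResult(
        spikes=spikes,
        trial_onsets=trial_onsets,
        phase_bounds=phase_bounds,
        clusters=clusters,
        weight_trace=trace,
        ee_snapshots=ee_snapshots,
        params=params,
        network=net,
    )
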