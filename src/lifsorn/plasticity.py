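"""The five plasticity mechanisms acting on the recurrent excitatory synapses.

Short-term plasticity (STP), spike-timing dependent plasticity (STDP) and
intrinsic plasticity (IP) are event/step rules: the jitted simulation kernel
applies them inline, and the functions here are the exact reference semantics
that the kernel is tested against.  Synaptic normalization (SN) and structural
plasticity (SP) run once per simulated second and the simulator calls the
implementations below directly.

Conventions
-----------
* STDP time lag ``dt = t_post - t_pre_arrival`` where the presynaptic arrival
  is the spike time plus the E->E conduction delay.  The window is zero at
  ``dt == 0`` and pairing is nearest-neighbour: each postsynaptic spike pairs
  with the most recent presynaptic arrival and each arrival with the most
  recent postsynaptic spike; same-time events update the pairing memories but
  contribute nothing.
* Pruning removes weights strictly below the threshold, so newborn synapses
  (one order of magnitude above it) always survive the second they are born.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.special import ndtr

from .params import StpParams, StdpParams, SpParams, IpParams, GeometryParams


# ---------------------------------------------------------------------------
# Short-term plasticity (per presynaptic excitatory neuron)
# ---------------------------------------------------------------------------

@dataclass
class StpState:
    """Facilitation ``u`` and depression ``x`` per excitatory neuron."""

    u: np.ndarray
    x: np.ndarray

    @classmethod
    def resting(cls, n: int, p: StpParams) -> "StpState":
        return cls(u=np.full(n, p.u_base), x=np.ones(n))


def stp_decay(s: StpState, dt: float, p: StpParams) -> StpState:
    """Relax ``u`` toward the baseline U and ``x`` toward 1 (exact exponentials)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    fu = np.exp(-dt / p.tau_f)
    fx = np.exp(-dt / p.tau_d)
    return StpState(u=p.u_base + (s.u - p.u_base) * fu, x=1.0 + (s.x - 1.0) * fx)


def stp_on_presyn_spike(s: StpState, idx, p: StpParams) -> Tuple[StpState, np.ndarray]:
    """Jump ``(u, x)`` of neurons ``idx`` at spike arrival.

    Returns the new state and the efficacy factor ``u(t-) * x(t-)`` read just
    before the jump; the effective transmitted weight is ``W * u(t-) * x(t-)``.
    """
    u0 = s.u[idx]
    x0 = s.x[idx]
    eff = u0 * x0
    u = s.u.copy()
    x = s.x.copy()
    u[idx] = u0 + p.u_base * (1.0 - u0)
    x[idx] = x0 - x0 * u0
    return StpState(u=u, x=x), eff


# ---------------------------------------------------------------------------
# STDP
# ---------------------------------------------------------------------------

def stdp_window(dt_post_minus_pre, p: StdpParams):
    """Asymmetric exponential weight change for lag ``t_post - t_pre_arrival``."""
    dt = np.asarray(dt_post_minus_pre, dtype=float)
    out = np.where(
        dt > 0,
        p.a_plus * np.exp(-dt / p.tau_plus),
        p.a_minus * np.exp(dt / p.tau_minus),
    )
    out = np.where(dt == 0, 0.0, out)
    return out if out.ndim else float(out)


def apply_stdp(
    spike_times: np.ndarray,
    spike_ids: np.ndarray,
    pre: np.ndarray,
    post: np.ndarray,
    weights: np.ndarray,
    p: StdpParams,
    delay_ee: float = 3.0,
    n_neurons: int | None = None,
    t_max: float | None = None,
) -> np.ndarray:
    """Replay a recorded spike stream through nearest-neighbour STDP.

    ``spike_times``/``spike_ids`` are the excitatory spikes sorted by time;
    ``pre``/``post``/``weights`` describe the E->E synapses at the start of the
    stream.  Returns updated weights (floored at 0 after every event, matching
    the online rule).  Presynaptic *arrivals* (spike + delay) drive depression
    and pairing memory; postsynaptic spikes drive potentiation.
    """
    if n_neurons is None:
        n_neurons = int(max(pre.max(initial=-1), post.max(initial=-1), spike_ids.max(initial=-1))) + 1
    w = weights.astype(float).copy()
    # synapse lists per pre and per post neuron
    out_syn = [[] for _ in range(n_neurons)]
    in_syn = [[] for _ in range(n_neurons)]
    for s, (m, n) in enumerate(zip(pre, post)):
        out_syn[m].append(s)
        in_syn[n].append(s)
    NEG = -np.inf
    last_arr = np.full(n_neurons, NEG)
    last_post = np.full(n_neurons, NEG)
    events = []
    # event times are rounded to a nanosecond grid so that a spike-plus-delay
    # arrival and a spike landing on the same timestep compare equal despite
    # float round-off (t + delay and (k + d)*dt can differ by one ulp)
    for t, i in zip(spike_times, spike_ids):
        if t_max is None or t + delay_ee <= t_max:
            events.append((round(t + delay_ee, 6), 0, int(i)))  # arrival
        if t_max is None or t <= t_max:
            events.append((round(t, 6), 1, int(i)))             # post spike
    events.sort(key=lambda e: (e[0], e[1]))
    # simultaneous events first update both pairing memories, then compute
    # contributions: a same-time pre-arrival/post pair yields exactly zero and
    # shadows any older partner
    k = 0
    n_ev = len(events)
    while k < n_ev:
        j = k
        t = events[k][0]
        while j < n_ev and events[j][0] == t:
            j += 1
        for _, kind, i in events[k:j]:
            if kind == 1:
                last_post[i] = t
            else:
                last_arr[i] = t
        for _, kind, i in events[k:j]:
            if kind == 1:  # postsynaptic spike: potentiate from last arrivals
                for s in in_syn[i]:
                    ta = last_arr[pre[s]]
                    if np.isfinite(ta) and ta != t:
                        w[s] += p.a_plus * np.exp(-(t - ta) / p.tau_plus)
                        if w[s] < 0:
                            w[s] = 0.0
            else:          # presynaptic arrival: depress from last post spikes
                for s in out_syn[i]:
                    tp = last_post[post[s]]
                    if np.isfinite(tp) and tp != t:
                        w[s] += p.a_minus * np.exp((tp - t) / p.tau_minus)
                        if w[s] < 0:
                            w[s] = 0.0
        k = j
    return w


# ---------------------------------------------------------------------------
# Synaptic normalization
# ---------------------------------------------------------------------------

def boundary_factor(pos: np.ndarray, geom: GeometryParams, sigma_c: float) -> np.ndarray:
    """Mass of a unit 2D Gaussian centred at ``pos`` inside the grid rectangle.

    Separable closed form via Gaussian CDF differences.  Neurons near an edge
    have factor < 1, down to ~0.25 in a corner; this scales down their target
    incoming weight so boundary neurons do not end up with stronger synapses
    than interior ones.
    """
    pos = np.atleast_2d(np.asarray(pos, dtype=float))
    if np.any(pos[:, 0] < 0) or np.any(pos[:, 0] > geom.width) or \
       np.any(pos[:, 1] < 0) or np.any(pos[:, 1] > geom.height):
        raise ValueError("position outside the grid")
    if sigma_c == 0:
        return np.ones(pos.shape[0])
    fx = ndtr((geom.width - pos[:, 0]) / sigma_c) - ndtr(-pos[:, 0] / sigma_c)
    fy = ndtr((geom.height - pos[:, 1]) / sigma_c) - ndtr(-pos[:, 1] / sigma_c)
    return fx * fy


def sn_targets(
    positions_exc: np.ndarray,
    n_pre: int,
    geom: GeometryParams,
    sigma_c: float,
    target_cf: float,
    mean_strength: float,
) -> np.ndarray:
    """Per-neuron target summed incoming weight W_total.

    ``target_cf * n_pre * mean_strength`` scaled by the boundary factor of the
    postsynaptic neuron's position.
    """
    return target_cf * n_pre * mean_strength * boundary_factor(positions_exc, geom, sigma_c)


def synaptic_normalization(
    post: np.ndarray, weights: np.ndarray, w_total: np.ndarray
) -> np.ndarray:
    """Rescale each neuron's incoming weights so they sum to its W_total.

    Neurons with zero incoming weight sum are skipped.  Proportions among a
    neuron's inputs are preserved; the operation is idempotent.
    """
    n = len(w_total)
    sums = np.bincount(post, weights=weights, minlength=n)
    scale = np.ones(n)
    nz = sums > 0
    scale[nz] = w_total[nz] / sums[nz]
    return weights * scale[post]


# ---------------------------------------------------------------------------
# Structural plasticity
# ---------------------------------------------------------------------------

def draw_growth_count(sp: SpParams, rng: np.random.Generator) -> int:
    """Number of synapses to create this second: Normal draw, rounded, floored at 0."""
    return max(0, int(round(rng.normal(sp.growth_mean, sp.growth_sd))))


def structural_growth(
    pre: np.ndarray,
    post: np.ndarray,
    weights: np.ndarray,
    n_new: int,
    log_kernel: np.ndarray,
    sp: SpParams,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Attempt ``n_new`` synapse insertions at kernel-weighted candidate pairs.

    Candidates are drawn without replacement from *all* ordered E->E pairs
    with probability proportional to the Gaussian distance kernel
    (``log_kernel`` is the flattened ``n_e x n_e`` matrix of log kernel
    values with -inf on the diagonal), via Gumbel-perturbed keys.  Draws that
    land on an already existing synapse are discarded, so the realized
    insertion rate falls as the well-connected neighbourhoods saturate: this
    self-throttling is what lets growth and pruning equilibrate at a
    connection fraction set by the kernel mass (about 0.1 at the default
    geometry) rather than growing without bound.
    """
    n_e = int(round(np.sqrt(log_kernel.size)))
    if n_e == 0 or n_new <= 0:
        return pre, post, weights
    k = min(n_new, int(np.isfinite(log_kernel).sum()))
    if k == 0:
        return pre, post, weights
    keys = log_kernel + rng.gumbel(size=log_kernel.size)
    top = np.argpartition(keys, -k)[-k:]
    existing = np.sort(pre.astype(np.int64) * n_e + post.astype(np.int64))
    pos = np.searchsorted(existing, top)
    pos[pos == len(existing)] = max(len(existing) - 1, 0)
    if len(existing):
        top = top[existing[pos] != top]
    if len(top) == 0:
        return pre, post, weights
    k = len(top)
    new_pre = (top // n_e).astype(pre.dtype)
    new_post = (top % n_e).astype(post.dtype)
    return (
        np.concatenate([pre, new_pre]),
        np.concatenate([post, new_post]),
        np.concatenate([weights, np.full(k, sp.init_weight)]),
    )


def structural_prune(
    pre: np.ndarray, post: np.ndarray, weights: np.ndarray, sp: SpParams
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Remove all synapses with weight strictly below the pruning threshold."""
    keep = weights >= sp.prune_threshold
    return pre[keep], post[keep], weights[keep]


# ---------------------------------------------------------------------------
# Intrinsic plasticity
# ---------------------------------------------------------------------------

def ip_update(v_thresh, spiked, ip: IpParams, dt_ms: float):
    """Per-step threshold update: ``V_T += eta * (N_spikes - h)``.

    ``h = r_target * dt`` is the target number of spikes per step; a neuron
    firing at exactly the target rate has zero mean threshold drift.
    """
    return np.asarray(v_thresh) + ip.eta * (np.asarray(spiked, dtype=float) - ip.h(dt_ms))
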