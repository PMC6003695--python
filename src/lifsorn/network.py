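"""Network geometry, connectivity initialization and simulation orchestration.

A :class:`Network` owns the full dynamical state of one instance of the
self-organizing recurrent network: neuron positions on the 2D sheet, membrane
and conductance state, the fixed inhibitory-involving synapse classes, the
plastic recurrent excitatory synapse table, and the short-term plasticity and
STDP bookkeeping.  Simulation proceeds in one-second blocks through the jitted
kernel; after each simulated second the slow mechanisms run in order —
structural growth, structural pruning, then synaptic normalization — so that
newborn synapses are normalized immediately.

Neuron ids: ``0 .. n_exc-1`` excitatory, ``n_exc .. n_exc+n_inh-1`` inhibitory.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Tuple

import numpy as np

from . import _kernel
from .params import LifSornParams, GeometryParams
from .plasticity import (
    StpState,
    sn_targets,
    synaptic_normalization,
    structural_growth,
    structural_prune,
    draw_growth_count,
    boundary_factor,
)
from .stimulus import StimulusSchedule


def place_neurons(
    n_exc: int, n_inh: int, geom: GeometryParams, rng: np.random.Generator
) -> np.ndarray:
    """Scatter ``n_exc + n_inh`` neurons independently and uniformly on the grid."""
    if n_exc <= 0 or n_inh < 0:
        raise ValueError("need n_exc > 0 and n_inh >= 0")
    n = n_exc + n_inh
    pos = np.empty((n, 2))
    pos[:, 0] = rng.uniform(0.0, geom.width, n)
    pos[:, 1] = rng.uniform(0.0, geom.height, n)
    return pos


def connection_probability(d, sigma_c: float = 200.0):
    """Unnormalized Gaussian wiring kernel ``exp(-d^2 / (2 sigma_c^2))``."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be nonnegative")
    out = np.exp(-(d ** 2) / (2.0 * sigma_c ** 2))
    return out if out.ndim else float(out)


def _weighted_topk(log_w: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k indices sampled without replacement with prob proportional to exp(log_w)."""
    if k > np.isfinite(log_w).sum():
        raise ValueError("requested more edges than available pairs")
    if k == 0:
        return np.empty(0, dtype=np.int64)
    keys = log_w + rng.gumbel(size=log_w.size)
    return np.argpartition(keys, -k)[-k:]


@dataclass
class SynapseTable:
    """Directed weighted edges of one connection class."""

    pre: np.ndarray
    post: np.ndarray
    weight: np.ndarray

    def __len__(self) -> int:
        return len(self.pre)


def init_fixed_connectivity(
    positions: np.ndarray,
    n_exc: int,
    n_inh: int,
    params: LifSornParams,
    rng: np.random.Generator,
) -> dict:
    """Realize the fixed E->I, I->E and I<->I connectivity.

    Edge counts are ``round(fraction * possible pairs)`` with pairs chosen
    without replacement, each with probability proportional to the Gaussian
    distance kernel.  The I<->I fraction counts *reciprocal* unordered pairs;
    both directions of a chosen pair are inserted.  After realization each
    class is normalized once: every postsynaptic neuron's summed incoming
    weight of that class is set to
    ``fraction * n_pre * class_weight * boundary_factor(position)``.
    """
    cp = params.connectivity
    geom = params.geometry
    pos_e = positions[:n_exc]
    pos_i = positions[n_exc:]
    tables: dict = {}

    def log_kernel(pa, pb):
        d2 = ((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1)
        return -d2 / (2.0 * cp.sigma_c ** 2)

    if n_inh == 0:
        z = np.empty(0, dtype=np.int32)
        zw = np.empty(0)
        for cls in ("EI", "IE", "II"):
            tables[cls] = SynapseTable(z.copy(), z.copy(), zw.copy())
        return tables

    # E->I
    lw = log_kernel(pos_e, pos_i).ravel()
    k = int(round(cp.cf_ei * n_exc * n_inh))
    idx = _weighted_topk(lw, k, rng)
    pre = (idx // n_inh).astype(np.int32)
    post = (idx % n_inh).astype(np.int32) + n_exc
    w = np.full(k, cp.w_ei)
    tgt = cp.cf_ei * n_exc * cp.w_ei * boundary_factor(pos_i, geom, cp.sigma_c)
    w = synaptic_normalization(post - n_exc, w, tgt)
    tables["EI"] = SynapseTable(pre, post, w)

    # I->E
    lw = log_kernel(pos_i, pos_e).ravel()
    k = int(round(cp.cf_ie * n_exc * n_inh))
    idx = _weighted_topk(lw, k, rng)
    pre = (idx // n_exc).astype(np.int32) + n_exc
    post = (idx % n_exc).astype(np.int32)
    w = np.full(k, cp.w_inh)
    tgt = cp.cf_ie * n_inh * cp.w_inh * boundary_factor(pos_e, geom, cp.sigma_c)
    w = synaptic_normalization(post, w, tgt)
    tables["IE"] = SynapseTable(pre, post, w)

    # I<->I (reciprocal pairs)
    iu, ju = np.triu_indices(n_inh, k=1)
    d2 = ((pos_i[iu] - pos_i[ju]) ** 2).sum(-1)
    lw = -d2 / (2.0 * cp.sigma_c ** 2)
    k = int(round(cp.cf_ii * len(iu)))
    sel = _weighted_topk(lw, k, rng)
    pre = np.concatenate([iu[sel], ju[sel]]).astype(np.int32) + n_exc
    post = np.concatenate([ju[sel], iu[sel]]).astype(np.int32) + n_exc
    w = np.full(2 * k, cp.w_inh)
    tgt = cp.cf_ii * n_inh * cp.w_inh * boundary_factor(pos_i, geom, cp.sigma_c)
    w = synaptic_normalization(post - n_exc, w, tgt)
    tables["II"] = SynapseTable(pre, post, w)
    return tables


def _csr_by_pre(pre, post, w, n_pre, pre_offset=0):
    """CSR (indptr, post, weight, order) grouping synapses by presynaptic neuron."""
    order = np.argsort(pre, kind="stable")
    p = pre[order] - pre_offset
    indptr = np.zeros(n_pre + 1, dtype=np.int64)
    np.add.at(indptr, p + 1, 1)
    np.cumsum(indptr, out=indptr)
    return indptr, post[order].astype(np.int32), w[order], order


@dataclass
class SpikeBuffer:
    """Growable spike log (global step index, neuron id)."""

    steps: List[np.ndarray] = field(default_factory=list)
    ids: List[np.ndarray] = field(default_factory=list)

    def append(self, steps: np.ndarray, ids: np.ndarray) -> None:
        self.steps.append(steps)
        self.ids.append(ids)

    def arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        if not self.steps:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int32)
        return np.concatenate(self.steps), np.concatenate(self.ids)


class Network:
    """One instance of the self-organizing spiking network.

    Parameters
    ----------
    params : LifSornParams
        Full parameter set (defaults are the model's reference parameterization).
    seed : int
        Master seed; independent child streams drive connectivity, membrane
        noise, structural plasticity and stimulus Poisson spikes, so the whole
        trajectory is a pure function of ``(params, seed)``.
    """

    def __init__(self, params: LifSornParams, seed: int = 0):
        self.params = params
        self.seed = seed
        ss = np.random.SeedSequence(seed)
        c_conn, c_noise, c_sp, c_stim, c_init = ss.spawn(5)
        self.rng_conn = np.random.Generator(np.random.PCG64(c_conn))
        self.rng_sp = np.random.Generator(np.random.PCG64(c_sp))
        self.rng_stim = np.random.Generator(np.random.PCG64(c_stim))
        self.rng_noise = np.random.Generator(np.random.PCG64(c_noise))
        self._noise_buf = np.empty(0, dtype=np.float32)
        rng_init = np.random.Generator(np.random.PCG64(c_init))

        n_e, n_i = params.n_exc, params.n_inh
        self.n_exc, self.n_inh = n_e, n_i
        n = n_e + n_i
        self.positions = place_neurons(n_e, n_i, params.geometry, self.rng_conn)
        self.fixed = init_fixed_connectivity(self.positions, n_e, n_i, params, self.rng_conn)

        np_ = params.neuron
        self.V = np.full(n, np_.e_leak)
        self.VT = np.empty(n)
        # initial excitatory thresholds: uniform between -58 mV and the fixed
        # inhibitory threshold; IP moves them to their operating point quickly
        self.VT[:n_e] = rng_init.uniform(-58.0, np_.v_thresh_inh, n_e)
        self.VT[n_e:] = np_.v_thresh_inh
        self.ge = np.zeros(n)
        self.gi = np.zeros(n)
        self.gext = np.zeros(n)
        self.refrac = np.zeros(n, dtype=np.int64)
        self.stp = StpState.resting(n_e, params.stp)
        self._stp_touch = np.zeros(n_e, dtype=np.int64)
        self.last_arr = np.full(n_e, _kernel.NEG, dtype=np.int64)
        self.last_post = np.full(n_e, _kernel.NEG, dtype=np.int64)
        self.ring_ids = np.zeros((_kernel.RING, n), dtype=np.int32)
        self.ring_cnt = np.zeros(_kernel.RING, dtype=np.int64)
        self.step = 0  # global step counter

        # plastic E->E table, initially empty
        self.ee = SynapseTable(
            np.empty(0, dtype=np.int32), np.empty(0, dtype=np.int32), np.empty(0)
        )

        # precomputed structures for SP and SN
        d2 = ((self.positions[:n_e, None, :] - self.positions[None, :n_e, :]) ** 2).sum(-1)
        lk = -d2 / (2.0 * params.connectivity.sigma_c ** 2)
        np.fill_diagonal(lk, -np.inf)
        self._log_kernel_ee = lk.ravel()
        self.w_total = sn_targets(
            self.positions[:n_e],
            n_e,
            params.geometry,
            params.connectivity.sigma_c,
            params.sn.target_cf,
            params.sn.mean_strength,
        )

        # fixed-class CSR structures for the kernel
        cp = params.connectivity
        t = self.fixed["EI"]
        self._ei_csr = _csr_by_pre(t.pre, t.post, t.weight, n_e)[:3]
        # I->E and I->I share a delay; merge into one outgoing structure
        pre = np.concatenate([self.fixed["IE"].pre, self.fixed["II"].pre])
        post = np.concatenate([self.fixed["IE"].post, self.fixed["II"].post])
        w = np.concatenate([self.fixed["IE"].weight, self.fixed["II"].weight])
        self._io_csr = _csr_by_pre(pre, post, w, n_i, pre_offset=n_e)[:3]
        if cp.delay_ie != cp.delay_ii:
            raise NotImplementedError("I->E and I->I delays must match")

        # accumulators for the mean STP efficacy at spike arrivals
        self.eff_sum = 0.0
        self.eff_count = 0

    # -- derived quantities -------------------------------------------------

    @property
    def connection_fraction(self) -> float:
        """Realized E->E synapses over possible ordered pairs."""
        n_e = self.n_exc
        return len(self.ee) / (n_e * (n_e - 1))

    def mean_arrival_efficacy(self) -> float:
        """Mean STP factor u*x observed at presynaptic spike arrivals so far."""
        return self.eff_sum / self.eff_count if self.eff_count else float("nan")

    # -- state management ---------------------------------------------------

    def copy(self) -> "Network":
        """Deep copy of the full dynamical state (for branching experiments)."""
        return _copy.deepcopy(self)

    def reseed(self, seed: int) -> "Network":
        """Re-derive the dynamical random streams (noise, SP, stimulus).

        Used when branching several experimental conditions off one grown
        state: the branches keep the state but draw independent randomness.
        Connectivity/geometry streams are not touched (positions are fixed).
        """
        ss = np.random.SeedSequence(seed)
        c_noise, c_sp, c_stim = ss.spawn(3)
        self.rng_noise = np.random.Generator(np.random.PCG64(c_noise))
        self.rng_sp = np.random.Generator(np.random.PCG64(c_sp))
        self.rng_stim = np.random.Generator(np.random.PCG64(c_stim))
        return self

    def _ee_csrs(self):
        n_e = self.n_exc
        indptr, post, w, order = _csr_by_pre(self.ee.pre, self.ee.post, self.ee.weight, n_e)
        # keep the table itself in CSR order so the kernel edits it in place
        self.ee = SynapseTable(self.ee.pre[order], post.copy(), w)
        in_indptr, in_pre, in_widx, _ = _csr_by_pre(
            self.ee.post, self.ee.pre, np.arange(len(w), dtype=np.int64), n_e
        )
        return indptr, self.ee.post, self.ee.weight, in_indptr, in_pre.astype(np.int32), in_widx

    # -- simulation ---------------------------------------------------------

    def _run_block(self, n_steps: int, stim_dense: Optional[np.ndarray], record: bool,
                   sink: Optional[SpikeBuffer]) -> None:
        p = self.params
        np_, cp = p.neuron, p.connectivity
        dt = np_.dt
        d_ee = int(round(cp.delay_ee / dt))
        d_ei = int(round(cp.delay_ei / dt))
        d_io = int(round(cp.delay_ie / dt))
        if max(d_ee, d_ei, d_io) >= _kernel.RING:
            raise ValueError("delay exceeds ring-buffer depth")
        ee_indptr, ee_post, ee_w, in_indptr, in_pre, in_widx = self._ee_csrs()
        ei_indptr, ei_post, ei_w = self._ei_csr
        io_indptr, io_post, io_w = self._io_csr
        if stim_dense is not None:
            rows, cols = np.nonzero(stim_dense)
            stim_step = rows.astype(np.int64)
            stim_neuron = cols.astype(np.int32)
            stim_inc = stim_dense[rows, cols].astype(np.float64)
        else:
            stim_step = np.empty(0, dtype=np.int64)
            stim_neuron = np.empty(0, dtype=np.int32)
            stim_inc = np.empty(0)
        n = self.V.shape[0]
        refrac_steps = int(round(np_.refractory / dt))
        if refrac_steps > 0:
            cap = int(n * (n_steps / max(refrac_steps, 1) + 2))
        else:
            cap = n * n_steps
        spk_step = np.empty(cap, dtype=np.int64)
        spk_id = np.empty(cap, dtype=np.int32)
        if np_.sigma_noise > 0:
            need = n_steps * n
            if self._noise_buf.size < need:
                self._noise_buf = np.empty(need, dtype=np.float32)
            noise = self._noise_buf[:need].reshape(n_steps, n)
            self.rng_noise.standard_normal(out=noise, dtype=np.float32)
        else:
            noise = np.empty((0, n), dtype=np.float32)
        status, nspk, eff_sum, eff_cnt = _kernel.run_block(
            n_steps, self.step, noise,
            self.V, self.VT, self.ge, self.gi, self.gext, self.refrac,
            self.n_exc, self.stp.u, self.stp.x, self._stp_touch,
            ee_indptr, ee_post, ee_w,
            in_indptr, in_pre, in_widx,
            ei_indptr, ei_post, ei_w,
            io_indptr, io_post, io_w,
            self.last_arr, self.last_post,
            self.ring_ids, self.ring_cnt,
            dt, np_.tau_m, np_.e_leak, np_.e_exc, np_.e_inh,
            np_.sigma_noise * np.sqrt(2.0 * dt / np_.tau_m),
            np_.v_reset_exc, np_.v_reset_inh, refrac_steps,
            np.exp(-dt / np_.tau_e), np.exp(-dt / np_.tau_i),
            p.stp.enabled, p.stp.u_base, p.stp.tau_f, p.stp.tau_d,
            p.stdp.enabled, p.stdp.a_plus, p.stdp.a_minus,
            p.stdp.tau_plus, p.stdp.tau_minus,
            p.ip.enabled, p.ip.eta, p.ip.eta * p.ip.h(dt),
            d_ee, d_ei, d_io,
            stim_step, stim_neuron, stim_inc,
            spk_step, spk_id,
        )
        if status == -1:
            raise RuntimeError("spike buffer overflow (network runaway?)")
        if not np.isfinite(self.V).all():
            raise FloatingPointError(
                f"non-finite membrane potential at step {self.step + n_steps}"
            )
        self.eff_sum += eff_sum
        self.eff_count += eff_cnt
        self.step += n_steps
        if record and sink is not None and nspk:
            sink.append(spk_step[:nspk].copy(), spk_id[:nspk].copy())

    def _slow_plasticity(self) -> None:
        """Once-per-second mechanisms: SP growth, SP pruning, then SN."""
        p = self.params
        pre, post, w = self.ee.pre, self.ee.post, self.ee.weight
        if p.sp.enabled:
            n_new = draw_growth_count(p.sp, self.rng_sp)
            pre, post, w = structural_growth(
                pre, post, w, n_new, self._log_kernel_ee, p.sp, self.rng_sp
            )
            pre, post, w = structural_prune(pre, post, w, p.sp)
        if p.sn.enabled:
            w = synaptic_normalization(post, w, self.w_total)
        self.ee = SynapseTable(pre, post, w)

    def run(
        self,
        duration_s: float,
        schedule: Optional[StimulusSchedule] = None,
        record: bool = True,
        per_second: Optional[Callable[["Network", float], None]] = None,
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Simulate ``duration_s`` seconds; returns (spike times in ms, neuron ids).

        The slow mechanisms (growth, pruning, normalization) run at every full
        simulated second, counted from the network's own t=0 (free-running,
        independent of phase boundaries).  ``per_second(net, t_s)`` is invoked
        after each second for snapshotting.
        """
        dt = self.params.neuron.dt
        steps_per_s = int(round(1000.0 / dt))
        total_steps = int(round(duration_s * 1000.0 / dt))
        sink = SpikeBuffer() if record else None
        done = 0
        while done < total_steps:
            # advance to the next whole-second boundary of the global clock
            to_boundary = steps_per_s - (self.step % steps_per_s)
            n_steps = min(to_boundary, total_steps - done)
            t0_ms = self.step * dt
            stim = None
            if schedule is not None:
                stim = schedule.block_increments(
                    t0_ms, n_steps, dt, self.positions[: self.n_exc], self.rng_stim
                )
            self._run_block(n_steps, stim, record, sink)
            done += n_steps
            if self.step % steps_per_s == 0:
                self._slow_plasticity()
                if per_second is not None:
                    per_second(self, self.step * dt / 1000.0)
        if record:
            steps, ids = sink.arrays()
            return steps.astype(float) * dt, ids
        return np.empty(0), np.empty(0, dtype=np.int32)
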