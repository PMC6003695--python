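"""Jitted clock-driven integration loop.

One call advances the whole population by ``n_steps`` timesteps of ``dt``.
Neurons are indexed with all excitatory neurons first (ids ``0..n_exc-1``),
then inhibitory.  Synapses are passed as CSR-like arrays; the recurrent
excitatory weights ``ee_w`` are modified in place by STDP.

Per-step update order (loops are fused for speed, the event semantics are):

1. integrate membranes (forward Euler + additive Gaussian noise increment);
   refractory neurons stay clamped at their reset potential; conductances
   decay by their exact exponential factors,
2. detect threshold crossings: record the spike, reset, start the refractory
   timer, update the postsynaptic STDP pairing memory,
3. apply deliveries due this step (spikes emitted ``delay/dt`` steps ago):
   conductance increments with the STP efficacy factor read before its jump,
   nearest-neighbour depression at presynaptic arrival, STP jump, presynaptic
   pairing-memory update; external input increments are applied here too,
4. nearest-neighbour potentiation for this step's postsynaptic spikes,
5. intrinsic plasticity threshold update for every excitatory neuron.

Same-step pre-arrival/post-spike pairs contribute zero weight change (the
window is zero at zero lag) but still update the pairing memories.

Two exact algebraic shortcuts keep the loop cheap without changing the
dynamics: the STP variables decay lazily (closed-form exponential applied at
each arrival event and flushed to the block end on exit), and the constant
homeostatic threshold drain ``-eta*h`` per step is carried as a scalar offset
that is folded into the per-neuron thresholds when the block ends.
"""

import numpy as np
from numba import njit

RING = 512           # ring-buffer depth in steps; delays must stay below this
NEG = -(1 << 62)     # sentinel for "no event recorded yet"


@njit(cache=True)
def run_block(
    n_steps, step0, noise,
    # population state (exc first)
    V, VT, ge, gi, gext, refrac,
    n_exc,
    u, x, stp_touch,
    # E->E synapses, CSR by presynaptic neuron; ee_w modified in place
    ee_indptr, ee_post, ee_w,
    # E->E incoming lists, CSR by postsynaptic neuron, with index into ee_w
    in_indptr, in_pre, in_widx,
    # E->I fixed synapses, CSR by presynaptic excitatory neuron
    ei_indptr, ei_post, ei_w,
    # I->E and I->I fixed synapses, CSR by presynaptic inhibitory neuron
    io_indptr, io_post, io_w,
    # STDP pairing memories (global step index of last event)
    last_arr, last_post,
    # spike ring buffer (persistent across calls)
    ring_ids, ring_cnt,
    # scalar parameters
    dt, tau_m, e_leak, e_exc, e_inh, noise_amp,
    v_reset_e, v_reset_i, refrac_steps,
    decay_e, decay_i,
    stp_on, u_base, tau_f, tau_d,
    stdp_on, a_plus, a_minus, tau_plus, tau_minus,
    ip_on, eta, eta_h,
    d_ee, d_ei, d_io,
    # sparse external-input increments for this block (rows sorted by step)
    stim_step, stim_neuron, stim_inc,
    # spike output
    spk_step, spk_id,
):
    """Advance the network by ``n_steps``.

    Returns ``(status, n_spikes, eff_sum, eff_count)`` where status 0 is
    success and -1 means the spike output buffer overflowed.  ``eff_sum`` /
    ``eff_count`` accumulate the STP efficacy factor u*x over presynaptic
    arrival events (used for the effective-EPSP readout).

    ``noise`` is the pregenerated (n_steps, n) float32 standard-normal field
    (an empty array disables noise); the per-step membrane increment is
    ``noise_amp * noise[k, i]``.
    """
    n = V.shape[0]
    has_noise = noise.shape[0] > 0
    nspk = 0
    eff_sum = 0.0
    eff_cnt = 0
    p_stim = 0
    m_stim = stim_step.shape[0]
    cap = spk_step.shape[0]
    lam = dt / tau_m
    vt_off = 0.0  # accumulated homeostatic drain, effective threshold VT + vt_off

    for k in range(n_steps):
        gstep = step0 + k
        slot = gstep % RING
        ring_cnt[slot] = 0

        # (1)+(2) integrate, decay, detect
        for i in range(n):
            ge[i] *= decay_e
            gext[i] *= decay_e
            gi[i] *= decay_i
            if refrac[i] > 0:
                refrac[i] -= 1
                continue
            v = V[i]
            v += (
                -(v - e_leak)
                - (ge[i] + gext[i]) * (v - e_exc)
                - gi[i] * (v - e_inh)
            ) * lam
            if has_noise:
                v += noise_amp * noise[k, i]
            if i < n_exc:
                thr = VT[i] + vt_off
            else:
                thr = VT[i]
            if v >= thr:
                c = ring_cnt[slot]
                ring_ids[slot, c] = i
                ring_cnt[slot] = c + 1
                if nspk >= cap:
                    return (-1, nspk, eff_sum, eff_cnt)
                spk_step[nspk] = gstep
                spk_id[nspk] = i
                nspk += 1
                if i < n_exc:
                    last_post[i] = gstep
                    v = v_reset_e
                else:
                    v = v_reset_i
                refrac[i] = refrac_steps
            V[i] = v

        # (3a) E->E deliveries (arrival = spike + d_ee)
        j = gstep - d_ee
        if j >= 0:
            sl = j % RING
            for c in range(ring_cnt[sl]):
                m = ring_ids[sl, c]
                if m < n_exc:
                    if stp_on:
                        # lazy exponential decay since the last touch
                        dtl = (gstep - stp_touch[m]) * dt
                        if dtl > 0:
                            u[m] = u_base + (u[m] - u_base) * np.exp(-dtl / tau_f)
                            x[m] = 1.0 + (x[m] - 1.0) * np.exp(-dtl / tau_d)
                        stp_touch[m] = gstep
                        eff = u[m] * x[m]
                    else:
                        eff = 1.0
                    eff_sum += eff
                    eff_cnt += 1
                    for s in range(ee_indptr[m], ee_indptr[m + 1]):
                        nn = ee_post[s]
                        ge[nn] += ee_w[s] * eff
                        if stdp_on:
                            tp = last_post[nn]
                            if tp > NEG and tp != gstep:
                                wv = ee_w[s] + a_minus * np.exp(
                                    (tp - gstep) * dt / tau_minus
                                )
                                ee_w[s] = wv if wv > 0.0 else 0.0
                    if stp_on:
                        u0 = u[m]
                        x0 = x[m]
                        u[m] = u0 + u_base * (1.0 - u0)
                        x[m] = x0 - x0 * u0
                    last_arr[m] = gstep

        # (3b) E->I deliveries
        j = gstep - d_ei
        if j >= 0:
            sl = j % RING
            for c in range(ring_cnt[sl]):
                m = ring_ids[sl, c]
                if m < n_exc:
                    for s in range(ei_indptr[m], ei_indptr[m + 1]):
                        ge[ei_post[s]] += ei_w[s]

        # (3c) I->E and I->I deliveries
        j = gstep - d_io
        if j >= 0:
            sl = j % RING
            for c in range(ring_cnt[sl]):
                m = ring_ids[sl, c]
                if m >= n_exc:
                    mi = m - n_exc
                    for s in range(io_indptr[mi], io_indptr[mi + 1]):
                        gi[io_post[s]] += io_w[s]

        # (3d) external input increments due this step
        while p_stim < m_stim and stim_step[p_stim] == k:
            gext[stim_neuron[p_stim]] += stim_inc[p_stim]
            p_stim += 1

        # (4) potentiation for this step's postsynaptic spikes
        if stdp_on:
            for c in range(ring_cnt[slot]):
                i = ring_ids[slot, c]
                if i < n_exc:
                    for s in range(in_indptr[i], in_indptr[i + 1]):
                        ta = last_arr[in_pre[s]]
                        if ta > NEG and ta != gstep:
                            wi = in_widx[s]
                            ee_w[wi] += a_plus * np.exp(
                                -(gstep - ta) * dt / tau_plus
                            )

        # (5) intrinsic plasticity
        if ip_on:
            vt_off -= eta_h
            for c in range(ring_cnt[slot]):
                i = ring_ids[slot, c]
                if i < n_exc:
                    VT[i] += eta

    # fold the scalar threshold drain back into the per-neuron thresholds
    if ip_on and vt_off != 0.0:
        for i in range(n_exc):
            VT[i] += vt_off
    # flush lazy STP decay to the end of the block
    if stp_on:
        end = step0 + n_steps
        for m in range(n_exc):
            dtl = (end - stp_touch[m]) * dt
            if dtl > 0:
                u[m] = u_base + (u[m] - u_base) * np.exp(-dtl / tau_f)
                x[m] = 1.0 + (x[m] - 1.0) * np.exp(-dtl / tau_d)
            stp_touch[m] = end
    return (0, nspk, eff_sum, eff_cnt)
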