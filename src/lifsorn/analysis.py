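"""Quantitative readouts: activity statistics, replay metrics, connectivity.

All replay metrics operate on pooled cluster spike trains.  A cluster's rate
curve is its pooled spikes convolved with a unit-mass Gaussian kernel of width
``tau_rate`` = 50 ms; its *firing time* within a trial is the first strict
local maximum of that curve in the 0-500 ms window after cue onset (plateaus
resolve to their midpoint).  The replay score of a trial is the Spearman rank
correlation between cluster firing times and cluster positions on the
start->goal axis; clusters without a firing time are dropped from the trial,
and trials with fewer than two firing clusters carry no score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .params import NeuronParams

TAU_RATE = 50.0         # ms, Gaussian rate-kernel width
REPLAY_WINDOW = 500.0   # ms after cue onset


# ---------------------------------------------------------------------------
# Generic spike-train statistics
# ---------------------------------------------------------------------------

def binned_counts(
    times: np.ndarray, ids: np.ndarray, n_neurons: int,
    t_start: float, t_end: float, bin_ms: float,
) -> np.ndarray:
    """(n_neurons, n_bins) spike-count matrix over [t_start, t_end)."""
    n_bins = int(np.floor((t_end - t_start) / bin_ms))
    if n_bins < 1:
        raise ValueError("degenerate window")
    sel = (times >= t_start) & (times < t_start + n_bins * bin_ms) & (ids < n_neurons)
    b = ((times[sel] - t_start) / bin_ms).astype(np.int64)
    flat = np.bincount(
        ids[sel].astype(np.int64) * n_bins + b, minlength=n_neurons * n_bins
    )
    return flat.reshape(n_neurons, n_bins)


def pairwise_correlation(
    times: np.ndarray, ids: np.ndarray, n_neurons: int,
    t_start: float, t_end: float, bin_ms: float = 20.0,
) -> np.ndarray:
    """Pearson correlations of binned spike counts for all disjoint pairs.

    Pairs involving a neuron with zero count variance in the window are
    excluded.  Returns the upper-triangle coefficients as a flat array.
    """
    counts = binned_counts(times, ids, n_neurons, t_start, t_end, bin_ms)
    keep = counts.std(axis=1) > 0
    c = np.corrcoef(counts[keep])
    if c.ndim == 0:
        return np.empty(0)
    iu = np.triu_indices(c.shape[0], k=1)
    return c[iu]


@dataclass
class IsiStats:
    """Interspike-interval summary of a population."""

    isis: np.ndarray        # pooled ISIs (ms)
    cvs: np.ndarray         # per-neuron coefficient of variation
    fit_rate: float         # 1/ms, exponential fit to the ISI tail (> 50 ms)


def isi_stats(
    times: np.ndarray, ids: np.ndarray, neuron_ids: Sequence[int],
    tail_ms: float = 50.0,
) -> IsiStats:
    """Per-neuron ISIs and CV; exponential tail fit restricted to ISI > tail_ms.

    Neurons with fewer than two spikes are skipped.  The tail fit is the
    maximum-likelihood exponential rate of the excess ``ISI - tail_ms``
    (memorylessness of the exponential), which sidesteps the refractory
    distortion at short intervals.
    """
    all_isis: List[np.ndarray] = []
    cvs: List[float] = []
    for n in neuron_ids:
        t = np.sort(times[ids == n])
        if len(t) < 2:
            continue
        isi = np.diff(t)
        all_isis.append(isi)
        m = isi.mean()
        cvs.append(isi.std() / m if m > 0 else np.nan)
    isis = np.concatenate(all_isis) if all_isis else np.empty(0)
    tail = isis[isis > tail_ms]
    fit_rate = 1.0 / (tail - tail_ms).mean() if len(tail) else np.nan
    return IsiStats(isis=isis, cvs=np.asarray(cvs), fit_rate=fit_rate)


# ---------------------------------------------------------------------------
# Rate curves and firing times
# ---------------------------------------------------------------------------

def rate_curve(
    times: np.ndarray, t_start: float, t_end: float,
    bin_ms: float = 1.0, tau_rate: float = TAU_RATE,
) -> Tuple[np.ndarray, np.ndarray]:
    """Pooled-spike rate (Hz) on a regular grid via Gaussian smoothing.

    The kernel has unit mass, so the integral of the curve equals the spike
    count whenever the kernel support does not leak past the window edges.
    """
    grid = np.arange(t_start, t_end, bin_ms)
    counts = np.zeros(len(grid))
    sel = (times >= t_start) & (times < t_start + len(grid) * bin_ms)
    idx = ((times[sel] - t_start) / bin_ms).astype(np.int64)
    np.add.at(counts, idx, 1.0)
    half = int(np.ceil(4.0 * tau_rate / bin_ms))
    kt = np.arange(-half, half + 1) * bin_ms
    kernel = np.exp(-0.5 * (kt / tau_rate) ** 2)
    kernel /= kernel.sum() * bin_ms          # unit mass in 1/ms
    rate = np.convolve(counts, kernel, mode="same") * 1000.0  # Hz
    return grid, rate


def first_peak(grid: np.ndarray, rate: np.ndarray) -> Optional[float]:
    """Time of the first strict local maximum; plateaus resolve to midpoints.

    Runs of equal values count as one candidate whose neighbours on both sides
    must be strictly lower; curve endpoints never qualify.  Returns None for
    monotone or empty curves.
    """
    n = len(rate)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and rate[j + 1] == rate[i]:
            j += 1
        if i > 0 and j < n - 1 and rate[i - 1] < rate[i] and rate[j + 1] < rate[i]:
            return float(0.5 * (grid[i] + grid[j]))
        i = j + 1
    return None


def firing_time(
    times: np.ndarray, onset: float,
    window: float = REPLAY_WINDOW, bin_ms: float = 1.0, tau_rate: float = TAU_RATE,
) -> Optional[float]:
    """First rate-curve peak within [onset, onset + window], relative to onset."""
    sel = (times >= onset) & (times <= onset + window)
    if not np.any(sel):
        return None
    grid, rate = rate_curve(times[sel], onset, onset + window, bin_ms, tau_rate)
    t = first_peak(grid, rate)
    return None if t is None else t - onset


# ---------------------------------------------------------------------------
# Replay scoring
# ---------------------------------------------------------------------------

def spearman_replay(
    firing_times: Sequence[Optional[float]], axis_positions: np.ndarray
) -> float:
    """Rank correlation between cluster firing times and axis positions.

    Missing clusters are excluded; with fewer than two points the score is
    undefined (NaN).  Average ranks are used for ties.
    """
    ft = np.array([np.nan if t is None else t for t in firing_times], dtype=float)
    ok = np.isfinite(ft)
    if ok.sum() < 2:
        return float("nan")
    pos = np.asarray(axis_positions, dtype=float)[ok]
    if np.all(ft[ok] == ft[ok][0]) or np.all(pos == pos[0]):
        return float("nan")  # rank correlation undefined for constant input
    rho = stats.spearmanr(ft[ok], pos).statistic
    return float(rho)


@dataclass
class ReplayTrial:
    trial: int
    firing_times: np.ndarray   # per cluster, NaN if missing (ms after onset)
    rho: float
    n_clusters: int


def replay_trials(
    spikes: pd.DataFrame,
    clusters,
    onsets: np.ndarray,
    phase: str,
    reverse_axis: bool = False,
    window: float = REPLAY_WINDOW,
    bin_ms: float = 1.0,
    tau_rate: float = TAU_RATE,
) -> List[ReplayTrial]:
    """Score every trial of a test phase.

    ``reverse_axis=True`` ranks positions on the goal->start axis (used for
    goal-point cues).  Only spikes in the 0-``window`` ms window after each
    onset enter the rate curves.
    """
    sub = spikes[spikes["phase"] == phase]
    pos = clusters.axis_positions.copy()
    if reverse_axis:
        pos = pos.max() - pos
    member_times = [
        sub[sub["neuron_id"].isin(ids)]["time_ms"].to_numpy()
        for ids in clusters.members
    ]
    out: List[ReplayTrial] = []
    for k, onset in enumerate(onsets):
        fts = []
        for t in member_times:
            fts.append(firing_time(t, onset, window, bin_ms, tau_rate))
        ft = np.array([np.nan if v is None else v for v in fts])
        rho = spearman_replay(fts, pos)
        out.append(ReplayTrial(k, ft, rho, int(np.isfinite(ft).sum())))
    return out


def trial_rhos(trials: List[ReplayTrial]) -> np.ndarray:
    """Defined replay scores of a trial list (trials with <2 clusters dropped)."""
    return np.array([t.rho for t in trials if math.isfinite(t.rho)])


def shift_test(rho_before: np.ndarray, rho_after: np.ndarray) -> Tuple[float, float, float]:
    """Change of mean replay score and a two-sample KS test between the pools."""
    if len(rho_before) == 0 or len(rho_after) == 0:
        raise ValueError("empty sample")
    d = float(np.mean(rho_after) - np.mean(rho_before))
    if np.array_equal(np.sort(rho_before), np.sort(rho_after)):
        return d, 0.0, 1.0
    ks = stats.ks_2samp(rho_before, rho_after)
    return d, float(ks.statistic), float(ks.pvalue)


# ---------------------------------------------------------------------------
# Cross-correlograms
# ---------------------------------------------------------------------------

def cluster_cross_correlogram(
    spikes: pd.DataFrame,
    clusters,
    onsets: np.ndarray,
    phase: str,
    bin_ms: float = 10.0,
    max_lag_ms: float = 250.0,
    window: float = REPLAY_WINDOW,
) -> Dict[int, np.ndarray]:
    """Count-based cross-correlation of pooled cluster trains, by cluster distance.

    For every trial and ordered cluster pair (i, j), the spike trains in the
    0-``window`` ms post-onset window are binned and cross-correlated; the raw
    correlograms are summed within each cluster-distance group ``j - i``.
    Returns distance -> correlogram over lags ``-max_lag..+max_lag`` (a
    positive-lag peak means cluster j fires after cluster i).  Normalization
    to [0, 1] is left to :func:`normalize_correlograms`.
    """
    sub = spikes[spikes["phase"] == phase]
    n_clu = clusters.n_clusters
    n_bins = int(round(window / bin_ms))
    n_lag = int(round(max_lag_ms / bin_ms))
    member_times = [
        sub[sub["neuron_id"].isin(ids)]["time_ms"].to_numpy()
        for ids in clusters.members
    ]
    acc: Dict[int, np.ndarray] = {
        d: np.zeros(2 * n_lag + 1) for d in range(-(n_clu - 1), n_clu) if d != 0
    }
    for onset in onsets:
        trains = []
        for t in member_times:
            sel = (t >= onset) & (t < onset + n_bins * bin_ms)
            b = ((t[sel] - onset) / bin_ms).astype(np.int64)
            trains.append(np.bincount(b, minlength=n_bins).astype(float))
        for i in range(n_clu):
            if not trains[i].any():
                continue
            for j in range(n_clu):
                if i == j or not trains[j].any():
                    continue
                full = np.correlate(trains[j], trains[i], mode="full")
                mid = n_bins - 1
                acc[j - i] += full[mid - n_lag: mid + n_lag + 1]
    return acc


def normalize_correlograms(cc: Dict[int, np.ndarray]) -> Dict[int, np.ndarray]:
    """Min-max normalize each distance group independently to [0, 1]."""
    out = {}
    for d, v in cc.items():
        lo, hi = v.min(), v.max()
        out[d] = (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)
    return out


# ---------------------------------------------------------------------------
# Spontaneous-activity transition structure
# ---------------------------------------------------------------------------

def transition_probabilities(
    spikes: pd.DataFrame,
    clusters,
    phase: str,
    t_start: float,
    t_end: float,
    bin_ms: float = 1.0,
    tau_rate: float = TAU_RATE,
) -> np.ndarray:
    """First-order transition matrix of cluster rate-peak sequences.

    All strict relative maxima of every cluster's rate curve over the whole
    phase are merged into one time-ordered label sequence; entry (i, j) is the
    number of i->j steps divided by the number of times i occurs as a source.
    Rows of clusters that never peak (or only appear last) are NaN.
    """
    sub = spikes[spikes["phase"] == phase]
    n_clu = clusters.n_clusters
    events: List[Tuple[float, int]] = []
    for c, ids in enumerate(clusters.members):
        t = sub[sub["neuron_id"].isin(ids)]["time_ms"].to_numpy()
        t = t[(t >= t_start) & (t <= t_end)]
        grid, rate = rate_curve(t, t_start, t_end, bin_ms, tau_rate)
        times = _all_peaks(grid, rate)
        events.extend((tt, c) for tt in times)
    events.sort(key=lambda e: (e[0], e[1]))
    counts = np.zeros((n_clu, n_clu))
    for (t0, a), (t1, b) in zip(events[:-1], events[1:]):
        counts[a, b] += 1
    out = np.full((n_clu, n_clu), np.nan)
    row = counts.sum(axis=1)
    nz = row > 0
    out[nz] = counts[nz] / row[nz, None]
    return out


def _all_peaks(grid: np.ndarray, rate: np.ndarray) -> List[float]:
    """All strict local maxima (plateau midpoints) of a sampled curve."""
    peaks = []
    n = len(rate)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and rate[j + 1] == rate[i]:
            j += 1
        if i > 0 and j < n - 1 and rate[i - 1] < rate[i] and rate[j + 1] < rate[i]:
            peaks.append(float(0.5 * (grid[i] + grid[j])))
        i = j + 1
    return peaks


def forward_backward_transition_change(
    before: np.ndarray, after: np.ndarray, max_span: int = 2
) -> Tuple[float, float]:
    """Mean transition-probability change for short forward vs backward steps.

    Forward means i -> j with ``0 < j - i <= max_span`` (at most ``max_span-1``
    clusters in between); backward is the mirror.  NaN entries are ignored.
    """
    diff = after - before
    n = diff.shape[0]
    fwd, bwd = [], []
    for i in range(n):
        for j in range(n):
            if 0 < j - i <= max_span:
                fwd.append(diff[i, j])
            elif 0 < i - j <= max_span:
                bwd.append(diff[i, j])
    return float(np.nanmean(fwd)), float(np.nanmean(bwd))


# ---------------------------------------------------------------------------
# Recall speed and persistence
# ---------------------------------------------------------------------------

def recall_speed(
    trials: List[ReplayTrial], axis_positions: np.ndarray, rho_threshold: float = 0.9
) -> pd.DataFrame:
    """Per-trial replay speed for trials with replay score above threshold.

    The speed is the slope (um/ms) of the ordinary least-squares fit of
    cluster-center axis position against cluster firing time.  Returns an
    empty frame when no trial qualifies.
    """
    rows = []
    for tr in trials:
        if not math.isfinite(tr.rho) or tr.rho <= rho_threshold:
            continue
        ok = np.isfinite(tr.firing_times)
        t = tr.firing_times[ok]
        xpos = np.asarray(axis_positions)[ok]
        if len(t) < 2 or np.all(t == t[0]):
            continue
        fit = stats.linregress(t, xpos)
        rows.append((tr.trial, float(fit.slope), tr.rho))
    return pd.DataFrame(rows, columns=["trial", "speed_um_per_ms", "rho"])


def match_persistence(
    rho_pre: np.ndarray,
    rho_post: np.ndarray,
    post_times_s: np.ndarray,
    threshold: float = 0.6,
    bin_s: float = 60.0,
) -> pd.DataFrame:
    """Change in percentage of matches (rho > threshold) per post-training bin.

    Trials with undefined scores are excluded from both numerator and
    denominator.  ``post_times_s`` are the trial times measured from the start
    of the post-training test phase.
    """
    ok_pre = np.isfinite(rho_pre)
    pre_pct = 100.0 * np.mean(rho_pre[ok_pre] > threshold) if ok_pre.any() else np.nan
    ok = np.isfinite(rho_post)
    rho_post = rho_post[ok]
    post_times_s = np.asarray(post_times_s)[ok]
    if len(post_times_s):
        n_bins = int(np.floor(post_times_s.max() / bin_s)) + 1
    else:
        n_bins = 0
    rows = []
    for b in range(n_bins):
        sel = (post_times_s >= b * bin_s) & (post_times_s < (b + 1) * bin_s)
        if not sel.any():
            continue
        pct = 100.0 * np.mean(rho_post[sel] > threshold)
        rows.append((b, (b + 0.5) * bin_s, pct - pre_pct, int(sel.sum())))
    return pd.DataFrame(rows, columns=["bin", "t_mid_s", "change_pct", "n_trials"])


# ---------------------------------------------------------------------------
# Connectivity readouts
# ---------------------------------------------------------------------------

def adjacent_cluster_weights(
    ee, membership_map: np.ndarray, n_clu: int
) -> Tuple[float, float]:
    """Mean E->E weight between adjacent clusters over all possible connections.

    For each adjacent pair (i, i+1) the summed weight of synapses from
    members of i to members of i+1 (forward) resp. i+1 to i (backward) is
    divided by the number of possible ordered connections between the two
    groups — absent connections count as zero, so the measure reflects both
    weight changes and synapse creation/pruning.  Pair values are averaged
    over the adjacent pairs; NaN if any group is empty.
    """
    counts = np.bincount(membership_map[membership_map >= 0], minlength=n_clu)
    if np.any(counts[: n_clu] == 0):
        return float("nan"), float("nan")
    fwd_vals, bwd_vals = [], []
    if len(ee.pre):
        cp = membership_map[ee.pre]
        cq = membership_map[ee.post]
    else:
        cp = cq = np.empty(0, dtype=int)
    for i in range(n_clu - 1):
        n_pairs = counts[i] * counts[i + 1]
        f = (cp == i) & (cq == i + 1)
        fwd_vals.append(ee.weight[f].sum() / n_pairs if len(cp) else 0.0)
        b = (cp == i + 1) & (cq == i)
        bwd_vals.append(ee.weight[b].sum() / n_pairs if len(cp) else 0.0)
    return float(np.mean(fwd_vals)), float(np.mean(bwd_vals))


def adjacent_cluster_weight_pairs(
    ee, membership_map: np.ndarray, n_clu: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-adjacent-pair forward and backward mean weight over possible connections."""
    counts = np.bincount(membership_map[membership_map >= 0], minlength=n_clu)
    fwd = np.full(n_clu - 1, np.nan)
    bwd = np.full(n_clu - 1, np.nan)
    if len(ee.pre):
        cp = membership_map[ee.pre]
        cq = membership_map[ee.post]
    else:
        cp = cq = np.empty(0, dtype=int)
    for i in range(n_clu - 1):
        if counts[i] == 0 or counts[i + 1] == 0:
            continue
        n_pairs = counts[i] * counts[i + 1]
        fwd[i] = ee.weight[(cp == i) & (cq == i + 1)].sum() / n_pairs if len(cp) else 0.0
        bwd[i] = ee.weight[(cp == i + 1) & (cq == i)].sum() / n_pairs if len(cp) else 0.0
    return fwd, bwd


def cluster_weight_matrix(ee, membership_map: np.ndarray, n_clu: int) -> np.ndarray:
    """Mean weight of existing synapses between every ordered cluster pair."""
    out = np.full((n_clu, n_clu), np.nan)
    cp = membership_map[ee.pre]
    cq = membership_map[ee.post]
    for i in range(n_clu):
        for j in range(n_clu):
            sel = (cp == i) & (cq == j)
            if sel.any():
                out[i, j] = ee.weight[sel].mean()
    return out


# ---------------------------------------------------------------------------
# Weight -> PSP conversion
# ---------------------------------------------------------------------------

_CLASS_REVERSAL_TAU = {
    "EE": ("e_exc", "tau_e"),
    "EI": ("e_exc", "tau_e"),
    "IE": ("e_inh", "tau_i"),
    "II": ("e_inh", "tau_i"),
}


def weight_to_psp(weight, cls: str, neuron: Optional[NeuronParams] = None):
    """Peak membrane deflection (mV) of a single spike of the given weight.

    Closed-form solution of the membrane equation linearized at rest: an
    exponentially decaying conductance transient of amplitude ``weight``
    drives the potential with fixed driving force ``E_rev - E_L``; the peak of
    the resulting double-exponential is

    ``dV = w (E_rev - E_L) (ts/(tau-ts)) [(tau/ts)^(-ts/(tau-ts)) - (tau/ts)^(-tau/(tau-ts))]``

    For an excitatory synapse the transmitted amplitude is the *effective*
    weight (bare weight times the short-term-plasticity factor u*x), which the
    caller must supply.  Negative values are inhibitory deflections.
    """
    p = neuron if neuron is not None else NeuronParams()
    erev_name, tau_name = _CLASS_REVERSAL_TAU[cls]
    e_rev = getattr(p, erev_name)
    ts = getattr(p, tau_name)
    tau = p.tau_m
    w = np.asarray(weight, dtype=float)
    if ts == tau:
        # degenerate limit: g ~ t * exp(-t/tau), peak at t = tau
        peak = np.exp(-1.0)
    else:
        r = tau / ts
        peak = (ts / (tau - ts)) * (r ** (-ts / (tau - ts)) - r ** (-tau / (tau - ts)))
    out = w * (e_rev - p.e_leak) * peak
    return out if out.ndim else float(out)


def mean_psp_amplitudes(net) -> Dict[str, float]:
    """Mean PSP amplitudes (mV) by connection class on the current network.

    Excitatory weights are converted at their mean effective amplitude for a
    single evoked spike at a random time: bare weight times the population
    mean of the short-term-plasticity factor u*x in the network's current
    (stationary) state.  This matches how PSP amplitudes are measured
    experimentally — one evoked presynaptic spike against the background
    state — rather than conditioning on the presynaptic neuron's own spike
    times, which oversamples post-spike depression.
    """
    p = net.params.neuron
    if net.params.stp.enabled:
        eff = float(np.mean(net.stp.u * net.stp.x))
    else:
        eff = 1.0
    out = {}
    if len(net.ee.weight):
        out["EE"] = float(np.mean(weight_to_psp(net.ee.weight * eff, "EE", p)))
    for cls in ("EI", "IE", "II"):
        t = net.fixed[cls]
        if len(t.weight):
            out[cls] = float(np.mean(np.abs(weight_to_psp(t.weight, cls, p))))
    return out


def firing_rates(
    times: np.ndarray, ids: np.ndarray, n_neurons: int, t_start: float, t_end: float
) -> np.ndarray:
    """Per-neuron mean firing rate (Hz) for neurons ``0..n_neurons-1`` in a window."""
    sel = (times >= t_start) & (times < t_end) & (ids < n_neurons)
    c = np.bincount(ids[sel].astype(np.int64), minlength=n_neurons)
    return c / ((t_end - t_start) * 1e-3)
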