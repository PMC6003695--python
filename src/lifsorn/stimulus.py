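"""External drive: moving-spot sweeps, stationary cue flashes, bar flashes.

A stimulus is a spatial rate field ``r(x, t)`` (Hz) sampled at the excitatory
neuron positions.  Each excitatory neuron receives ``n_input`` independent
Poisson trains at that rate; their superposition is generated as per-timestep
Poisson counts with mean ``n_input * r * dt`` (statistically identical to the
individual trains and the train identity is not observable downstream).  Every
input spike increments the neuron's external conductance by ``w_ff``; the
conductance decays with the excitatory synaptic time constant.

The spot's cross-section is a super-Gaussian ``r_max * exp(-(d/alpha)^beta)``
with ``beta = 4``, i.e. a flat-topped bump with steep flanks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .params import StimulusParams


@dataclass
class SpotStimulus:
    """A spot moving linearly from ``x_start`` to ``x_end`` during [t0, t0+duration].

    A stationary cue is the special case ``x_end == x_start`` (default duration
    100 ms).  For a sweep the duration is the path length divided by the sweep
    speed.
    """

    x_start: np.ndarray
    x_end: np.ndarray
    t0: float              # ms, onset
    duration: float        # ms
    r_max: float = 50.0
    alpha: float = 150.0
    beta: float = 4.0

    def __post_init__(self) -> None:
        self.x_start = np.asarray(self.x_start, dtype=float)
        self.x_end = np.asarray(self.x_end, dtype=float)
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @classmethod
    def sweep(cls, sp: StimulusParams, t0: float, reverse: bool = False) -> "SpotStimulus":
        a, b = np.asarray(sp.x_start, float), np.asarray(sp.x_goal, float)
        if reverse:
            a, b = b, a
        duration = float(np.linalg.norm(b - a)) / sp.v_spot
        return cls(a, b, t0, duration, sp.r_max, sp.alpha, sp.beta)

    @classmethod
    def cue(cls, sp: StimulusParams, t0: float, where: str = "start") -> "SpotStimulus":
        pos = {"start": sp.x_start, "mid": sp.x_mid, "goal": sp.x_goal}[where]
        pos = np.asarray(pos, float)
        return cls(pos, pos, t0, sp.t_cue, sp.r_max, sp.alpha, sp.beta)

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    def position(self, t) -> np.ndarray:
        """Spot centre at time ``t`` (linear interpolation along the path)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < self.t0) or np.any(t > self.t_end):
            raise ValueError("t outside the stimulus interval")
        frac = (t - self.t0) / self.duration
        return self.x_start + np.multiply.outer(frac, self.x_end - self.x_start)

    def rate(self, pos: np.ndarray, t: float) -> np.ndarray:
        """Rate field (Hz) at positions ``pos`` and time ``t``; 0 outside the window."""
        pos = np.atleast_2d(np.asarray(pos, dtype=float))
        if t < self.t0 or t > self.t_end:
            return np.zeros(pos.shape[0])
        d = np.linalg.norm(pos - self.position(t), axis=1)
        return self.r_max * np.exp(-((d / self.alpha) ** self.beta))


@dataclass
class BarStimulus:
    """A bar spanning the segment ``x_start -> x_end``, flashed for ``duration``.

    The cross-section orthogonal to the bar equals the spot's profile: the rate
    is ``r_max * exp(-(d/alpha)^beta)`` with ``d`` the distance from the
    segment (perpendicular within the span, endpoint distance beyond it).
    """

    x_start: np.ndarray
    x_end: np.ndarray
    t0: float
    duration: float = 100.0
    r_max: float = 50.0
    alpha: float = 150.0
    beta: float = 4.0

    def __post_init__(self) -> None:
        self.x_start = np.asarray(self.x_start, dtype=float)
        self.x_end = np.asarray(self.x_end, dtype=float)

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    def rate(self, pos: np.ndarray, t: float) -> np.ndarray:
        pos = np.atleast_2d(np.asarray(pos, dtype=float))
        if t < self.t0 or t > self.t_end:
            return np.zeros(pos.shape[0])
        seg = self.x_end - self.x_start
        seg_len2 = float(seg @ seg)
        if seg_len2 == 0:
            d = np.linalg.norm(pos - self.x_start, axis=1)
        else:
            frac = np.clip((pos - self.x_start) @ seg / seg_len2, 0.0, 1.0)
            nearest = self.x_start + frac[:, None] * seg
            d = np.linalg.norm(pos - nearest, axis=1)
        return self.r_max * np.exp(-((d / self.alpha) ** self.beta))


def generate_input_spikes(
    rates: np.ndarray, n_input: int, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-neuron (or per-neuron-per-step) Poisson counts for superposed trains.

    ``rates`` in Hz; the mean count is ``n_input * rate * dt`` with ``dt`` in
    ms.  Entries with negligible rate are skipped (no draw), which leaves the
    result exactly zero there.
    """
    lam = np.asarray(rates, dtype=float) * (n_input * dt * 1e-3)
    counts = np.zeros(lam.shape, dtype=np.int64)
    mask = lam > 1e-12
    if np.any(mask):
        counts[mask] = rng.poisson(lam[mask])
    return counts


def external_conductance_step(g_ext, counts, w_ff: float, dt: float, tau_e: float):
    """One step of the external conductance: exponential decay plus input jumps."""
    return np.asarray(g_ext) * np.exp(-dt / tau_e) + w_ff * np.asarray(counts)


@dataclass
class StimulusSchedule:
    """A timed list of stimulus events feeding one simulation run."""

    events: List[object] = field(default_factory=list)
    n_input: int = 100
    w_ff: float = 0.04

    def add(self, event) -> None:
        self.events.append(event)

    def block_increments(
        self,
        t0_ms: float,
        n_steps: int,
        dt: float,
        positions_exc: np.ndarray,
        rng: np.random.Generator,
    ) -> Optional[np.ndarray]:
        """External-conductance increments for one simulation block.

        Returns a ``(n_steps, n_exc)`` float32 array of g_ext jumps (already
        multiplied by ``w_ff``), or None if no event overlaps the block.
        Increment at row k is applied at the end of step k, matching a spike
        delivered during that step.
        """
        t1_ms = t0_ms + n_steps * dt
        active = [ev for ev in self.events if ev.t0 < t1_ms and ev.t_end > t0_ms]
        if not active:
            return None
        out = np.zeros((n_steps, positions_exc.shape[0]), dtype=np.float32)
        for ev in active:
            k0 = max(0, int(np.ceil((ev.t0 - t0_ms) / dt - 1e-9)))
            k1 = min(n_steps, int(np.floor((ev.t_end - t0_ms) / dt + 1e-9)) + 1)
            for k in range(k0, k1):
                t = t0_ms + k * dt
                if t > ev.t_end:
                    break
                counts = generate_input_spikes(
                    ev.rate(positions_exc, t), self.n_input, dt, rng
                )
                if counts.any():
                    out[k] += (self.w_ff * counts).astype(np.float32)
        return out
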