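"""Model parameters with defaults for the layer-5 cortical sheet model.

Every quantity that the network, plasticity, stimulus and protocol layers use
is collected here in plain dataclasses so that a whole experiment is a pure
function of one :class:`LifSornParams` object and a seed.  All defaults can be
overridden from a YAML config file (:func:`load_params` / :func:`save_params`).

Units: lengths in micrometres, times in milliseconds unless a field name says
otherwise (``*_s`` fields are in seconds), voltages in millivolts, rates in Hz.
Conductances and synaptic weights are dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields as dc_fields
from pathlib import Path
from typing import Optional

import yaml


@dataclass
class GeometryParams:
    """Rectangular cortical sheet on which neurons are scattered."""

    width: float = 2500.0   # um
    height: float = 1000.0  # um

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("grid dimensions must be positive")


@dataclass
class NeuronParams:
    """Leaky integrate-and-fire membrane and synapse constants."""

    e_leak: float = -60.0       # mV, resting potential
    tau_m: float = 20.0         # ms, membrane time constant
    e_exc: float = 0.0          # mV, reversal of excitatory conductances
    e_inh: float = -80.0        # mV, reversal of inhibitory conductances
    tau_e: float = 3.0          # ms, excitatory synaptic time constant
    tau_i: float = 5.0          # ms, inhibitory synaptic time constant
    sigma_noise: float = 16.0   # mV, stationary std of the free membrane potential
    v_reset_exc: float = -70.0  # mV
    v_reset_inh: float = -60.0  # mV
    v_thresh_inh: float = -48.0  # mV, fixed inhibitory threshold
    refractory: float = 5.0     # ms, absolute refractory period (not stated in
    # the original description of the model; taken from its predecessor)
    dt: float = 0.1             # ms, simulation timestep


@dataclass
class ConnectivityParams:
    """Distance-dependent wiring of the fixed (non-plastic) connection classes."""

    sigma_c: float = 200.0   # um, std of the Gaussian connection-probability kernel
    cf_ei: float = 0.1       # connection fraction E->I
    cf_ie: float = 0.1       # connection fraction I->E
    cf_ii: float = 0.5       # fraction of reciprocal I<->I pairs
    w_ei: float = 0.15       # E->I weight
    w_inh: float = 0.4       # I->E and I->I weight
    delay_ee: float = 3.0    # ms
    delay_ei: float = 1.0    # ms
    delay_ie: float = 2.0    # ms
    delay_ii: float = 2.0    # ms


@dataclass
class StpParams:
    """Short-term facilitation/depression of outgoing E->E efficacy."""

    u_base: float = 0.04     # U, facilitation increment and resting u
    tau_f: float = 2000.0    # ms, facilitation time constant
    tau_d: float = 500.0     # ms, depression time constant
    enabled: bool = True


@dataclass
class StdpParams:
    """Asymmetric exponential STDP window, nearest-neighbour pairing."""

    a_plus: float = 4.8e-2
    a_minus: float = -2.4e-2
    tau_plus: float = 15.0   # ms
    tau_minus: float = 30.0  # ms
    enabled: bool = True


@dataclass
class SnParams:
    """Synaptic normalization: per-neuron incoming E->E weight budget."""

    target_cf: float = 0.1       # target connection fraction entering W_total
    mean_strength: float = 0.8   # mean recurrent excitatory synapse strength
    interval_s: float = 1.0      # s, how often incoming weights are rescaled
    enabled: bool = True


@dataclass
class SpParams:
    """Structural plasticity: stochastic synapse creation and pruning."""

    growth_mean: float = 6000.0     # synapses per second
    growth_sd: float = 6000.0       # synapses per second
    init_weight: float = 1e-3
    prune_threshold: float = 1e-4   # strict '<' comparison
    interval_s: float = 1.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.init_weight <= self.prune_threshold:
            raise ValueError("newborn synapses would be pruned immediately")


@dataclass
class IpParams:
    """Intrinsic plasticity of excitatory firing thresholds."""

    eta: float = 0.1         # mV per update
    r_target: float = 3.0    # Hz
    enabled: bool = True

    def h(self, dt_ms: float) -> float:
        """Target spikes per timestep (r_target * dt)."""
        return self.r_target * dt_ms * 1e-3


@dataclass
class StimulusParams:
    """Moving-spot drive: geometry, rate field and feed-forward coupling."""

    x_start: tuple = (375.0, 500.0)   # um, S~
    x_goal: tuple = (2125.0, 500.0)   # um, G~
    r_max: float = 50.0               # Hz, peak rate of each input train
    alpha: float = 150.0              # um, spot scale
    beta: float = 4.0                 # spot shape (super-Gaussian exponent)
    n_input: int = 100                # Poisson trains per excitatory neuron
    w_ff: float = 0.04                # feed-forward weight
    v_spot: float = 4.0               # um/ms, sweep speed
    t_cue: float = 100.0              # ms, duration of a stationary cue flash

    @property
    def x_mid(self) -> tuple:
        return (
            0.5 * (self.x_start[0] + self.x_goal[0]),
            0.5 * (self.x_start[1] + self.x_goal[1]),
        )


@dataclass
class ClusterParams:
    """Recording clusters standing in for multi-electrode channels."""

    n_clusters: int = 8
    radius: float = 100.0  # um


@dataclass
class LifSornParams:
    """Complete parameter set of one network instance."""

    n_exc: int = 1000
    n_inh: int = 200
    geometry: GeometryParams = field(default_factory=GeometryParams)
    neuron: NeuronParams = field(default_factory=NeuronParams)
    connectivity: ConnectivityParams = field(default_factory=ConnectivityParams)
    stp: StpParams = field(default_factory=StpParams)
    stdp: StdpParams = field(default_factory=StdpParams)
    sn: SnParams = field(default_factory=SnParams)
    sp: SpParams = field(default_factory=SpParams)
    ip: IpParams = field(default_factory=IpParams)
    stimulus: StimulusParams = field(default_factory=StimulusParams)
    clusters: ClusterParams = field(default_factory=ClusterParams)

    def __post_init__(self) -> None:
        if self.n_exc <= 0 or self.n_inh < 0:
            raise ValueError("need n_exc > 0 and n_inh >= 0")


_SECTION_TYPES = {
    "geometry": GeometryParams,
    "neuron": NeuronParams,
    "connectivity": ConnectivityParams,
    "stp": StpParams,
    "stdp": StdpParams,
    "sn": SnParams,
    "sp": SpParams,
    "ip": IpParams,
    "stimulus": StimulusParams,
    "clusters": ClusterParams,
}


def params_to_dict(p: LifSornParams) -> dict:
    d = asdict(p)
    d["stimulus"]["x_start"] = list(p.stimulus.x_start)
    d["stimulus"]["x_goal"] = list(p.stimulus.x_goal)
    return d


def params_from_dict(d: dict) -> LifSornParams:
    kwargs: dict = {}
    for key, val in d.items():
        if key in _SECTION_TYPES:
            cls = _SECTION_TYPES[key]
            names = {f.name for f in dc_fields(cls)}
            unknown = set(val) - names
            if unknown:
                raise KeyError(f"unknown keys in section {key!r}: {sorted(unknown)}")
            sec = dict(val)
            if key == "stimulus":
                for k in ("x_start", "x_goal"):
                    if k in sec:
                        sec[k] = tuple(sec[k])
            kwargs[key] = cls(**sec)
        else:
            kwargs[key] = val
    return LifSornParams(**kwargs)


def save_params(p: LifSornParams, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(params_to_dict(p), sort_keys=False))


def load_params(path: str | Path, base: Optional[LifSornParams] = None) -> LifSornParams:
    """Read a YAML config; missing keys fall back to defaults (or ``base``)."""
    d = yaml.safe_load(Path(path).read_text()) or {}
    if base is not None:
        merged = params_to_dict(base)
        for key, val in d.items():
            if key in _SECTION_TYPES and isinstance(val, dict):
                merged[key].update(val)
            else:
                merged[key] = val
        d = merged
    return params_from_dict(d)
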