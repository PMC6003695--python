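# lifsorn

A self-organizing spiking network model of sequence learning in primary
visual cortex, with the full stimulation protocol and analysis suite for
cue-triggered sequence replay.

## The science

Rodent V1 can learn a repeated spatio-temporal stimulus: after conditioning
with a light spot swept across the visual field, a brief flash at the
sequence's start point evokes spiking that anticipates the rest of the
sequence.  `lifsorn` implements a spiking-circuit explanation: a recurrent
network of conductance-based leaky integrate-and-fire neurons (N^E = 1000,
N^I = 200) on a 2D cortical sheet whose excitatory-to-excitatory connectivity
is shaped online by five interacting plasticity mechanisms —

* spike-timing dependent plasticity (STDP): asymmetric exponential window,
  A₊ = 4.8·10⁻², τ₊ = 15 ms, A₋ = −2.4·10⁻², τ₋ = 30 ms, nearest-neighbour
  pairing on spike *arrivals* (spike + 3 ms conduction delay);
* short-term plasticity: facilitation u and depression x per presynaptic
  neuron (U = 0.04, τ_f = 2 s, τ_d = 0.5 s), effective weight W·u·x;
* synaptic normalization: each neuron's summed incoming E→E weight is
  rescaled once per second to 0.1·N^E·0.8·(boundary factor);
* structural plasticity: ~N(6000, 6000) kernel-weighted synapse insertion
  attempts per second at weight 10⁻³, pruning below 10⁻⁴; the connection
  fraction self-organizes to ≈ 0.1;
* intrinsic plasticity: thresholds drift by η(N_spikes − h) per 0.1 ms step,
  pinning every excitatory neuron at 3 Hz.

The moving spot enters as a super-Gaussian rate field
r(x,t) = 50 Hz·exp(−(‖x−u(t)‖/150 µm)⁴) feeding 100 Poisson input trains per
excitatory neuron.  Recording is modelled as eight 100 µm circles (clusters
A–H) along the sweep axis; replay is quantified per test trial by the
Spearman rank correlation ρ between cluster firing times (first peak of the
50 ms-smoothed pooled rate in the 500 ms post-cue window) and cluster
positions.  Training strengthens forward (A→B…) and weakens backward
connections between clusters — a stripe-like connectivity that biases
cue-evoked and spontaneous activity toward the trained order, decaying again
within minutes once training stops.

It is a tool for computational neuroscientists who want to simulate the
model at full or reduced scale, rerun the training/testing protocol and its
variants, or reuse the replay analyses on their own spike data.

## Worked example

```python
from lifsorn import Network, LifSornParams
from lifsorn.analysis import firing_rates, mean_psp_amplitudes

net = Network(LifSornParams(), seed=7)        # full-size network
times, ids = net.run(150.0)                   # 150 s, membrane noise only
rates = firing_rates(times, ids, net.n_exc, 100e3, 150e3)
print(f"mean excitatory rate: {rates.mean():.2f} Hz")
print(f"E->E connection fraction: {net.connection_fraction:.3f}")
print(f"mean EPSP: {mean_psp_amplitudes(net)['EE']:.2f} mV")
```

prints (seed 7, ~40 s wall time):

```
mean excitatory rate: 2.99 Hz
E->E connection fraction: 0.108
mean EPSP: 0.62 mV
```

The 2.99 Hz is the intrinsic-plasticity target: every excitatory threshold
adapts until its neuron fires at 3 Hz, so the population mean lands on the
target once the ~100 s transient has passed.  The connection fraction has
self-organized from an initially unconnected excitatory population to its
growth/pruning equilibrium near 0.1, and converting the equilibrated weights
to postsynaptic-potential amplitudes gives sub-millivolt EPSPs, in the
physiological range.

A full experiment (growth → test → train → test) and its analyses:

```python
from lifsorn import run_experiment, standard_plan
from lifsorn.analysis import replay_trials, trial_rhos, shift_test

res = run_experiment(LifSornParams(), standard_plan(cue="start"), seed=1)
r1 = trial_rhos(replay_trials(res.spikes, res.clusters,
                              res.trial_onsets["test1"], "test1"))
r2 = trial_rhos(replay_trials(res.spikes, res.clusters,
                              res.trial_onsets["test2"], "test2"))
print(shift_test(r1, r2))   # (delta mean rho, KS statistic, p value)
```

There is also a thin CLI: `lifsorn grow`, `lifsorn run --experiment
{main,midcue,goalcue,spont,persist,shifted,bar,flash}`, `lifsorn analyze`.
Reduced desk-scale networks for experimentation come from
`lifsorn.fixtures.make_mini_network`.

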