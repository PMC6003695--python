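# Methods

## The model

`lifsorn` simulates a self-organizing recurrent network of leaky
integrate-and-fire (LIF) neurons modelling a small patch of layer 5 of rodent
visual cortex: N^E = 1000 excitatory and N^I = 200 inhibitory neurons
scattered uniformly on a 2500 um x 1000 um sheet.  The membrane potential of
neuron n follows

    dV/dt = -(V - E_L)/tau - (g_e + g_ext)(V - E_e)/tau - g_i (V - E_i)/tau + noise

with E_L = -60 mV, tau = 20 ms, E_e = 0 mV, E_i = -80 mV.  The conductances
are dimensionless and decay exponentially (tau_e = 3 ms for recurrent
excitatory and external input, tau_i = 5 ms for inhibitory input); presynaptic
spikes increment the conductance of the target after a class-specific axonal
delay (E->E 3 ms, E->I 1 ms, I->E and I->I 2 ms).  A spike is emitted when V
crosses the threshold (fixed -48 mV for inhibitory neurons, plastic for
excitatory ones); V then resets (-70 mV excitatory, -60 mV inhibitory) and the
neuron is clamped for an absolute refractory period of 5 ms.  The refractory
duration is a modelling choice; the default is 5 ms (the predecessor
model's value) and it is config-exposed.

The membrane noise is an additive Gaussian increment per timestep,
`sigma * sqrt(2 dt / tau) * N(0,1)` with sigma = 16 mV, which makes sigma the
stationary standard deviation of the free membrane potential (the
Ornstein-Uhlenbeck reading of the noise term).  With the fixed -48 mV
threshold this puts the free inhibitory firing rate near 6 Hz, consistent
with inhibitory neurons firing at roughly twice the excitatory 3 Hz target.

Connections involving inhibitory neurons are fixed: pairs are chosen without
replacement with probability proportional to a Gaussian kernel of the
distance (sigma_c = 200 um, the same length scale the structural
plasticity uses), at connection fractions
0.1 (E->I, I->E) and 0.5 of reciprocal I<->I pairs, with weights 0.15 (E->I)
and 0.4 (inhibitory).  Each class is normalized once at build time so each
neuron's summed incoming weight of that class equals
`fraction * N_pre * class_weight * boundary_factor(position)`.

## Plasticity

Recurrent excitatory (E->E) synapses start absent and are shaped online by
five mechanisms:

* **STP** — per presynaptic neuron, facilitation u (rest U = 0.04, tau_f =
  2 s) and depression x (rest 1, tau_d = 0.5 s).  The transmitted weight at
  spike arrival is `W * u(t-) * x(t-)`; then u += U(1-u), x -= x u.
* **STDP** — asymmetric exponential window, A+ = 4.8e-2 (tau+ = 15 ms),
  A- = -2.4e-2 (tau- = 30 ms), zero at zero lag, lag measured between the
  postsynaptic spike and the presynaptic *arrival* (spike + 3 ms).  Pairing
  is nearest-neighbour: each event pairs with the most recent opposite event;
  same-timestep pairs contribute nothing but still update the pairing
  memories.  Weights are floored at 0 after every depression event.
* **SN** — once per second each excitatory neuron's incoming E->E weights are
  rescaled to sum to `0.1 * N^E * 0.8 * boundary_factor(position)`.  The
  boundary factor is the mass of a unit 2D Gaussian (sigma_c) centred at the
  neuron inside the sheet rectangle (closed form via Gaussian CDFs); it
  prevents corner-seeded activity waves.
* **SP** — once per second, `max(0, round(N(6000, 6000)))` insertion attempts
  at candidate ordered pairs drawn without replacement from the Gaussian
  distance kernel over *all* pairs; draws landing on existing synapses are
  discarded, and survivors are inserted at weight 1e-3.  Because the total
  kernel mass is about 0.1 * (N^E)^2, insertion self-throttles as local
  neighbourhoods fill up and the connection fraction equilibrates near 0.1
  (measured plateau ~0.12 at full size).  Pruning then removes every synapse
  with weight strictly below 1e-4.  On the reduced fixtures the growth
  mean/sd scale by (N^E/1000)^2, which preserves the per-pair rates and hence
  the equilibrium.
* **IP** — every timestep, every excitatory threshold moves by
  `eta * (N_spikes - h)` with eta = 0.1 mV and h = 3 Hz * dt, pinning each
  neuron's long-run rate at 3 Hz.

Order within a step: integrate, decay, detect spikes/reset, deliver due
spikes (with STP factors and STDP depression), potentiate, IP.  Once per
simulated second (free-running from t = 0): SP growth, SP pruning, then SN,
so newborn synapses are normalized immediately.

## Numerics

Forward Euler at dt = 0.1 ms; conductances and STP variables decay by exact
exponential factors for stability.  The integration loop is JIT-compiled
(numba); two exact algebraic shortcuts keep it cheap: STP decay is applied
lazily at arrival events (closed form), and the constant IP drain is carried
as a scalar threshold offset folded back at block ends.  The membrane noise
field is pregenerated per one-second block with a dedicated numpy generator;
connectivity, structural plasticity and stimulus Poisson draws each have
their own stream, so a run is a pure, bit-reproducible function of
(parameters, seed).  Spike delivery uses a ring buffer indexed by timestep;
delays land exactly `delay/dt` steps after emission.

Initial excitatory thresholds are drawn uniformly in [-58, -48] mV; IP
erases the choice within tens of seconds, and all equilibrium readouts use late time windows.

## Stimulation and recording

The moving-spot drive is a super-Gaussian rate field
`r = 50 Hz * exp(-(d/alpha)^beta)` (alpha = 150 um, beta = 4) centred on a
point sweeping from (375, 500) um to (2125, 500) um at v_spot = 4 um/ms;
cues are 100 ms stationary flashes of the same spot.  Each excitatory neuron
receives 100 Poisson trains at its local rate, generated as per-step Poisson
counts of the superposed trains (identical in law, train identity is
unobservable); every input spike adds W_FF = 0.04 to g_ext.  The spatial profile of the bar-flash
training variant is a modelling choice: it uses the spot's cross-section
applied to the distance from the start-goal segment (perpendicular inside
the span, endpoint distance beyond), flashed for 100 ms.

Recording is abstracted as eight disjoint circles (radius 100 um) placed
equidistantly on the start-goal line with the outer circles touching the
endpoints; replay metrics act on pooled cluster spikes.  Cluster rates are
spikes convolved with a unit-mass Gaussian (tau_rate = 50 ms) on a 1 ms grid
(peak-time error <= 0.5 ms, negligible against tau_rate); a cluster's firing
time in a trial is the first strict local maximum in the 0-500 ms post-cue
window, plateaus resolved to midpoints, missing if the curve is monotone.
The replay score of a trial is the Spearman rank correlation between firing
times and cluster positions on the start->goal axis (goal->start for goal
cues); clusters without a firing time are dropped, trials with fewer than two
firing clusters carry no score.  Cross-correlograms of pooled cluster trains
use 10 ms bins and +-250 ms lags (both configurable).  Spontaneous-activity transition matrices count, over the
time-ordered sequence of all cluster rate maxima, how often cluster j peaks
directly after cluster i, normalized by i's appearances as a source (so rows
with at least one outgoing event sum to one).

Adjacent-cluster connectivity is summarized as the mean weight over all
*possible* ordered connections between neighbouring clusters (absent
connections count as zero), forward (i -> i+1) and backward (i+1 -> i)
averaged over the seven adjacent pairs.  Normalizing by possible rather
than existing connections includes the structural component of the training
effect and is robust to synapse turnover in small clusters —
per-existing-synapse means jump discontinuously when a sparse cluster pair
gains or loses a synapse.

## Experiment protocol

The main experiment: 400 s growth under noise, 100 s test (50 cue flashes,
one per 2 s), 10 s relaxation, 200 s training (100 sweeps, one per 2 s),
10 s relaxation, 100 s test with the same cue.  Variants: cue at the mid or
goal point; no test stimulus at all (spontaneous activity); tripled final
test phase (persistence); training by bar flash, stationary flash, or a
sweep shifted orthogonally off the cluster axis.  Test phases before and
after training use independent stimulus randomness.

## Desk-scale study conditions

The replay experiments in the test suite run on a geometry-scaled fixture
chosen once: scale factor 0.4 (sheet 1000 x 400 um; sigma_c, alpha, cluster
radius and the start/goal points scale with it), v_spot scaled by the same
factor so the sweep duration and all inter-cluster time lags are preserved,
N^E = 400 / N^I = 80 (2.5x the full areal density so each recording circle
holds ~5 neurons — enough pooled spikes for rate curves), SP growth scaled by
(N^E/1000)^2.  Phases: growth 300 s (the connection fraction is stationary
well before that), tests 100 s / 50 trials, training 200 s / 100 sweeps as at
full scale.  Several conditions branch off one grown state per seed with
independently reseeded dynamical randomness.

What the fixture preserves: the asynchronous-irregular regime, the 3 Hz IP
target, the connection-fraction equilibrium, all time constants and lags, and
the direction of the training effect on connectivity.  What it does not
preserve: statistical power for the replay-score shift.  At full scale the shift is
small, ~+0.04 in the replay score pooled over ~1000 trials; with five-neuron clusters the
cue-evoked drive between neighbouring clusters is ~2.5x weaker and the desk
runs pool only 150 trials, so the replay-score change is dominated by trial
noise even when the connectivity substrate of the effect (forward weights up,
backward weights down) is unambiguous.  Passing desk-scale tests therefore
demonstrate the mechanism and its direction, not the full-scale effect size.
For the same reason the desk-scale recall-speed and match analyses use a
replay-score threshold of 0.6 where the full-scale analysis uses 0.9: with
~5-neuron clusters no trial reaches 0.9, and 0.6 is the match threshold
the persistence analysis itself uses.

## Known limitations

* The weight-to-PSP conversion is the closed-form peak of the membrane response linearized at
  rest, `w (E_rev - E_L) (ts/(tau-ts)) [(tau/ts)^(-ts/(tau-ts)) -
  (tau/ts)^(-tau/(tau-ts))]`, with excitatory weights taken at their mean
  effective amplitude for a spike evoked at a random time (bare weight times
  the population-mean STP factor u*x in the stationary state, ~0.17 at 3 Hz;
  conditioning on the presynaptic neuron's own spike times instead gives
  ~0.14 because bursts oversample depression).  Reported mean amplitudes
  depend on the realized equilibrium mean weight and therefore inherit the
  ~20% connection-fraction overshoot.
* Inhibitory-involving synapses are static by construction; no dendritic
  structure; delays are class-homogeneous and purely axonal.
* The I->E and I->I delays must be equal (they are, at 2 ms); the kernel
  merges both classes into one delivery structure.
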