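# neuroarena

A hardware-free simulator of classical (fear) conditioning in a
neuromorphic mobile agent.  A virtual robot explores a 2.6 m-diameter
circular open-field arena whose wall is partly painted red and whose floor
carries road-bumper strips.  Crossing a bumper produces a vertical
acceleration transient ≥ 5 m/s² — an innately aversive unconditioned
stimulus (US).  The red wall is a neutral conditioned stimulus (CS).  A
19-neuron spiking network with Hebbian plasticity learns the CS→US
association, after which the sight of red alone evokes avoidance, exactly
as a conditioned rodent avoids a cue-marked quadrant.

The package is aimed at computational-neuroscience and neurorobotics work
that wants the whole conditioning loop — spiking sensory encoding,
plasticity, and embodied behaviour — on a desk, with no ROS, Gazebo or
robot hardware.

## The model

**Neurons.** All 19 units are leaky integrate-and-fire (LIF):

τ_m dV/dt = −(V − V_reset) + R·I(t),

integrated by explicit Euler at a 1 ms step in normalized units
(V_reset = 0, V_th = 1); a spike resets V and starts an absolute
refractory period.  Nine CS neurons (τ_m = 50 ms) encode per-region red
pixel rates, one US neuron (τ_m = 20 ms) encodes vibration magnitude, and
nine associative neurons (τ_m = 20 ms) integrate both channels.

**Encoding.** The accelerometer stream is collapsed to
a = √(aₓ² + a_y² + (a_z − g)²), low-pass filtered (τ = 0.2 s), smoothed
by a moving average and normalized to [0, 1]; the US gain is calibrated so
a sustained 5 m/s² is exactly suprathreshold.  Camera images are split
3×3; each region's red-pixel rate is gated at 0.4 and drives its CS
neuron (population coding).

**Plasticity.** Associative neuron *i* is driven by
w_CS[i]·x_i + w_US[i]·u, with x, u exponential spike traces (τ = 20 ms).
US weights start in [0.8, 1.0] (innate reflex), CS weights in
[0.01, 0.05] (initially silent channel).  When a CS neuron and the US
neuron are co-active, Oja's rule

Δw = η·y·(x − y·w)

raises w_CS toward the self-normalized fixed point x/y.  A non-spiking
output unit fires when the associative layer's windowed spike count
crosses a threshold and drives the avoidance behaviour.

**Spatial cells.** Grid cells fire on a hexagonal lattice (spacing *s*,
orientation θ, phase φ) with rate 1/2 − arctan(κ(d/s − ζ))/π, where *d*
is the distance to the nearest lattice vertex; place cells are
thresholded sums over a grid-cell bank with a Gaussian landmark-match
term.  These supply the cognitive-map side of the model and the
firing-field maps.

**Protocol.** Conditioning runs in four phases — US alone, CS alone,
paired CS+US bouts, CS alone — and behaviour is evaluated in baseline
(naive), post-learning (frozen weights) and probe (US channel disabled)
arena trials.  Learning accuracy is the fraction of non-bumper trajectory
points per 3-s interval.

## Worked example

Condition a network and probe it with the colour cue alone:

```bash
$ neuroarena condition --seed 1 --out out/
{
  "final_mean_w_cs": 0.6270793552064169,
  "cs_only_probe_output_spikes": 984
}
```

The CS weights rose from ~0.03 to ~0.63 — past the 0.5 activation
threshold — so a 1-s red-only presentation now fires the output on 984 of
1,000 ms (a conditioned response; a naive network yields 0).  The
per-step weight/spike trace lands in `out/learning_trace.csv`.

Run a naive (unconditioned) 60-s arena trial:

```bash
$ neuroarena run-trial --seed 1 --duration 60 --out out/
{
  "seed": 1,
  "duration_s": 60.0,
  "collisions": 8,
  "wall_contacts": 1,
  "path_length_m": 9.951272705510934,
  "phase": "trial"
}
```

The naive agent crosses the bumper strips 8 times in a minute because red
means nothing to it yet.  `neuroarena run-experiment post_learning`
repeats this with frozen post-conditioning weights (collisions drop to
zero in the default configuration), and `neuroarena replicate-tables`
emits the full baseline / post-learning / probe comparison as CSV + JSON.
`neuroarena firing-map --preset unit` writes a grid-cell firing map over
the arena disc.

## Layout

- `src/neuroarena/snn_core.py` — LIF dynamics, spike trains
- `src/neuroarena/sensory_encoding.py` — accelerometer/camera → currents
- `src/neuroarena/spatial_cells.py` — grid/place-cell models, rate maps
- `src/neuroarena/associative_net.py` — 19-neuron network, Oja rule,
  conditioning protocol
- `src/neuroarena/arena_sim.py` — arena geometry, synthetic sensors,
  movement logic, closed-loop trials
- `src/neuroarena/experiments.py` — metrics and batch runners
- `src/neuroarena/cli.py` — `neuroarena` command
- `docs/methods.md` — modelling choices, parameters and limitations
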