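# Methods

This note records the model as implemented, the parameter choices that
matter, what the synthetic arena does and does not emulate, and the
numerical conventions a maintainer needs.

## Neuron model

All spiking units are leaky integrate-and-fire neurons,
τ_m dV/dt = −(V − V_reset) + R·I(t), advanced by explicit Euler at
dt = 1 ms; an exact exponential update is available
(`LIFParams(exact=True)`) and is used by the convergence tests.  A spike
occurs on V ≥ V_th (ties spike — a deterministic tie-break), resets V to
V_reset and clamps it there for the refractory period.  Internally the
potential scale is normalized (V_reset = 0, V_th = 1); the affine map
v_mV = −65 + 15·v recovers a conventional −65 mV rest / −50 mV threshold
pair.  Working in normalized units removes the unit clashes that arise
when different sensory populations are specified partly in millivolts and
partly in arbitrary units, while preserving every time constant.

Per-population presets:

| population   | τ_m    | t_ref | rationale |
|--------------|--------|-------|-----------|
| vibration US | 20 ms  | 2 ms  | fast response to transient bumps |
| visual CS    | 50 ms  | 2 ms  | slow integration; brief red flashes do not spike |
| associative  | 20 ms  | 1 ms  | cortical-like response layer |

With dt = 1 ms the refractory clamp quantizes to whole steps, so the
effective refractory period is up to one step longer than nominal; the
interspike-interval tests account for this.

## Sensory encoding and threshold calibration

The US channel computes a = √(aₓ² + a_y² + (a_z − g)²) with g = 9.81
m/s², applies a first-order low-pass with τ_lp = 0.2 s (the nominal 5 Hz
cutoff is kept as documentation; first-order theory would give ≈ 0.032 s
for 5 Hz, but 0.2 s is the stated constant and is what the filter uses),
then a causal moving average (default 5 samples) and a fixed
normalization ceiling of 10 m/s².  The ceiling is fixed rather than
run-relative so that threshold semantics do not depend on history.

The innate danger threshold is 5 m/s².  A LIF neuron whose steady-state
potential for the 5 m/s² current sat exactly at threshold would approach
threshold exponentially and never cross it, so the US gain carries a 1%
margin: r_m = (V_th / 0.5)·1.01 = 2.02.  A sustained 5 m/s² then crosses
threshold in ≈ τ_m·ln(1.01/0.01) ≈ 92 ms, while any sustained magnitude
below ≈ 4.95 m/s² never spikes.  The CS gain is calibrated the same way
against the 0.4 red-rate gate (r_m = 2.525), so every rate that passes
the gate eventually drives its neuron.

A camera image is partitioned into a 3×3 grid of near-equal rectangles,
row-major from the top-left.  A pixel is "red" iff R ≥ 150, R ≥ 2G and
R ≥ 2B on 8-bit channels — a deterministic rule; the arena simulator
emits pure red, so any sensible rule agrees.  The 0.4 gate is applied to
the normalized rates and passes values unchanged (it is idempotent).

## Spatial cells

A grid cell (s, θ, φ, κ, ζ) fires on the hexagonal lattice generated by
basis vectors of length s at angles θ and θ + π/3, anchored at the phase
origin (the world point whose grid-frame coordinates vanish; the
grid-frame map is Mᵀp − φ with M the basis matrix, implemented exactly
as written even though other transpose conventions exist — it is an
oblique-basis change of coordinates).  With d the distance to the nearest
lattice vertex, rate = 1/2 − arctan(κ(d/s − ζ))/π, which is bounded in
(0, 1), peaks at vertices, and is strictly decreasing in d.  The
arctangent-of-distance reading was chosen over a three-grating
interference construction because it is directly testable (periodicity,
six neighbours at distance s, monotonicity) and produces the same
hexagonal fields; the single "preferred location" of a grid cell is
taken as the nearest lattice vertex, since a single point cannot produce
a multi-peaked field.  Preset `unit` (s = 1 m, θ = π/4, φ = (0.5, 0),
κ = 0.5, ζ = 0) is the desk-scale demonstration cell; preset `nav`
(s = 8.8, θ = π/4, φ = (0.5, 1.2), κ = 5, ζ = 0.3) is the coarse cell
used by the navigation stack, its spacing stored as given (its units are
unspecified upstream).

Place cells are binary threshold units over a grid-cell bank (ties
active), with an optional landmark response
Σ exp(−Δd²/σ_d² − Δθ²/σ_θ²); angle differences are wrapped into
(−π, π].

## Associative network

Nine CS sensory + one US sensory + nine associative spiking neurons — 19
spiking units, the only accounting consistent with the model's headline
count — plus one non-spiking output aggregator.  Associative neuron i
receives w_CS[i]·x_i + w_US[i]·u where x_i, u are exponential spike
traces (jump to 1 on a spike, decay with τ = 20 ms).  Traces rather than
raw binary spikes make the Oja product y·w well-scaled; they are the
standard rate-like realization of a Hebbian rule in spiking networks.
The associative gain (r_m = 4) makes a single US spike at the minimum
initial weight (0.8) suprathreshold (peak response R·w/e ≈ 1.18), while
the maximum initial CS drive (0.05·4 = 0.2) stays far below threshold:
vibration alone fires the network from the start, red alone cannot.

Plasticity is localist: whenever CS trace i and the US trace are both
above a coincidence threshold of 0.2 (both neurons spiked within roughly
two trace time constants), w_CS[i] ← w_CS[i] + η·y·(x − y·w), with y the
associative neuron's trace.  Same-millisecond binary coincidence was
rejected because deterministic spike trains make it a phase accident.
Weights are floored at 0; Oja's subtractive term bounds growth near the
x/y activity ratio (~0.63 under the default stimulus, comfortably above
the 0.5 activation threshold).

η defaults to 0.01 (the value used for the behavioural experiments);
`ETA_PRESETS["slow"] = 1e-4` gives the conservative deployment rate at
which conditioning needs many more pairing bouts.  The output aggregator
fires when the associative layer produces ≥ 1 spike within a 50 ms
window (one motion step); both the threshold and the window are
configuration knobs, since only their existence — not their values — is
constrained by the model description.

The four-phase protocol presents US alone (1 s), CS alone (1 s), a
number of 0.5-s CS+US pairing bouts separated by 0.25-s gaps, and CS
alone (1 s).  Learning is enabled only in phases presenting both
stimuli.  Dynamic state (traces, output window) settles between phases so
one phase's activity cannot leak into the next; membrane potentials decay
naturally.  The desk stimulus generator drives all nine regions at a red
rate of 0.8 (wall filling the view) and the US at 0.6 normalized
(a 6 m/s² bumper plateau) — the plateau the arena's bumpers produce.

## Arena

A disc of radius 1.3 m.  The red arc defaults to the north quadrant
(π/4..3π/4).  Three bumper strips (0.45 × 0.4 m) sit in front of the red
wall, centred 1.0 m from the arena centre, so that wall-following paths
through the red quadrant cross them; baseline (naive) agents collide
with them several times per minute, matching the reflex-only behaviour
the learning experiment starts from.

Sensors per 50 ms motion step: a 270° scanner (91 beams, exact
ray–circle intersection); a pinhole camera with 90° horizontal field of
view collapsed to 3 columns × 3 rows, where a column's red fraction is
its angular overlap with the red arc (sampled by 12 rays/column) and rows
are weighted uniformly — the simplest geometry with the one property the
loop needs, "red fills more of the view as the wall nears"; an IMU
magnitude channel reading a deterministic 6 m/s² plateau on bumper
overlap and |N(0, 0.1)| noise otherwise.  Vibration pre-processing runs
online at the motion rate, which delays US onset by ~0.4 s after bumper
entry — comparable to a real filtered IMU pipeline.

Movement priority: (1) learned avoidance — back away at 0.2 m/s steering
away from the red arc until red leaves the view; (2) vibration reflex —
stop and rotate at 1.5 rad/s for 2 s (direction drawn once per event);
(3) boundary avoidance — when a wall is within 0.3 m of the forward
sector, steer toward the furthest scan bearing at half speed;
(4) otherwise forward at 0.2 m/s with angular jitter uniform in
±0.3 rad/s.  Vibration is prioritized over boundary handling when both
occur.  The pose integrates unicycle kinematics and is clamped inside the
disc.  The network runs 50 one-millisecond substeps per motion step on
zero-order-held currents.

Collisions are rising-edge entries of the 0.1 m footprint into a bumper
zone, debounced at 0.5 s.  A red-wall "contact" (probe metric) is the
footprint coming within 0.2 m of the wall inside the red arc — 0.1 m
footprint plus 0.1 m proximity.

## Metrics and experiment scale

Learning accuracy is computed per whole 3-s interval as the fraction of
logged poses (the 50 ms trajectory log is the natural discretization of
"points") outside all bumper zones; a trailing partial interval is
dropped.  Trial success means zero debounced collision events; wall
grazes do not count.  Trials-to-criterion is the first index of two
consecutive collision-free trials.  Batch summaries report mean, SD and a
t-distribution 95% CI (n−1 df; appropriate at n = 10).

Default replication scale is 10–20 trials × 60 s with seeds 1..n, chosen
to mirror a ten-trial behavioural study while completing in minutes on
one core.  The acceptance script (`scripts/acceptance.py`) conditions a
network, freezes weights, and recomputes the post-learning success rate
(20 trials), the probe red-wall avoidance rate (20 US-disabled trials)
and the mean final-interval accuracy (10 trials), all seeded from its
`--seed` argument.

## What the simulation does and does not show

The synthetic arena reproduces the geometry, stimulus contingencies and
timing of the conditioning experiment, so passing tests demonstrate that
the network acquires, retains and behaviourally expresses the CS→US
association under the stated protocol.  It does not emulate camera
noise, lighting, colour-space variation, wheel slip, IMU drift, or
LiDAR artefacts; real-world success rates would be bounded above by the
simulated ones.  Extinction (weight decay under unreinforced CS) is out
of scope — no decay rule is defined, so retention is trivially perfect.
The vibration channel uses only the gravity-compensated magnitude;
lateral-axis fusion is deliberately omitted (lateral accelerations carry
little information about the bumps being detected).  The grid/place-cell
module informs firing-field analyses and is exercised by its own tests;
the avoidance behaviour itself is driven by the associative network, not
by the cognitive map.

## Numerical conventions

- Threshold comparisons (spike, gate, place-cell activation) treat ties
  as crossings.
- Angles wrap into (−π, π]; the red-arc membership test works on wrapped
  offsets so arcs crossing ±π behave correctly.
- The moving average uses a causal shrinking window at the start (no
  lookahead, length-preserving).
- All stochastic components (weight init, sensor noise, motion jitter,
  rotation direction) draw from `numpy.random.default_rng` seeded per
  trial; trials are bit-reproducible.
- Empty input series are legal and yield empty outputs; non-finite
  currents are rejected with the offending timestep named.
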