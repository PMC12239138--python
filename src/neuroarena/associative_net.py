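"""The 19-neuron associative (classical-conditioning) network.

Architecture: nine CS sensory neurons (one per camera region), one US
sensory neuron (vibration), and nine associative neurons — 19 spiking
units — plus a non-spiking output aggregator.  Associative neuron ``i``
is driven by ``w_cs[i] * cs_trace[i] + w_us[i] * us_trace`` where the
traces are exponentially smoothed spike indicators (tau = 20 ms): a spike
sets the trace to 1 and it decays between spikes.  US weights start high
(0.8-1.0) so vibration alone fires the network; CS weights start low
(0.01-0.05) so red alone is initially silent.

Plasticity follows Oja's rule,

    dw = eta * y * (x - y * w),

applied per region whenever the region's CS neuron and the US neuron are
co-active (both spike traces above a coincidence threshold), with
``x`` the CS trace and ``y`` the associative neuron's trace.  The
subtractive term self-normalizes the weights, which converge toward the
x/y activity ratio.

Conditioning runs in four phases: US alone (reflex baseline), CS alone
(no response — baseline check), paired CS+US (weights grow), CS alone
(probe: the learned response fires on red alone).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from . import sensory_encoding as enc
from . import snn_core

__all__ = [
    "NetworkConfig",
    "NetworkState",
    "Phase",
    "ConditioningSchedule",
    "LearningTrace",
    "build_network",
    "oja_update",
    "network_step",
    "run_conditioning",
    "response_decision",
    "four_phase_schedule",
    "default_stimulus",
    "cs_only_probe",
    "pairings_to_acquisition",
    "condition_network",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Network parameterization.

    n_regions : CS channel count (camera regions).
    w_us_init_range, w_cs_init_range : uniform initialization intervals.
    eta : Oja learning rate per 1 ms step (preset "slow" = 1e-4 mirrors a
        conservative deployment; the default 0.01 completes conditioning
        within the 10-15-pairing budget).
    theta_activation : CS weight level regarded as a learned response.
    output_threshold : associative spikes within ``output_window`` needed
        for the output aggregator to fire.
    output_window : aggregation window, s.
    tau_trace : spike-trace time constant, s (also Oja's x/y smoothing).
    coact_threshold : both CS and US traces must exceed this for a
        pairing event (spikes within ~2 trace time constants).
    gain_* : membrane gains (r_m) per population; US and CS gains realize
        the 5 m/s^2 and 0.4-red-rate thresholds (see sensory_encoding).
    """

    n_regions: int = 9
    w_us_init_range: tuple[float, float] = (0.8, 1.0)
    w_cs_init_range: tuple[float, float] = (0.01, 0.05)
    eta: float = 0.01
    theta_activation: float = 0.5
    output_threshold: int = 1
    output_window: float = 0.05
    tau_trace: float = 0.02
    coact_threshold: float = 0.2
    gain_assoc: float = 4.0
    theta_cs: float = 0.4
    dt: float = 0.001
    seed: int = 0
    filter_cfg: enc.FilterConfig = field(default_factory=enc.FilterConfig)

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        for name, (lo, hi) in (
            ("w_us_init_range", self.w_us_init_range),
            ("w_cs_init_range", self.w_cs_init_range),
        ):
            if not (0.0 <= lo < hi <= 1.0):
                raise ValueError(f"{name} must satisfy 0 <= low < high <= 1")
        if not self.eta > 0:
            raise ValueError("eta must be positive")

    @property
    def cs_params(self) -> snn_core.LIFParams:
        return replace(
            snn_core.PRESETS["visual"], dt=self.dt,
            r_m=enc.cs_gain(self.theta_cs),
        )

    @property
    def us_params(self) -> snn_core.LIFParams:
        return replace(
            snn_core.PRESETS["vibration"], dt=self.dt,
            r_m=enc.us_gain(self.filter_cfg),
        )

    @property
    def assoc_params(self) -> snn_core.LIFParams:
        return replace(
            snn_core.PRESETS["associative"], dt=self.dt, r_m=self.gain_assoc
        )

    @property
    def window_steps(self) -> int:
        return max(1, int(round(self.output_window / self.dt)))


#: Named learning-rate presets.
ETA_PRESETS = {"default": 0.01, "slow": 1e-4}


@dataclass
class NetworkState:
    """Weights, per-neuron membrane states and smoothed spike traces."""

    w_us: np.ndarray
    w_cs: np.ndarray
    v_cs: np.ndarray
    ref_cs: np.ndarray
    v_us: np.ndarray
    ref_us: np.ndarray
    v_assoc: np.ndarray
    ref_assoc: np.ndarray
    cs_trace: np.ndarray
    us_trace: float
    assoc_trace: np.ndarray
    assoc_spike_window: np.ndarray  # ring buffer of per-step spike counts
    window_pos: int
    output_activity: float = 0.0
    # spike flags from the most recent step (diagnostics / traces)
    cs_spiked: np.ndarray = None
    us_spiked: bool = False
    assoc_spiked: np.ndarray = None

    @property
    def n_spiking_neurons(self) -> int:
        """9 CS + 1 US + 9 associative spiking units."""
        return self.v_cs.size + self.v_us.size + self.v_assoc.size

    def copy(self) -> "NetworkState":
        return NetworkState(
            **{
                k: (v.copy() if isinstance(v, np.ndarray) else v)
                for k, v in self.__dict__.items()
            }
        )


def build_network(cfg: NetworkConfig) -> NetworkState:
    """Fresh network with seed-reproducible uniform weight initialization."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_regions
    return NetworkState(
        w_us=rng.uniform(*cfg.w_us_init_range, size=n),
        w_cs=rng.uniform(*cfg.w_cs_init_range, size=n),
        v_cs=np.zeros(n),
        ref_cs=np.zeros(n, dtype=int),
        v_us=np.zeros(1),
        ref_us=np.zeros(1, dtype=int),
        v_assoc=np.zeros(n),
        ref_assoc=np.zeros(n, dtype=int),
        cs_trace=np.zeros(n),
        us_trace=0.0,
        assoc_trace=np.zeros(n),
        assoc_spike_window=np.zeros(cfg.window_steps, dtype=int),
        window_pos=0,
        cs_spiked=np.zeros(n, dtype=bool),
        assoc_spiked=np.zeros(n, dtype=bool),
    )


def oja_update(w: float, x: float, y: float, eta: float) -> float:
    """One Oja-rule step: w + eta * y * (x - y * w)."""
    if not all(map(math.isfinite, (w, x, y, eta))):
        raise ValueError("oja_update requires finite inputs")
    return w + eta * y * (x - y * w)


def network_step(
    state: NetworkState,
    cs_currents: Sequence[float] | np.ndarray,
    us_current: float,
    learning_on: bool,
    cfg: NetworkConfig,
) -> tuple[NetworkState, bool]:
    """Advance the whole network by one neural step (``cfg.dt``).

    Mutates ``state`` in place and returns it along with the output
    aggregator's fired/silent flag for this step.
    """
    cs_currents = np.asarray(cs_currents, dtype=float)
    decay = math.exp(-cfg.dt / cfg.tau_trace)

    # sensory layer
    state.v_cs, state.ref_cs, cs_spiked = snn_core.lif_step_array(
        state.v_cs, state.ref_cs, cs_currents, cfg.cs_params
    )
    state.v_us, state.ref_us, us_spiked_a = snn_core.lif_step_array(
        state.v_us, state.ref_us, np.array([us_current]), cfg.us_params
    )
    us_spiked = bool(us_spiked_a[0])

    # spike traces: jump to 1 on a spike, exponential decay otherwise
    state.cs_trace = np.where(cs_spiked, 1.0, state.cs_trace * decay)
    state.us_trace = 1.0 if us_spiked else state.us_trace * decay

    # associative layer
    i_assoc = state.w_cs * state.cs_trace + state.w_us * state.us_trace
    state.v_assoc, state.ref_assoc, assoc_spiked = snn_core.lif_step_array(
        state.v_assoc, state.ref_assoc, i_assoc, cfg.assoc_params
    )
    state.assoc_trace = np.where(assoc_spiked, 1.0, state.assoc_trace * decay)

    # output aggregator: windowed associative spike count vs threshold
    state.assoc_spike_window[state.window_pos] = int(assoc_spiked.sum())
    state.window_pos = (state.window_pos + 1) % state.assoc_spike_window.size
    state.output_activity = float(state.assoc_spike_window.sum())
    output_spiked = state.output_activity >= cfg.output_threshold

    # localist Oja plasticity on CS/US co-activation
    if learning_on:
        co = (
            (state.cs_trace >= cfg.coact_threshold)
            & (state.us_trace >= cfg.coact_threshold)
        )
        if np.any(co):
            x = state.cs_trace[co]
            y = state.assoc_trace[co]
            w = state.w_cs[co]
            state.w_cs[co] = np.maximum(w + cfg.eta * y * (x - y * w), 0.0)

    state.cs_spiked = cs_spiked
    state.us_spiked = us_spiked
    state.assoc_spiked = assoc_spiked
    return state, bool(output_spiked)


def response_decision(
    output_spiked: bool, red_visible: bool, prev_action: str = "none"
) -> str:
    """Avoidance policy: avoid when the output fires, and keep avoiding
    until red has left the field of view."""
    if output_spiked:
        return "avoid"
    if prev_action == "avoid" and red_visible:
        return "avoid"
    return "none"


# -- conditioning protocol ---------------------------------------------------

@dataclass(frozen=True)
class Phase:
    """One protocol phase: which stimuli are presented, for how long."""

    stimuli: frozenset[str]
    duration: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("phase duration must be positive")
        unknown = self.stimuli - {"CS", "US"}
        if unknown:
            raise ValueError(f"unknown stimuli: {sorted(unknown)}")


@dataclass(frozen=True)
class ConditioningSchedule:
    phases: tuple[Phase, ...]

    @property
    def duration(self) -> float:
        return sum(p.duration for p in self.phases)


def four_phase_schedule(
    n_pairings: int = 15,
    pairing_s: float = 0.5,
    gap_s: float = 0.25,
    phase_s: float = 1.0,
) -> ConditioningSchedule:
    """US-only, CS-only, n paired CS+US bouts (gap-separated), CS-only."""
    phases = [Phase(frozenset({"US"}), phase_s, "us_only"),
              Phase(frozenset({"CS"}), phase_s, "cs_only_pre")]
    for k in range(n_pairings):
        phases.append(Phase(frozenset({"CS", "US"}), pairing_s,
                            f"pairing_{k + 1}"))
        if gap_s > 0 and k < n_pairings - 1:
            phases.append(Phase(frozenset(), gap_s, "gap"))
    phases.append(Phase(frozenset({"CS"}), phase_s, "cs_only_post"))
    return ConditioningSchedule(tuple(phases))


def default_stimulus(
    cfg: NetworkConfig,
    cs_level: float = 0.8,
    us_level: float = 0.6,
    active_regions: Iterable[int] | None = None,
) -> Callable[[Phase, int], tuple[np.ndarray, float]]:
    """Desk stimulus generator emulating the study conditions: the red
    wall filling the view drives the active regions at ``cs_level`` and
    a bumper strip drives the US channel at ``us_level`` (a 6 m/s^2
    plateau under the default 10 m/s^2 normalization ceiling)."""
    regions = (
        np.arange(cfg.n_regions)
        if active_regions is None
        else np.asarray(list(active_regions), dtype=int)
    )
    cs = np.zeros(cfg.n_regions)
    cs[regions] = cs_level

    def generate(phase: Phase, step: int) -> tuple[np.ndarray, float]:
        cs_cur = cs if "CS" in phase.stimuli else np.zeros(cfg.n_regions)
        us_cur = us_level if "US" in phase.stimuli else 0.0
        return cs_cur, us_cur

    return generate


@dataclass
class LearningTrace:
    """Per-step record of a conditioning run (CSV-exportable)."""

    dt: float
    time_s: list[float] = field(default_factory=list)
    phase: list[str] = field(default_factory=list)
    w_cs: list[np.ndarray] = field(default_factory=list)
    v_us: list[float] = field(default_factory=list)
    cs_spikes: list[int] = field(default_factory=list)
    us_spikes: list[int] = field(default_factory=list)
    assoc_spikes: list[int] = field(default_factory=list)
    output: list[int] = field(default_factory=list)

    def w_cs_array(self) -> np.ndarray:
        return np.asarray(self.w_cs)

    def phase_slice(self, label: str) -> np.ndarray:
        return np.array([p == label for p in self.phase])

    def output_spikes_in(self, label: str) -> int:
        mask = self.phase_slice(label)
        return int(np.asarray(self.output)[mask].sum())

    def to_frame(self) -> pd.DataFrame:
        w = self.w_cs_array()
        data = {
            "step": np.arange(len(self.time_s)),
            "time_s": self.time_s,
            "phase": self.phase,
            "v_us": self.v_us,
            "cs_spikes": self.cs_spikes,
            "us_spikes": self.us_spikes,
            "assoc_spikes": self.assoc_spikes,
            "output": self.output,
        }
        for r in range(w.shape[1] if w.size else 0):
            data[f"w_cs_{r + 1}"] = w[:, r]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_conditioning(
    state: NetworkState,
    schedule: ConditioningSchedule,
    stimulus: Callable[[Phase, int], tuple[np.ndarray, float]],
    cfg: NetworkConfig,
    record: bool = True,
) -> tuple[NetworkState, LearningTrace]:
    """Execute a schedule.  Learning is enabled only in phases presenting
    both CS and US (pairing phases)."""
    trace = LearningTrace(dt=cfg.dt)
    t = 0.0
    for phase in schedule.phases:
        # phases are separate stimulus presentations: spike traces and the
        # output window settle between them so one phase's activity cannot
        # bleed into the next through the 20 ms traces / 50 ms window
        state.cs_trace[:] = 0.0
        state.us_trace = 0.0
        state.assoc_trace[:] = 0.0
        state.assoc_spike_window[:] = 0
        n_steps = int(round(phase.duration / cfg.dt))
        learn = {"CS", "US"} <= phase.stimuli
        for k in range(n_steps):
            cs_cur, us_cur = stimulus(phase, k)
            state, out = network_step(state, cs_cur, us_cur, learn, cfg)
            if record:
                trace.time_s.append(t)
                trace.phase.append(phase.label)
                trace.w_cs.append(state.w_cs.copy())
                trace.v_us.append(float(state.v_us[0]))
                trace.cs_spikes.append(int(state.cs_spiked.sum()))
                trace.us_spikes.append(int(state.us_spiked))
                trace.assoc_spikes.append(int(state.assoc_spiked.sum()))
                trace.output.append(int(out))
            t += cfg.dt
    return state, trace


def cs_only_probe(
    state: NetworkState,
    cfg: NetworkConfig,
    duration: float = 1.0,
    cs_level: float = 0.8,
    active_regions: Iterable[int] | None = None,
) -> int:
    """Count output spikes during a CS-only presentation on a copy of the
    network (no learning, no state carry-over)."""
    probe_state = state.copy()
    # probe on a quiescent copy: clear dynamic state, keep weights
    probe_state.cs_trace[:] = 0.0
    probe_state.us_trace = 0.0
    probe_state.assoc_trace[:] = 0.0
    probe_state.assoc_spike_window[:] = 0
    schedule = ConditioningSchedule(
        (Phase(frozenset({"CS"}), duration, "probe"),)
    )
    stim = default_stimulus(cfg, cs_level=cs_level, us_level=0.0,
                            active_regions=active_regions)
    _, trace = run_conditioning(probe_state, schedule, stim, cfg)
    return trace.output_spikes_in("probe")


def pairings_to_acquisition(
    cfg: NetworkConfig,
    max_pairings: int = 30,
    pairing_s: float = 0.5,
    gap_s: float = 0.25,
) -> int | None:
    """Number of CS+US pairing bouts until a CS-only probe first evokes
    output spikes; None if not acquired within ``max_pairings``."""
    state = build_network(cfg)
    stim = default_stimulus(cfg)
    # reflex baseline and CS baseline
    pre = ConditioningSchedule(
        (Phase(frozenset({"US"}), 1.0, "us_only"),
         Phase(frozenset({"CS"}), 1.0, "cs_only_pre"))
    )
    state, _ = run_conditioning(state, pre, stim, cfg, record=False)
    pair = ConditioningSchedule(
        (Phase(frozenset({"CS", "US"}), pairing_s, "pairing"),
         Phase(frozenset(), max(gap_s, 1e-3), "gap"))
    )
    for k in range(1, max_pairings + 1):
        state, _ = run_conditioning(state, pair, stim, cfg, record=False)
        if cs_only_probe(state, cfg) > 0:
            return k
    return None


def condition_network(
    cfg: NetworkConfig,
    n_pairings: int = 15,
    record: bool = False,
) -> tuple[NetworkState, LearningTrace]:
    """Build and condition a network with the four-phase protocol;
    returns the trained state (weights then frozen by running trials with
    ``learning_on=False``)."""
    state = build_network(cfg)
    schedule = four_phase_schedule(n_pairings=n_pairings)
    return run_conditioning(state, schedule, default_stimulus(cfg), cfg,
                            record=record)
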