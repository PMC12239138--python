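"""Leaky integrate-and-fire (LIF) neuron dynamics on a fixed time grid.

The membrane potential obeys

    tau_m * dV/dt = -(V - V_reset) + R * I(t),

integrated by explicit Euler at a fixed step ``dt`` (an exact exponential
update is available for convergence checks).  A neuron spikes when
``V >= v_threshold`` (ties spike), resets to ``v_reset`` and is clamped
there for the refractory period ``t_ref``.

Potentials are expressed in normalized units: ``v_reset = 0`` and
``v_threshold = 1`` by default.  Each sensory population keeps its own time
constants; see :data:`PRESETS`.  An affine map v_mV = -65 + 15*v relates the
normalized scale to a conventional -65 mV rest / -50 mV threshold pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LIFParams",
    "LIFState",
    "SpikeTrain",
    "PRESETS",
    "lif_step",
    "lif_step_array",
    "simulate_neuron",
    "first_spike_time",
]


@dataclass(frozen=True)
class LIFParams:
    """Parameterization of one LIF population.

    Parameters
    ----------
    tau_m : float
        Membrane time constant in seconds.
    r_m : float
        Membrane resistance (dimensionless gain; input currents are
        pre-scaled to [0, 1] by the encoders).
    v_reset : float
        Reset/rest potential, normalized units.
    v_threshold : float
        Firing threshold, normalized units.  Must exceed ``v_reset``.
    t_ref : float
        Absolute refractory period in seconds.
    dt : float
        Integration step in seconds.  Must not exceed ``tau_m``.
    exact : bool
        If True, use the exact exponential update instead of explicit
        Euler (used by convergence tests; dynamics agree as dt -> 0).
    """

    tau_m: float = 0.02
    r_m: float = 1.0
    v_reset: float = 0.0
    v_threshold: float = 1.0
    t_ref: float = 0.002
    dt: float = 0.001
    exact: bool = False

    def __post_init__(self) -> None:
        if not self.tau_m > 0:
            raise ValueError(f"tau_m must be positive, got {self.tau_m}")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.dt > self.tau_m:
            raise ValueError(f"dt={self.dt} exceeds tau_m={self.tau_m}")
        if not self.v_threshold > self.v_reset:
            raise ValueError("v_threshold must exceed v_reset")
        if self.t_ref < 0:
            raise ValueError("t_ref must be non-negative")

    @property
    def ref_steps(self) -> int:
        """Number of whole steps a neuron is held refractory."""
        return math.ceil(self.t_ref / self.dt) if self.t_ref > 0 else 0


#: Per-population presets.  ``vibration``: fast US channel; ``visual``:
#: slower-integrating CS channels (transient red flashes do not spike);
#: ``associative``: cortical-like response layer (20 ms, 1 ms refractory).
PRESETS: dict[str, LIFParams] = {
    "vibration": LIFParams(tau_m=0.02, t_ref=0.002),
    "visual": LIFParams(tau_m=0.05, t_ref=0.002),
    "associative": LIFParams(tau_m=0.02, t_ref=0.001),
}


@dataclass
class LIFState:
    """Evolving state of a single neuron."""

    v: float = 0.0
    t_since_spike: float = math.inf
    in_refractory: bool = False

    def copy(self) -> "LIFState":
        return replace(self)


@dataclass
class SpikeTrain:
    """Spike record of one or more neurons on a shared time grid.

    ``spikes`` holds (step index, neuron id) pairs with step indices
    non-decreasing per neuron; consecutive spikes of one neuron are
    separated by at least ``ceil(t_ref / dt)`` steps.
    """

    dt: float
    spikes: list[tuple[int, int]] = field(default_factory=list)

    def append(self, step: int, neuron_id: int = 0) -> None:
        self.spikes.append((step, neuron_id))

    def steps(self, neuron_id: int = 0) -> np.ndarray:
        return np.array([s for s, n in self.spikes if n == neuron_id], dtype=int)

    def times(self, neuron_id: int = 0) -> np.ndarray:
        return self.steps(neuron_id) * self.dt

    def count(self, neuron_id: int | None = None) -> int:
        if neuron_id is None:
            return len(self.spikes)
        return int(sum(1 for _, n in self.spikes if n == neuron_id))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.spikes, columns=["step", "neuron_id"])
        df.insert(1, "time_s", df["step"] * self.dt)
        return df


def lif_step(
    state: LIFState, i_in: float, params: LIFParams
) -> tuple[LIFState, bool]:
    """Advance one neuron by one step of ``params.dt``.

    Returns the new state and whether the neuron spiked on this step.
    During the refractory period the potential is clamped at ``v_reset``
    and no spike can occur.  Non-finite input is rejected.
    """
    if not math.isfinite(i_in):
        raise ValueError(f"non-finite input current: {i_in!r}")

    t_since = state.t_since_spike + params.dt
    if state.t_since_spike < params.t_ref:
        return LIFState(params.v_reset, t_since, t_since < params.t_ref), False

    drive = params.r_m * i_in
    if params.exact:
        a = math.exp(-params.dt / params.tau_m)
        v = params.v_reset + (state.v - params.v_reset) * a + drive * (1.0 - a)
    else:
        v = state.v + (params.dt / params.tau_m) * (
            -(state.v - params.v_reset) + drive
        )
    if v >= params.v_threshold:
        return LIFState(params.v_reset, 0.0, params.t_ref > 0), True
    return LIFState(v, t_since, False), False


def lif_step_array(
    v: np.ndarray,
    ref_left: np.ndarray,
    i_in: np.ndarray,
    params: LIFParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Euler step for a homogeneous population.

    ``ref_left`` counts remaining refractory steps (int).  Returns
    ``(v, ref_left, spiked)``; semantics match :func:`lif_step`.
    Used by the associative network where per-object scalar states would
    dominate the runtime.
    """
    refractory = ref_left > 0
    drive = params.r_m * i_in
    if params.exact:
        a = math.exp(-params.dt / params.tau_m)
        v_new = params.v_reset + (v - params.v_reset) * a + drive * (1.0 - a)
    else:
        v_new = v + (params.dt / params.tau_m) * (-(v - params.v_reset) + drive)
    v_new = np.where(refractory, params.v_reset, v_new)
    spiked = (v_new >= params.v_threshold) & ~refractory
    v_new = np.where(spiked, params.v_reset, v_new)
    ref_left = np.where(
        spiked, params.ref_steps, np.maximum(ref_left - 1, 0)
    )
    return v_new, ref_left, spiked


def simulate_neuron(
    input_series: Sequence[float] | np.ndarray,
    params: LIFParams,
    initial: LIFState | None = None,
    neuron_id: int = 0,
) -> tuple[SpikeTrain, np.ndarray]:
    """Run one neuron over a current series; returns spikes and the
    potential trace (one entry per input sample, post-update)."""
    series = np.asarray(input_series, dtype=float)
    if series.size and not np.all(np.isfinite(series)):
        bad = int(np.flatnonzero(~np.isfinite(series))[0])
        raise ValueError(f"non-finite input current at timestep {bad}")
    state = initial.copy() if initial is not None else LIFState(v=params.v_reset)
    train = SpikeTrain(dt=params.dt)
    trace = np.empty(series.size, dtype=float)
    for k, i_in in enumerate(series):
        state, spiked = lif_step(state, float(i_in), params)
        trace[k] = state.v
        if spiked:
            train.append(k, neuron_id)
    return train, trace


def first_spike_time(params: LIFParams, i_const: float) -> float:
    """Closed-form first-threshold-crossing time for constant input from
    rest; ``inf`` if the steady state never reaches threshold.

    Independent of the stepped integrator: solves the membrane ODE
    analytically (used as an oracle against :func:`simulate_neuron`).
    """
    drive = params.r_m * i_const
    gap = params.v_threshold - params.v_reset
    if drive <= gap:
        return math.inf
    return params.tau_m * math.log(drive / (drive - gap))


def trace_to_frame(
    trace: np.ndarray, train: SpikeTrain, neuron_id: int = 0
) -> pd.DataFrame:
    """CSV-ready table: step, time_s, neuron_id, v, spike."""
    n = trace.size
    spike = np.zeros(n, dtype=int)
    steps = train.steps(neuron_id)
    spike[steps[steps < n]] = 1
    return pd.DataFrame(
        {
            "step": np.arange(n),
            "time_s": np.arange(n) * train.dt,
            "neuron_id": neuron_id,
            "v": trace,
            "spike": spike,
        }
    )
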