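"""Encoders turning raw sensor streams into normalized LIF input currents.

Vibration (US) channel: 3-axis accelerometer samples are collapsed to a
gravity-compensated magnitude

    a = sqrt(ax^2 + ay^2 + (az - g)^2),

low-pass filtered (first-order exponential, tau_lp), smoothed with a causal
moving average, and normalized by a fixed ceiling ``norm_max`` so the
currents live in [0, 1].  The US neuron's gain is calibrated so a sustained
magnitude of 5 m/s^2 — the innate danger threshold — is suprathreshold
while 4 m/s^2 is not (see :func:`us_gain`).

Visual (CS) channel: each camera image is split into a 3x3 grid of regions
(row-major from the top-left); per region the red-pixel rate is the
fraction of pixels classified red.  Rates below a 0.4 gate are zeroed so
only salient red patches drive the nine CS neurons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

G_STANDARD = 9.81  # m/s^2

__all__ = [
    "AccelSample",
    "FilterConfig",
    "VisualFrame",
    "vibration_magnitude",
    "lowpass",
    "moving_average",
    "normalize_vibration",
    "encode_vibration",
    "red_pixel_rates",
    "gate_cs",
    "us_gain",
    "cs_gain",
    "read_accel_csv",
    "read_visual_csv",
]


@dataclass(frozen=True)
class AccelSample:
    """One accelerometer reading: timestamp (s) and 3-axis acceleration
    in m/s^2 (gravity included in az when at rest)."""

    t: float
    ax: float
    ay: float
    az: float


@dataclass(frozen=True)
class FilterConfig:
    """Vibration pre-processing parameters.

    tau_lp : low-pass time constant, s.  The nominal 5 Hz cutoff is kept
        as documentation only (``cutoff_hz``); the filter is defined by
        ``tau_lp`` alone.
    n_window : causal moving-average length, samples.
    norm_max : fixed normalization ceiling, m/s^2.  Fixed (not running
        min-max) so the 5 m/s^2 threshold semantics are run-independent.
    """

    tau_lp: float = 0.2
    cutoff_hz: float = 5.0
    n_window: int = 5
    norm_max: float = 10.0

    def __post_init__(self) -> None:
        if not self.tau_lp > 0:
            raise ValueError("tau_lp must be positive")
        if self.n_window < 1:
            raise ValueError("n_window must be >= 1")
        if not self.norm_max > 0:
            raise ValueError("norm_max must be positive")


@dataclass(frozen=True)
class VisualFrame:
    """Nine per-region red-pixel rates in [0, 1], row-major 3x3."""

    t: float
    red_rates: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.red_rates) != 9:
            raise ValueError("red_rates must have exactly 9 entries")
        if any(not (0.0 <= r <= 1.0) for r in self.red_rates):
            raise ValueError("red_rates must lie in [0, 1]")


def vibration_magnitude(sample: AccelSample, g: float = G_STANDARD) -> float:
    """Gravity-compensated acceleration magnitude (m/s^2)."""
    if g <= 0:
        raise ValueError("g must be positive")
    vals = (sample.ax, sample.ay, sample.az)
    if not all(np.isfinite(vals)):
        raise ValueError(f"non-finite acceleration sample at t={sample.t}")
    return float(np.sqrt(sample.ax**2 + sample.ay**2 + (sample.az - g) ** 2))


def lowpass(
    series: Sequence[float] | np.ndarray, cfg: FilterConfig, dt: float
) -> np.ndarray:
    """First-order exponential low-pass with time constant ``cfg.tau_lp``.

    Discrete-exact recursion y[k] = a*y[k-1] + (1-a)*x[k], a = exp(-dt/tau);
    DC gain 1, output bounded by the input range.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        return x.copy()
    a = float(np.exp(-dt / cfg.tau_lp))
    y = np.empty_like(x)
    acc = 0.0
    for k, xk in enumerate(x):
        acc = a * acc + (1.0 - a) * xk
        y[k] = acc
    return y


def moving_average(
    series: Sequence[float] | np.ndarray, n_window: int
) -> np.ndarray:
    """Causal moving average; the window shrinks at the start (no
    lookahead), so output[k] = mean(x[max(0, k-n+1) : k+1])."""
    if n_window < 1:
        raise ValueError("n_window must be >= 1")
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        return x.copy()
    csum = np.cumsum(x)
    out = np.empty_like(x)
    n = min(n_window, x.size)
    out[:n] = csum[:n] / np.arange(1, n + 1)
    if x.size > n_window:
        out[n_window:] = (csum[n_window:] - csum[:-n_window]) / n_window
    return out


def normalize_vibration(
    series: Sequence[float] | np.ndarray, norm_max: float
) -> np.ndarray:
    """Scale magnitudes to currents in [0, 1] by a fixed ceiling."""
    if not norm_max > 0:
        raise ValueError("norm_max must be positive")
    return np.clip(np.asarray(series, dtype=float) / norm_max, 0.0, 1.0)


def encode_vibration(
    magnitudes: Sequence[float] | np.ndarray, cfg: FilterConfig, dt: float
) -> np.ndarray:
    """Full US pipeline: low-pass -> moving average -> normalize."""
    return normalize_vibration(
        moving_average(lowpass(magnitudes, cfg, dt), cfg.n_window), cfg.norm_max
    )


def us_gain(
    cfg: FilterConfig,
    v_threshold: float = 1.0,
    threshold_accel: float = 5.0,
    margin: float = 0.01,
) -> float:
    """US neuron membrane gain realizing the innate 5 m/s^2 threshold.

    Chosen so the steady-state potential for a sustained ``threshold_accel``
    input sits ``margin`` above threshold: the exponential approach then
    crosses in finite time (~ tau_m * ln(1/margin)), while any sustained
    magnitude below ``threshold_accel/(1+margin)`` never spikes.
    """
    i_th = threshold_accel / cfg.norm_max
    return v_threshold / i_th * (1.0 + margin)


def cs_gain(theta_cs: float = 0.4, v_threshold: float = 1.0,
            margin: float = 0.01) -> float:
    """CS neuron gain: any red rate passing the gate is suprathreshold."""
    return v_threshold / theta_cs * (1.0 + margin)


# -- visual channel ----------------------------------------------------------

def _is_red(image: np.ndarray) -> np.ndarray:
    """Boolean red mask.  A pixel is red iff R >= 150, R >= 2G and R >= 2B
    (8-bit channels); the arena simulator emits pure red (255, 0, 0)."""
    r = image[..., 0].astype(np.int32)
    g = image[..., 1].astype(np.int32)
    b = image[..., 2].astype(np.int32)
    return (r >= 150) & (r >= 2 * g) & (r >= 2 * b)


def red_pixel_rates(image: np.ndarray, t: float = 0.0) -> VisualFrame:
    """Per-region red-pixel rates over a 3x3 partition of the image.

    The partition uses near-equal rectangles (row/column counts differ by
    at most one when H or W is not divisible by 3) and covers every pixel
    exactly once.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValueError("image must be H x W x 3 (RGB)")
    h, w = image.shape[:2]
    if h < 3 or w < 3:
        raise ValueError("image must be at least 3 x 3 pixels")
    red = _is_red(image)
    rates = []
    row_edges = np.linspace(0, h, 4).round().astype(int)
    col_edges = np.linspace(0, w, 4).round().astype(int)
    for i in range(3):
        for j in range(3):
            block = red[row_edges[i]:row_edges[i + 1],
                        col_edges[j]:col_edges[j + 1]]
            rates.append(float(block.mean()))
    return VisualFrame(t=t, red_rates=tuple(rates))


def gate_cs(
    frame: VisualFrame | Sequence[float] | np.ndarray, theta_cs: float = 0.4
) -> np.ndarray:
    """Zero rates below the gate; pass rates at/above it unchanged.

    Idempotent: gating a gated vector is a no-op.
    """
    if not 0.0 <= theta_cs <= 1.0:
        raise ValueError("theta_cs must lie in [0, 1]")
    rates = np.asarray(
        frame.red_rates if isinstance(frame, VisualFrame) else frame,
        dtype=float,
    )
    return np.where(rates >= theta_cs, rates, 0.0)


# -- CSV I/O -----------------------------------------------------------------

def read_accel_csv(path) -> list[AccelSample]:
    """Read an accelerometer log with columns t, ax, ay, az."""
    df = pd.read_csv(path, comment="#")
    samples = [
        AccelSample(float(r.t), float(r.ax), float(r.ay), float(r.az))
        for r in df.itertuples()
    ]
    ts = [s.t for s in samples]
    if any(b <= a for a, b in zip(ts, ts[1:])):
        raise ValueError("timestamps must be strictly increasing")
    return samples


def read_visual_csv(path) -> list[VisualFrame]:
    """Read a visual log with columns t, r1..r9 (row-major 3x3 regions,
    region 1 at the top-left)."""
    df = pd.read_csv(path, comment="#")
    cols = [f"r{i}" for i in range(1, 10)]
    return [
        VisualFrame(float(row["t"]), tuple(float(row[c]) for c in cols))
        for _, row in df.iterrows()
    ]


def currents_to_frame(t: np.ndarray, currents: np.ndarray,
                      prefix: str = "i") -> pd.DataFrame:
    """Encoded current traces as a CSV-ready table."""
    currents = np.atleast_2d(np.asarray(currents, dtype=float))
    if currents.shape[0] == np.asarray(t).size and currents.ndim == 2:
        data = {f"{prefix}{k + 1}": currents[:, k]
                for k in range(currents.shape[1])}
    else:
        data = {f"{prefix}{k + 1}": currents[k] for k in range(len(currents))}
    return pd.DataFrame({"t": np.asarray(t, dtype=float), **data})
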