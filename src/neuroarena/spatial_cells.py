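"""Grid-cell and place-cell firing models on a hexagonal lattice.

A grid cell is parameterized by spacing ``s``, orientation ``theta`` in
[0, pi/3], a two-component phase ``phi``, an intensity factor ``kappa``
and a baseline ``zeta``.  Its firing field peaks on the vertices of the
hexagonal (triangular) lattice generated by the two basis vectors

    b1 = s * (cos theta, sin theta),
    b2 = s * (cos(theta + pi/3), sin(theta + pi/3)),

anchored at the phase origin.  With ``d`` the distance from the animal's
position to the nearest lattice vertex, the rate is

    rate = 1/2 - arctan(kappa * (d/s - zeta)) / pi,

bounded in (0, 1) and strictly decreasing in ``d``; larger ``kappa``
sharpens the peaks and larger ``zeta`` widens the fields.

Place cells are thresholded sums over a bank of grid cells, optionally
corrected by a Gaussian landmark-response term comparing observed to
remembered landmark range/bearing pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GridCellSpec",
    "FrameTransform",
    "PlaceCellSpec",
    "RateMap",
    "GRID_PRESETS",
    "place_to_grid",
    "grid_rate",
    "nearest_vertex_distance",
    "rate_map",
    "transform_frame",
    "inverse_transform",
    "place_activity",
    "landmark_response",
    "find_rate_peaks",
]

_TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class GridCellSpec:
    """One grid cell: spacing (m), orientation (rad, in [0, pi/3]),
    two phase offsets (wrapped into [0, 2*pi)), intensity ``kappa`` and
    baseline ``zeta``."""

    s: float
    theta: float
    phi: tuple[float, float] = (0.0, 0.0)
    kappa: float = 0.5
    zeta: float = 0.0

    def __post_init__(self) -> None:
        if not self.s > 0:
            raise ValueError("grid spacing s must be positive")
        if not 0.0 <= self.theta <= math.pi / 3:
            raise ValueError("theta must lie in [0, pi/3]")
        object.__setattr__(
            self, "phi", tuple(float(p) % _TWO_PI for p in self.phi)
        )

    @property
    def basis(self) -> np.ndarray:
        """2x2 matrix whose columns are the lattice basis vectors."""
        t = self.theta
        return self.s * np.array(
            [[math.cos(t), math.cos(t + math.pi / 3)],
             [math.sin(t), math.sin(t + math.pi / 3)]]
        )

    @property
    def phase_origin(self) -> np.ndarray:
        """World-space point with zero grid-frame coordinates (the lattice
        anchor): solves basis^T @ x = phi."""
        return np.linalg.solve(self.basis.T, np.asarray(self.phi, float))


#: Named presets: ``unit`` is the desk-scale demonstration cell used for
#: the 1.3 m arena firing-field figures; ``nav`` is the coarse cell used by
#: the robot's navigation stack (spacing stored as given; units unstated
#: upstream).
GRID_PRESETS: dict[str, GridCellSpec] = {
    "unit": GridCellSpec(s=1.0, theta=math.pi / 4, phi=(0.5, 0.0),
                         kappa=0.5, zeta=0.0),
    "nav": GridCellSpec(s=8.8, theta=math.pi / 4, phi=(0.5, 1.2),
                        kappa=5.0, zeta=0.3),
}


@dataclass(frozen=True)
class FrameTransform:
    """Rigid transform between two place-cell frames: a rotation by
    ``phi_rot`` (applied as the transpose of the standard CCW matrix, i.e.
    a clockwise rotation of coordinates) followed by a translation."""

    phi_rot: float = 0.0
    trans: tuple[float, float] = (0.0, 0.0)

    @property
    def rotation(self) -> np.ndarray:
        c, s = math.cos(self.phi_rot), math.sin(self.phi_rot)
        return np.array([[c, -s], [s, c]]).T


@dataclass(frozen=True)
class PlaceCellSpec:
    """Place cell: contributing grid-cell ids, activation threshold on the
    summed grid input, and landmark variance terms (m^2, rad^2)."""

    grid_ids: tuple[str, ...]
    theta_sum: float = 0.5
    sigma_d2: float = 0.04
    sigma_theta2: float = 0.1

    def __post_init__(self) -> None:
        if len(self.grid_ids) == 0:
            raise ValueError("a place cell needs at least one grid input")
        if not (self.sigma_d2 > 0 and self.sigma_theta2 > 0):
            raise ValueError("landmark variances must be positive")


def place_to_grid(pos: Sequence[float], spec: GridCellSpec) -> np.ndarray:
    """Map a place-frame position into the grid-cell frame:
    basis^T @ pos - phi."""
    p = np.asarray(pos, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("position must be finite")
    return spec.basis.T @ p - np.asarray(spec.phi, float)


def nearest_vertex_distance(
    pos: np.ndarray, spec: GridCellSpec
) -> np.ndarray:
    """Distance from each position to the nearest lattice vertex.

    ``pos`` has shape (..., 2).  The nearest vertex is found by rounding
    lattice coordinates and checking the 3x3 neighbor block (sufficient
    for an oblique basis at 60 degrees).
    """
    p = np.asarray(pos, dtype=float)
    rel = p - spec.phase_origin
    coords = rel @ np.linalg.inv(spec.basis).T  # lattice coordinates
    base = np.floor(coords)
    best = np.full(p.shape[:-1], np.inf)
    for di in (0.0, 1.0, -1.0):
        for dj in (0.0, 1.0, -1.0):
            n = base + np.array([di, dj])
            vert = n @ spec.basis.T
            d = np.linalg.norm(rel - vert, axis=-1)
            best = np.minimum(best, d)
    return best


def grid_rate(pos: Sequence[float] | np.ndarray, spec: GridCellSpec):
    """Firing rate in (0, 1) at one or many positions."""
    p = np.asarray(pos, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("position must be finite")
    d = nearest_vertex_distance(p, spec)
    sigma = np.arctan(spec.kappa * (d / spec.s - spec.zeta))
    rate = 0.5 - sigma / math.pi
    return float(rate) if p.ndim == 1 else rate


@dataclass
class RateMap:
    """Firing rates sampled on a square lattice covering a disc; NaN marks
    points outside the arena."""

    x: np.ndarray
    y: np.ndarray
    rates: np.ndarray
    spec: GridCellSpec = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.x, self.y)
        return pd.DataFrame(
            {"x": xx.ravel(), "y": yy.ravel(), "rate": self.rates.ravel()}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, path=None, ax=None):
        """Render the field (requires matplotlib)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        ax.pcolormesh(self.x, self.y, self.rates, shading="auto")
        ax.set_aspect("equal")
        ax.set_xlabel("x (m)")
        ax.set_ylabel("y (m)")
        if path is not None:
            ax.figure.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(ax.figure)
        return ax


def rate_map(
    spec: GridCellSpec, arena_radius: float = 1.3, resolution: float = 0.02
) -> RateMap:
    """Sample the firing field on a square grid over the arena disc."""
    if not resolution > 0:
        raise ValueError("resolution must be positive")
    n = int(np.floor(2 * arena_radius / resolution)) + 1
    ax = np.linspace(-arena_radius, arena_radius, n)
    xx, yy = np.meshgrid(ax, ax)
    pts = np.stack([xx, yy], axis=-1)
    rates = grid_rate(pts.reshape(-1, 2), spec).reshape(xx.shape)
    outside = xx**2 + yy**2 > arena_radius**2
    rates = np.where(outside, np.nan, rates)
    return RateMap(x=ax, y=ax, rates=rates, spec=spec)


def find_rate_peaks(rmap: RateMap, min_rate: float = 0.48) -> np.ndarray:
    """Firing-peak locations (x, y pairs) of a rate map.

    Contiguous regions with rate >= ``min_rate`` (one per lattice vertex
    when the threshold sits just below the peak rate) are labelled and
    reduced to their centroids, which is robust to sampling ties that a
    pointwise local-maximum filter would split into multiple peaks.
    """
    from scipy import ndimage

    high = np.nan_to_num(rmap.rates, nan=-np.inf) >= min_rate
    labels, n = ndimage.label(high)
    peaks = []
    for k in range(1, n + 1):
        iy, ix = np.nonzero(labels == k)
        peaks.append([rmap.x[ix].mean(), rmap.y[iy].mean()])
    return np.asarray(peaks).reshape(-1, 2)


def transform_frame(
    pos: Sequence[float], tf: FrameTransform
) -> np.ndarray:
    """Map a position from the current place-cell frame into the global
    one: R @ pos + trans."""
    p = np.asarray(pos, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("position must be finite")
    return tf.rotation @ p + np.asarray(tf.trans, float)


def inverse_transform(
    pos: Sequence[float], tf: FrameTransform
) -> np.ndarray:
    """Inverse of :func:`transform_frame`; the round trip is the identity
    to machine precision."""
    p = np.asarray(pos, dtype=float)
    return tf.rotation.T @ (p - np.asarray(tf.trans, float))


def place_activity(
    pos: Sequence[float],
    spec: PlaceCellSpec,
    grid_bank: Mapping[str, GridCellSpec],
) -> int:
    """Binary place-cell activity: 1 iff the summed grid input reaches the
    activation threshold (ties active)."""
    missing = [g for g in spec.grid_ids if g not in grid_bank]
    if missing:
        raise KeyError(f"unknown grid cell id(s): {missing}")
    total = sum(grid_rate(pos, grid_bank[g]) for g in spec.grid_ids)
    return int(total >= spec.theta_sum)


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap angle differences into (-pi, pi]."""
    return -((-np.asarray(a) + math.pi) % _TWO_PI - math.pi)


def landmark_response(
    observed: Iterable[tuple[float, float]],
    remembered: Iterable[tuple[float, float]],
    spec: PlaceCellSpec,
) -> float:
    """Gaussian landmark match: sum over landmarks of
    exp(-(d - d_hat)^2 / sigma_d2 - wrap(theta - theta_hat)^2 / sigma_theta2).

    Equal lists give exactly the number of landmarks; gross mismatches
    contribute ~0.
    """
    obs = np.asarray(list(observed), dtype=float)
    rem = np.asarray(list(remembered), dtype=float)
    if obs.shape != rem.shape:
        raise ValueError(
            f"observed and remembered landmark lists differ in shape: "
            f"{obs.shape} vs {rem.shape}"
        )
    if obs.size == 0:
        return 0.0
    dd = obs[:, 0] - rem[:, 0]
    dth = _wrap_angle(obs[:, 1] - rem[:, 1])
    return float(
        np.sum(np.exp(-(dd**2) / spec.sigma_d2 - dth**2 / spec.sigma_theta2))
    )
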