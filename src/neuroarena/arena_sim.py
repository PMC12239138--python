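"""Hardware-free circular open-field arena.

Geometry: a disc of radius 1.3 m (2.6 m diameter) bounded by a high wall;
one angular arc of the wall is painted red (the CS), and bumper strips —
convex polygons on the floor in front of the red arc — produce a vertical
acceleration plateau well above the 5 m/s^2 danger threshold when the
agent's footprint overlaps them (the US).

Sensors are synthesized from geometry alone: a 270-degree range scanner
(exact ray-circle intersections), a pinhole camera reduced to nine
region red-pixel rates (3 columns x 3 rows; a column's rate is its
angular overlap with the red arc, rows uniform by default), and an IMU
magnitude channel (bumper plateau + rectified Gaussian noise).

Movement follows a priority policy: learned avoidance (back away from
red) > vibration reflex (stop and rotate for 2 s) > boundary avoidance
(steer toward the furthest scan point) > forward exploration with random
angular jitter.  Kinematics are unicycle at 50 ms steps; the embedded
spiking network runs 50 one-millisecond substeps per motion step on
zero-order-held input currents.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon
from shapely import affinity

from . import associative_net as anet
from . import sensory_encoding as enc

__all__ = [
    "ArenaConfig",
    "Pose",
    "SensorFrame",
    "TrialResult",
    "NavController",
    "default_bumper_zones",
    "simulate_lidar",
    "sense",
    "movement_step",
    "run_trial",
]

_TWO_PI = 2.0 * math.pi


def _wrap(a: float) -> float:
    """Wrap an angle into (-pi, pi]."""
    return -((-a + math.pi) % _TWO_PI - math.pi)


def default_bumper_zones(
    radius: float = 1.3,
    arc_center: float = math.pi / 2,
    zone_radius: float = 1.0,
    n_zones: int = 3,
    length: float = 0.45,
    depth: float = 0.4,
) -> list[Polygon]:
    """Bumper strips in front of the red wall: tangentially oriented
    rectangles spread across the arc, extending from mid-field toward the
    wall so that wall-following paths through the red quadrant cross
    them (the study's road-bumper placement)."""
    zones = []
    angles = arc_center + np.linspace(-1, 1, n_zones) * math.pi / 6
    for a in angles:
        box = Polygon(
            [(-length / 2, -depth / 2), (length / 2, -depth / 2),
             (length / 2, depth / 2), (-length / 2, depth / 2)]
        )
        box = affinity.rotate(box, math.degrees(a + math.pi / 2), origin=(0, 0))
        box = affinity.translate(
            box, zone_radius * math.cos(a), zone_radius * math.sin(a)
        )
        zones.append(box)
    return zones


@dataclass(frozen=True)
class ArenaConfig:
    """Arena geometry, sensing and kinematic parameters.

    The red arc is the angular interval [red_arc[0], red_arc[1]] of the
    wall (radians, CCW; default the north quadrant pi/4..3*pi/4).  Bumper
    zones default to three strips in front of that quadrant.
    """

    radius: float = 1.3
    red_arc: tuple[float, float] = (math.pi / 4, 3 * math.pi / 4)
    bumper_zones: tuple[Polygon, ...] = None
    v_lin: float = 0.2
    w_rot: float = 1.5
    rotate_duration: float = 2.0
    lidar_fov: float = 3 * math.pi / 2
    lidar_n: int = 91
    dt_motion: float = 0.05
    bump_accel: float = 6.0
    boundary_threshold: float = 0.3
    jitter_rad_s: float = 0.3
    footprint_radius: float = 0.1
    camera_fov: float = math.pi / 2
    rays_per_column: int = 12
    noise_sigma: float = 0.1
    wall_contact_margin: float = 0.2
    debounce_s: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("radius must be positive")
        if not 0 < self.lidar_fov <= _TWO_PI:
            raise ValueError("lidar_fov must lie in (0, 2*pi]")
        if not self.bump_accel > 5.0:
            raise ValueError("bump_accel must exceed the 5 m/s^2 threshold")
        if self.bumper_zones is None:
            arc_c = _wrap((self.red_arc[0] + self.red_arc[1]) / 2)
            object.__setattr__(
                self, "bumper_zones",
                tuple(default_bumper_zones(self.radius, arc_center=arc_c)),
            )
        else:
            object.__setattr__(self, "bumper_zones", tuple(self.bumper_zones))
        for z in self.bumper_zones:
            if max(math.hypot(x, y) for x, y in z.exterior.coords) > self.radius:
                raise ValueError("bumper zones must lie inside the arena disc")


@dataclass(frozen=True)
class Pose:
    """Agent pose in the arena-centred frame; heading CCW from +x."""

    x: float
    y: float
    heading: float

    @property
    def r(self) -> float:
        return math.hypot(self.x, self.y)

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass(frozen=True)
class SensorFrame:
    """One timestep's percept: nine red-pixel rates (row-major 3x3),
    raw vibration magnitude (m/s^2) and the range scan."""

    t: float
    red_rates: np.ndarray
    vibration: float
    scan: np.ndarray


def simulate_lidar(pose: Pose, cfg: ArenaConfig) -> np.ndarray:
    """Range scan: ``lidar_n`` beams spread over ``lidar_fov`` centred on
    the heading; each range is the exact ray-circle intersection distance.
    The rear (2*pi - fov) sector is absent."""
    if pose.r > cfg.radius:
        raise ValueError("pose lies outside the arena disc")
    rel = np.linspace(-cfg.lidar_fov / 2, cfg.lidar_fov / 2, cfg.lidar_n)
    angles = pose.heading + rel
    return _ray_ranges(pose.x, pose.y, angles, cfg.radius)


def _ray_ranges(x: float, y: float, angles: np.ndarray,
                radius: float) -> np.ndarray:
    ux, uy = np.cos(angles), np.sin(angles)
    b = x * ux + y * uy
    c = x * x + y * y - radius * radius  # <= 0 inside the disc
    return -b + np.sqrt(np.maximum(b * b - c, 0.0))


def _red_column_fractions(pose: Pose, cfg: ArenaConfig) -> np.ndarray:
    """Fraction of each camera column's rays that hit the red arc."""
    lo, hi = cfg.red_arc
    fractions = np.empty(3)
    col_w = cfg.camera_fov / 3
    for j in range(3):
        start = pose.heading + cfg.camera_fov / 2 - (j + 1) * col_w
        rays = start + (np.arange(cfg.rays_per_column) + 0.5) / \
            cfg.rays_per_column * col_w
        r = _ray_ranges(pose.x, pose.y, rays, cfg.radius)
        hx = pose.x + r * np.cos(rays)
        hy = pose.y + r * np.sin(rays)
        wall_angle = np.arctan2(hy, hx)
        # membership of the wall hit angle in the (possibly wrapped) arc
        span = (hi - lo) % _TWO_PI
        off = (wall_angle - lo) % _TWO_PI
        fractions[j] = np.mean(off <= span)
    return fractions


def _on_bumper(pose: Pose, cfg: ArenaConfig) -> bool:
    p = Point(pose.x, pose.y)
    return any(z.distance(p) <= cfg.footprint_radius
               for z in cfg.bumper_zones)


def sense(
    pose: Pose, cfg: ArenaConfig, rng: np.random.Generator, t: float = 0.0
) -> SensorFrame:
    """Synthesize one percept from geometry.

    Columns are ordered left-to-right in the image; with rows weighted
    uniformly the nine rates are the column fractions tiled row-major.
    Vibration is the bumper plateau when the footprint overlaps a zone,
    else magnitude-rectified Gaussian sensor noise.
    """
    cols = _red_column_fractions(pose, cfg)
    red_rates = np.tile(cols, 3)
    if _on_bumper(pose, cfg):
        vibration = cfg.bump_accel
    else:
        vibration = abs(float(rng.normal(0.0, cfg.noise_sigma)))
    return SensorFrame(
        t=t, red_rates=red_rates, vibration=vibration,
        scan=simulate_lidar(pose, cfg),
    )


class NavController:
    """Movement logic with the small amount of state the policy needs
    (the 2 s vibration-rotation timer and its turn direction)."""

    def __init__(self, cfg: ArenaConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.rotate_left = 0.0
        self.rotate_sign = 1.0

    def movement_step(
        self,
        pose: Pose,
        scan: np.ndarray,
        vibration: float,
        action: str = "none",
    ) -> Pose:
        """Advance the pose by one kinematic step (``dt_motion``).

        Priority: learned avoidance > vibration reflex > boundary
        avoidance > forward exploration.  The resulting pose is clamped
        inside the disc.
        """
        cfg = self.cfg
        dt = cfg.dt_motion
        v, w = 0.0, 0.0

        if action == "avoid":
            # back away from the red wall, steering away from its centre
            self.rotate_left = 0.0
            arc_c = (cfg.red_arc[0] + cfg.red_arc[1]) / 2
            bearing = _wrap(arc_c - pose.heading)
            v = -cfg.v_lin
            w = -math.copysign(cfg.w_rot, bearing)
        elif self.rotate_left > 0.0 or vibration >= 5.0:
            # vibration reflex: stop and rotate for rotate_duration
            if self.rotate_left <= 0.0:
                self.rotate_left = cfg.rotate_duration
                self.rotate_sign = 1.0 if self.rng.random() < 0.5 else -1.0
            v = 0.0
            w = self.rotate_sign * cfg.w_rot
            self.rotate_left -= dt
        else:
            fwd = scan[np.abs(_rel_angles(scan.size, cfg.lidar_fov))
                       <= math.pi / 6]
            if fwd.size and fwd.min() < cfg.boundary_threshold:
                # boundary: steer toward the bearing of the furthest point
                rel = _rel_angles(scan.size, cfg.lidar_fov)
                target = rel[int(np.argmax(scan))]
                w = float(np.clip(target / dt, -cfg.w_rot, cfg.w_rot))
                v = cfg.v_lin * 0.5
            else:
                v = cfg.v_lin
                w = float(self.rng.uniform(-cfg.jitter_rad_s,
                                           cfg.jitter_rad_s))

        heading = _wrap(pose.heading + w * dt)
        x = pose.x + v * dt * math.cos(heading)
        y = pose.y + v * dt * math.sin(heading)
        r = math.hypot(x, y)
        r_max = cfg.radius - 0.02
        if r > r_max:
            x, y = x * r_max / r, y * r_max / r
        return Pose(x, y, heading)


def _rel_angles(n: int, fov: float) -> np.ndarray:
    return np.linspace(-fov / 2, fov / 2, n)


def movement_step(
    pose: Pose,
    scan: np.ndarray,
    vibration: float,
    action: str,
    cfg: ArenaConfig,
    rng: np.random.Generator,
) -> Pose:
    """Stateless convenience wrapper around :class:`NavController` for a
    single step (the vibration-rotation timer does not persist)."""
    return NavController(cfg, rng).movement_step(pose, scan, vibration, action)


@dataclass
class TrialResult:
    """Full record of one closed-loop arena trial."""

    seed: int
    dt_motion: float
    times: np.ndarray
    poses: np.ndarray  # (n, 3): x, y, heading
    actions: list[str]
    vibrations: np.ndarray
    red_rates: np.ndarray  # (n, 9)
    output_spikes: np.ndarray  # output-aggregator firings per motion step
    w_cs_trace: np.ndarray  # (n, 9)
    collision_events: list[tuple[float, int]]  # (time, zone id)
    wall_contacts: list[float]  # times the red wall region was touched
    phase: str = "trial"

    @property
    def n_steps(self) -> int:
        return self.times.size

    def path_length(self) -> float:
        d = np.diff(self.poses[:, :2], axis=0)
        return float(np.sum(np.hypot(d[:, 0], d[:, 1])))

    def poses_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "x": self.poses[:, 0],
                "y": self.poses[:, 1],
                "heading": self.poses[:, 2],
                "action": self.actions,
                "vibration": self.vibrations,
                "output_spikes": self.output_spikes,
            }
        )

    def summary(self) -> dict:
        return {
            "seed": self.seed,
            "duration_s": float(self.times[-1] + self.dt_motion)
            if self.n_steps else 0.0,
            "collisions": len(self.collision_events),
            "wall_contacts": len(self.wall_contacts),
            "path_length_m": self.path_length(),
            "phase": self.phase,
        }

    def to_csv(self, path) -> None:
        self.poses_frame().to_csv(path, index=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def _touching_red_wall(pose: Pose, cfg: ArenaConfig) -> bool:
    if pose.r < cfg.radius - cfg.wall_contact_margin:
        return False
    a = math.atan2(pose.y, pose.x)
    lo, hi = cfg.red_arc
    return (a - lo) % _TWO_PI <= (hi - lo) % _TWO_PI


def run_trial(
    arena: ArenaConfig,
    net: anet.NetworkState,
    net_cfg: anet.NetworkConfig,
    duration: float = 60.0,
    learning_on: bool = False,
    us_enabled: bool = True,
    seed: int = 0,
    start_pose: Pose | None = None,
) -> TrialResult:
    """Closed-loop trial: sense -> encode -> network -> decide -> move.

    The network runs ``dt_motion / dt`` one-millisecond substeps per
    motion step on zero-order-held currents.  ``us_enabled=False``
    silences the whole vibration channel (probe trials): the network
    receives no US current and the reflex rotation is disabled.
    Deterministic and bit-reproducible given the seed.
    """
    if not duration > 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    nav = NavController(arena, rng)
    state = net.copy()
    pose = start_pose if start_pose is not None else Pose(0.0, 0.0, 0.0)

    n_sub = max(1, int(round(arena.dt_motion / net_cfg.dt)))
    n_steps = int(round(duration / arena.dt_motion))
    fcfg = net_cfg.filter_cfg

    times = np.arange(n_steps) * arena.dt_motion
    poses = np.empty((n_steps, 3))
    vibrations = np.empty(n_steps)
    red = np.empty((n_steps, 9))
    out_spikes = np.zeros(n_steps, dtype=int)
    w_trace = np.empty((n_steps, net_cfg.n_regions))
    actions: list[str] = []
    collisions: list[tuple[float, int]] = []
    wall_contacts: list[float] = []

    # online vibration pre-processing state (motion-rate stream)
    lp_a = math.exp(-arena.dt_motion / fcfg.tau_lp)
    lp_acc = 0.0
    ma_buf: list[float] = []

    action = "none"
    on_zone_prev = False
    last_collision_t = -math.inf
    wall_prev = False

    for k in range(n_steps):
        t = float(times[k])
        frame = sense(pose, arena, rng, t=t)

        # encode US: low-pass -> moving average -> normalize, online
        lp_acc = lp_a * lp_acc + (1.0 - lp_a) * frame.vibration
        ma_buf.append(lp_acc)
        if len(ma_buf) > fcfg.n_window:
            ma_buf.pop(0)
        us_current = min(max(sum(ma_buf) / len(ma_buf) / fcfg.norm_max, 0.0),
                         1.0)
        if not us_enabled:
            us_current = 0.0

        cs_currents = enc.gate_cs(frame.red_rates, net_cfg.theta_cs)
        red_visible = bool(np.any(cs_currents > 0))

        fired = 0
        for _ in range(n_sub):
            state, out = anet.network_step(
                state, cs_currents, us_current, learning_on, net_cfg
            )
            fired += int(out)
        out_spikes[k] = fired

        action = anet.response_decision(fired > 0, red_visible, action)

        vib_for_reflex = frame.vibration if us_enabled else 0.0
        new_pose = nav.movement_step(pose, frame.scan, vib_for_reflex, action)

        # bookkeeping
        poses[k] = (pose.x, pose.y, pose.heading)
        vibrations[k] = frame.vibration
        red[k] = frame.red_rates
        w_trace[k] = state.w_cs
        actions.append(action)

        zone_id = next(
            (i for i, z in enumerate(arena.bumper_zones)
             if z.distance(Point(pose.x, pose.y)) <= arena.footprint_radius),
            None,
        )
        on_zone = zone_id is not None
        if on_zone and not on_zone_prev and (
            t - last_collision_t >= arena.debounce_s
        ):
            collisions.append((t, zone_id))
            last_collision_t = t
        on_zone_prev = on_zone

        wall_now = _touching_red_wall(pose, arena)
        if wall_now and not wall_prev:
            wall_contacts.append(t)
        wall_prev = wall_now

        pose = new_pose

    return TrialResult(
        seed=seed,
        dt_motion=arena.dt_motion,
        times=times,
        poses=poses,
        actions=actions,
        vibrations=vibrations,
        red_rates=red,
        output_spikes=out_spikes,
        w_cs_trace=w_trace,
        collision_events=collisions,
        wall_contacts=wall_contacts,
    )
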