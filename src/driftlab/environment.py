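"""Corridor world: wall texture, shuttling agent, and its visual stream.

An agent moves back and forth along a rectangular corridor [0, Lx]×[0, Ly],
its heading deflecting slightly around the corridor axis as a clamped
Gaussian random walk.  The walls carry a fixed smooth random texture; at
every step the agent reads out ``L_vis`` pixels along evenly spaced rays
spanning its visual field.  Predicting the next frame from the current one
is the task the network is trained on.

Conventions (fixed, since several geometric details admit choices):

- The perimeter is parameterized counter-clockwise starting at (0, 0):
  bottom wall (y=0), right (x=Lx), top (y=Ly), left (x=0).  Texture index 0
  sits at the origin; fractional perimeter coordinates are linearly
  interpolated with wrap-around.
- The heading is a deflection θ around the +y axis, clamped to ±π/2 so the
  forward direction stays defined; the displacement per step is
  V0·(sin θ, ±cos θ) with the y-sign flipping when the agent enters the
  wall buffer (distance Ly·L_buffer from either end).
- Lateral wall contacts reflect the x coordinate and mirror the heading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "CorridorConfig",
    "GeometryError",
    "Trajectory",
    "VisualStream",
    "WallTexture",
    "generate_wall_texture",
    "render_visual_input",
    "simulate_trajectory",
]


class GeometryError(ValueError):
    """Raised when a ray cannot be traced (agent outside the arena)."""


@dataclass(frozen=True)
class CorridorConfig:
    """Geometry and kinematics of the corridor task.

    Lengths are in arbitrary units; the corridor runs along y.
    """

    Lx: float = 1.0        # corridor width
    Ly: float = 10.0       # corridor length (shuttling axis)
    V0: float = 0.4        # speed per step
    sigma_theta_sq: float = 0.02  # variance of the per-step heading increment (rad²)
    theta_vis: float = np.pi / 2  # visual field angle (rad)
    L_vis: int = 15        # visual-field pixels
    K_smooth: float = 0.05  # texture smoothing: kernel variance = K_smooth · L_walls
    L_buffer: float = 0.05  # wall buffer as a fraction of Ly

    def __post_init__(self) -> None:
        if min(self.Lx, self.Ly, self.V0, self.theta_vis) <= 0 or self.L_vis < 1:
            raise ValueError("lengths, speed, visual field and L_vis must be positive")
        if not 0.0 < self.L_buffer < 1.0:
            raise ValueError("L_buffer must lie strictly between 0 and 1")
        if self.sigma_theta_sq < 0 or self.K_smooth < 0:
            raise ValueError("variances must be non-negative")

    @property
    def perimeter(self) -> float:
        return 2.0 * (self.Lx + self.Ly)

    @property
    def L_walls(self) -> int:
        """Total texture pixels on the perimeter: 2·(Lx+Ly)·L_vis."""
        return int(round(2.0 * (self.Lx + self.Ly) * self.L_vis))


@dataclass
class WallTexture:
    """Real-valued texture intensities along the (circular) perimeter."""

    values: NDArray[np.float64]
    L_walls: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size != self.L_walls:
            raise ValueError("texture length must equal L_walls")


@dataclass
class Trajectory:
    """Agent path: positions, absolute headings and per-step velocities.

    ``headings[t]``/``velocities[t]`` describe the step taken from
    ``positions[t]`` to ``positions[t+1]`` (and the gaze at time t).
    """

    positions: NDArray[np.float64]   # (T, 2)
    headings: NDArray[np.float64]    # (T,) absolute angle, radians, 0 = +x
    velocities: NDArray[np.float64]  # (T, 2)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.headings = np.asarray(self.headings, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if not (len(self.positions) == len(self.headings) == len(self.velocities)):
            raise ValueError("positions, headings and velocities must share length")

    @property
    def T(self) -> int:
        return self.positions.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": np.arange(self.T),
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "heading": self.headings,
            }
        )

    def save(self, path) -> None:
        np.savez(path, positions=self.positions, headings=self.headings,
                 velocities=self.velocities)


@dataclass
class VisualStream:
    """Stack of visual frames, one row per trajectory step."""

    frames: NDArray[np.float64]  # (T, L_vis)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 2:
            raise ValueError("frames must be T x L_vis")


def generate_wall_texture(
    config: CorridorConfig, seed: int, normalize: bool = False
) -> WallTexture:
    """Random Gaussian texture smoothed along the circular perimeter.

    The smoothing kernel has variance ``K_smooth · L_walls`` (std in pixel
    units); ``K_smooth = 0`` returns the raw Gaussian vector.  With
    ``normalize=True`` the smoothed texture is rescaled to unit variance,
    which keeps the prediction loss O(1) regardless of smoothing strength.
    """
    n = config.L_walls
    rng = np.random.default_rng(seed)
    values = rng.standard_normal(n)
    kernel_var = config.K_smooth * n
    if kernel_var > 0:
        values = gaussian_filter1d(values, sigma=float(np.sqrt(kernel_var)), mode="wrap")
    if normalize:
        sd = values.std()
        if sd > 0:
            values = (values - values.mean()) / sd
    return WallTexture(values=values, L_walls=n)


def simulate_trajectory(
    config: CorridorConfig, T: int, seed: int, start: tuple[float, float] | None = None
) -> Trajectory:
    """Shuttling random-deflection walk along the corridor.

    The heading deflection performs a Gaussian random walk (variance
    ``sigma_theta_sq`` per step) clamped to ±π/2; the y-direction sign
    flips whenever the agent comes within ``Ly·L_buffer`` of either end.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    lo, hi = config.Ly * config.L_buffer, config.Ly * (1.0 - config.L_buffer)
    if config.V0 >= hi - lo:
        raise ValueError(
            f"V0={config.V0} overshoots the corridor interior ({hi - lo:.3g}) in one step"
        )
    rng = np.random.default_rng(seed)
    clamp = np.pi / 2 - 1e-9
    sigma = float(np.sqrt(config.sigma_theta_sq))

    x, y = start if start is not None else (config.Lx / 2.0, config.Ly / 2.0)
    theta, s = 0.0, 1.0
    positions = np.empty((T, 2))
    headings = np.empty(T)
    velocities = np.empty((T, 2))
    for t in range(T):
        vx = config.V0 * np.sin(theta)
        vy = s * config.V0 * np.cos(theta)
        positions[t] = (x, y)
        headings[t] = np.arctan2(vy, vx)
        velocities[t] = (vx, vy)
        x += vx
        y += vy
        if x < 0.0:  # reflect off the side walls, mirroring the deflection
            x, theta = -x, -theta
        elif x > config.Lx:
            x, theta = 2.0 * config.Lx - x, -theta
        if s > 0 and y >= hi:
            s = -1.0
        elif s < 0 and y <= lo:
            s = 1.0
        y = min(max(y, 0.0), config.Ly)
        if sigma > 0:
            theta += rng.normal(0.0, sigma)
            theta = min(max(theta, -clamp), clamp)
    return Trajectory(positions=positions, headings=headings, velocities=velocities)


def _perimeter_coordinate(
    px: NDArray, py: NDArray, wall: NDArray, config: CorridorConfig
) -> NDArray:
    """Counter-clockwise perimeter coordinate of wall points, from (0,0)."""
    Lx, Ly = config.Lx, config.Ly
    s = np.empty_like(px)
    s[wall == 0] = px[wall == 0]                        # bottom: y = 0
    s[wall == 1] = Lx + py[wall == 1]                   # right:  x = Lx
    s[wall == 2] = Lx + Ly + (Lx - px[wall == 2])       # top:    y = Ly
    s[wall == 3] = 2 * Lx + Ly + (Ly - py[wall == 3])   # left:   x = 0
    return s


def render_visual_input(
    traj: Trajectory, texture: WallTexture, config: CorridorConfig
) -> VisualStream:
    """Cast ``L_vis`` rays per step and read the texture where they hit.

    Rays span ``theta_vis`` symmetrically around the heading; each pixel is
    the linearly interpolated texture value at the ray–wall intersection,
    mapped through the fixed perimeter parameterization.
    """
    P = traj.positions
    eps = 1e-9
    if np.any(P[:, 0] < -eps) or np.any(P[:, 0] > config.Lx + eps) or np.any(
        P[:, 1] < -eps
    ) or np.any(P[:, 1] > config.Ly + eps):
        raise GeometryError("trajectory leaves the arena; rays undefined")

    offsets = np.linspace(-config.theta_vis / 2, config.theta_vis / 2, config.L_vis)
    ang = traj.headings[:, None] + offsets[None, :]      # (T, L_vis)
    dx, dy = np.cos(ang), np.sin(ang)
    px = np.clip(P[:, 0], 0.0, config.Lx)[:, None]
    py = np.clip(P[:, 1], 0.0, config.Ly)[:, None]

    with np.errstate(divide="ignore", invalid="ignore"):
        t_candidates = np.stack(
            [
                np.where(dy < 0, (0.0 - py) / dy, np.inf),          # bottom
                np.where(dx > 0, (config.Lx - px) / dx, np.inf),    # right
                np.where(dy > 0, (config.Ly - py) / dy, np.inf),    # top
                np.where(dx < 0, (0.0 - px) / dx, np.inf),          # left
            ]
        )
    wall = np.argmin(t_candidates, axis=0)
    t_hit = np.take_along_axis(t_candidates, wall[None], axis=0)[0]
    if not np.all(np.isfinite(t_hit)):
        raise GeometryError("a ray failed to intersect any wall")
    hx = np.clip(px + t_hit * dx, 0.0, config.Lx)
    hy = np.clip(py + t_hit * dy, 0.0, config.Ly)

    s = _perimeter_coordinate(hx, hy, wall, config)
    u = s / config.perimeter * texture.L_walls
    i0 = np.floor(u).astype(int)
    frac = u - i0
    tex = texture.values
    L = texture.L_walls
    frames = tex[i0 % L] * (1.0 - frac) + tex[(i0 + 1) % L] * frac
    return VisualStream(frames=frames)
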