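"""Synthetic active-monolayer generator.

The motion model is the minimal one that spans caged ("jammed-like") and
flowing ("unjammed-like") collective dynamics with a single motility knob:
overdamped active Brownian disks with soft harmonic pairwise repulsion in a
square periodic box.  Each cell i carries a polarity angle theta_i that
diffuses rotationally; per Euler-Maruyama step of size dt,

    dr_i = v0 * dt * (cos theta_i, sin theta_i) + dt * sum_j F_ij
    dtheta_i = sqrt(2 * D_r * dt) * xi,        xi ~ N(0, 1)

with F_ij = k * (2R - |r_ij|) * r_hat_ij for overlapping pairs
(|r_ij| < 2R) and zero otherwise.  Mobility is absorbed into the stiffness
k, so k carries units of 1/min (an overlap of 1 um produces a 1 um/min
push at k = 1).

For a single non-interacting cell the model has the closed-form
mean-squared displacement

    MSD(t) = (2 v0^2 / D_r^2) * (D_r t - 1 + exp(-D_r t)),

ballistic (~v0^2 t^2) below the persistence time 1/D_r and diffusive above
it.  That closed form is the independent oracle used by the test suite.

Default geometry emulates the imaged fields of the study system: roughly
300 cells per field of view at confluent (near-hexagonal) packing, with
positions recorded every 5 minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "SimulationConfig",
    "MonolayerTrajectory",
    "PackingError",
    "simulate_monolayer",
    "drift_trajectory",
    "abp_msd_closed_form",
    "HEX_PACKING_LIMIT",
]

#: densest packing fraction of equal disks in the plane (hexagonal lattice)
HEX_PACKING_LIMIT = math.pi / (2.0 * math.sqrt(3.0))


class PackingError(ValueError):
    """Requested density exceeds what non-overlapping disks can realise."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one monolayer simulation.

    Units: lengths in micrometres, times in minutes, rates in 1/min.
    Defaults give ~320 confluent cells in a 400 um periodic box, recorded
    every 5 min for 200 min (41 frames).
    """

    n_cells: int = 320
    box_size: float = 400.0
    v0: float = 1.0
    d_r: float = 0.1
    cell_radius: float = 12.0
    repulsion_stiffness: float = 1.0
    dt: float = 0.5
    n_frames: int = 41
    frame_interval: float = 5.0
    rng_seed: int = 0
    #: all cells share one diffusing polarity angle (plug-flow limit of
    #: collective migration); single-cell MSD still follows the ABP closed
    #: form, but the motion is spatially coherent, as PIV-resolvable
    #: collective flows are
    collective_headings: bool = False

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.box_size <= 2 * self.cell_radius:
            raise ValueError("box_size must exceed one cell diameter")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.v0 < 0 or self.d_r < 0:
            raise ValueError("v0 and d_r must be non-negative")
        if self.repulsion_stiffness < 0:
            raise ValueError("repulsion_stiffness must be non-negative")
        if self.n_frames < 1 or self.frame_interval <= 0:
            raise ValueError("need n_frames >= 1 and frame_interval > 0")
        ratio = self.frame_interval / self.dt
        if abs(ratio - round(ratio)) > 1e-9 * max(1.0, ratio):
            raise ValueError("frame_interval must be an integer multiple of dt")
        # explicit-Euler stability guard: a cell must not cross a tenth of
        # its own radius per step under self-propulsion alone
        if self.v0 > 0 and self.dt > self.cell_radius / (10.0 * self.v0):
            raise ValueError(
                f"dt={self.dt} too large for v0={self.v0}: "
                f"require dt <= cell_radius / (10 v0) = "
                f"{self.cell_radius / (10.0 * self.v0):.4g} min"
            )

    @property
    def steps_per_frame(self) -> int:
        return int(round(self.frame_interval / self.dt))

    @property
    def packing_fraction(self) -> float:
        return self.n_cells * math.pi * self.cell_radius**2 / self.box_size**2


@dataclass
class MonolayerTrajectory:
    """Ground-truth cell tracks from one simulation.

    ``positions`` are periodic-wrapped into [0, box_size)^2;
    ``unwrapped_positions`` accumulate true displacements and are the
    ground truth for MSD.  Both have shape (n_frames, n_cells, 2) with the
    last axis ordered (x, y).
    """

    positions: np.ndarray
    unwrapped_positions: np.ndarray
    headings: np.ndarray
    config: SimulationConfig

    def __post_init__(self) -> None:
        t_expect = self.config.n_frames
        for arr in (self.positions, self.unwrapped_positions):
            if arr.shape != (t_expect, self.config.n_cells, 2):
                raise ValueError("trajectory arrays inconsistent with config")
        if self.headings.shape != (t_expect, self.config.n_cells):
            raise ValueError("headings inconsistent with config")

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in minutes."""
        return np.arange(self.config.n_frames) * self.config.frame_interval

    def save_csv(self, path) -> None:
        """Write tidy ground truth: frame, cell_id, x_um, y_um, x_unwrapped, y_unwrapped."""
        import pandas as pd

        t, n = self.positions.shape[:2]
        frames = np.repeat(np.arange(t), n)
        cells = np.tile(np.arange(n), t)
        pd.DataFrame(
            {
                "frame": frames,
                "cell_id": cells,
                "x_um": self.positions[..., 0].ravel(),
                "y_um": self.positions[..., 1].ravel(),
                "x_unwrapped": self.unwrapped_positions[..., 0].ravel(),
                "y_unwrapped": self.unwrapped_positions[..., 1].ravel(),
            }
        ).to_csv(path, index=False)


def _hex_lattice(n: int, box: float, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Jittered hexagonal lattice of n points in a periodic square box.

    Row count is forced even so the alternating half-column offsets tile
    periodically; surplus lattice sites are dropped at random.  Returns the
    points and the lattice spacing used for jitter scaling.
    """
    ny = max(2, int(round(math.sqrt(2.0 * n / math.sqrt(3.0)))))
    if ny % 2:
        ny += 1
    nx = max(1, int(math.ceil(n / ny)))
    ax, ay = box / nx, box / ny
    cols = np.arange(nx) * ax
    rows = np.arange(ny) * ay
    x = cols[None, :] + (np.arange(ny)[:, None] % 2) * (ax / 2.0)
    y = np.broadcast_to(rows[:, None], (ny, nx)).copy()
    pts = np.stack([x.ravel(), y.ravel()], axis=1)
    if len(pts) > n:
        keep = np.sort(rng.choice(len(pts), size=n, replace=False))
        pts = pts[keep]
    spacing = min(ax, ay)
    pts = pts + rng.normal(0.0, 0.05 * spacing, size=pts.shape)
    return np.mod(pts, box), spacing


def _pair_forces(pos: np.ndarray, box: float, radius: float, k: float) -> np.ndarray:
    """Harmonic repulsion velocities for all overlapping pairs (periodic)."""
    f = np.zeros_like(pos)
    if k == 0.0:
        return f
    tree = cKDTree(pos, boxsize=box)
    pairs = tree.query_pairs(2.0 * radius, output_type="ndarray")
    if len(pairs) == 0:
        return f
    i, j = pairs[:, 0], pairs[:, 1]
    delta = pos[i] - pos[j]
    delta -= box * np.round(delta / box)  # minimum image
    dist = np.hypot(delta[:, 0], delta[:, 1])
    # coincident centres: push apart along a fixed direction
    zero = dist < 1e-12
    if zero.any():
        delta[zero] = (1e-12, 0.0)
        dist[zero] = 1e-12
    overlap = 2.0 * radius - dist
    push = k * overlap / dist
    fx = push[:, None] * delta
    np.add.at(f, i, fx)
    np.add.at(f, j, -fx)
    return f


def simulate_monolayer(config: SimulationConfig) -> MonolayerTrajectory:
    """Integrate the active-Brownian monolayer and record it at frame cadence.

    Deterministic for a fixed ``config.rng_seed``.  Raises
    :class:`PackingError` when the requested density exceeds the hexagonal
    disk-packing bound, i.e. no non-overlapping initial placement exists.
    """
    phi = config.packing_fraction
    # non-interacting ensembles (stiffness 0) may overlap freely
    if config.repulsion_stiffness > 0 and phi > HEX_PACKING_LIMIT:
        raise PackingError(
            f"packing fraction {phi:.4f} exceeds the hexagonal bound "
            f"{HEX_PACKING_LIMIT:.4f}; reduce n_cells or cell_radius"
        )
    rng = np.random.default_rng(config.rng_seed)
    box = config.box_size
    pos, _ = _hex_lattice(config.n_cells, box, rng)
    upos = pos.copy()
    if config.collective_headings:
        theta = np.full(config.n_cells, rng.uniform(0.0, 2.0 * math.pi))
    else:
        theta = rng.uniform(0.0, 2.0 * math.pi, size=config.n_cells)

    n_rec = config.n_frames
    spf = config.steps_per_frame
    positions = np.empty((n_rec, config.n_cells, 2))
    unwrapped = np.empty_like(positions)
    headings = np.empty((n_rec, config.n_cells))
    positions[0], unwrapped[0], headings[0] = pos, upos, theta

    sigma_theta = math.sqrt(2.0 * config.d_r * config.dt)
    for frame in range(1, n_rec):
        for _ in range(spf):
            vel = config.v0 * np.stack([np.cos(theta), np.sin(theta)], axis=1)
            vel += _pair_forces(pos, box, config.cell_radius, config.repulsion_stiffness)
            step = vel * config.dt
            upos = upos + step
            pos = np.mod(pos + step, box)
            if sigma_theta > 0:
                if config.collective_headings:
                    theta = theta + sigma_theta * rng.standard_normal()
                else:
                    theta = theta + sigma_theta * rng.standard_normal(config.n_cells)
        positions[frame], unwrapped[frame], headings[frame] = pos, upos, theta
    return MonolayerTrajectory(positions, unwrapped, headings, config)


def drift_trajectory(
    config: SimulationConfig, velocity: tuple[float, float]
) -> MonolayerTrajectory:
    """Analytic trajectory in which every cell drifts at a fixed velocity.

    The initial placement is the same jittered hexagonal lattice the
    simulator uses; the motion is exactly ``r(t) = r(0) + v t`` with
    ``velocity`` in um/min.  Useful as a fixture whose MSD and V_RMS are
    known in closed form.
    """
    rng = np.random.default_rng(config.rng_seed)
    pos0, _ = _hex_lattice(config.n_cells, config.box_size, rng)
    t = (np.arange(config.n_frames) * config.frame_interval)[:, None, None]
    v = np.asarray(velocity, dtype=float)[None, None, :]
    unwrapped = pos0[None, :, :] + v * t
    positions = np.mod(unwrapped, config.box_size)
    headings = np.full(
        (config.n_frames, config.n_cells), math.atan2(v[0, 0, 1], v[0, 0, 0])
    )
    return MonolayerTrajectory(positions, unwrapped, headings, config)


def abp_msd_closed_form(lags: np.ndarray, v0: float, d_r: float) -> np.ndarray:
    """Closed-form 2-D active-Brownian MSD, the simulator's analytic oracle.

    MSD(t) = (2 v0^2 / d_r^2) (d_r t - 1 + e^{-d_r t}); the d_r -> 0 limit
    is the ballistic (v0 t)^2.
    """
    lags = np.asarray(lags, dtype=float)
    if d_r == 0:
        return (v0 * lags) ** 2
    x = d_r * lags
    return (2.0 * v0**2 / d_r**2) * (x - 1.0 + np.exp(-x))
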