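"""Trajectory integration and collective-dynamics statistics.

Velocity-field sequences are turned into tracer trajectories by seeding a
regular grid of virtual tracers at t = 0 and forward-integrating them
through the successive fields (explicit Euler with bilinear velocity
interpolation).  From the trajectories the three standard statistics of
collective monolayer dynamics are computed:

* MSD(dt)   = < | r_i(t + dt) - r_i(t) |^2 >                  (um^2)
* Q(dt)     = N^-1 sum_i w_i, with w_i = 1 when the displacement of
              tracer i over lag dt stays below a cutoff d_c    (unitless)
* V_RMS(t)  = sqrt( M^-1 sum_j |v_j(t)|^2 ) over the M valid
              grid vectors of one field                        (um/min)

The indicator w_i is implemented as the displacement-below-cutoff
criterion standard for the self-overlap order parameter; d_c defaults to
one final-pass PIV grid spacing in um.  Averages run over tracks and, by
default, over sliding time origins; a strict t = 0-origin mode is kept
for replication.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .piv import VelocityField

__all__ = [
    "TrajectorySet",
    "DynamicsSummary",
    "integrate_trajectories",
    "compute_msd",
    "compute_overlap",
    "compute_vrms",
    "default_overlap_cutoff",
    "summarize_dynamics",
    "trajectory_set_from_positions",
]


@dataclass
class TrajectorySet:
    """Grid-seeded tracer tracks integrated through velocity fields.

    ``r`` has shape (T, N, 2) in um (x, y); ``active`` marks, per time
    point and track, whether the tracer is still inside the field of view
    (a tracer that leaves is frozen at its last position and excluded from
    statistics thereafter).
    """

    r: np.ndarray
    times: np.ndarray
    active: np.ndarray
    seed_spacing: float

    def __post_init__(self) -> None:
        if self.r.ndim != 3 or self.r.shape[2] != 2:
            raise ValueError("r must have shape (T, N, 2)")
        if self.active.shape != self.r.shape[:2]:
            raise ValueError("active must have shape (T, N)")
        if len(self.times) != self.r.shape[0]:
            raise ValueError("times axis mismatch")
        if not np.isfinite(self.r[self.active]).all():
            raise ValueError("active positions must be finite")

    @property
    def n_tracks(self) -> int:
        return self.r.shape[1]

    @property
    def n_frames(self) -> int:
        return self.r.shape[0]


@dataclass
class DynamicsSummary:
    """Bundle of the three dynamics statistics for one movie."""

    lags: np.ndarray
    msd: np.ndarray
    q_overlap: np.ndarray
    d_c: float
    times: np.ndarray
    vrms: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: (statistic, lag_or_time_min, value)."""
        parts = [
            pd.DataFrame(
                {"statistic": "msd", "lag_or_time_min": self.lags, "value": self.msd}
            ),
            pd.DataFrame(
                {
                    "statistic": "q_overlap",
                    "lag_or_time_min": self.lags,
                    "value": self.q_overlap,
                }
            ),
            pd.DataFrame(
                {"statistic": "vrms", "lag_or_time_min": self.times, "value": self.vrms}
            ),
        ]
        return pd.concat(parts, ignore_index=True)


def default_overlap_cutoff(fields: list[VelocityField]) -> float:
    """One final-pass grid spacing in um — the default overlap cutoff d_c."""
    f = fields[0]
    if len(f.grid_x) > 1:
        return float((f.grid_x[1] - f.grid_x[0]) * f.pixel_size)
    return float(f.pixel_size)


def _check_geometry(fields: list[VelocityField]) -> None:
    f0 = fields[0]
    for f in fields[1:]:
        if not (
            np.array_equal(f.grid_x, f0.grid_x)
            and np.array_equal(f.grid_y, f0.grid_y)
            and f.pixel_size == f0.pixel_size
        ):
            raise ValueError("fields do not share grid geometry")


def integrate_trajectories(
    fields: list[VelocityField],
    seed_spacing: float | None = None,
    frame_interval: float | None = None,
) -> TrajectorySet:
    """Forward-integrate grid-seeded tracers through a field sequence.

    Tracers are seeded on a regular grid at the first field's time; the
    default spacing is the final-pass PIV grid spacing (one tracer per
    independent velocity estimate).  Per step the local velocity is
    bilinearly interpolated at the tracer position and the tracer advanced
    by ``v * frame_interval`` (explicit Euler).  Tracers leaving the
    gridded region are frozen and flagged inactive.

    ``frame_interval`` (min) defaults to the spacing of the field
    timestamps, or 1.0 when only one field is given.
    """
    if not fields:
        raise ValueError("need at least one velocity field")
    _check_geometry(fields)
    f0 = fields[0]
    px = f0.pixel_size
    gx_um = f0.grid_x * px
    gy_um = f0.grid_y * px
    if frame_interval is None:
        ts = [f.t for f in fields]
        frame_interval = float(ts[1] - ts[0]) if len(ts) > 1 else 1.0
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    if seed_spacing is None:
        seed_spacing = float(gx_um[1] - gx_um[0]) if len(gx_um) > 1 else px
    sx = np.arange(gx_um[0], gx_um[-1] + 1e-9, seed_spacing)
    sy = np.arange(gy_um[0], gy_um[-1] + 1e-9, seed_spacing)
    mx, my = np.meshgrid(sx, sy)
    pos = np.column_stack([mx.ravel(), my.ravel()]).astype(float)
    n = len(pos)
    t_steps = len(fields) + 1
    r = np.empty((t_steps, n, 2))
    active = np.zeros((t_steps, n), dtype=bool)
    r[0] = pos
    alive = np.ones(n, dtype=bool)
    active[0] = alive
    lo = np.array([gx_um[0], gy_um[0]])
    hi = np.array([gx_um[-1], gy_um[-1]])
    for k, f in enumerate(fields):
        interp_u = RegularGridInterpolator(
            (gy_um, gx_um), f.u, method="linear", bounds_error=False, fill_value=0.0
        )
        interp_v = RegularGridInterpolator(
            (gy_um, gx_um), f.v, method="linear", bounds_error=False, fill_value=0.0
        )
        pts = pos[:, ::-1]  # (y, x) ordering for the interpolator
        vel = np.column_stack([interp_u(pts), interp_v(pts)])
        new = pos + np.where(alive[:, None], vel, 0.0) * frame_interval
        out = (new < lo).any(axis=1) | (new > hi).any(axis=1)
        newly_frozen = alive & out
        new[newly_frozen] = pos[newly_frozen]
        alive = alive & ~out
        pos = new
        r[k + 1] = pos
        active[k + 1] = alive
    times = fields[0].t + np.arange(t_steps) * frame_interval
    return TrajectorySet(r=r, times=times, active=active, seed_spacing=float(seed_spacing))


def _pair_displacements(traj: TrajectorySet, lag_idx: int, sliding: bool):
    """Yield squared displacements (flat array) for one lag index."""
    t_max = traj.n_frames - lag_idx
    origins = range(t_max) if sliding else range(1)
    chunks = []
    for t0 in origins:
        ok = traj.active[t0 + lag_idx]  # active at t+dt implies active at t
        if not ok.any():
            continue
        d = traj.r[t0 + lag_idx, ok] - traj.r[t0, ok]
        chunks.append((d**2).sum(axis=1))
    if not chunks:
        return None
    return np.concatenate(chunks)


def compute_msd(
    traj: TrajectorySet,
    origin_policy: str = "sliding",
    max_lag_frames: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-squared displacement over tracks (and, by default, time origins).

    ``origin_policy`` is ``"sliding"`` (all time origins, better statistics
    on short movies) or ``"zero"`` (displacements from t = 0 only).
    ``max_lag_frames`` truncates the lag axis (useful on long movies).
    Returns (lags_min, msd_um2) with MSD(0) = 0.
    """
    if origin_policy not in ("sliding", "zero"):
        raise ValueError("origin_policy must be 'sliding' or 'zero'")
    if traj.n_frames < 2:
        raise ValueError("need at least two time points")
    if not traj.active[0].any():
        raise ValueError("no active tracks at t = 0; statistics are empty")
    dt = traj.times[1] - traj.times[0]
    sliding = origin_policy == "sliding"
    n_lags = traj.n_frames if max_lag_frames is None else min(
        traj.n_frames, max_lag_frames + 1
    )
    lags = np.arange(n_lags) * dt
    msd = np.zeros(n_lags)
    for k in range(1, n_lags):
        sq = _pair_displacements(traj, k, sliding)
        msd[k] = np.nan if sq is None else sq.mean()
    return lags, msd


def compute_overlap(
    traj: TrajectorySet,
    d_c: float,
    origin_policy: str = "sliding",
    max_lag_frames: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Self-overlap order parameter Q(dt).

    w_i = 1 when |r_i(t + dt) - r_i(t)| < d_c, else 0; Q is the track
    (and, by default, origin) average, so Q(0) = 1 by construction and
    Q is confined to [0, 1].
    """
    if d_c <= 0:
        raise ValueError("d_c must be positive")
    if origin_policy not in ("sliding", "zero"):
        raise ValueError("origin_policy must be 'sliding' or 'zero'")
    dt = traj.times[1] - traj.times[0] if traj.n_frames > 1 else 1.0
    sliding = origin_policy == "sliding"
    n_lags = traj.n_frames if max_lag_frames is None else min(
        traj.n_frames, max_lag_frames + 1
    )
    lags = np.arange(n_lags) * dt
    q = np.ones(n_lags)
    for k in range(1, n_lags):
        sq = _pair_displacements(traj, k, sliding)
        q[k] = np.nan if sq is None else float((sq < d_c**2).mean())
    return lags, q


def trajectory_set_from_positions(
    r: np.ndarray, frame_interval: float, seed_spacing: float = 1.0
) -> TrajectorySet:
    """Wrap raw (T, N, 2) positions (e.g. simulator ground truth) so the
    same MSD / Q machinery applies to them."""
    r = np.asarray(r, dtype=float)
    active = np.ones(r.shape[:2], dtype=bool)
    times = np.arange(r.shape[0]) * frame_interval
    return TrajectorySet(r=r, times=times, active=active, seed_spacing=seed_spacing)


def compute_vrms(fields: list[VelocityField]) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous root-mean-squared speed per field.

    V_RMS(t) = sqrt( M^-1 sum_j |v_j(t)|^2 ) over the valid grid vectors;
    a field with no valid vectors yields NaN with a warning.
    """
    if not fields:
        raise ValueError("need at least one velocity field")
    times = np.array([f.t for f in fields])
    vrms = np.empty(len(fields))
    for k, f in enumerate(fields):
        ok = f.valid
        if not ok.any():
            warnings.warn(f"field at t={f.t:g} min has no valid vectors", stacklevel=2)
            vrms[k] = np.nan
            continue
        vrms[k] = np.sqrt(np.mean(f.u[ok] ** 2 + f.v[ok] ** 2))
    return times, vrms


def summarize_dynamics(
    fields: list[VelocityField],
    d_c: float | None = None,
    seed_spacing: float | None = None,
    origin_policy: str = "sliding",
) -> DynamicsSummary:
    """Convenience wrapper: integrate tracers and compute all three statistics."""
    if d_c is None:
        d_c = default_overlap_cutoff(fields)
    traj = integrate_trajectories(fields, seed_spacing=seed_spacing)
    lags, msd = compute_msd(traj, origin_policy)
    _, q = compute_overlap(traj, d_c, origin_policy)
    times, vrms = compute_vrms(fields)
    return DynamicsSummary(lags=lags, msd=msd, q_overlap=q, d_c=d_c, times=times, vrms=vrms)
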