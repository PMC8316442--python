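"""Shared fixtures: textured images and small trajectory factories."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from jamscope.simulate import MonolayerTrajectory, SimulationConfig


def textured_image(shape: tuple[int, int], seed: int, sigma: float = 2.0) -> np.ndarray:
    """Smoothed random speckle — generic PIV-friendly texture."""
    rng = np.random.default_rng(seed)
    img = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    img -= img.min()
    return 50.0 + 150.0 * img / img.max()


@pytest.fixture
def texture():
    return textured_image


def manual_trajectory(
    centers: np.ndarray, box_size: float, n_cells: int | None = None
) -> MonolayerTrajectory:
    """Single-frame trajectory from explicit cell centres (um)."""
    centers = np.asarray(centers, dtype=float)
    n = len(centers) if n_cells is None else n_cells
    cfg = SimulationConfig(
        n_cells=n,
        box_size=box_size,
        v0=0.0,
        d_r=0.0,
        cell_radius=min(1.0, box_size / 10.0),
        repulsion_stiffness=0.0,
        dt=1.0,
        n_frames=1,
        frame_interval=1.0,
    )
    pos = centers[None, :, :]
    return MonolayerTrajectory(pos, pos.copy(), np.zeros((1, n)), cfg)


@pytest.fixture
def make_trajectory():
    return manual_trajectory
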