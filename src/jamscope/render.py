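"""Rasterisation of simulated monolayers: textured movie frames and label masks.

``render_frames`` paints every cell as a frozen pseudo-random speckle patch
(seeded per cell, constant across frames) filling a soft-edged disk of the
cell's physical radius, so windowed cross-correlation has intra-cell
texture to lock onto everywhere in the confluent layer — smooth blobs
would leave the correlation peak dominated by the slowly varying envelope
and make subpixel PIV ill-posed.  ``voronoi_masks``
rasterises the periodic Voronoi tessellation of the cell centres into an
integer label image, the synthetic stand-in for membrane-stained,
segmented cell borders.

The rendered window is an interior crop of the periodic box (centred), so
the velocimetry never sees wrap-around seams.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .image import ImageStack, LabelMask
from .simulate import MonolayerTrajectory

__all__ = ["RenderConfig", "render_frames", "voronoi_masks"]


@dataclass(frozen=True)
class RenderConfig:
    """How a trajectory is turned into pixels.

    ``pixel_size`` defaults to the 0.75488 um/px calibration of the
    acquisition setup the pipeline targets.  ``blob_sigma`` is the softness
    (px) of each cell's disk-shaped texture envelope edge;
    ``texture_amplitude`` and ``noise_sigma`` are in intensity counts of
    the output bit depth.
    """

    pixel_size: float = 0.75488
    image_shape: tuple[int, int] = (512, 512)
    blob_sigma: float = 2.0
    texture_amplitude: float = 90.0
    noise_sigma: float = 2.0
    bit_depth: int = 8
    background: float = 30.0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if len(self.image_shape) != 2 or min(self.image_shape) < 8:
            raise ValueError("image_shape must be (H, W) with H, W >= 8")

    @property
    def extent_um(self) -> tuple[float, float]:
        """Physical (height, width) of the rendered window in um."""
        return (self.image_shape[0] * self.pixel_size, self.image_shape[1] * self.pixel_size)


def _check_window(rc: RenderConfig, box: float) -> tuple[float, float]:
    h_um, w_um = rc.extent_um
    if h_um > box * (1 + 1e-9) or w_um > box * (1 + 1e-9):
        raise ValueError(
            f"rendered window {w_um:.1f} x {h_um:.1f} um does not fit the "
            f"{box:.1f} um periodic box"
        )
    # centre the crop in the box
    return (box - w_um) / 2.0, (box - h_um) / 2.0  # (origin_x, origin_y)


#: correlation length (px) of the intra-cell speckle; short enough that the
#: correlation peak is set by the speckle, not the cell envelope
_SPECKLE_SIGMA = 0.8
#: speckle contrast: intensity std as a fraction of the amplitude
_SPECKLE_CONTRAST = 0.4


def _cell_textures(
    n_cells: int, rc: RenderConfig, base_seed: int, radius_px: float
) -> np.ndarray:
    """One frozen speckle patch per cell: high-contrast smoothed noise
    filling a soft-edged disk of the cell's physical radius."""
    edge = max(rc.blob_sigma, 0.5)
    half = int(np.ceil(radius_px + 3.0 * edge + 2.0))
    size = 2 * half + 1
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    r = np.hypot(xx, yy)
    envelope = 1.0 / (1.0 + np.exp((r - radius_px) / edge))
    patches = np.empty((n_cells, size, size))
    for cid in range(n_cells):
        rng = np.random.default_rng(np.random.SeedSequence([base_seed, 7, cid]))
        speckle = ndimage.gaussian_filter(rng.standard_normal((size, size)), _SPECKLE_SIGMA)
        speckle = 0.5 + _SPECKLE_CONTRAST * speckle / speckle.std()
        patches[cid] = rc.texture_amplitude * np.clip(speckle, 0.0, 1.0) * envelope
    return patches


def render_frames(traj: MonolayerTrajectory, rc: RenderConfig) -> ImageStack:
    """Render a trajectory into a calibrated movie stack.

    Identical (trajectory, config) pairs reproduce identical pixels: the
    per-cell texture and the per-frame sensor noise are both derived
    deterministically from the simulation seed.
    """
    box = traj.config.box_size
    origin_x, origin_y = _check_window(rc, box)
    h, w = rc.image_shape
    n_frames, n_cells = traj.positions.shape[:2]
    radius_px = traj.config.cell_radius / rc.pixel_size
    patches = _cell_textures(n_cells, rc, traj.config.rng_seed, radius_px)
    half = (patches.shape[1] - 1) // 2
    max_count = 2**rc.bit_depth - 1
    out = np.empty((n_frames, h, w), dtype=np.uint8 if rc.bit_depth == 8 else np.uint16)

    for f in range(n_frames):
        img = np.full((h, w), float(rc.background))
        pos = traj.positions[f]
        for cid in range(n_cells):
            # periodic images so cells straddling the box edge still paint
            # into an interior window that spans (nearly) the whole box
            for ox in (-box, 0.0, box):
                for oy in (-box, 0.0, box):
                    px = (pos[cid, 0] + ox - origin_x) / rc.pixel_size - 0.5
                    py = (pos[cid, 1] + oy - origin_y) / rc.pixel_size - 0.5
                    if px < -half or px > w + half or py < -half or py > h + half:
                        continue
                    _stamp(img, patches[cid], px, py, half)
        if rc.noise_sigma > 0:
            rng = np.random.default_rng(
                np.random.SeedSequence([traj.config.rng_seed, 11, f])
            )
            img += rng.normal(0.0, rc.noise_sigma, size=img.shape)
        out[f] = np.clip(np.round(img), 0, max_count)
    return ImageStack(
        out,
        frame_interval=traj.config.frame_interval,
        pixel_size=rc.pixel_size,
        source_id=f"synthetic:seed={traj.config.rng_seed}",
    )


def _stamp(img: np.ndarray, patch: np.ndarray, px: float, py: float, half: int) -> None:
    """Add ``patch`` centred at subpixel position (px, py) into ``img``."""
    ix, iy = int(np.floor(px)), int(np.floor(py))
    fx, fy = px - ix, py - iy
    # cubic interpolation keeps the speckle spectrum under fractional
    # shifts (linear interpolation blurs it and aggravates peak locking)
    shifted = ndimage.shift(patch, (fy, fx), order=3, mode="constant", cval=0.0)
    size = patch.shape[0]
    y0, x0 = iy - half, ix - half
    ys0, xs0 = max(0, -y0), max(0, -x0)
    ye = min(size, img.shape[0] - y0)
    xe = min(size, img.shape[1] - x0)
    if ys0 >= ye or xs0 >= xe:
        return
    img[y0 + ys0 : y0 + ye, x0 + xs0 : x0 + xe] += shifted[ys0:ye, xs0:xe]


def voronoi_masks(
    traj: MonolayerTrajectory,
    frame: int,
    rc: RenderConfig,
    draw_boundaries: bool = False,
) -> LabelMask:
    """Rasterise the periodic Voronoi tessellation of one frame's centres.

    Every pixel is assigned ``cell index + 1`` of its nearest centre under
    the periodic metric, so the tessellation is space-filling: by default
    there is no background.  With ``draw_boundaries=True``, pixels adjacent
    to a different label are set to 0, giving (approximately 1-px) boundary
    lines.  Coincident centres are perturbed by ``1e-9 * box_size`` with a
    warning so the nearest-neighbour query is well defined.
    """
    if not 0 <= frame < traj.positions.shape[0]:
        raise IndexError(f"frame {frame} out of range")
    box = traj.config.box_size
    origin_x, origin_y = _check_window(rc, box)
    centers = np.mod(traj.positions[frame], box)
    # cKDTree with boxsize requires points strictly inside [0, box)
    centers = np.where(centers >= box, 0.0, centers)
    if len(centers) > 1:
        rounded = np.round(centers / (1e-9 * box)).astype(np.int64)
        _, first = np.unique(rounded, axis=0, return_index=True)
        dupes = np.setdiff1d(np.arange(len(centers)), first)
        if len(dupes):
            warnings.warn(
                f"{len(dupes)} coincident cell centres perturbed by 1e-9 box",
                stacklevel=2,
            )
            rng = np.random.default_rng(traj.config.rng_seed)
            centers[dupes] = np.mod(
                centers[dupes] + rng.normal(0, 1e-9 * box, (len(dupes), 2)), box
            )
    tree = cKDTree(centers, boxsize=box)
    h, w = rc.image_shape
    xs = np.mod(origin_x + (np.arange(w) + 0.5) * rc.pixel_size, box)
    ys = np.mod(origin_y + (np.arange(h) + 0.5) * rc.pixel_size, box)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    _, idx = tree.query(pts, workers=-1)
    labels = (idx.reshape(h, w) + 1).astype(np.uint16)
    if draw_boundaries:
        from skimage.segmentation import find_boundaries

        labels = labels.copy()
        labels[find_boundaries(labels, mode="inner")] = 0
    return LabelMask(labels, rc.pixel_size)
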