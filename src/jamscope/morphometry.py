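"""Cell-shape morphometry and the shape-index jamming call.

Per-cell shape index q = perimeter / sqrt(area) and aspect ratio
(major / minor best-fit-ellipse axis) are computed from integer label
masks.  Vertex-model theory places the rigidity (jamming) transition of a
confluent epithelium at a critical shape index p0 ~ 3.81; a monolayer
whose mean q lies below the threshold (default 3.813) is called jammed,
otherwise unjammed.

The perimeter uses a Crofton multi-directional intercept estimator
(:func:`crofton_perimeter`): by Crofton's formula the perimeter equals
pi/2 times the mean number of boundary intercepts of unit-spaced parallel
scan lines, averaged over line directions.  Naive boundary-pixel counting
overestimates perimeters of rasterised shapes by 5-10%, and few-direction
approximations bias axis-aligned edges by several percent; both would
systematically distort q near the jamming threshold.  Regular reference
shapes pin the estimator: a square has q = 4, a regular hexagon
q = 6 / sqrt(3 sqrt(3) / 2) ~ 3.722, a disk q = 2 sqrt(pi) ~ 3.545 (the
isoperimetric lower bound).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import h_minima
from skimage.segmentation import watershed

from .image import LabelMask

__all__ = [
    "CellShapeTable",
    "JammingCall",
    "EmptyMaskError",
    "JAMMING_THRESHOLD",
    "crofton_perimeter",
    "segment_membranes",
    "shape_metrics",
    "classify_jamming",
    "colorize_aspect_ratio",
]

#: default critical shape index of the jamming transition
JAMMING_THRESHOLD = 3.813


def crofton_perimeter(
    mask: np.ndarray, n_directions: int = 16, smoothing_sigma: float | None = None
) -> float:
    """Multi-directional Crofton perimeter of a binary mask, in pixels.

    Crofton's formula gives P = (pi / 2) * h * E_theta[I(theta)], where
    I(theta) counts intersections of the boundary with parallel lines of
    spacing h at angle theta.  The mask indicator is lightly smoothed, the
    image rotated (bilinear) for each of ``n_directions`` angles in
    [0, pi), and half-unit-spaced 0.5-level crossings are counted along
    scan rows; the smoothing suppresses spurious staircase crossings on
    scan lines nearly tangent to the boundary.  By default the smoothing
    scale grows with the object (max(0.8, 0.007 sqrt(area)) px), which
    keeps the relative staircase error — and hence the shape index —
    invariant under resampling.  Accurate to well under 1% for convex
    shapes with characteristic size >= 150 px.
    """
    ind = np.asarray(mask, dtype=float)
    if ind.ndim != 2:
        raise ValueError("mask must be 2-D")
    if smoothing_sigma is None:
        smoothing_sigma = max(0.8, 0.007 * float(np.sqrt(ind.sum())))
    pad = int(np.ceil(3 * smoothing_sigma)) + 1
    ind = np.pad(ind, pad)
    if smoothing_sigma > 0:
        ind = ndimage.gaussian_filter(ind, smoothing_sigma)
    total = 0.0
    oversample = 2  # scan-line spacing 0.5 px averages alignment jitter
    for k in range(n_directions):
        theta = 180.0 * k / n_directions
        if theta == 0.0:
            rot = ind
        else:
            rot = ndimage.rotate(ind, theta, order=1, reshape=True, prefilter=False)
        rot = ndimage.zoom(rot, (oversample, 1), order=1, prefilter=False)
        above = rot >= 0.5
        total += np.count_nonzero(above[:, 1:] != above[:, :-1]) / oversample
    return (np.pi / 2.0) * total / n_directions

#: labels smaller than this (px) carry no meaningful shape information
MIN_CELL_PIXELS = 9

#: tidy per-cell output columns
CellShapeTable = pd.DataFrame


class EmptyMaskError(ValueError):
    """Segmentation produced no cells."""


@dataclass(frozen=True)
class JammingCall:
    """Monolayer-level jamming classification.

    ``state`` is ``"jammed"`` iff ``mean_q < threshold`` (a tie counts as
    unjammed: at the critical point the tissue is marginally rigid and the
    call deliberately errs on the motile side).
    """

    mean_q: float
    threshold: float
    state: str
    n_cells: int

    def to_dict(self) -> dict:
        return {
            "mean_q": self.mean_q,
            "threshold": self.threshold,
            "state": self.state,
            "n_cells": self.n_cells,
        }


def segment_membranes(
    image: np.ndarray,
    seeds: np.ndarray | None = None,
    pixel_size: float = 1.0,
    smoothing_sigma: float = 2.0,
    h_rel: float = 0.1,
) -> LabelMask:
    """Seeded watershed segmentation of a membrane/F-actin image.

    The membrane signal (bright cell borders) is Gaussian-smoothed and
    flooded by watershed.  Markers are the supplied ``seeds`` — an (n, 2)
    array of (x, y) pixel coordinates, typically nuclei — or, when absent,
    the regional minima of the smoothed image after h-minima suppression
    at depth ``h_rel`` times the intensity range.  Raises
    :class:`EmptyMaskError` when no markers are found (e.g. a blank image).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    smooth = ndimage.gaussian_filter(img, smoothing_sigma)
    if seeds is not None:
        seeds = np.atleast_2d(np.asarray(seeds))
        if len(seeds) < 1:
            raise EmptyMaskError("empty seed list")
        markers = np.zeros(img.shape, dtype=np.int32)
        for k, (x, y) in enumerate(seeds, start=1):
            iy = int(np.clip(round(y), 0, img.shape[0] - 1))
            ix = int(np.clip(round(x), 0, img.shape[1] - 1))
            markers[iy, ix] = k
    else:
        rng_int = float(smooth.max() - smooth.min())
        if rng_int <= 0:
            raise EmptyMaskError("blank image: no intensity variation to segment")
        minima = h_minima(smooth, h_rel * rng_int)
        markers = cc_label(minima)
        if markers.max() == 0:
            raise EmptyMaskError("no regional minima found; is the image inverted?")
    labels = watershed(smooth, markers)
    return LabelMask(labels.astype(np.uint16), pixel_size)


def shape_metrics(mask: LabelMask, exclude_border: bool = True) -> CellShapeTable:
    """Per-cell area, perimeter, shape index and aspect ratio.

    area = pixel count * pixel_size^2; perimeter = Crofton 4-direction
    estimate * pixel_size; q = perimeter / sqrt(area); aspect ratio from
    the second-moment best-fit ellipse.  Labels touching the image border
    are flagged and, with ``exclude_border`` (the default), dropped —
    truncated cells bias q upward.  Labels below ``MIN_CELL_PIXELS`` are
    excluded with a warning.
    """
    labels = mask.labels
    px = mask.pixel_size
    rows = []
    tiny = 0
    h, w = labels.shape
    for rp in regionprops(labels):
        if rp.area < MIN_CELL_PIXELS:
            tiny += 1
            continue
        minr, minc, maxr, maxc = rp.bbox
        touches = minr == 0 or minc == 0 or maxr == h or maxc == w
        area = rp.area * px**2
        perimeter = crofton_perimeter(rp.image) * px
        minor = rp.axis_minor_length
        major = rp.axis_major_length
        rows.append(
            {
                "cell_id": rp.label,
                "area_um2": area,
                "perimeter_um": perimeter,
                "q": perimeter / np.sqrt(area),
                "aspect_ratio": major / minor if minor > 0 else np.nan,
                "centroid_x_um": (rp.centroid[1] + 0.5) * px,
                "centroid_y_um": (rp.centroid[0] + 0.5) * px,
                "touches_border": touches,
            }
        )
    if tiny:
        warnings.warn(
            f"excluded {tiny} label(s) below {MIN_CELL_PIXELS} px", stacklevel=2
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "area_um2",
            "perimeter_um",
            "q",
            "aspect_ratio",
            "centroid_x_um",
            "centroid_y_um",
            "touches_border",
        ],
    )
    if exclude_border:
        table = table[~table["touches_border"]].reset_index(drop=True)
    return table


def classify_jamming(
    table: CellShapeTable, threshold: float = JAMMING_THRESHOLD
) -> JammingCall:
    """Call jammed vs unjammed from the mean shape index of a cell table."""
    if len(table) == 0:
        raise ValueError("empty cell table: nothing to classify")
    mean_q = float(table["q"].mean())
    state = "jammed" if mean_q < threshold else "unjammed"
    return JammingCall(mean_q=mean_q, threshold=threshold, state=state, n_cells=len(table))


def colorize_aspect_ratio(
    mask: LabelMask,
    table: CellShapeTable,
    ar_range: tuple[float, float] = (1.0, 4.0),
    cmap: str = "viridis",
) -> np.ndarray:
    """RGB image with each cell filled by a colormap value for its aspect ratio.

    Aspect ratios are mapped linearly over ``ar_range`` (clipped at the
    ends); background/boundary pixels and unlisted labels stay black.
    Returns a uint8 (H, W, 3) array; the mapping is deterministic so
    identical inputs yield identical pixels.
    """
    import matplotlib

    lo, hi = ar_range
    if hi <= lo:
        raise ValueError("ar_range must be increasing")
    colormap = matplotlib.colormaps[cmap]
    lut_size = int(mask.labels.max()) + 1
    lut = np.zeros((lut_size, 3), dtype=np.uint8)
    for _, row in table.iterrows():
        lab = int(row["cell_id"])
        if lab >= lut_size or not np.isfinite(row["aspect_ratio"]):
            continue
        frac = np.clip((row["aspect_ratio"] - lo) / (hi - lo), 0.0, 1.0)
        lut[lab] = (np.asarray(colormap(frac)[:3]) * 255).astype(np.uint8)
    return lut[mask.labels]
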