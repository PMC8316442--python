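"""Core image containers and TIFF I/O.

Coordinate convention used throughout the package: x = column, y = row,
origin at the top-left pixel, velocities expressed in image coordinates.
Physical positions are in micrometres; the pixel centre of pixel (row i,
col j) sits at ((j + 0.5) * pixel_size, (i + 0.5) * pixel_size) relative to
the image origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile


@dataclass
class ImageStack:
    """A calibrated time-lapse image sequence.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Intensity images, any real dtype.
    frame_interval : float
        Time between consecutive frames, minutes.
    pixel_size : float
        Physical size of one pixel, micrometres.
    source_id : str
        Free-text provenance tag (file path, simulation id, ...).
    """

    frames: np.ndarray
    frame_interval: float
    pixel_size: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("ImageStack needs >= 2 frames of identical shape")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def save(self, path) -> None:
        tifffile.imwrite(path, self.frames, photometric="minisblack")

    @classmethod
    def load(cls, path, frame_interval: float, pixel_size: float) -> "ImageStack":
        frames = tifffile.imread(path)
        return cls(frames, frame_interval, pixel_size, source_id=str(path))


@dataclass
class LabelMask:
    """Integer-labelled segmentation with physical calibration.

    ``labels`` is a 2-D non-negative integer image; 0 marks background or
    boundary lines, each positive label one cell.
    """

    labels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D image")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def save(self, path) -> None:
        tifffile.imwrite(path, self.labels.astype(np.uint16), photometric="minisblack")

    @classmethod
    def load(cls, path, pixel_size: float) -> "LabelMask":
        return cls(tifffile.imread(path), pixel_size)
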