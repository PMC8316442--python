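"""Multi-pass FFT cross-correlation particle image velocimetry.

The scheme mirrors standard two-pass PIV practice: a coarse pass
(64 x 64 px interrogation windows, 50% overlap) whose validated vectors
are interpolated onto the finer grid and used as window-offset predictors
for the second pass (32 x 32 px).  Correlation is mean-subtracted circular
cross-correlation without zero-padding (the windows are texture-filled),
with a 3-point Gaussian subpixel peak fit falling back to a parabolic fit
when a neighbouring correlation sample is non-positive.

Sign convention: the returned displacement is the motion of frame b
relative to frame a, positive along +x (columns) and +y (rows).

Outlier handling uses the normalized median test against the
8-neighbourhood (epsilon = 0.1 px); flagged vectors are replaced by the
neighbourhood median.  Pixel displacements are calibrated to um/min via
``pixel_size / frame_interval``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .image import ImageStack

__all__ = [
    "PIVConfig",
    "VelocityField",
    "LowQualityFieldWarning",
    "cross_correlate_window",
    "piv_pass",
    "validate_vectors",
    "multipass_piv",
]


class LowQualityFieldWarning(UserWarning):
    """Raised when too few vectors in a field pass validation."""


@dataclass(frozen=True)
class PIVConfig:
    """Interrogation and validation settings.

    ``window_sizes`` must be strictly decreasing powers of two; the
    defaults reproduce the two-pass 64 -> 32 px, 50%-overlap scheme.
    ``outlier_threshold`` is the normalized-median-test statistic above
    which a vector is replaced; ``min_valid_fraction`` is the share of
    originally-valid vectors below which a field is flagged low-quality.
    """

    window_sizes: tuple[int, ...] = (64, 32)
    overlap_fraction: float = 0.5
    outlier_threshold: float = 2.0
    min_valid_fraction: float = 0.8
    eps_px: float = 0.1

    def __post_init__(self) -> None:
        ws = self.window_sizes
        if not ws or any(w < 4 or (w & (w - 1)) for w in ws):
            raise ValueError("window_sizes must be powers of two >= 4")
        if any(b >= a for a, b in zip(ws, ws[1:])):
            raise ValueError("window_sizes must be strictly decreasing")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.outlier_threshold <= 0 or self.eps_px < 0:
            raise ValueError("invalid validation settings")


@dataclass
class VelocityField:
    """One gridded instantaneous velocity field.

    ``grid_x``/``grid_y`` are 1-D window-centre coordinates in pixels
    (x = columns, y = rows); ``u``/``v`` are (ny, nx) velocity components.
    Units are px/frame straight out of a pass and um/min after
    calibration (``units`` records which).  ``t`` is the acquisition time
    of the first frame of the pair, in minutes.
    """

    grid_x: np.ndarray
    grid_y: np.ndarray
    u: np.ndarray
    v: np.ndarray
    valid: np.ndarray
    t: float = 0.0
    pixel_size: float = 1.0
    units: str = "px/frame"
    low_quality: bool = False
    replaced_fraction: float = 0.0

    def __post_init__(self) -> None:
        expected = (len(self.grid_y), len(self.grid_x))
        for arr in (self.u, self.v, self.valid):
            if arr.shape != expected:
                raise ValueError("field arrays inconsistent with grid")

    @property
    def M(self) -> int:
        """Number of grid vectors (the M of the V_RMS normalisation)."""
        return self.u.size

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def to_frame(self) -> pd.DataFrame:
        gx, gy = np.meshgrid(self.grid_x, self.grid_y)
        return pd.DataFrame(
            {
                "t_min": self.t,
                "grid_x_px": gx.ravel(),
                "grid_y_px": gy.ravel(),
                "u_um_min": self.u.ravel(),
                "v_um_min": self.v.ravel(),
                "valid": self.valid.ravel().astype(int),
            }
        )


def _subpixel_1d(c_m: float, c_0: float, c_p: float) -> float:
    """3-point Gaussian peak interpolation; parabolic fallback."""
    if c_m > 0 and c_0 > 0 and c_p > 0:
        lm, l0, lp = np.log(c_m), np.log(c_0), np.log(c_p)
        denom = 2.0 * (lm + lp - 2.0 * l0)
        if denom != 0:
            return float(np.clip((lm - lp) / denom, -1.0, 1.0))
    denom = 2.0 * (c_m + c_p - 2.0 * c_0)
    if denom != 0:
        return float(np.clip((c_m - c_p) / denom, -1.0, 1.0))
    return 0.0


def cross_correlate_window(
    win_a: np.ndarray, win_b: np.ndarray
) -> tuple[float, float, bool]:
    """Displacement of ``win_b`` relative to ``win_a`` by circular correlation.

    Returns ``(dx, dy, ok)``.  A constant (zero-variance) patch cannot be
    correlated; it yields ``(nan, nan, False)`` rather than an exception.
    """
    a = np.asarray(win_a, dtype=float)
    b = np.asarray(win_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("windows must be square and identically shaped")
    a = a - a.mean()
    b = b - b.mean()
    if not a.any() or not b.any():
        return float("nan"), float("nan"), False
    corr = np.fft.irfft2(np.fft.rfft2(b) * np.conj(np.fft.rfft2(a)), s=a.shape)
    n = a.shape[0]
    peak = int(np.argmax(corr))
    py, px = divmod(peak, n)

    def signed(idx: int) -> int:
        return idx - n if idx > n // 2 else idx

    c0 = corr[py, px]
    dx = signed(px) + _subpixel_1d(corr[py, (px - 1) % n], c0, corr[py, (px + 1) % n])
    dy = signed(py) + _subpixel_1d(corr[(py - 1) % n, px], c0, corr[(py + 1) % n, px])
    return float(dx), float(dy), True


def _tile_starts(extent: int, window: int, spacing: int) -> np.ndarray:
    """Top-left tile offsets; tiles that do not fully fit are dropped."""
    n = (extent - window) // spacing + 1
    return np.arange(n) * spacing


def piv_pass(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    window: int,
    overlap: float,
    predictor: tuple[np.ndarray, np.ndarray] | None = None,
) -> VelocityField:
    """One interrogation pass over a frame pair, in px/frame.

    With a ``predictor`` (``(u, v)`` arrays matching this pass's grid),
    each second-frame window is offset by the rounded predictor before
    correlation and the applied offset is added back.  Near the image
    border, where the shifted window would leave the frame, the remainder
    of the offset is applied to the first-frame window in the opposite
    direction, so edge tiles keep the full predictor benefit.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames must share a shape")
    h, w = a.shape
    if window > min(h, w):
        raise ValueError(f"window {window} exceeds image {a.shape}")
    spacing = max(1, int(round(window * (1.0 - overlap))))
    xs = _tile_starts(w, window, spacing)
    ys = _tile_starts(h, window, spacing)
    nx, ny = len(xs), len(ys)
    u = np.zeros((ny, nx))
    v = np.zeros((ny, nx))
    valid = np.zeros((ny, nx), dtype=bool)
    if predictor is not None:
        pu, pv = predictor
        if pu.shape != (ny, nx) or pv.shape != (ny, nx):
            raise ValueError("predictor shape does not match the pass grid")
    def _split_offset(desired: int, t0: int, extent: int) -> tuple[int, int]:
        """Split a window offset between frame b (+) and frame a (-)."""
        sb = int(np.clip(desired, -t0, extent - window - t0))
        sa = int(np.clip(sb - desired, -t0, extent - window - t0))
        return sa, sb

    for iy, y0 in enumerate(ys):
        for ix, x0 in enumerate(xs):
            sax = say = sbx = sby = 0
            if predictor is not None:
                dx0 = int(np.round(pu[iy, ix])) if np.isfinite(pu[iy, ix]) else 0
                dy0 = int(np.round(pv[iy, ix])) if np.isfinite(pv[iy, ix]) else 0
                sax, sbx = _split_offset(dx0, x0, w)
                say, sby = _split_offset(dy0, y0, h)
            win_a = a[y0 + say : y0 + say + window, x0 + sax : x0 + sax + window]
            win_b = b[y0 + sby : y0 + sby + window, x0 + sbx : x0 + sbx + window]
            dx, dy, ok = cross_correlate_window(win_a, win_b)
            if ok:
                u[iy, ix] = dx + sbx - sax
                v[iy, ix] = dy + sby - say
                valid[iy, ix] = True
            else:
                u[iy, ix] = np.nan
                v[iy, ix] = np.nan
    centre = (window - 1) / 2.0
    return VelocityField(
        grid_x=xs + centre, grid_y=ys + centre, u=u, v=v, valid=valid
    )


def validate_vectors(
    field: VelocityField,
    outlier_threshold: float = 2.0,
    eps_px: float = 0.1,
    min_valid_fraction: float = 0.8,
) -> VelocityField:
    """Normalized median test with neighbour-median replacement.

    Each component is compared against the median of its (up to 8) valid
    neighbours, normalised by the median absolute neighbour residual plus
    ``eps_px``.  Vectors whose statistic exceeds ``outlier_threshold`` on
    either component — and vectors already invalid — are replaced by the
    neighbourhood median and flagged replaced.  If fewer than
    ``min_valid_fraction`` of vectors were originally valid, the field is
    marked ``low_quality`` and a :class:`LowQualityFieldWarning` is emitted.
    """
    ny, nx = field.u.shape
    u, v = field.u.copy(), field.v.copy()
    ok = field.valid & np.isfinite(u) & np.isfinite(v)
    flagged = ~ok
    for comp in (u, v):
        stat = np.zeros((ny, nx))
        for iy in range(ny):
            for ix in range(nx):
                if not ok[iy, ix]:
                    continue
                nb = _neighbours(comp, ok, iy, ix)
                if nb.size < 3:
                    continue
                med = np.median(nb)
                resid = np.median(np.abs(nb - med))
                stat[iy, ix] = abs(comp[iy, ix] - med) / (resid + eps_px)
        flagged |= stat > outlier_threshold
    good = ok & ~flagged
    replaced_ok = np.zeros_like(flagged)
    for iy in range(ny):
        for ix in range(nx):
            if not flagged[iy, ix]:
                continue
            nb_u = _neighbours(u, good, iy, ix)
            nb_v = _neighbours(v, good, iy, ix)
            if nb_u.size:
                u[iy, ix] = np.median(nb_u)
                v[iy, ix] = np.median(nb_v)
                replaced_ok[iy, ix] = True
            else:
                u[iy, ix] = 0.0
                v[iy, ix] = 0.0
    valid_fraction = ok.mean() if ok.size else 0.0
    low_quality = valid_fraction < min_valid_fraction
    if low_quality:
        warnings.warn(
            f"only {valid_fraction:.0%} of vectors valid before replacement",
            LowQualityFieldWarning,
            stacklevel=2,
        )
    return VelocityField(
        grid_x=field.grid_x,
        grid_y=field.grid_y,
        u=u,
        v=v,
        valid=good | replaced_ok,  # replaced vectors are usable downstream
        t=field.t,
        pixel_size=field.pixel_size,
        units=field.units,
        low_quality=low_quality,
        replaced_fraction=flagged.mean() if flagged.size else 0.0,
    )


def _neighbours(arr: np.ndarray, ok: np.ndarray, iy: int, ix: int) -> np.ndarray:
    ny, nx = arr.shape
    vals = []
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == 0 and dx == 0:
                continue
            y, x = iy + dy, ix + dx
            if 0 <= y < ny and 0 <= x < nx and ok[y, x]:
                vals.append(arr[y, x])
    return np.asarray(vals)


def _interp_to_grid(
    field: VelocityField, gx: np.ndarray, gy: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear interpolation of a validated field onto a finer grid."""
    out = []
    tx = np.clip(gx, field.grid_x[0], field.grid_x[-1])
    ty = np.clip(gy, field.grid_y[0], field.grid_y[-1])
    mx, my = np.meshgrid(tx, ty)
    pts = np.column_stack([my.ravel(), mx.ravel()])
    for comp in (field.u, field.v):
        if len(field.grid_y) < 2 or len(field.grid_x) < 2:
            out.append(np.full((len(gy), len(gx)), float(np.nanmean(comp))))
            continue
        f = RegularGridInterpolator(
            (field.grid_y, field.grid_x), comp, method="linear"
        )
        out.append(f(pts).reshape(len(gy), len(gx)))
    return out[0], out[1]


def multipass_piv(stack: ImageStack, cfg: PIVConfig | None = None) -> list[VelocityField]:
    """Two-(or more-)pass PIV over every consecutive frame pair of a stack.

    Pass 1 runs at the coarsest window, is validated, and is bilinearly
    interpolated onto the next pass's grid as a window-offset predictor;
    the final validated pass is calibrated from px/frame to um/min via
    ``stack.pixel_size / stack.frame_interval``.  Returns one
    :class:`VelocityField` per frame pair, time-stamped with the first
    frame's acquisition time.
    """
    cfg = cfg or PIVConfig()
    scale = stack.pixel_size / stack.frame_interval
    fields: list[VelocityField] = []
    for k in range(stack.n_frames - 1):
        a, b = stack.frames[k], stack.frames[k + 1]
        fld: VelocityField | None = None
        for window in cfg.window_sizes:
            predictor = None
            if fld is not None:
                spacing = max(1, int(round(window * (1.0 - cfg.overlap_fraction))))
                xs = _tile_starts(a.shape[1], window, spacing) + (window - 1) / 2.0
                ys = _tile_starts(a.shape[0], window, spacing) + (window - 1) / 2.0
                predictor = _interp_to_grid(fld, xs, ys)
            raw = piv_pass(a, b, window, cfg.overlap_fraction, predictor)
            fld = validate_vectors(
                raw, cfg.outlier_threshold, cfg.eps_px, cfg.min_valid_fraction
            )
        assert fld is not None
        fld.u = fld.u * scale
        fld.v = fld.v * scale
        fld.t = k * stack.frame_interval
        fld.pixel_size = stack.pixel_size
        fld.units = "um/min"
        fields.append(fld)
    return fields


def fields_to_frame(fields: list[VelocityField]) -> pd.DataFrame:
    """Concatenate fields into one tidy table (t_min, grid, u, v, valid)."""
    return pd.concat([f.to_frame() for f in fields], ignore_index=True)


def save_speed_map(field: VelocityField, path, vmax: float | None = None) -> None:
    """Write a PNG colour map of |v| on the PIV grid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    speed = np.hypot(field.u, field.v)
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(speed, origin="upper", cmap="inferno", vmax=vmax)
    fig.colorbar(im, ax=ax, label=f"speed ({field.units})")
    ax.set_title(f"t = {field.t:g} min")
    fig.savefig(path, dpi=150)
    plt.close(fig)
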