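"""Strain elastograms on the measurement-window grid.

An elastogram is the axial strain (Dyy) of every measurement window for
one consecutive frame pair, laid out on the overlapping window grid.
Values follow the compression-positive display convention: systolic
wall compression is positive, diastolic dilation negative (the raw
engineering-strain sign is the opposite and is noted in metadata).
Missing windows (outside the segmented wall, skipped, or unconverged)
are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import io
from .io import WallMask
from .motion import AffineEstimateField

__all__ = ["WindowGrid", "build_grid", "Elastogram", "from_motion_field",
           "window_selection", "apply_segmentation", "median_filter_5x5",
           "render"]


@dataclass(frozen=True)
class WindowGrid:
    """Layout of overlapping measurement windows over a frame.

    Half-open windows: window (i, j) covers rows
    ``[ax_starts[i], ax_starts[i] + win_ax)`` and columns
    ``[lat_starts[j], lat_starts[j] + win_lat)``.
    """

    frame_shape: tuple[int, int]
    win_ax: int
    win_lat: int
    step_ax: int
    step_lat: int

    @property
    def ax_starts(self) -> np.ndarray:
        n = (self.frame_shape[0] - self.win_ax) // self.step_ax + 1
        return np.arange(n) * self.step_ax

    @property
    def lat_starts(self) -> np.ndarray:
        n = (self.frame_shape[1] - self.win_lat) // self.step_lat + 1
        return np.arange(n) * self.step_lat

    @property
    def n_windows(self) -> tuple[int, int]:
        return len(self.ax_starts), len(self.lat_starts)

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Window-centre image coordinates (axial, lateral), float."""
        return (self.ax_starts + (self.win_ax - 1) / 2.0,
                self.lat_starts + (self.win_lat - 1) / 2.0)


def build_grid(frame_shape: tuple[int, int], window: tuple[int, int],
               overlap: float | tuple[float, float]) -> WindowGrid:
    """Build the overlapping window layout.

    The step per axis is ``max(1, round((1 - overlap) * extent))`` (90 %
    overlap on a 70-sample window gives a 7-sample step); the window
    count per axis is ``floor((frame_extent - window_extent)/step) + 1``.
    """
    wa, wl = int(window[0]), int(window[1])
    if not np.isscalar(overlap):
        ov_ax, ov_lat = overlap  # type: ignore[misc]
    else:
        ov_ax = ov_lat = float(overlap)  # type: ignore[assignment]
    for ov in (ov_ax, ov_lat):
        if not 0.0 <= ov < 1.0:
            raise ValueError(f"overlap must be in [0, 1); got {ov}")
    if wa < 4 or wl < 4:
        raise ValueError("window extents must be >= 4 samples")
    if wa > frame_shape[0] or wl > frame_shape[1]:
        raise ValueError(
            f"window {(wa, wl)} does not fit in frame {frame_shape}")
    step_ax = max(1, round((1.0 - ov_ax) * wa))
    step_lat = max(1, round((1.0 - ov_lat) * wl))
    return WindowGrid(frame_shape=tuple(frame_shape), win_ax=wa, win_lat=wl,
                      step_ax=step_ax, step_lat=step_lat)


@dataclass
class Elastogram:
    """Axial-strain map on the window grid for one frame pair.

    ``values`` are compression-positive strains (fractions, not %);
    NaN marks missing windows.
    """

    values: np.ndarray
    grid: WindowGrid
    frame_pair_index: int = 0
    convention: str = "compression-positive"

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)


def from_motion_field(field: AffineEstimateField,
                      require_converged: bool = True) -> Elastogram:
    """Assemble an elastogram from per-window affine estimates.

    The raw engineering strain Dyy (stretch positive) is negated so
    that wall compression reads positive.
    """
    vals = -np.asarray(field.dyy, dtype=float)
    bad = field.missing.copy()
    if require_converged:
        bad |= ~field.converged
    vals = np.where(bad, np.nan, vals)
    vals = np.where(np.abs(vals) > 0.2, np.nan, vals)
    return Elastogram(values=vals, grid=field.grid,
                      frame_pair_index=field.frame_pair_index)


def window_selection(mask_frame: np.ndarray, grid: WindowGrid,
                     wall: str = "near") -> np.ndarray:
    """Boolean window-grid array: True where the window centre lies in
    the selected wall band (``"near"`` or ``"far"``)."""
    label = io.WALL_LABELS[wall]
    cy, cx = grid.centers()
    iy = np.clip(np.round(cy).astype(int), 0, mask_frame.shape[0] - 1)
    ix = np.clip(np.round(cx).astype(int), 0, mask_frame.shape[1] - 1)
    return mask_frame[np.ix_(iy, ix)] == label


def apply_segmentation(elast: Elastogram, mask: WallMask | np.ndarray,
                       wall: str = "near",
                       frame_index: int | None = None) -> Elastogram:
    """Restrict an elastogram to one wall band.

    Windows whose centre lies outside the selected label are set
    missing.  ``mask`` may be a full per-frame stack (the frame at
    ``frame_index``, default the elastogram's frame-pair index, is
    used) or a single label frame.
    """
    if isinstance(mask, WallMask):
        idx = elast.frame_pair_index if frame_index is None else frame_index
        mask_frame = mask.labels[idx]
    else:
        mask_frame = np.asarray(mask)
    if mask_frame.shape != elast.grid.frame_shape:
        raise ValueError(
            f"mask frame shape {mask_frame.shape} does not match frame "
            f"shape {elast.grid.frame_shape}")
    keep = window_selection(mask_frame, elast.grid, wall)
    vals = np.where(keep, elast.values, np.nan)
    return Elastogram(values=vals, grid=elast.grid,
                      frame_pair_index=elast.frame_pair_index,
                      convention=elast.convention)


def median_filter_5x5(elast: Elastogram, size: int = 5) -> Elastogram:
    """Median post-filter on the window grid.

    Each present cell is replaced by the median of the *present* values
    in its size x size neighbourhood; missing (NaN) cells stay missing
    and are simply left out of their neighbours' medians.  The grid is
    reflect-padded so edge cells see a full odd-sized block, which keeps
    the filter idempotent on piecewise-constant fields.
    """
    v = elast.values
    na, nl = v.shape
    h = size // 2
    pad = np.pad(v, h, mode="reflect") if min(na, nl) > h \
        else np.pad(v, h, mode="edge")
    out = np.full_like(v, np.nan)
    for i in range(na):
        for j in range(nl):
            if np.isnan(v[i, j]):
                continue
            block = pad[i:i + size, j:j + size]
            out[i, j] = np.nanmedian(block)
    return Elastogram(values=out, grid=elast.grid,
                      frame_pair_index=elast.frame_pair_index,
                      convention=elast.convention)


def render(elast: Elastogram, background: np.ndarray | None = None,
           ax=None, vmax: float | None = None, cmap: str = "RdBu"):
    """Overlay an elastogram on a B-mode background.

    Positive (compressive, systolic) strain maps to the blue half of
    the diverging scale, negative (dilative, diastolic) to the warm
    half; missing cells are transparent.  The colour bar reads percent
    strain.  Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if background is not None:
        ax.imshow(background, cmap="gray", aspect="auto",
                  extent=(0, background.shape[1], background.shape[0], 0))
    pct = elast.values * 100.0
    if vmax is None:
        vmax = float(np.nanmax(np.abs(pct))) if np.isfinite(pct).any() \
            else 1.0
        vmax = vmax or 1.0
    cy, cx = elast.grid.centers()
    half_ax = elast.grid.step_ax / 2.0
    half_lat = elast.grid.step_lat / 2.0
    masked = np.ma.masked_invalid(pct)
    im = ax.imshow(masked, cmap=cmap, vmin=-vmax, vmax=vmax, aspect="auto",
                   alpha=0.85, interpolation="nearest",
                   extent=(cx[0] - half_lat, cx[-1] + half_lat,
                           cy[-1] + half_ax, cy[0] - half_ax))
    cbar = ax.figure.colorbar(im, ax=ax)
    cbar.set_label("axial strain (%), compression positive")
    return ax
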