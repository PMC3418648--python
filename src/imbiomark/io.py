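"""Sequence, mask and result-table I/O.

The shared data model is :class:`RFSequence` — an ordered stack of 2D
echo-sample frames (axis 0 of each frame is axial/depth, axis 1 is
lateral/scan-line) plus its :class:`~imbiomark.config.AcquisitionConfig`.
RF sequences are stored in a single HDF5 container whose header carries
every acquisition field; wall masks are multi-page TIFF label stacks;
result tables are plain CSV.

Coordinate convention: axis 0 = axial (depth, increasing downward),
axis 1 = lateral; indices are 0-based and all window/ROI extents are
half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .config import AcquisitionConfig

# Wall-mask labels
BACKGROUND, NEAR_WALL, FAR_WALL, LUMEN = 0, 1, 2, 3
VALID_LABELS = frozenset({BACKGROUND, NEAR_WALL, FAR_WALL, LUMEN})
WALL_LABELS = {"near": NEAR_WALL, "far": FAR_WALL}


class FormatError(ValueError):
    """Raised when a file does not match the expected on-disk layout."""


@dataclass
class RFSequence:
    """A stack of echo frames with acquisition metadata.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, n_axial, n_lateral)
        Echo samples.  RF data are signed; B-mode data are in [0, 1].
    acq : AcquisitionConfig
        Acquisition parameters (axial spacing, pitch, frame rate ...).
    modality : {"RF", "BMODE"}
    """

    frames: np.ndarray
    acq: AcquisitionConfig
    modality: str = "RF"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise FormatError(
                f"frames must be 3-D (n_frames, axial, lateral); "
                f"got shape {self.frames.shape}")
        if self.frames.shape[0] < 2:
            raise FormatError("a sequence needs at least 2 frames")
        if self.modality not in ("RF", "BMODE"):
            raise FormatError(f"unknown modality {self.modality!r}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]  # type: ignore[return-value]


@dataclass
class WallMask:
    """Per-frame label grid: 0 background, 1 near wall, 2 far wall, 3 lumen."""

    labels: np.ndarray  # (n_frames, n_axial, n_lateral) uint8

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise FormatError("mask labels must be 3-D")
        extra = set(np.unique(self.labels)) - VALID_LABELS
        if extra:
            raise FormatError(f"mask contains invalid labels {sorted(extra)}")

    def validate_against(self, seq: RFSequence) -> None:
        if self.labels.shape != seq.frames.shape:
            raise FormatError(
                f"mask shape {self.labels.shape} does not match "
                f"sequence shape {seq.frames.shape}")


# ---------------------------------------------------------------------------
# unit conversion

def um_to_samples_axial(um: float, acq: AcquisitionConfig) -> int:
    """Convert an axial length in µm to samples (nearest integer, >= 1)."""
    return max(1, round(um / acq.axial_spacing_um))


def um_to_samples_lateral(um: float, acq: AcquisitionConfig) -> int:
    """Convert a lateral length in µm to scan lines (nearest integer, >= 1)."""
    return max(1, round(um / acq.lateral_pitch_um))


def window_um_to_samples(axial_um: float, lateral_um: float,
                         acq: AcquisitionConfig) -> tuple[int, int]:
    return (um_to_samples_axial(axial_um, acq),
            um_to_samples_lateral(lateral_um, acq))


# ---------------------------------------------------------------------------
# sequence container (HDF5)

_ACQ_ATTRS = [f.name for f in fields(AcquisitionConfig)]


def write_sequence(seq: RFSequence, path: str | Path) -> None:
    """Write a sequence to an HDF5 container (lossless for integer data)."""
    with h5py.File(path, "w") as h5:
        ds = h5.create_dataset("frames", data=seq.frames)
        ds.attrs["modality"] = seq.modality
        h5.attrs["n_frames"] = seq.n_frames
        for name in _ACQ_ATTRS:
            val = getattr(seq.acq, name)
            if val is not None:
                h5.attrs[name] = val


def read_sequence(path: str | Path) -> RFSequence:
    """Read a sequence written by :func:`write_sequence`.

    Raises
    ------
    FormatError
        If the header is incomplete or inconsistent with the payload,
        naming the offending field.
    """
    with h5py.File(path, "r") as h5:
        if "frames" not in h5:
            raise FormatError("missing dataset 'frames'")
        frames = h5["frames"][()]
        if "n_frames" not in h5.attrs:
            raise FormatError("missing header field 'n_frames'")
        n = int(h5.attrs["n_frames"])
        if n != frames.shape[0]:
            raise FormatError(
                f"header field 'n_frames' = {n} does not match payload "
                f"frame count {frames.shape[0]}")
        kw = {}
        for name in _ACQ_ATTRS:
            if name in h5.attrs:
                val = h5.attrs[name]
                kw[name] = val.item() if hasattr(val, "item") else val
        kw["n_frames"] = n
        modality = h5["frames"].attrs.get("modality", "RF")
        if isinstance(modality, bytes):
            modality = modality.decode()
    return RFSequence(frames=frames, acq=AcquisitionConfig(**kw),
                      modality=str(modality))


def quantize(seq: RFSequence) -> RFSequence:
    """Quantise real-valued frames to the configured bit depth.

    Signed (RF) data are mapped symmetrically around mid-scale; the
    internal pipeline stays real-valued, quantisation is export-only.
    """
    bits = int(seq.acq.bit_depth)
    levels = 2 ** bits
    f = np.asarray(seq.frames, dtype=float)
    peak = np.max(np.abs(f))
    if peak == 0:
        q = np.full(f.shape, levels // 2)
    else:
        half = levels / 2 - 0.5
        q = np.clip(np.round(levels / 2 - 0.5 + f / peak * half),
                    0, levels - 1)
    dtype = np.uint8 if bits <= 8 else np.uint16
    return RFSequence(frames=q.astype(dtype), acq=seq.acq,
                      modality=seq.modality)


# ---------------------------------------------------------------------------
# masks (multi-page TIFF label stacks)

def write_mask(mask: WallMask, path: str | Path) -> None:
    tifffile.imwrite(path, mask.labels.astype(np.uint8))


def read_mask(path: str | Path, seq: RFSequence | None = None) -> WallMask:
    """Read a label stack; if ``seq`` is given, validate shapes match."""
    labels = tifffile.imread(path)
    if labels.ndim == 2:
        labels = labels[None]
    mask = WallMask(labels=labels)
    if seq is not None:
        mask.validate_against(seq)
    return mask


def write_bmode_stack(seq: RFSequence, path: str | Path) -> None:
    """Export a B-mode sequence as an 8-bit multi-page TIFF."""
    img = np.clip(seq.frames, 0.0, 1.0)
    tifffile.imwrite(path, (img * 255 + 0.5).astype(np.uint8))


# ---------------------------------------------------------------------------
# result tables

def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a tidy result table as CSV with stable column order."""
    table.to_csv(path, index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
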