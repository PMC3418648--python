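"""Cyclic stiffness biomarkers from elastogram stacks.

The mean axial strain (MAS) curve is the ROI-averaged elastogram value
per consecutive frame pair, in percent strain, under the
compression-positive convention (systole positive, diastole negative).
From its detected cardiac cycles come the stiffness biomarkers:

* PSS / PDS — peak systolic / peak diastolic strain, each averaged over
  three cardiac cycles (rodent carotid RF protocol, 5 x 9-cell ROI in
  the near wall);
* MSS / MDS — mean systolic / mean diastolic strain over the positive-
  and negative-strain phases of each cycle (human ascending-aorta
  B-mode protocol, 3 x 9-cell ROI, near and far walls), with the
  reported mean strain (|MSS| + |MDS|) / 2.

Larger strain at a given pressure pulse means a more compliant wall, so
these biomarkers are inverse measures of stiffness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .elastogram import Elastogram

__all__ = ["MASCurve", "StiffnessSummary", "CycleDetectionError",
           "mas_curve", "detect_cycles", "summarize_stiffness",
           "pool_measurements"]


class CycleDetectionError(ValueError):
    """No periodic structure found in a MAS curve."""


@dataclass
class MASCurve:
    """ROI-mean axial strain per frame pair, in percent."""

    values: np.ndarray                 # (n_frames - 1,), % strain
    roi: tuple[slice, slice]           # window-grid cells
    wall: str = "near"
    gap_frames: np.ndarray = field(default_factory=lambda: np.array([], int))
    peaks: np.ndarray | None = None    # systolic peak indices
    troughs: np.ndarray | None = None  # diastolic trough indices
    period: float | None = None        # frames per cycle


@dataclass
class StiffnessSummary:
    """Pooled cyclic-stiffness biomarkers for one recording."""

    subject: str = ""
    group: str = ""
    label: str = ""            # side (rat: L/R) or wall (human: near/far)
    mode: str = "peak"         # "peak" (PSS/PDS) or "mean" (MSS/MDS)
    pss: float | None = None   # % strain, >= 0 (compression-positive)
    pds: float | None = None   # % strain magnitude
    mss: float | None = None   # % strain
    mds: float | None = None   # % strain (negative phase mean)
    mean_strain: float | None = None   # (|MSS| + |MDS|) / 2
    n_cycles_used: int = 3


def _auto_roi(stack: np.ndarray, roi_cells: tuple[int, int]
              ) -> tuple[slice, slice]:
    """Centre the ROI on the cell with the largest time-mean |strain|."""
    counts = np.sum(np.isfinite(stack), axis=0)
    sums = np.nansum(np.abs(stack), axis=0)
    score = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if not np.isfinite(score).any():
        raise ValueError("elastogram stack is entirely missing")
    ci, cj = np.unravel_index(int(np.nanargmax(score)), score.shape)
    ra, rl = roi_cells
    na, nl = score.shape
    i0 = int(np.clip(ci - ra // 2, 0, max(0, na - ra)))
    j0 = int(np.clip(cj - rl // 2, 0, max(0, nl - rl)))
    return slice(i0, min(i0 + ra, na)), slice(j0, min(j0 + rl, nl))


def mas_curve(elastograms: list[Elastogram] | np.ndarray,
              roi: tuple[int, int] | tuple[slice, slice] = (5, 9),
              wall: str = "near") -> MASCurve:
    """Mean axial strain over an ROI, per frame pair, in percent.

    ``roi`` is either an (axial, lateral) cell count — the ROI is then
    centred on the cell of maximum time-mean strain magnitude — or an
    explicit pair of window-grid slices.  Frame pairs whose ROI is
    entirely missing are flagged as gaps (NaN in the curve).
    """
    if isinstance(elastograms, np.ndarray):
        stack = np.asarray(elastograms, dtype=float)
    else:
        stack = np.stack([e.values for e in elastograms])
    if isinstance(roi[0], slice):
        sl = (roi[0], roi[1])
    else:
        sl = _auto_roi(stack, roi)  # type: ignore[arg-type]
    sub = stack[:, sl[0], sl[1]].reshape(stack.shape[0], -1)
    counts = np.sum(np.isfinite(sub), axis=1)
    vals = np.where(counts > 0,
                    np.nansum(sub, axis=1) / np.maximum(counts, 1),
                    np.nan) * 100.0
    gaps = np.flatnonzero(counts == 0)
    return MASCurve(values=vals, roi=sl, wall=wall, gap_frames=gaps)


def _period_from_autocorrelation(x: np.ndarray) -> float:
    x = x - np.mean(x)
    if np.all(x == 0):
        raise CycleDetectionError(
            "constant MAS curve has no cycles; supply the period manually")
    # biased autocorrelation: peak heights decay with lag, so the
    # global peak is the fundamental period, not a late multiple
    ac = np.correlate(x, x, mode="full")[x.size - 1:] / x.size
    cand, _ = find_peaks(ac[1:])
    cand = cand + 1
    cand = cand[cand <= 0.8 * x.size]
    if cand.size == 0:
        raise CycleDetectionError(
            "no periodicity detected in MAS curve; supply the period "
            "manually or provide an ECG channel")
    return float(cand[np.argmax(ac[cand])])


def detect_cycles(curve: MASCurve, expected_rate: float | None = None,
                  frame_rate: float | None = None,
                  ecg: np.ndarray | None = None) -> MASCurve:
    """Locate systolic peaks and diastolic troughs of each cardiac cycle.

    If an ECG series (sampled per frame) is given, cycles are gated by
    its R-peaks.  Otherwise the cycle period comes from the MAS
    autocorrelation peak (``expected_rate`` in beats/min with
    ``frame_rate`` frames/s may seed it instead).  One systolic maximum
    and one diastolic minimum are then extracted per cycle.
    """
    x = np.asarray(curve.values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 4:
        raise CycleDetectionError("too few valid MAS samples")
    xf = x.copy()
    xf[~finite] = np.nanmean(x)

    if ecg is not None:
        ecg = np.asarray(ecg, dtype=float)
        r_peaks, _ = find_peaks(ecg, prominence=0.5 * np.ptp(ecg))
        if r_peaks.size < 2:
            raise CycleDetectionError("fewer than 2 R-peaks in ECG channel")
        period = float(np.mean(np.diff(r_peaks)))
    elif expected_rate is not None and frame_rate is not None:
        period = frame_rate * 60.0 / expected_rate
    else:
        period = _period_from_autocorrelation(xf)
    if period < 2:
        raise CycleDetectionError(f"implausible cycle period {period}")

    # no prominence threshold: cycles truncated by the series ends have
    # arbitrarily small prominence.  The distance constraint (0.8 of a
    # period) allows one extremum per cycle, and the sign constraint
    # under the compression-positive convention removes ripple extrema
    # sitting in the wrong half-cycle.
    dist = max(2, int(round(0.8 * period)))
    mid = float(np.mean(xf))
    peaks, _ = find_peaks(xf, distance=dist)
    troughs, _ = find_peaks(-xf, distance=dist)
    peaks = peaks[xf[peaks] > mid]
    troughs = troughs[xf[troughs] < mid]
    if peaks.size < 2 or troughs.size < 2:
        raise CycleDetectionError(
            "fewer than 2 cycles detected; need at least 2")
    curve.peaks = peaks
    curve.troughs = troughs
    curve.period = period
    return curve


def _central(indices: np.ndarray, n: int, length: int) -> np.ndarray:
    """The n indices closest to the curve centre, in time order."""
    mid = (length - 1) / 2.0
    order = np.argsort(np.abs(indices - mid), kind="stable")[:n]
    return np.sort(indices[order])


def summarize_stiffness(curve: MASCurve, mode: str = "peak",
                        n_cycles_used: int = 3, *,
                        subject: str = "", group: str = "",
                        label: str = "") -> StiffnessSummary:
    """Average per-cycle strain biomarkers over the most central cycles.

    ``peak`` mode (rodent RF protocol): PSS is the mean of the chosen
    systolic peak values, PDS the mean magnitude of the diastolic
    troughs.  ``mean`` mode (human AA protocol): MSS/MDS are the means
    of the positive-/negative-strain samples of each chosen cycle,
    averaged over cycles, and mean_strain = (|MSS| + |MDS|) / 2.
    """
    if curve.peaks is None or curve.troughs is None:
        raise ValueError("run detect_cycles first")
    n_det = min(curve.peaks.size, curve.troughs.size)
    if n_det < n_cycles_used:
        raise ValueError(
            f"only {n_det} cycles detected; {n_cycles_used} required")
    x = np.asarray(curve.values, dtype=float)
    n = x.size
    peaks = _central(curve.peaks, n_cycles_used, n)
    troughs = _central(curve.troughs, n_cycles_used, n)
    out = StiffnessSummary(subject=subject, group=group, label=label,
                           mode=mode, n_cycles_used=n_cycles_used)
    if mode == "peak":
        out.pss = float(np.mean(x[peaks]))
        out.pds = float(np.mean(np.abs(x[troughs])))
    elif mode == "mean":
        # one cycle window per chosen systolic peak
        period = curve.period or float(np.mean(np.diff(curve.peaks)))
        half = period / 2.0
        mss_c, mds_c = [], []
        for p in peaks:
            lo = max(0, int(round(p - half)))
            hi = min(n, int(round(p + half)) + 1)
            seg = x[lo:hi]
            seg = seg[np.isfinite(seg)]
            pos, neg = seg[seg > 0], seg[seg < 0]
            if pos.size:
                mss_c.append(np.mean(pos))
            if neg.size:
                mds_c.append(np.mean(neg))
        if not mss_c or not mds_c:
            raise ValueError("cycle windows contain no signed-phase samples")
        out.mss = float(np.mean(mss_c))
        out.mds = float(np.mean(mds_c))
        out.mean_strain = 0.5 * (abs(out.mss) + abs(out.mds))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


def pool_measurements(summaries: pd.DataFrame, scheme: str
                      ) -> tuple[pd.DataFrame, int]:
    """Pool per-recording biomarkers into one tidy observation table.

    Schemes
    -------
    ``rat_side_phase``
        Input: one row per (subject, side in {L, R}) with ``pss`` and
        ``pds`` columns.  Sides and cycle phases (systole = PSS,
        diastole = PDS, both as magnitudes) are pooled, multiplying the
        effective observations per animal by 4.
    ``human_wall_triplicate``
        Input: one row per (subject, recording 1..3, wall in
        {near, far}) with a ``mean_strain`` column.  Walls and the
        triplicate recordings pool to 6 observations per subject.
    ``single``
        Identity: one observation per input row, multiplier 1.

    Returns the pooled long-format table (columns ``subject``,
    ``group``, factor columns, ``strain``) and the multiplier (the
    product of pooled factor level counts).
    """
    df = summaries.copy()
    if scheme == "rat_side_phase":
        for col in ("subject", "side", "pss", "pds"):
            if col not in df.columns:
                raise ValueError(f"scheme {scheme!r} needs column {col!r}")
        long = df.melt(
            id_vars=[c for c in ("subject", "group", "side") if c in df],
            value_vars=["pss", "pds"], var_name="phase", value_name="strain")
        long["phase"] = long["phase"].map({"pss": "systole",
                                           "pds": "diastole"})
        multiplier = df["side"].nunique() * 2
        return long.reset_index(drop=True), int(multiplier)
    if scheme == "human_wall_triplicate":
        for col in ("subject", "recording", "wall", "mean_strain"):
            if col not in df.columns:
                raise ValueError(f"scheme {scheme!r} needs column {col!r}")
        long = df.rename(columns={"mean_strain": "strain"})
        per_subject = (df.groupby("subject")
                       .apply(lambda g: g["recording"].nunique()
                              * g["wall"].nunique(),
                              include_groups=False))
        multiplier = int(per_subject.iloc[0])
        if not (per_subject == multiplier).all():
            raise ValueError("unbalanced recordings/walls across subjects")
        cols = [c for c in ("subject", "group", "recording", "wall",
                            "strain") if c in long.columns]
        return long[cols].reset_index(drop=True), multiplier
    if scheme == "single":
        value_col = next(c for c in ("strain", "mean_strain", "pss")
                         if c in df.columns)
        long = df.rename(columns={value_col: "strain"})
        return long.reset_index(drop=True), 1
    raise ValueError(f"unknown pooling scheme {scheme!r}")
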