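"""End-to-end convenience drivers tying the pipeline stages together.

These are thin orchestration helpers; each stage remains individually
usable (and tested) on its own.
"""

from __future__ import annotations

import numpy as np

from . import biomarkers, elastogram, io, motion

DEFAULT_WINDOW_UM = (108.0, 312.0)   # axial x lateral
DEFAULT_OVERLAP = 0.9


def track_sequence(seq: io.RFSequence, mask: io.WallMask | None = None,
                   wall: str = "near",
                   window_um: tuple[float, float] = DEFAULT_WINDOW_UM,
                   overlap: float = DEFAULT_OVERLAP, *,
                   search: tuple[int, int] = (6, 3),
                   median_filter: bool = True,
                   require_converged: bool = True
                   ) -> list[elastogram.Elastogram]:
    """Track every consecutive frame pair and assemble elastograms.

    The measurement-window size is given in µm (axial x lateral) and
    converted to samples through the acquisition geometry; windows are
    laid out with the configured overlap, restricted to the selected
    wall band when a mask is supplied, and each elastogram is
    median-post-filtered on the window grid.
    """
    win = io.window_um_to_samples(window_um[0], window_um[1], seq.acq)
    grid = elastogram.build_grid(seq.frame_shape, win, overlap)
    out: list[elastogram.Elastogram] = []
    for k in range(seq.n_frames - 1):
        select = None
        if mask is not None:
            select = elastogram.window_selection(mask.labels[k], grid, wall)
        fld = motion.estimate_frame_pair(
            seq.frames[k], seq.frames[k + 1], grid, select=select,
            search=search, frame_pair_index=k)
        el = elastogram.from_motion_field(fld,
                                          require_converged=require_converged)
        if median_filter:
            el = elastogram.median_filter_5x5(el)
        out.append(el)
    return out


def stiffness_from_elastograms(elastograms: list[elastogram.Elastogram],
                               roi: tuple[int, int] = (5, 9),
                               wall: str = "near", mode: str = "peak",
                               n_cycles_used: int = 3, *,
                               expected_rate: float | None = None,
                               frame_rate: float | None = None,
                               subject: str = "", group: str = "",
                               label: str = ""
                               ) -> tuple[biomarkers.MASCurve,
                                          biomarkers.StiffnessSummary]:
    """MAS curve, cycle detection and stiffness summary in one call."""
    curve = biomarkers.mas_curve(elastograms, roi=roi, wall=wall)
    curve = biomarkers.detect_cycles(curve, expected_rate=expected_rate,
                                     frame_rate=frame_rate)
    summary = biomarkers.summarize_stiffness(
        curve, mode=mode, n_cycles_used=n_cycles_used,
        subject=subject, group=group, label=label)
    return curve, summary
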