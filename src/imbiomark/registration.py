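"""Rigid pre-registration of B-mode sequences.

The ascending aorta rides on bulk cardiac and respiratory motion that
would swamp the small wall strains, so each frame is rigidly aligned
(two translations and one in-plane rotation about the image centre) to
a fixed reference frame before speckle tracking.  The transform
maximises normalised cross-correlation over a coarse grid of shifts
(1 sample) and rotations (0.5 deg), refined by a local quadratic fit.
Out-of-view samples after resampling are NaN-flagged and excluded from
downstream measurement windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .io import RFSequence
from .motion import DegenerateInputError, _parabolic_offset, ncc_surface

__all__ = ["RigidTransform", "register_frame", "apply_transform",
           "register_sequence"]

MAX_ROTATION_DEG = 15.0


@dataclass
class RigidTransform:
    """Axial/lateral shift in samples and rotation (deg, about centre)
    that map the moving frame onto the reference."""

    shift_ax: float
    shift_lat: float
    rotation_deg: float
    score: float = np.nan

    def __post_init__(self) -> None:
        if abs(self.rotation_deg) > MAX_ROTATION_DEG:
            raise ValueError(
                f"|rotation| must be <= {MAX_ROTATION_DEG} deg; "
                f"got {self.rotation_deg}")


def _rotate(frame: np.ndarray, angle_deg: float) -> np.ndarray:
    if abs(angle_deg) < 1e-12:
        return frame
    return ndi.rotate(frame, angle_deg, reshape=False, order=1,
                      mode="constant", cval=np.nan)


def apply_transform(frame: np.ndarray, t: RigidTransform) -> np.ndarray:
    """Resample a frame under a rigid transform (bilinear).

    Rotation about the image centre, then translation; samples pulled
    from outside the original field of view become NaN.
    """
    frame = np.asarray(frame, dtype=float)
    out = _rotate(frame, t.rotation_deg)
    if t.shift_ax != 0 or t.shift_lat != 0:
        out = ndi.shift(out, (t.shift_ax, t.shift_lat), order=1,
                        mode="constant", cval=np.nan)
    return out


def _nan_to_mean(frame: np.ndarray) -> np.ndarray:
    bad = np.isnan(frame)
    if bad.any():
        frame = frame.copy()
        frame[bad] = np.nanmean(frame)
    return frame


def register_frame(moving: np.ndarray, reference: np.ndarray, *,
                   max_shift: int = 8, max_angle: float = 3.0,
                   angle_step: float = 0.5) -> RigidTransform:
    """Find the rigid transform aligning ``moving`` to ``reference``.

    Exhaustive coarse search over rotations (``angle_step`` deg) and
    integer shifts (via an NCC lag surface), then parabolic refinement
    of shift and rotation around the best grid node.  The returned
    ``score`` is the refined-peak NCC.
    """
    moving = np.asarray(moving, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if moving.shape != reference.shape:
        raise ValueError("frames must share a shape")
    if np.ptp(reference[np.isfinite(reference)]) == 0 \
            or np.ptp(moving[np.isfinite(moving)]) == 0:
        raise DegenerateInputError("flat frame cannot be registered")

    ref = _nan_to_mean(reference)
    # score on an interior crop so rotation edge artefacts (NaN fills,
    # interpolation transients) cannot bias the angle comparison
    inset = min(int(np.ceil(np.deg2rad(max_angle)
                            * 0.5 * np.hypot(*moving.shape))) + 4,
                min(moving.shape) // 4)
    core = (slice(inset, moving.shape[0] - inset),
            slice(inset, moving.shape[1] - inset))

    def scan(angles):
        best = None
        scores = np.full(len(angles), -np.inf)
        for k, ang in enumerate(angles):
            rot = _nan_to_mean(_rotate(moving, ang))
            surf = ncc_surface(rot[core], ref[core], max_shift, max_shift)
            iu, iv = np.unravel_index(int(np.argmax(surf)), surf.shape)
            scores[k] = surf[iu, iv]
            if best is None or surf[iu, iv] > best[0]:
                best = (float(surf[iu, iv]), k, iu, iv, surf)
        return best, scores

    coarse = np.arange(-max_angle, max_angle + angle_step / 2, angle_step)
    (_, kc, _, _, _), _coarse_scores = scan(coarse)
    # fine pass: the best shift is re-found per angle, so the NCC peak
    # is smooth enough in angle for a parabolic fit
    fine_step = angle_step / 5.0
    lo = max(-max_angle, coarse[kc] - angle_step)
    hi = min(max_angle, coarse[kc] + angle_step)
    angles = np.arange(lo, hi + fine_step / 2, fine_step)
    best, angle_scores = scan(angles)
    score, k, iu, iv, surf = best
    angle_step = fine_step

    du = dv = 0.0
    dang = 0.0
    if score > 1.0 - 1e-9:
        # exact match at a grid node: refinement against
        # interpolation-smoothed neighbours would only bias it
        la = (surf.shape[0] - 1) // 2
        ll = (surf.shape[1] - 1) // 2
        return RigidTransform(shift_ax=float(iu - la),
                              shift_lat=float(iv - ll),
                              rotation_deg=float(angles[k]), score=score)
    if 0 < iu < surf.shape[0] - 1:
        du = _parabolic_offset(surf[iu - 1, iv], surf[iu, iv],
                               surf[iu + 1, iv])
    if 0 < iv < surf.shape[1] - 1:
        dv = _parabolic_offset(surf[iu, iv - 1], surf[iu, iv],
                               surf[iu, iv + 1])
    if 0 < k < angles.size - 1:
        dang = _parabolic_offset(angle_scores[k - 1], angle_scores[k],
                                 angle_scores[k + 1]) * angle_step

    la = (surf.shape[0] - 1) // 2
    ll = (surf.shape[1] - 1) // 2
    return RigidTransform(
        shift_ax=float(iu - la + du), shift_lat=float(iv - ll + dv),
        rotation_deg=float(angles[k] + dang), score=score)


def register_sequence(seq: RFSequence, *, reference_index: int = 0,
                      max_shift: int = 8, max_angle: float = 3.0,
                      angle_step: float = 0.5
                      ) -> tuple[RFSequence, list[RigidTransform]]:
    """Stabilise a sequence against a fixed reference frame.

    Each frame is registered to ``frames[reference_index]`` and
    resampled by bilinear interpolation; the inverse observed motion is
    applied, so the returned stack is in the reference frame's
    coordinates with NaNs where data left the field of view.
    """
    transforms: list[RigidTransform] = []
    ref = seq.frames[reference_index]
    out = np.empty_like(np.asarray(seq.frames, dtype=float))
    for i, frame in enumerate(seq.frames):
        try:
            t = register_frame(frame, ref, max_shift=max_shift,
                               max_angle=max_angle, angle_step=angle_step)
        except DegenerateInputError as err:
            raise DegenerateInputError(f"frame {i}: {err}") from err
        transforms.append(t)
        out[i] = apply_transform(frame, t)
    stabilized = RFSequence(frames=out, acq=seq.acq, modality=seq.modality)
    return stabilized, transforms
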