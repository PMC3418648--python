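"""Windowed affine speckle-motion estimation.

For each measurement window and consecutive frame pair, tissue motion is
modelled as affine: a point (x, y) in the window at time t maps to

    x' = x + T1 + Dxx (x - xc) + Dxy (y - yc)
    y' = y + T2 + Dyx (x - xc) + Dyy (y - yc)

in the frame at t + dt, where (xc, yc) is the window centre, (T1, T2)
are lateral/axial translations, Dxx/Dyy lateral/axial strain, and
Dxy/Dyx the shears.  Translations are first estimated by normalised
cross-correlation with parabolic subsample refinement; the full
parameter set is then refined by damped (Levenberg-style) iterative
least squares on the sum-of-squared-differences matching criterion,
warping the second window by quintic B-spline interpolation (cubic
accuracy is marginal at RF carrier frequencies; one order up makes the
interpolation error negligible against sub-percent strains).

``Dyy`` here is the raw engineering strain from t to t + dt (stretch
positive); the compression-positive display convention is applied at
the elastogram stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates, spline_filter
from scipy.signal import fftconvolve

__all__ = [
    "DegenerateInputError", "TranslationEstimate", "AffineMotionEstimate",
    "AffineEstimateField", "ncc_surface", "estimate_translation",
    "estimate_deformation", "estimate_frame_pair",
]

DELTA_BOUND = 0.2          # optimizer bound on each deformation entry
_MIN_VALID_FRACTION = 0.5  # window usable if at least this many pixels map


class DegenerateInputError(ValueError):
    """Raised on constant/flat inputs that carry no trackable texture."""


@dataclass
class TranslationEstimate:
    t1: float                 # lateral shift, samples
    t2: float                 # axial shift, samples
    peak_ncc: float
    converged: bool


@dataclass
class AffineMotionEstimate:
    """Affine window motion between consecutive frames."""

    t1: float
    t2: float
    dxx: float
    dxy: float
    dyx: float
    dyy: float
    residual: float           # final SSD normalised by window energy
    converged: bool

    @property
    def delta(self) -> np.ndarray:
        """2x2 deformation matrix [[Dxx, Dxy], [Dyx, Dyy]]."""
        return np.array([[self.dxx, self.dxy], [self.dyx, self.dyy]])


@dataclass
class AffineEstimateField:
    """Per-window estimates over a window grid for one frame pair."""

    grid: object                       # elastogram.WindowGrid
    t1: np.ndarray
    t2: np.ndarray
    dxx: np.ndarray
    dxy: np.ndarray
    dyx: np.ndarray
    dyy: np.ndarray
    residual: np.ndarray
    converged: np.ndarray              # bool
    missing: np.ndarray                # bool
    frame_pair_index: int = 0


# ---------------------------------------------------------------------------
# normalised cross-correlation

def ncc_surface(a: np.ndarray, b: np.ndarray, max_lag_ax: int,
                max_lag_lat: int) -> np.ndarray:
    """Zero-normalised cross-correlation of two equal-shape patches.

    ``surface[u + max_lag_ax, v + max_lag_lat]`` compares ``a[i, j]``
    against ``b[i + u, j + v]`` over their overlap, i.e. the peak lag is
    the displacement of the speckle pattern from ``a`` to ``b``.
    Overlap means/variances are computed with sliding sums so partial
    overlaps are normalised correctly.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"patch shapes differ: {a.shape} vs {b.shape}")
    ma, na = a.shape
    max_lag_ax = int(min(max_lag_ax, ma - 2))
    max_lag_lat = int(min(max_lag_lat, na - 2))

    ones_a = np.ones_like(a)
    ones_b = np.ones_like(b)
    af = a[::-1, ::-1]
    oaf = ones_a[::-1, ::-1]
    s_ab = fftconvolve(b, af)
    s_a = fftconvolve(ones_b, af)
    s_a2 = fftconvolve(ones_b, (a * a)[::-1, ::-1])
    s_b = fftconvolve(b, oaf)
    s_b2 = fftconvolve(b * b, oaf)
    n = fftconvolve(ones_b, oaf)

    r0, c0 = ma - 1, na - 1
    sl = (slice(r0 - max_lag_ax, r0 + max_lag_ax + 1),
          slice(c0 - max_lag_lat, c0 + max_lag_lat + 1))
    s_ab, s_a, s_a2, s_b, s_b2, n = (x[sl] for x in
                                     (s_ab, s_a, s_a2, s_b, s_b2, n))
    n = np.maximum(n, 1.0)
    cov = s_ab - s_a * s_b / n
    var_a = np.maximum(s_a2 - s_a ** 2 / n, 0.0)
    var_b = np.maximum(s_b2 - s_b ** 2 / n, 0.0)
    denom = np.sqrt(var_a * var_b)
    out = np.zeros_like(cov)
    ok = denom > 1e-12 * max(1.0, float(np.max(denom)))
    out[ok] = cov[ok] / denom[ok]
    return np.clip(out, -1.0, 1.0)


def _parabolic_offset(cm: float, c0: float, cp: float) -> float:
    denom = cm - 2.0 * c0 + cp
    if denom >= 0 or abs(denom) < 1e-15:
        return 0.0
    return float(np.clip(0.5 * (cm - cp) / denom, -0.5, 0.5))


def estimate_translation(win_t: np.ndarray, win_t2: np.ndarray,
                         max_lag: tuple[int, int] | None = None
                         ) -> TranslationEstimate:
    """Cross-correlation translation estimate with subsample refinement.

    The integer lag is the argmax of the normalised cross-correlation
    within the search range (default: half the window in each axis); a
    parabolic fit of the correlation peak in each axis refines it to
    subsample precision.  A peak on the search boundary is flagged
    non-converged.
    """
    win_t = np.asarray(win_t, dtype=float)
    win_t2 = np.asarray(win_t2, dtype=float)
    if np.ptp(win_t) == 0 or np.ptp(win_t2) == 0:
        raise DegenerateInputError("constant patch has no trackable texture")
    if max_lag is None:
        max_lag = (max(1, win_t.shape[0] // 2), max(1, win_t.shape[1] // 2))
    la, ll = max_lag
    surf = ncc_surface(win_t, win_t2, la, ll)
    la = (surf.shape[0] - 1) // 2
    ll = (surf.shape[1] - 1) // 2
    iu, iv = np.unravel_index(int(np.argmax(surf)), surf.shape)
    on_edge = iu in (0, surf.shape[0] - 1) or iv in (0, surf.shape[1] - 1)
    du = dv = 0.0
    if surf[iu, iv] > 1.0 - 1e-6:
        # exact match at an integer lag: refining against unrelated
        # neighbour correlations would only bias it
        return TranslationEstimate(
            t1=float(iv - ll), t2=float(iu - la),
            peak_ncc=float(surf[iu, iv]), converged=not on_edge)
    if not on_edge:
        du = _parabolic_offset(surf[iu - 1, iv], surf[iu, iv],
                               surf[iu + 1, iv])
        dv = _parabolic_offset(surf[iu, iv - 1], surf[iu, iv],
                               surf[iu, iv + 1])
    return TranslationEstimate(
        t1=float(iv - ll + dv), t2=float(iu - la + du),
        peak_ncc=float(surf[iu, iv]), converged=not on_edge)


# ---------------------------------------------------------------------------
# affine refinement

def _warp_coords(p: np.ndarray, yy: np.ndarray, xx: np.ndarray,
                 yc: float, xc: float) -> tuple[np.ndarray, np.ndarray]:
    t1, t2, dxx, dxy, dyx, dyy = p
    dx = xx - xc
    dy = yy - yc
    xw = xx + t1 + dxx * dx + dxy * dy
    yw = yy + t2 + dyx * dx + dyy * dy
    return yw, xw


def estimate_deformation(win_t: np.ndarray, win_t2: np.ndarray,
                         init: tuple[float, float] = (0.0, 0.0), *,
                         margin: int = 0, max_iter: int = 50,
                         tol: float = 1e-6,
                         bound: float = DELTA_BOUND) -> AffineMotionEstimate:
    """Fit the 6-parameter affine motion of a window between two times.

    Minimises the SSD between the window at t and the warped window at
    t + dt by damped iterative least squares, starting from the
    translation ``init`` and zero deformation.  ``win_t2`` may carry a
    symmetric ``margin`` of extra context samples on every side, which
    lets warped coordinates leave the nominal window without
    extrapolating.  Deterministic; never raises on non-convergence —
    the estimate is returned with ``converged=False``.
    """
    win_t = np.asarray(win_t, dtype=float)
    win_t2 = np.asarray(win_t2, dtype=float)
    na, nl = win_t.shape
    if win_t2.shape != (na + 2 * margin, nl + 2 * margin):
        raise ValueError(
            f"win_t2 shape {win_t2.shape} incompatible with window "
            f"{(na, nl)} and margin {margin}")
    if np.ptp(win_t) == 0 or np.ptp(win_t2) == 0:
        raise DegenerateInputError("constant patch has no trackable texture")

    yy, xx = np.meshgrid(np.arange(na, dtype=float),
                         np.arange(nl, dtype=float), indexing="ij")
    yc, xc = (na - 1) / 2.0, (nl - 1) / 2.0
    coef = spline_filter(win_t2, order=5, mode="mirror")
    gy, gx = np.gradient(win_t2)
    coef_gy = spline_filter(gy, order=5, mode="mirror")
    coef_gx = spline_filter(gx, order=5, mode="mirror")
    hi_y, hi_x = win_t2.shape[0] - 1.0, win_t2.shape[1] - 1.0
    energy = float(np.sum(win_t ** 2))
    energy = energy if energy > 0 else 1.0
    t_bound_y = na / 2.0 + margin
    t_bound_x = nl / 2.0 + margin

    def clip_params(p):
        q = p.copy()
        q[0] = np.clip(q[0], -t_bound_x, t_bound_x)
        q[1] = np.clip(q[1], -t_bound_y, t_bound_y)
        q[2:] = np.clip(q[2:], -bound, bound)
        return q

    def evaluate(p):
        yw, xw = _warp_coords(p, yy, xx, yc, xc)
        ys, xs = yw + margin, xw + margin
        valid = (ys >= 0) & (ys <= hi_y) & (xs >= 0) & (xs <= hi_x)
        coords = np.vstack([ys.ravel(), xs.ravel()])
        i2w = map_coordinates(coef, coords, order=5, prefilter=False,
                              mode="mirror").reshape(na, nl)
        r = np.where(valid, win_t - i2w, 0.0)
        return r, valid, coords

    p = clip_params(np.array([init[0], init[1], 0.0, 0.0, 0.0, 0.0]))
    r, valid, coords = evaluate(p)
    nv = int(valid.sum())
    if nv < max(12, int(_MIN_VALID_FRACTION * na * nl)):
        return AffineMotionEstimate(*p, residual=float(np.sum(r ** 2) / energy),
                                    converged=False)
    cost = float(np.sum(r ** 2))
    lam = 1e-3
    converged = False
    for _ in range(max_iter):
        gyw = map_coordinates(coef_gy, coords, order=5, prefilter=False,
                              mode="mirror").reshape(na, nl)
        gxw = map_coordinates(coef_gx, coords, order=5, prefilter=False,
                              mode="mirror").reshape(na, nl)
        dxg = xx - xc
        dyg = yy - yc
        # columns: d(I2w)/d(T1, T2, Dxx, Dxy, Dyx, Dyy)
        jac = np.stack([
            gxw, gyw, gxw * dxg, gxw * dyg, gyw * dxg, gyw * dyg,
        ], axis=-1)
        jac = jac * valid[..., None]
        jt = jac.reshape(-1, 6)
        jtj = jt.T @ jt
        jtr = jt.T @ r.ravel()
        step_ok = False
        first_delta = None
        for _damp in range(8):
            try:
                delta = np.linalg.solve(
                    jtj + lam * np.diag(np.maximum(np.diag(jtj), 1e-12)),
                    jtr)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            if first_delta is None:
                first_delta = float(np.max(np.abs(delta)))
            p_new = clip_params(p + delta)
            r_new, valid_new, coords_new = evaluate(p_new)
            cost_new = float(np.sum(r_new ** 2))
            if cost_new < cost:
                step_ok = True
                break
            lam *= 10.0
        if not step_ok:
            # stalled: at a numerical minimum if the (least-damped)
            # Gauss-Newton step was already tiny
            converged = first_delta is not None and first_delta < 1e-3
            break
        moved = float(np.max(np.abs(p_new - p)))
        p, r, valid, coords, cost = p_new, r_new, valid_new, coords_new, \
            cost_new
        lam = max(lam / 3.0, 1e-8)
        if moved < tol:
            converged = True
            break
    return AffineMotionEstimate(
        t1=float(p[0]), t2=float(p[1]), dxx=float(p[2]), dxy=float(p[3]),
        dyx=float(p[4]), dyy=float(p[5]),
        residual=float(cost / energy), converged=converged)


# ---------------------------------------------------------------------------
# frame-pair driver

def estimate_frame_pair(frame_t: np.ndarray, frame_t2: np.ndarray,
                        grid, *, select: np.ndarray | None = None,
                        search: tuple[int, int] | None = (6, 3),
                        margin: int = 4,
                        frame_pair_index: int = 0) -> AffineEstimateField:
    """Estimate affine motion for every window of a grid.

    ``select`` is an optional boolean array over the window grid;
    deselected windows (and windows touching NaN-flagged samples, e.g.
    out-of-view areas after registration) are marked missing rather
    than estimated.  ``search`` bounds the translation search in
    (axial, lateral) samples; None uses half the window.
    """
    frame_t = np.asarray(frame_t, dtype=float)
    frame_t2 = np.asarray(frame_t2, dtype=float)
    if frame_t.shape != frame_t2.shape:
        raise ValueError("frames must share a shape")
    n_ax, n_lat = grid.n_windows
    if n_ax == 0 or n_lat == 0:
        raise ValueError("empty window grid")
    shape = (n_ax, n_lat)
    out = AffineEstimateField(
        grid=grid,
        t1=np.full(shape, np.nan), t2=np.full(shape, np.nan),
        dxx=np.full(shape, np.nan), dxy=np.full(shape, np.nan),
        dyx=np.full(shape, np.nan), dyy=np.full(shape, np.nan),
        residual=np.full(shape, np.nan),
        converged=np.zeros(shape, dtype=bool),
        missing=np.ones(shape, dtype=bool),
        frame_pair_index=frame_pair_index)
    wa, wl = grid.win_ax, grid.win_lat
    fa, fl = frame_t.shape
    for i, y0 in enumerate(grid.ax_starts):
        for j, x0 in enumerate(grid.lat_starts):
            if select is not None and not select[i, j]:
                continue
            pt = frame_t[y0:y0 + wa, x0:x0 + wl]
            # symmetric context margin, shrunk at frame edges
            m = min(margin, y0, x0, fa - (y0 + wa), fl - (x0 + wl))
            m = max(m, 0)
            pt2 = frame_t2[y0 - m:y0 + wa + m, x0 - m:x0 + wl + m]
            if np.isnan(pt).any() or np.isnan(pt2).any():
                continue
            if np.ptp(pt) == 0 or np.ptp(pt2) == 0:
                continue
            inner2 = frame_t2[y0:y0 + wa, x0:x0 + wl]
            if np.ptp(inner2) == 0:
                continue
            tr = estimate_translation(pt, inner2, max_lag=search)
            est = estimate_deformation(pt, pt2, init=(tr.t1, tr.t2),
                                       margin=m)
            out.t1[i, j] = est.t1
            out.t2[i, j] = est.t2
            out.dxx[i, j] = est.dxx
            out.dxy[i, j] = est.dxy
            out.dyx[i, j] = est.dyx
            out.dyy[i, j] = est.dyy
            out.residual[i, j] = est.residual
            out.converged[i, j] = est.converged
            out.missing[i, j] = False
    return out
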