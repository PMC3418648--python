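"""Shared fixtures: band-limited speckle patches and exact affine warps.

Speckle test pairs are built by warping discrete samples in the same
B-spline space the estimator interpolates in, so the affine matching
model holds exactly and accuracy checks measure the estimator, not the
fixture.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter, map_coordinates

from imbiomark.config import AcquisitionConfig, PhantomConfig


def smooth_speckle(rng: np.random.Generator, shape: tuple[int, int],
                   sigma: float = 1.0) -> np.ndarray:
    """Band-limited correlated-noise patch (fully developed speckle)."""
    return gaussian_filter(rng.standard_normal(shape), sigma)


def warp_affine(patch: np.ndarray, t1: float = 0.0, t2: float = 0.0,
                dxx: float = 0.0, dxy: float = 0.0, dyx: float = 0.0,
                dyy: float = 0.0, order: int = 5) -> np.ndarray:
    """Window at time t whose affine match to ``patch`` (time t+dt) is
    exact in spline space: returns I_t with
    I_t(y, x) = patch(y + T2 + Dyx(x-xc) + Dyy(y-yc),
                      x + T1 + Dxx(x-xc) + Dxy(y-yc))."""
    na, nl = patch.shape
    yy, xx = np.meshgrid(np.arange(na, dtype=float),
                         np.arange(nl, dtype=float), indexing="ij")
    yc, xc = (na - 1) / 2.0, (nl - 1) / 2.0
    xw = xx + t1 + dxx * (xx - xc) + dxy * (yy - yc)
    yw = yy + t2 + dyx * (xx - xc) + dyy * (yy - yc)
    return map_coordinates(patch, [yw.ravel(), xw.ravel()], order=order,
                           mode="mirror").reshape(na, nl)


@pytest.fixture(scope="session")
def default_acq() -> AcquisitionConfig:
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def tiny_phantom() -> PhantomConfig:
    """Small, fast phantom used by unit tests (not the study conditions)."""
    return PhantomConfig(n_lines=12, lumen_diameter_um=400.0,
                         wall_thickness_um=120.0, margin_um=100.0,
                         scatterer_density_per_mm2=1500.0, n_cycles=3,
                         noise_level=0.05, seed=7)


@pytest.fixture(scope="session")
def tiny_sequence(tiny_phantom, default_acq):
    from imbiomark import phantom
    return phantom.generate_sequence(tiny_phantom, default_acq)
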