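"""Synthetic pulsating-vessel speckle phantom.

Emulates a longitudinal ultrasound view of an artery: two echogenic wall
bands (near and far) around a hypoechoic lumen, embedded in an anechoic
margin.  Over each cardiac cycle both walls undergo a through-thickness
axial compression following a raised-cosine time profile, the lumen
dilating in step; scatterers are displaced by the analytic field and RF
frames are rendered as a sum of separable point-spread functions
(Gaussian-windowed cosine axially, Gaussian laterally).  The exact
inter-frame wall strain is exported as ground truth so every downstream
tracking stage can be validated without real recordings.

Sign convention: exported true strain is *compression-positive* — wall
thinning (systole) gives positive values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.signal import hilbert

from . import io
from .config import AcquisitionConfig, ConfigurationError, PhantomConfig

__all__ = [
    "ScattererSet", "PhantomGroundTruth", "vessel_boundaries", "image_shape",
    "compression_amplitude", "generate_scatterers", "deform_scatterers",
    "render_rf_frame", "render_bmode", "envelope_db", "generate_sequence",
    "n_frames_for",
]


@dataclass
class ScattererSet:
    """Point scatterers at rest: positions in µm, echogenicity amplitudes."""

    y_um: np.ndarray      # axial (depth) position
    x_um: np.ndarray      # lateral position
    amplitude: np.ndarray
    region: np.ndarray    # io.NEAR_WALL / io.FAR_WALL / io.LUMEN

    def __len__(self) -> int:
        return self.y_um.size


@dataclass
class PhantomGroundTruth:
    """Analytic truth exported with a generated sequence.

    ``true_strain[k]`` is the engineering axial strain of the wall
    between frames k and k+1, compression-positive.  ``masks`` holds
    per-frame wall/lumen label grids, ``phase`` the cardiac phase of
    each frame in [0, 1).
    """

    true_strain: np.ndarray          # (n_frames - 1,)
    masks: io.WallMask               # per-frame labels
    phase: np.ndarray                # (n_frames,)
    cumulative_compression: np.ndarray  # (n_frames,)


# ---------------------------------------------------------------------------
# geometry and kinematics

def vessel_boundaries(phantom: PhantomConfig) -> dict[str, float]:
    """Rest-state depth (µm) of the four wall boundaries."""
    m, w, lum = phantom.margin_um, phantom.wall_thickness_um, \
        phantom.lumen_diameter_um
    return {
        "near_outer": m,
        "near_inner": m + w,
        "far_inner": m + w + lum,
        "far_outer": m + 2 * w + lum,
    }


def image_shape(phantom: PhantomConfig, acq: AcquisitionConfig
                ) -> tuple[int, int]:
    """(n_axial_samples, n_lateral_lines) of the rendered frames."""
    n_ax = int(math.ceil(phantom.image_depth_um / acq.axial_spacing_um))
    return n_ax, int(phantom.n_lines)


def n_frames_for(phantom: PhantomConfig, acq: AcquisitionConfig) -> int:
    """ceil(n_cycles * frame_rate * 60 / heart_rate)."""
    n = int(math.ceil(phantom.n_cycles * acq.frame_rate * 60.0
                      / phantom.heart_rate))
    if n < 2:
        raise ConfigurationError(
            f"configuration yields {n} frame(s); need at least 2 "
            "(increase n_cycles or frame_rate, or lower heart_rate)")
    return n


def frame_phases(phantom: PhantomConfig, acq: AcquisitionConfig,
                 n_frames: int | None = None) -> np.ndarray:
    """Cardiac phase in [0, 1) of each frame."""
    if n_frames is None:
        n_frames = n_frames_for(phantom, acq)
    dphi = phantom.heart_rate / (60.0 * acq.frame_rate)
    return (np.arange(n_frames) * dphi) % 1.0


def _raised_cosine(phase: np.ndarray | float) -> np.ndarray | float:
    """Unit raised-cosine cycle shape: 0 at phase 0, 1 at phase 0.5."""
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * np.asarray(phase)))


def compression_amplitude(phantom: PhantomConfig, acq: AcquisitionConfig
                          ) -> float:
    """Cumulative raised-cosine compression amplitude.

    Solved so that the peak *inter-frame* engineering strain magnitude
    over the actual frame grid equals ``phantom.peak_axial_strain``
    exactly.
    """
    peak = phantom.peak_axial_strain
    if peak == 0:
        return 0.0
    phases = frame_phases(phantom, acq)
    u = np.asarray(_raised_cosine(phases))

    def peak_pair_strain(amp: float) -> float:
        c = amp * u
        return float(np.max(np.abs((c[1:] - c[:-1]) / (1.0 - c[:-1]))))

    max_du = float(np.max(u[1:] - u[:-1]))
    if max_du <= 0:
        raise ConfigurationError(
            "frame grid never samples a compressing phase; cannot reach "
            "the requested peak strain")
    hi = min(0.45, 2.0 * peak / max_du)
    if peak_pair_strain(hi) < peak:
        raise ConfigurationError(
            f"peak_axial_strain={peak} unreachable with this frame timing")
    return float(brentq(lambda a: peak_pair_strain(a) - peak, 0.0, hi,
                        xtol=1e-14))


def cumulative_compression(phase, amplitude: float):
    """Wall through-thickness compression c(phase) = A * raised-cosine."""
    return amplitude * _raised_cosine(phase)


def generate_scatterers(phantom: PhantomConfig, acq: AcquisitionConfig,
                        rng: np.random.Generator | None = None
                        ) -> ScattererSet:
    """Draw scatterer positions and amplitudes for the rest-state vessel.

    Counts in each region are Poisson with mean density x area; positions
    are uniform within the region; amplitudes are zero-mean Gaussian,
    wall amplitudes scaled by the wall-to-lumen echogenicity ratio.
    Reproducible from ``phantom.seed`` when ``rng`` is not supplied.
    """
    if rng is None:
        rng = np.random.default_rng(phantom.seed)
    b = vessel_boundaries(phantom)
    lat_extent_um = phantom.n_lines * acq.lateral_pitch_um
    if phantom.image_depth_um <= 0 or lat_extent_um <= 0:
        raise ConfigurationError("degenerate phantom geometry")

    wall_density = phantom.scatterer_density_per_mm2
    lumen_density = (phantom.lumen_density_per_mm2
                     if phantom.lumen_density_per_mm2 is not None
                     else wall_density)
    regions = [
        (io.NEAR_WALL, b["near_outer"], b["near_inner"], wall_density,
         phantom.wall_to_lumen_echogenicity_ratio),
        (io.LUMEN, b["near_inner"], b["far_inner"], lumen_density, 1.0),
        (io.FAR_WALL, b["far_inner"], b["far_outer"], wall_density,
         phantom.wall_to_lumen_echogenicity_ratio),
    ]
    ys, xs, amps, labs = [], [], [], []
    for label, y0, y1, density, gain in regions:
        area_mm2 = (y1 - y0) * lat_extent_um * 1e-6
        n = int(rng.poisson(density * area_mm2))
        ys.append(rng.uniform(y0, y1, n))
        xs.append(rng.uniform(0.0, lat_extent_um, n))
        amps.append(gain * rng.standard_normal(n))
        labs.append(np.full(n, label, dtype=np.uint8))
    return ScattererSet(
        y_um=np.concatenate(ys), x_um=np.concatenate(xs),
        amplitude=np.concatenate(amps), region=np.concatenate(labs))


def deform_scatterers(scatterers: ScattererSet, phase: float,
                      phantom: PhantomConfig,
                      acq: AcquisitionConfig | None = None,
                      amplitude: float | None = None) -> ScattererSet:
    """Displace scatterers to the given cardiac phase.

    Wall scatterers follow a uniform through-thickness axial compression
    anchored at each wall's outer boundary; lumen scatterers move
    rigidly with the inner boundary of their nearer wall (the lumen
    dilates as the walls thin).  The displacement field is analytic.
    """
    if amplitude is None:
        if acq is None:
            raise ValueError("provide acq to derive the compression "
                             "amplitude, or pass amplitude explicitly")
        amplitude = compression_amplitude(phantom, acq)
    c = float(cumulative_compression(phase, amplitude))
    b = vessel_boundaries(phantom)
    w = phantom.wall_thickness_um
    y0 = scatterers.y_um
    y = y0.copy()

    near = scatterers.region == io.NEAR_WALL
    far = scatterers.region == io.FAR_WALL
    lum = scatterers.region == io.LUMEN
    # walls: uniform strain anchored at the outer boundary
    y[near] = b["near_outer"] + (y0[near] - b["near_outer"]) * (1.0 - c)
    y[far] = b["far_outer"] - (b["far_outer"] - y0[far]) * (1.0 - c)
    # lumen halves ride rigidly on the adjacent inner boundary
    mid = 0.5 * (b["near_inner"] + b["far_inner"])
    top = lum & (y0 < mid)
    bot = lum & ~top
    y[top] = y0[top] - w * c
    y[bot] = y0[bot] + w * c
    return ScattererSet(y_um=y, x_um=scatterers.x_um,
                        amplitude=scatterers.amplitude,
                        region=scatterers.region)


# ---------------------------------------------------------------------------
# rendering

def _axial_sigma_samples(acq: AcquisitionConfig) -> float:
    # Gaussian pulse envelope whose -6 dB (half-amplitude) spectral full
    # width equals the fractional bandwidth times the centre frequency.
    bw_hz = acq.fractional_bandwidth * acq.center_frequency
    sigma_t = math.sqrt(2.0 * math.log(2.0)) / (math.pi * bw_hz)
    return sigma_t * acq.sampling_frequency


def _lateral_sigma_lines(phantom: PhantomConfig,
                         acq: AcquisitionConfig) -> float:
    sigma_um = phantom.lateral_beam_fwhm_um / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    return sigma_um / acq.lateral_pitch_um


def render_rf_frame(scatterers: ScattererSet, phantom: PhantomConfig,
                    acq: AcquisitionConfig, *,
                    noise_std: float | None = None,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Render one RF frame from a (possibly deformed) scatterer set.

    Each scatterer contributes a separable point-spread function: a
    Gaussian-windowed cosine at the centre frequency axially and a
    Gaussian of configurable -6 dB width laterally.  White Gaussian
    noise of standard deviation ``noise_std`` is added when given (if
    None, ``phantom.noise_level`` times the clean-frame RMS is used;
    zero noise_level adds nothing).  Frames stay real-valued; bit-depth
    quantisation is applied only on export.
    """
    n_ax, n_lat = image_shape(phantom, acq)
    frame = np.zeros((n_ax, n_lat))
    if len(scatterers) > 0:
        ds = acq.axial_spacing_um
        pitch = acq.lateral_pitch_um
        sig_ax = _axial_sigma_samples(acq)
        sig_lat = _lateral_sigma_lines(phantom, acq)
        f_norm = acq.center_frequency / acq.sampling_frequency

        iy = scatterers.y_um / ds          # fractional sample position
        ix = scatterers.x_um / pitch
        ha = int(math.ceil(4.0 * sig_ax))
        hl = int(math.ceil(3.0 * sig_lat))
        off_ax = np.arange(-ha, ha + 1)
        off_lat = np.arange(-hl, hl + 1)

        i0 = np.round(iy).astype(int)
        j0 = np.round(ix).astype(int)
        I = i0[:, None] + off_ax[None, :]              # (n, Pa)
        J = j0[:, None] + off_lat[None, :]             # (n, Pl)
        t = I - iy[:, None]
        u = J - ix[:, None]
        prof_ax = np.exp(-0.5 * (t / sig_ax) ** 2) \
            * np.cos(2.0 * np.pi * f_norm * t)
        prof_lat = np.exp(-0.5 * (u / sig_lat) ** 2)
        contrib = (scatterers.amplitude[:, None, None]
                   * prof_ax[:, :, None] * prof_lat[:, None, :])
        valid = ((I[:, :, None] >= 0) & (I[:, :, None] < n_ax)
                 & (J[:, None, :] >= 0) & (J[:, None, :] < n_lat))
        flat = (np.clip(I, 0, n_ax - 1)[:, :, None] * n_lat
                + np.clip(J, 0, n_lat - 1)[:, None, :])
        np.add.at(frame.ravel(), flat[valid], contrib[valid])

    if phantom.attenuation_db_per_mm > 0:
        depth_mm = np.arange(n_ax) * acq.axial_spacing_um * 1e-3
        frame *= 10.0 ** (-phantom.attenuation_db_per_mm * depth_mm
                          / 20.0)[:, None]

    if noise_std is None:
        noise_std = phantom.noise_level * float(np.sqrt(np.mean(frame ** 2)))
    if noise_std > 0:
        if rng is None:
            rng = np.random.default_rng(phantom.seed)
        frame = frame + rng.normal(0.0, noise_std, frame.shape)
    return frame


def envelope_db(frame: np.ndarray) -> np.ndarray:
    """Echo envelope in dB (analytic-signal magnitude, un-normalised)."""
    env = np.abs(hilbert(np.asarray(frame, dtype=float), axis=0))
    with np.errstate(divide="ignore"):
        return 20.0 * np.log10(env)


def render_bmode(rf_frame: np.ndarray, dynamic_range_db: float = 40.0,
                 ref_db: float | None = None) -> np.ndarray:
    """Log-compressed B-mode image in [0, 1].

    The envelope is the analytic-signal magnitude along the axial axis;
    log compression spans ``dynamic_range_db`` below the reference level
    (the frame's peak envelope unless ``ref_db`` is given, which lets a
    whole sequence share one normalisation).
    """
    db = envelope_db(rf_frame)
    if ref_db is None:
        ref_db = float(np.max(db))
    if not np.isfinite(ref_db):      # all-zero frame: floor-clipped image
        return np.zeros_like(db)
    with np.errstate(invalid="ignore"):
        img = (db - ref_db + dynamic_range_db) / dynamic_range_db
    return np.clip(np.nan_to_num(img, nan=0.0, neginf=0.0), 0.0, 1.0)


# ---------------------------------------------------------------------------
# full sequence

def _masks_for_phases(phases: np.ndarray, amplitude: float,
                      phantom: PhantomConfig, acq: AcquisitionConfig
                      ) -> io.WallMask:
    n_ax, n_lat = image_shape(phantom, acq)
    b = vessel_boundaries(phantom)
    w = phantom.wall_thickness_um
    depth = np.arange(n_ax) * acq.axial_spacing_um
    labels = np.zeros((phases.size, n_ax, n_lat), dtype=np.uint8)
    for k, phi in enumerate(phases):
        c = float(cumulative_compression(phi, amplitude))
        near_in = b["near_outer"] + w * (1.0 - c)
        far_in = b["far_outer"] - w * (1.0 - c)
        col = np.zeros(n_ax, dtype=np.uint8)
        col[(depth >= b["near_outer"]) & (depth < near_in)] = io.NEAR_WALL
        col[(depth >= near_in) & (depth < far_in)] = io.LUMEN
        col[(depth >= far_in) & (depth < b["far_outer"])] = io.FAR_WALL
        labels[k] = col[:, None]
    return io.WallMask(labels=labels)


def generate_sequence(phantom: PhantomConfig, acq: AcquisitionConfig
                      ) -> tuple[io.RFSequence, io.RFSequence,
                                 PhantomGroundTruth]:
    """Generate (RF sequence, B-mode sequence, ground truth).

    The frame count is ceil(n_cycles x frame_rate x 60 / heart_rate);
    everything is deterministic given ``phantom.seed``.
    """
    n_frames = n_frames_for(phantom, acq)
    acq = acq.replace(n_frames=n_frames)
    phases = frame_phases(phantom, acq, n_frames)
    amplitude = compression_amplitude(phantom, acq)
    rng = np.random.default_rng(phantom.seed)
    scat = generate_scatterers(phantom, acq, rng)

    # fixed noise std from the rest-state clean frame, so noise is
    # stationary across the sequence
    clean0 = render_rf_frame(deform_scatterers(scat, phases[0], phantom,
                                               amplitude=amplitude),
                             phantom, acq, noise_std=0.0)
    noise_std = phantom.noise_level * float(np.sqrt(np.mean(clean0 ** 2)))

    frames = np.empty((n_frames,) + clean0.shape)
    for k, phi in enumerate(phases):
        moved = deform_scatterers(scat, phi, phantom, amplitude=amplitude)
        frames[k] = render_rf_frame(moved, phantom, acq,
                                    noise_std=noise_std, rng=rng)

    rf = io.RFSequence(frames=frames, acq=acq, modality="RF")

    env_ref = max(float(np.max(envelope_db(f))) for f in frames)
    bmode_frames = np.stack([render_bmode(f, ref_db=env_ref) for f in frames])
    bmode = io.RFSequence(frames=bmode_frames, acq=acq, modality="BMODE")

    c = np.asarray(cumulative_compression(phases, amplitude))
    true_strain = (c[1:] - c[:-1]) / (1.0 - c[:-1])
    gt = PhantomGroundTruth(
        true_strain=true_strain,
        masks=_masks_for_phases(phases, amplitude, phantom, acq),
        phase=phases,
        cumulative_compression=c,
    )
    return rf, bmode, gt
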