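"""Acquisition and phantom configuration objects.

All physical lengths are in micrometres (µm) unless a field name says
otherwise; frequencies in Hz; rates in their conventional units
(frames/s, beats/min).  Strains are dimensionless fractions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path


class ConfigurationError(ValueError):
    """Raised when a configuration is internally inconsistent."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(msg)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Ultrasound acquisition parameters.

    Defaults describe a 40 MHz single-element biomicroscope digitised at
    500 MHz in 8 bits at 60 frames/s, the setup used for high-frequency
    small-vessel (rodent carotid) RF imaging.

    Parameters
    ----------
    center_frequency : float
        Probe centre frequency in Hz.
    sampling_frequency : float
        Axial (fast-time) sampling frequency in Hz.
    frame_rate : float
        Frames per second.
    speed_of_sound : float
        Assumed tissue sound speed in m/s.
    lateral_pitch_um : float
        Spacing between adjacent scan lines in µm.
    bit_depth : int
        Sample quantisation used when exporting integer data.
    n_frames : int or None
        Number of frames in an associated sequence, if known.
    fractional_bandwidth : float
        Pulse fractional bandwidth at -6 dB (1.1 means 110 %).
    """

    center_frequency: float = 40e6
    sampling_frequency: float = 500e6
    frame_rate: float = 60.0
    speed_of_sound: float = 1540.0
    lateral_pitch_um: float = 30.0
    bit_depth: int = 8
    n_frames: int | None = None
    fractional_bandwidth: float = 1.10

    def __post_init__(self) -> None:
        for name in ("center_frequency", "sampling_frequency", "frame_rate",
                     "speed_of_sound", "lateral_pitch_um",
                     "fractional_bandwidth"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")
        _require(int(self.bit_depth) >= 1, "bit_depth must be >= 1")
        if self.n_frames is not None:
            _require(int(self.n_frames) >= 1, "n_frames must be >= 1")

    @property
    def axial_spacing_um(self) -> float:
        """Axial sample spacing c / (2 fs), in µm."""
        return self.speed_of_sound / (2.0 * self.sampling_frequency) * 1e6

    @property
    def wavelength_um(self) -> float:
        return self.speed_of_sound / self.center_frequency * 1e6

    def replace(self, **kw) -> "AcquisitionConfig":
        d = asdict(self)
        d.update(kw)
        return AcquisitionConfig(**d)


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, motion and speckle statistics of the pulsating-vessel phantom.

    The phantom is a longitudinal vessel view: an echogenic near wall and
    far wall band around a hypoechoic lumen, all embedded in an anechoic
    margin.  Both walls undergo a periodic through-thickness axial
    compression; the lumen dilates accordingly.

    ``peak_axial_strain`` is the peak *inter-frame* (consecutive frame
    pair) axial strain of the wall under the compression-positive
    convention; the cumulative raised-cosine compression amplitude is
    derived from it and the frame timing.
    """

    wall_thickness_um: float = 150.0
    lumen_diameter_um: float = 800.0
    margin_um: float = 150.0
    n_lines: int = 32
    scatterer_density_per_mm2: float = 2000.0
    lumen_density_per_mm2: float | None = None   # None -> same as wall
    wall_to_lumen_echogenicity_ratio: float = 10.0
    peak_axial_strain: float = 0.02
    heart_rate: float = 351.0
    n_cycles: int = 7
    noise_level: float = 0.1
    lateral_beam_fwhm_um: float = 80.0
    attenuation_db_per_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.wall_thickness_um > 0, "wall_thickness_um must be > 0")
        _require(self.lumen_diameter_um > 0, "lumen_diameter_um must be > 0")
        _require(self.margin_um >= 0, "margin_um must be >= 0")
        _require(int(self.n_lines) >= 4, "n_lines must be >= 4")
        _require(self.scatterer_density_per_mm2 >= 0,
                 "scatterer_density_per_mm2 must be >= 0")
        if self.lumen_density_per_mm2 is not None:
            _require(self.lumen_density_per_mm2 >= 0,
                     "lumen_density_per_mm2 must be >= 0")
        _require(self.wall_to_lumen_echogenicity_ratio >= 1,
                 "wall_to_lumen_echogenicity_ratio must be >= 1")
        _require(0 <= self.peak_axial_strain < 0.2,
                 "peak_axial_strain must lie in [0, 0.2)")
        _require(self.heart_rate > 0, "heart_rate must be > 0")
        _require(int(self.n_cycles) >= 1, "n_cycles must be >= 1")
        _require(self.noise_level >= 0, "noise_level must be >= 0")
        _require(self.lateral_beam_fwhm_um > 0,
                 "lateral_beam_fwhm_um must be > 0")
        _require(self.attenuation_db_per_mm >= 0,
                 "attenuation_db_per_mm must be >= 0")

    @property
    def image_depth_um(self) -> float:
        """Total axial extent: margin + wall + lumen + wall + margin."""
        return (2 * self.margin_um + 2 * self.wall_thickness_um
                + self.lumen_diameter_um)

    def replace(self, **kw) -> "PhantomConfig":
        d = asdict(self)
        d.update(kw)
        return PhantomConfig(**d)


def _from_dict(cls, d: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ConfigurationError(
            f"unknown {cls.__name__} field(s): {sorted(unknown)}")
    return cls(**d)


def load_configs(path: str | Path) -> tuple[PhantomConfig, AcquisitionConfig]:
    """Load ``{"phantom": {...}, "acquisition": {...}}`` from a JSON file.

    Either section may be omitted; defaults apply.
    """
    with open(path) as fh:
        raw = json.load(fh)
    phantom = _from_dict(PhantomConfig, raw.get("phantom", {}))
    acq = _from_dict(AcquisitionConfig, raw.get("acquisition", {}))
    return phantom, acq


def save_configs(phantom: PhantomConfig, acq: AcquisitionConfig,
                 path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({"phantom": asdict(phantom), "acquisition": asdict(acq)},
                  fh, indent=2)
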