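"""Instrument configurations and pixel calibration.

An :class:`InstrumentConfig` captures everything needed to map between the
pixel grid of a B-scan and physical units: the axial (depth) sampling is
derived from the calibrated scan depth *in air* divided by a tissue
refractive index, and the lateral sampling from the scan width.

Two presets are provided:

``uhr``
    An ultra-high-resolution research instrument: 3 µm axial resolution,
    1365 (depth) x 2048 (width) pixels over an 8 mm scan, 1.48 mm scan
    depth in air.
``rtvue100``
    A commercial instrument: 5 µm axial resolution, 640 x 960 pixels over
    the same 8 mm scan width.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ConfigError, InvalidParameterError

GAUSSIAN_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # ~0.42466


@dataclass(frozen=True)
class InstrumentConfig:
    """Geometry and optics of one OCT instrument.

    Parameters
    ----------
    name : str
        Identifier used in output metadata.
    axial_resolution_um : float
        Axial point-spread-function FWHM in micrometres.
    depth_pixels, width_pixels : int
        B-scan grid size (rows = depth, columns = lateral). Minimum 16 each.
    scan_width_mm : float
        Lateral extent of the scan.
    scan_depth_air_mm : float
        Calibrated scan depth in air; divided by ``tissue_refractive_index``
        to obtain the depth sampling in tissue.
    tissue_refractive_index : float, default 1.38
        Group refractive index used to convert the air-calibrated depth to
        tissue micrometres.
    """

    name: str
    axial_resolution_um: float
    depth_pixels: int
    width_pixels: int
    scan_width_mm: float
    scan_depth_air_mm: float
    tissue_refractive_index: float = 1.38

    def __post_init__(self) -> None:
        if self.depth_pixels < 16 or self.width_pixels < 16:
            raise InvalidParameterError(
                "depth_pixels and width_pixels must be >= 16, got "
                f"{self.depth_pixels}x{self.width_pixels}"
            )
        for attr in (
            "axial_resolution_um",
            "scan_width_mm",
            "scan_depth_air_mm",
            "tissue_refractive_index",
        ):
            value = getattr(self, attr)
            if not np.isfinite(value) or value <= 0:
                raise InvalidParameterError(f"{attr} must be a positive finite real, got {value!r}")

    @property
    def axial_um_per_pixel(self) -> float:
        """Depth sampling in tissue micrometres per pixel."""
        return self.scan_depth_air_mm * 1000.0 / self.tissue_refractive_index / self.depth_pixels

    @property
    def lateral_um_per_pixel(self) -> float:
        return self.scan_width_mm * 1000.0 / self.width_pixels

    @property
    def psf_sigma_px(self) -> float:
        """Axial PSF standard deviation in pixels (FWHM -> sigma)."""
        return self.axial_resolution_um * GAUSSIAN_FWHM_TO_SIGMA / self.axial_um_per_pixel

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "InstrumentConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown InstrumentConfig keys: {sorted(unknown)}")
        missing = {f for f in known if f != "tissue_refractive_index"} - set(data)
        if missing:
            raise ConfigError(f"missing InstrumentConfig keys: {sorted(missing)}")
        return cls(**data)


PRESETS: dict[str, InstrumentConfig] = {
    "uhr": InstrumentConfig(
        name="uhr",
        axial_resolution_um=3.0,
        depth_pixels=1365,
        width_pixels=2048,
        scan_width_mm=8.0,
        scan_depth_air_mm=1.48,
    ),
    # Only the UHR scan depth is calibrated against a physical standard; the
    # commercial preset reuses the same air depth so both grids span the same
    # tissue range and differ only in sampling and PSF.
    "rtvue100": InstrumentConfig(
        name="rtvue100",
        axial_resolution_um=5.0,
        depth_pixels=640,
        width_pixels=960,
        scan_width_mm=8.0,
        scan_depth_air_mm=1.48,
    ),
}


def get_config(config: "InstrumentConfig | str") -> InstrumentConfig:
    """Resolve a preset name or pass an explicit config through."""
    if isinstance(config, InstrumentConfig):
        return config
    try:
        return PRESETS[config]
    except KeyError:
        raise ConfigError(
            f"unknown instrument preset {config!r}; available: {sorted(PRESETS)}"
        ) from None
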