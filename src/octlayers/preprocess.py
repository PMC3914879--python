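"""Noise suppression and directional-gradient cost images.

The boundary tracker works on *cost images*: per-pixel node costs in [0, 1]
where strong intensity transitions of the requested polarity are cheap.
Retinal boundaries come in two flavours — a dark layer above a bright one
(``dark-to-bright``, e.g. the vitreous/ILM interface) or the reverse
(``bright-to-dark``, e.g. RPE/choroid) — so the vertical derivative is
signed and half-wave rectified before inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import InvalidInputError, InvalidParameterError

DARK_TO_BRIGHT = "dark-to-bright"
BRIGHT_TO_DARK = "bright-to-dark"
POLARITIES = (DARK_TO_BRIGHT, BRIGHT_TO_DARK)


@dataclass
class BScan:
    """A calibrated 2-D OCT B-scan.

    Rows are depth with row 0 on the inner (vitreous) side; columns are
    lateral position. Intensities are non-negative, typically in [0, 1].
    """

    pixels: np.ndarray
    axial_um_per_pixel: float
    lateral_um_per_pixel: float
    instrument: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise InvalidInputError(f"B-scan must be 2-D, got shape {self.pixels.shape}")
        if min(self.pixels.shape) < 16:
            raise InvalidInputError(
                f"B-scan must be at least 16x16 pixels, got {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise InvalidInputError("B-scan intensities must be finite")
        if self.pixels.min() < 0:
            raise InvalidInputError("B-scan intensities must be non-negative")
        for attr in ("axial_um_per_pixel", "lateral_um_per_pixel"):
            value = getattr(self, attr)
            if not np.isfinite(value) or value <= 0:
                raise InvalidParameterError(f"{attr} must be positive, got {value!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class CostImage:
    """Node-cost grid for one boundary polarity; low cost = strong edge."""

    costs: np.ndarray
    polarity: str

    def __post_init__(self) -> None:
        self.costs = np.asarray(self.costs, dtype=float)
        if self.polarity not in POLARITIES:
            raise InvalidParameterError(
                f"polarity must be one of {POLARITIES}, got {self.polarity!r}"
            )
        if not np.all(np.isfinite(self.costs)):
            raise InvalidInputError("cost image must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.costs.shape


def _minmax01(values: np.ndarray) -> np.ndarray:
    """Affine rescale to [0, 1]; a constant array maps to all 0.5."""
    lo = float(values.min())
    hi = float(values.max())
    if hi == lo:
        return np.full_like(values, 0.5)
    return (values - lo) / (hi - lo)


def denoise(image: BScan, median_window: int = 3, gaussian_sigma_px: float = 1.5) -> BScan:
    """Median filter followed by Gaussian smoothing.

    The median step knocks out impulsive speckle spikes; the Gaussian step
    suppresses the remaining granular texture before differentiation.
    Borders are handled by edge reflection. ``median_window=1`` together
    with ``gaussian_sigma_px=0`` is the identity.
    """
    if median_window < 1 or median_window % 2 == 0:
        raise InvalidParameterError(f"median_window must be odd and >= 1, got {median_window}")
    if gaussian_sigma_px < 0:
        raise InvalidParameterError(f"gaussian_sigma_px must be >= 0, got {gaussian_sigma_px}")
    out = image.pixels
    if median_window > 1:
        out = ndimage.median_filter(out, size=median_window, mode="reflect")
    if gaussian_sigma_px > 0:
        out = ndimage.gaussian_filter(out, sigma=gaussian_sigma_px, mode="reflect")
    return replace(image, pixels=out)


def directional_gradient(image: BScan, polarity: str) -> CostImage:
    """Signed vertical-gradient cost image for one boundary polarity.

    The depth derivative is computed by central differences (one-sided at
    the first/last row). For ``dark-to-bright`` the positive derivative is
    kept, for ``bright-to-dark`` the negated one; negative responses are
    clamped to zero so each cost image sees only edges of its own polarity.
    The rectified response is min-max normalized and inverted, so the
    strongest edge of the requested polarity has cost 0 and featureless
    regions cost 1.
    """
    if polarity not in POLARITIES:
        raise InvalidParameterError(f"polarity must be one of {POLARITIES}, got {polarity!r}")
    d = np.gradient(image.pixels, axis=0)
    g = d if polarity == DARK_TO_BRIGHT else -d
    g = np.clip(g, 0.0, None)
    return CostImage(costs=1.0 - _minmax01(g), polarity=polarity)


def normalize_cost(cost: CostImage) -> CostImage:
    """Min-max rescale costs to [0, 1]; constant input maps to all 0.5.

    Idempotent: normalizing twice equals normalizing once.
    """
    if np.any(np.isnan(cost.costs)):
        raise InvalidInputError("cost image contains NaN")
    return CostImage(costs=_minmax01(cost.costs), polarity=cost.polarity)
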