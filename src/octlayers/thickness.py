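"""Calibrated layer-thickness profiles and central-window summaries.

Layers are consecutive boundary gaps:

====== =======================
RNFL    ILM -> NFL/GCL
GCL+IPL NFL/GCL -> IPL/INL
INL     IPL/INL -> INL/OPL
OPL     INL/OPL -> OPL/ONL
ONL     OPL/ONL -> ELM
IS      ELM -> IS/OS
OS      IS/OS -> OS/RPE
RPE     OS/RPE -> RPE/choroid
Total   ILM -> RPE/choroid
====== =======================

Thickness in micrometres is the row difference times the axial
calibration, so it is invariant under a global axial shift of all
boundaries and scales linearly with the calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InvalidInputError, InvalidParameterError
from .segmentation import BoundarySet

LAYER_NAMES = ("RNFL", "GCL+IPL", "INL", "OPL", "ONL", "IS", "OS", "RPE")

LAYER_BOUNDS: dict[str, tuple[str, str]] = {
    "RNFL": ("ILM", "NFL/GCL"),
    "GCL+IPL": ("NFL/GCL", "IPL/INL"),
    "INL": ("IPL/INL", "INL/OPL"),
    "OPL": ("INL/OPL", "OPL/ONL"),
    "ONL": ("OPL/ONL", "ELM"),
    "IS": ("ELM", "IS/OS"),
    "OS": ("IS/OS", "OS/RPE"),
    "RPE": ("OS/RPE", "RPE/choroid"),
}


@dataclass
class ThicknessProfile:
    """Per-column thickness in µm for the eight layers and the total retina.

    ``data`` has one row per image column with columns ``column``, the
    eight layer names and ``Total``.
    """

    data: pd.DataFrame
    axial_um_per_pixel: float
    lateral_um_per_pixel: float

    @property
    def n_columns(self) -> int:
        return len(self.data)

    def positions_mm(self, fovea: int) -> np.ndarray:
        """Signed lateral positions in mm relative to the fovea."""
        return (self.data["column"].to_numpy() - fovea) * self.lateral_um_per_pixel / 1000.0


def layer_profiles(bounds: BoundarySet, axial_um_per_pixel: float | None = None) -> ThicknessProfile:
    """Thickness profiles of the eight layers plus Total, in µm.

    The ordering invariant of :class:`BoundarySet` guarantees every
    thickness is non-negative; ``Total`` equals the sum of the eight
    layers exactly (shared boundaries telescope).
    """
    ax = axial_um_per_pixel if axial_um_per_pixel is not None else bounds.axial_um_per_pixel
    if ax <= 0 or not np.isfinite(ax):
        raise InvalidParameterError(f"axial_um_per_pixel must be positive, got {ax!r}")
    width = bounds.shape[1]
    out = {"column": np.arange(width)}
    for layer, (upper, lower) in LAYER_BOUNDS.items():
        out[layer] = (bounds.boundaries[lower] - bounds.boundaries[upper]) * ax
    out["Total"] = (bounds.boundaries["RPE/choroid"] - bounds.boundaries["ILM"]) * ax
    return ThicknessProfile(
        data=pd.DataFrame(out),
        axial_um_per_pixel=ax,
        lateral_um_per_pixel=bounds.lateral_um_per_pixel,
    )


def locate_fovea(total_um: np.ndarray, smooth_window_px: int = 31) -> int:
    """Column index of the fovea: minimum of the smoothed total thickness.

    The total-thickness profile is moving-average smoothed and the argmin
    taken over the central 50% of columns (scans are acquired centred on
    the macula, so the edge halves are excluded); ties resolve to the
    smaller column.
    """
    total_um = np.asarray(total_um, dtype=float)
    if total_um.ndim != 1:
        raise InvalidInputError("total thickness profile must be 1-D")
    if not np.all(np.isfinite(total_um)):
        raise InvalidInputError("total thickness profile contains non-finite values")
    if smooth_window_px < 1 or smooth_window_px % 2 == 0:
        raise InvalidParameterError(
            f"smooth_window_px must be odd and >= 1, got {smooth_window_px}"
        )
    if total_um.size <= smooth_window_px:
        raise InvalidInputError("profile shorter than the smoothing window")
    smoothed = ndimage.uniform_filter1d(total_um, size=smooth_window_px, mode="nearest")
    n = total_um.size
    start = n // 4
    stop = n - n // 4
    central = smoothed[start:stop]
    return start + int(np.argmin(central))


def mean_central(
    profile: ThicknessProfile,
    fovea: int,
    window_mm: float = 6.0,
    lateral_um_per_pixel: float | None = None,
) -> pd.DataFrame:
    """Mean and SD thickness over the central window around the fovea.

    Returns one row per layer (plus ``Total``) with columns
    ``layer, mean_um, sd_um, n_columns, window_mm``. The window is
    ``fovea +/- window_mm/2`` converted to columns and clipped to the scan
    (with a logged warning when clipping occurs). SD uses the n-1
    denominator.
    """
    import logging

    if window_mm <= 0:
        raise InvalidParameterError(f"window_mm must be positive, got {window_mm}")
    lat = lateral_um_per_pixel if lateral_um_per_pixel is not None else profile.lateral_um_per_pixel
    half_cols = int(round(window_mm * 1000.0 / 2.0 / lat))
    n = profile.n_columns
    lo = fovea - half_cols
    hi = fovea + half_cols
    if lo < 0 or hi > n - 1:
        logging.getLogger(__name__).warning(
            "central window [%d, %d] clipped to the scan extent [0, %d]", lo, hi, n - 1
        )
    lo = max(lo, 0)
    hi = min(hi, n - 1)
    window = profile.data.iloc[lo : hi + 1]
    records = []
    for layer in (*LAYER_NAMES, "Total"):
        values = window[layer].to_numpy()
        records.append(
            {
                "layer": layer,
                "mean_um": float(values.mean()),
                "sd_um": float(values.std(ddof=1)) if values.size > 1 else 0.0,
                "n_columns": int(values.size),
                "window_mm": window_mm,
            }
        )
    return pd.DataFrame.from_records(records)
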