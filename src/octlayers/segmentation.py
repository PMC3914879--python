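"""Sequential nine-boundary segmentation of a macular B-scan.

Strategy
--------
The two highest-contrast boundaries anchor everything else:

1. The ILM (vitreous/retina interface) is initialized per A-scan as the
   onset of the first prominent intensity peak from the inner side, then
   refined by a shortest-path search in a narrow band around the
   initialization.
2. The RPE/choroid boundary is initialized from the brightest pixel below
   the ILM in each A-scan (the RPE is the most reflective band) and
   refined the same way.

The remaining seven boundaries are then detected recursively, each by a
single shortest-path search restricted to the band between the nearest
already-found enclosing boundaries (shrunk by a guard gap that keeps the
search out of the blurred gradient tails of the enclosing edges). The
detection order puts high-contrast interfaces (IS/OS) before faint ones
(ELM) so that later searches run in tight, unambiguous bands.

Errors in regions of very low reflectivity are handled by
:func:`correct_boundary`: a semi-automated re-run of the constrained
search forced through caller-supplied anchor points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DetectionFailureError,
    InvalidAnchorError,
    InvalidInputError,
    InvalidParameterError,
)
from .graphsearch import Boundary, SearchBand, shortest_path
from .instruments import GAUSSIAN_FWHM_TO_SIGMA, InstrumentConfig
from .preprocess import (
    BRIGHT_TO_DARK,
    DARK_TO_BRIGHT,
    BScan,
    CostImage,
    denoise,
    directional_gradient,
)

logger = logging.getLogger(__name__)

BOUNDARY_NAMES = (
    "ILM",
    "NFL/GCL",
    "IPL/INL",
    "INL/OPL",
    "OPL/ONL",
    "ELM",
    "IS/OS",
    "OS/RPE",
    "RPE/choroid",
)

#: Edge polarity of each boundary, from the standard macular reflectivity
#: pattern (bright RNFL/OPL/OS/RPE over dark GCL-IPL/INL/ONL/choroid).
POLARITY: dict[str, str] = {
    "ILM": DARK_TO_BRIGHT,
    "NFL/GCL": BRIGHT_TO_DARK,
    "IPL/INL": BRIGHT_TO_DARK,
    "INL/OPL": DARK_TO_BRIGHT,
    "OPL/ONL": BRIGHT_TO_DARK,
    "ELM": DARK_TO_BRIGHT,
    "IS/OS": DARK_TO_BRIGHT,
    "OS/RPE": DARK_TO_BRIGHT,
    "RPE/choroid": BRIGHT_TO_DARK,
}

#: Detection order for the seven dependent boundaries (after ILM and
#: RPE/choroid): strong outer-complex edges first so later bands are tight.
DEPENDENT_ORDER = ("IS/OS", "OS/RPE", "ELM", "OPL/ONL", "NFL/GCL", "IPL/INL", "INL/OPL")


@dataclass
class BoundarySet:
    """The nine named, anatomically ordered boundary traces of one B-scan."""

    boundaries: dict[str, np.ndarray]
    shape: tuple[int, int]
    axial_um_per_pixel: float
    lateral_um_per_pixel: float
    instrument: str = ""
    log: list[dict] = field(default_factory=list)
    finalized: bool = True

    def __post_init__(self) -> None:
        if tuple(self.boundaries) != BOUNDARY_NAMES:
            raise InvalidInputError(
                f"BoundarySet requires the nine boundaries {BOUNDARY_NAMES} in order"
            )
        width = self.shape[1]
        arrays = {}
        for name, rows in self.boundaries.items():
            rows = np.asarray(rows, dtype=float)
            if rows.shape != (width,):
                raise InvalidInputError(
                    f"{name}: expected {width} columns, got shape {rows.shape}"
                )
            arrays[name] = rows
        self.boundaries = arrays
        stack = self.trace_array()
        if np.any(np.diff(stack, axis=0) < -1e-9):
            raise InvalidInputError("boundary traces violate the anatomical ordering")
        if stack.min() < 0 or stack.max() > self.shape[0] - 1:
            raise InvalidInputError("boundary traces leave the image depth range")

    def trace_array(self) -> np.ndarray:
        return np.stack([self.boundaries[n] for n in BOUNDARY_NAMES])

    def copy(self) -> "BoundarySet":
        return BoundarySet(
            boundaries={k: v.copy() for k, v in self.boundaries.items()},
            shape=self.shape,
            axial_um_per_pixel=self.axial_um_per_pixel,
            lateral_um_per_pixel=self.lateral_um_per_pixel,
            instrument=self.instrument,
            log=list(self.log),
            finalized=self.finalized,
        )


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the segmentation pipeline.

    Defaults are expressed in pixels of the image at hand; use
    :meth:`defaults_for` to derive a physically sensible set from a
    B-scan's calibration (filter scales, guard gaps and jump limits all
    scale with the axial sampling).
    """

    median_window: int = 3
    gaussian_sigma_px: float = 1.5
    max_jump: int = 2
    step_penalty: float = 0.05
    peak_threshold: float = 0.3
    rpe_margin_px: int = 13
    ilm_half_width_px: int = 23
    rpe_half_width_px: int = 41
    guard_px: int = 8
    order: tuple[str, ...] = DEPENDENT_ORDER
    polarity: tuple[tuple[str, str], ...] = tuple(POLARITY.items())

    def polarity_of(self, name: str) -> str:
        return dict(self.polarity)[name]

    @classmethod
    def defaults_for(
        cls, image: BScan, config: InstrumentConfig | None = None, **overrides
    ) -> "SegmentationParams":
        """Derive defaults from the image calibration.

        ``config`` (when available) supplies the true axial PSF width used
        to size the guard gap; otherwise a 4 µm blur is assumed. Any field
        can still be overridden by keyword.
        """
        ax = image.axial_um_per_pixel
        rows = image.shape[0]
        if config is not None:
            sigma_px = config.psf_sigma_px
        else:
            sigma_px = 4.0 * GAUSSIAN_FWHM_TO_SIGMA / ax
        fine_grid = rows >= 1024
        values = dict(
            median_window=3,
            gaussian_sigma_px=1.5 if fine_grid else 1.0,
            max_jump=2 if fine_grid else 1,
            step_penalty=0.05,
            peak_threshold=0.3,
            rpe_margin_px=max(2, round(10.0 / ax)),
            # the ILM init lands within half the RNFL of the interface; the
            # RPE init (brightest pixel) can sit a full RPE thickness above
            # the choroid interface, so its band is wider
            ilm_half_width_px=max(3, round(18.0 / ax)),
            rpe_half_width_px=max(3, round(32.0 / ax)),
            guard_px=max(1, int(np.ceil(3.0 * sigma_px)) + 1),
        )
        values.update(overrides)
        return cls(**values)


def init_ilm(image: BScan, peak_threshold: float = 0.3) -> Boundary:
    """Initialize the ILM as the onset of the first prominent A-scan peak.

    Per column, the first local maximum (from the inner side) whose
    prominence exceeds ``peak_threshold`` times the column's dynamic range
    is located; the returned row is the half-rise point on its leading
    flank — the position of the first highly reflective increase. Columns
    without a qualifying peak are interpolated from their neighbours.
    """
    from scipy.signal import find_peaks

    if not 0 < peak_threshold < 1:
        raise InvalidParameterError(f"peak_threshold must be in (0, 1), got {peak_threshold}")
    px = image.pixels
    depth, width = px.shape
    rows = np.full(width, np.nan)
    for c in range(width):
        col = px[:, c]
        rng = float(col.max() - col.min())
        if rng <= 0:
            continue
        peaks, props = find_peaks(col, prominence=peak_threshold * rng)
        if peaks.size == 0:
            continue
        p = int(peaks[0])
        left_base = int(props["left_bases"][0])
        half = 0.5 * (col[p] + col[left_base])
        seg = col[left_base : p + 1]
        below = np.nonzero(seg <= half)[0]
        if below.size == 0:
            rows[c] = p
            continue
        i = left_base + int(below[-1])
        if i >= p:
            rows[c] = p
            continue
        # interpolated crossing of the half-rise level, rounded up so a
        # single-pixel impulse maps to the impulse row itself
        t = i + (half - col[i]) / (col[i + 1] - col[i])
        rows[c] = min(int(np.ceil(t)), p)
    valid = np.isfinite(rows)
    if not valid.any():
        raise DetectionFailureError("no column has a qualifying ILM peak")
    if not valid.all():
        cols = np.arange(width)
        rows[~valid] = np.interp(cols[~valid], cols[valid], rows[valid])
    return Boundary(rows=np.clip(np.round(rows), 0, depth - 1).astype(int), name="ILM")


def init_rpe(image: BScan, ilm: Boundary, margin_px: int = 13) -> Boundary:
    """Initialize the RPE complex from the brightest pixel below the ILM.

    Per column the intensity argmax over rows strictly below
    ``ilm + margin_px`` is taken (ties resolve to the smaller row). The
    margin keeps the search clear of the bright RNFL just under the ILM.
    """
    px = image.pixels
    depth, width = px.shape
    start = np.asarray(np.round(ilm.rows), dtype=int) + margin_px
    if np.any(start >= depth):
        raise DetectionFailureError("ILM too deep: empty search range below it")
    row_idx = np.arange(depth)[:, None]
    masked = np.where(row_idx >= start[None, :], px, -np.inf)
    rows = np.argmax(masked, axis=0)
    return Boundary(rows=rows, name="RPE/choroid")


def refine(
    init: Boundary,
    cost: CostImage,
    half_width_px: int,
    max_jump: int,
    step_penalty: float = 0.0,
) -> Boundary:
    """Refine an initialization by a banded shortest-path search.

    The band is ``init +/- half_width_px`` clipped to the image; with
    ``half_width_px=0`` the band collapses and the initialization is
    returned unchanged.
    """
    if half_width_px < 0:
        raise InvalidParameterError(f"half_width_px must be >= 0, got {half_width_px}")
    depth = cost.shape[0]
    band = SearchBand.around(init.rows, half_width_px, depth)
    out = shortest_path(cost, band, max_jump=max_jump, step_penalty=step_penalty)
    return Boundary(rows=out.rows, name=init.name, total_cost=out.total_cost)


def _enclosing(found: dict[str, np.ndarray], name: str) -> tuple[np.ndarray, np.ndarray]:
    """Nearest already-found boundaries above and below ``name``."""
    i = BOUNDARY_NAMES.index(name)
    inner = next(
        found[n] for n in reversed(BOUNDARY_NAMES[:i]) if n in found
    )
    outer = next(found[n] for n in BOUNDARY_NAMES[i + 1 :] if n in found)
    return inner, outer


def _band_between(
    inner: np.ndarray, outer: np.ndarray, guard_px: int, depth: int
) -> SearchBand:
    """Band between two traces shrunk by a guard gap.

    Where the gap collapses (foveal degeneracy) the band contracts to the
    midpoint so coincident boundaries are allowed rather than an error.
    """
    lo = np.floor(inner).astype(int) + guard_px
    hi = np.ceil(outer).astype(int) - guard_px
    mid = np.round((inner + outer) / 2.0).astype(int)
    # always include the midpoint curve: it varies as smoothly as the
    # enclosing traces, so a connected path exists even where the guarded
    # gap collapses
    lo = np.minimum(lo, mid)
    hi = np.maximum(hi, mid)
    lo = np.clip(lo, 0, depth - 1)
    hi = np.clip(hi, 0, depth - 1)
    lo = np.minimum(lo, hi)
    return SearchBand(lo=lo, hi=hi)


def _smooth_trace(rows: np.ndarray, size: int = 15) -> np.ndarray:
    """Laterally smooth an initialization trace.

    A lateral median rejects isolated columns where the per-A-scan
    initializer latched onto a speckle grain; the small Gaussian keeps the
    band edges gentle enough for the jump-limited path search.
    """
    from scipy import ndimage

    out = ndimage.median_filter(np.asarray(rows, dtype=float), size=size, mode="nearest")
    return ndimage.gaussian_filter1d(out, sigma=2.0, mode="nearest")


def _limit_slope(rows: np.ndarray, max_slope: float) -> np.ndarray:
    """Clamp per-column steps of a trace so banded searches stay feasible."""
    out = np.asarray(rows, dtype=float).copy()
    for c in range(1, out.size):
        out[c] = np.clip(out[c], out[c - 1] - max_slope, out[c - 1] + max_slope)
    for c in range(out.size - 2, -1, -1):
        out[c] = np.clip(out[c], out[c + 1] - max_slope, out[c + 1] + max_slope)
    return out


def segment_boundaries(
    image: BScan,
    params: SegmentationParams | None = None,
    config: InstrumentConfig | None = None,
) -> BoundarySet:
    """Run the full sequential nine-boundary segmentation.

    Deterministic: identical image and parameters give an identical
    result. The returned set always satisfies the anatomical ordering
    (enforced by clipping each boundary to its enclosing pair). A
    per-boundary log entry records the band extent and path cost.
    """
    params = params or SegmentationParams.defaults_for(image, config)
    depth, width = image.shape
    den = denoise(image, params.median_window, params.gaussian_sigma_px)
    costs = {
        DARK_TO_BRIGHT: directional_gradient(den, DARK_TO_BRIGHT),
        BRIGHT_TO_DARK: directional_gradient(den, BRIGHT_TO_DARK),
    }
    log: list[dict] = []

    def note(name: str, band: SearchBand, path: Boundary) -> None:
        entry = {
            "boundary": name,
            "band_min": int(band.lo.min()),
            "band_max": int(band.hi.max()),
            "path_cost": None if path.total_cost is None else float(path.total_cost),
        }
        log.append(entry)
        logger.debug("segmented %s: %s", name, entry)

    try:
        ilm0 = init_ilm(den, params.peak_threshold)
        init_trace = _limit_slope(_smooth_trace(ilm0.rows), params.max_jump)
        band = SearchBand.around(init_trace, params.ilm_half_width_px, depth)
        ilm = shortest_path(
            costs[params.polarity_of("ILM")], band, params.max_jump, params.step_penalty
        )
        note("ILM", band, ilm)

        rpe0 = init_rpe(den, ilm, params.rpe_margin_px)
        init_trace = _limit_slope(_smooth_trace(rpe0.rows), params.max_jump)
        band = SearchBand.around(init_trace, params.rpe_half_width_px, depth)
        rpe = shortest_path(
            costs[params.polarity_of("RPE/choroid")], band, params.max_jump, params.step_penalty
        )
        note("RPE/choroid", band, rpe)
    except DetectionFailureError as exc:
        raise DetectionFailureError(f"initialization failed: {exc}") from exc

    found: dict[str, np.ndarray] = {
        "ILM": ilm.rows.astype(float),
        "RPE/choroid": np.maximum(rpe.rows.astype(float), ilm.rows.astype(float)),
    }
    for name in params.order:
        inner, outer = _enclosing(found, name)
        band = _band_between(inner, outer, params.guard_px, depth)
        try:
            path = shortest_path(
                costs[params.polarity_of(name)], band, params.max_jump, params.step_penalty
            )
        except Exception as exc:
            raise DetectionFailureError(f"boundary {name}: {exc}") from exc
        rows = np.clip(path.rows.astype(float), inner, outer)
        found[name] = rows
        note(name, band, path)

    # Enforce the ordering invariant exactly (clipping guards against
    # rounding at collapsed bands).
    stack = np.stack([found[n] for n in BOUNDARY_NAMES])
    stack = np.maximum.accumulate(stack, axis=0)
    boundaries = {n: stack[i] for i, n in enumerate(BOUNDARY_NAMES)}
    return BoundarySet(
        boundaries=boundaries,
        shape=image.shape,
        axial_um_per_pixel=image.axial_um_per_pixel,
        lateral_um_per_pixel=image.lateral_um_per_pixel,
        instrument=image.instrument,
        log=log,
    )


def correct_boundary(
    image: BScan,
    bounds: BoundarySet,
    name: str,
    anchors: list[tuple[int, int]],
    params: SegmentationParams | None = None,
    config: InstrumentConfig | None = None,
) -> BoundarySet:
    """Semi-automated correction: re-detect one boundary through anchors.

    The named boundary's search band (between its enclosing neighbours in
    ``bounds``) is collapsed to the anchor row at each anchor column, and
    the shortest-path search re-run, so the returned trace is the
    constrained optimum passing exactly through every anchor. Other
    boundaries are re-clipped where the correction violates the ordering.
    The input ``bounds`` is left untouched.
    """
    if name not in BOUNDARY_NAMES:
        raise InvalidParameterError(f"unknown boundary {name!r}")
    if not anchors:
        raise InvalidParameterError("at least one anchor is required")
    cols = [a[0] for a in anchors]
    if cols != sorted(cols) or len(set(cols)) != len(cols):
        raise InvalidAnchorError("anchors must be sorted by column without duplicates")
    params = params or SegmentationParams.defaults_for(image, config)
    depth, width = image.shape

    i = BOUNDARY_NAMES.index(name)
    others = {n: r for n, r in bounds.boundaries.items() if n != name}
    if i == 0:
        inner = np.zeros(width)
    else:
        inner = bounds.boundaries[BOUNDARY_NAMES[i - 1]]
    if i == len(BOUNDARY_NAMES) - 1:
        outer = np.full(width, depth - 1.0)
    else:
        outer = bounds.boundaries[BOUNDARY_NAMES[i + 1]]
    for col, row in anchors:
        if not 0 <= col < width:
            raise InvalidAnchorError(f"anchor column {col} outside the image")
        if not inner[col] <= row <= outer[col]:
            raise InvalidAnchorError(
                f"anchor ({col}, {row}) lies outside the enclosing boundaries "
                f"[{inner[col]:.1f}, {outer[col]:.1f}]"
            )

    den = denoise(image, params.median_window, params.gaussian_sigma_px)
    cost = directional_gradient(den, params.polarity_of(name))
    band = _band_between(inner, outer, params.guard_px, depth)
    lo = band.lo.copy()
    hi = band.hi.copy()
    for col, row in anchors:
        lo[col] = hi[col] = int(round(row))
    band = SearchBand(lo=lo, hi=hi)
    path = shortest_path(cost, band, params.max_jump, params.step_penalty)

    out = bounds.copy()
    out.boundaries[name] = np.clip(path.rows.astype(float), inner, outer)
    # Re-clip neighbours so the ordering invariant survives the correction.
    stack = out.trace_array()
    for k in range(i - 1, -1, -1):
        stack[k] = np.minimum(stack[k], stack[k + 1])
    for k in range(i + 1, len(BOUNDARY_NAMES)):
        stack[k] = np.maximum(stack[k], stack[k - 1])
    out.boundaries = {n: stack[j] for j, n in enumerate(BOUNDARY_NAMES)}
    out.log = list(bounds.log) + [
        {
            "boundary": name,
            "correction_anchors": [list(map(int, a)) for a in anchors],
            "path_cost": None if path.total_cost is None else float(path.total_cost),
        }
    ]
    return BoundarySet(
        boundaries=out.boundaries,
        shape=out.shape,
        axial_um_per_pixel=out.axial_um_per_pixel,
        lateral_um_per_pixel=out.lateral_um_per_pixel,
        instrument=out.instrument,
        log=out.log,
    )
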