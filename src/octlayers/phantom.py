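"""Synthetic macular B-scan phantoms with known ground truth.

The phantom emulates a single horizontal (or vertical) macular B-scan:
nine ordered sub-pixel boundary traces delimit eight retinal layers plus
vitreous above and choroid below. Inner layers (RNFL through OPL) thin
toward a foveal pit modelled as a Gaussian depression, while the outer
complex (ELM through RPE/choroid) runs through the fovea unchanged.
Rendering assigns each pixel the reflectivity of the layer containing its
centre, blurs axially with the instrument's Gaussian PSF, and multiplies
by unit-mean gamma-distributed speckle (the standard fully-developed
coherent-imaging approximation; the contrast parameter is SD/mean).

The default reflectivity palette follows the contrast pattern of real
macular OCT: hyper-reflective RNFL, OPL, photoreceptor outer segments and
RPE; hypo-reflective vitreous, INL, ONL. Values are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InvalidGeometryError, InvalidParameterError
from .instruments import InstrumentConfig, get_config
from .preprocess import BScan

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

#: Media in depth order: vitreous, the eight retinal layers, choroid.
MEDIA_NAMES = ("vitreous", "RNFL", "GCL+IPL", "INL", "OPL", "ONL", "IS", "OS", "RPE", "choroid")

#: Default reflectivities chosen so that, within each detection band used by
#: the sequential pipeline, the target boundary carries the strongest
#: gradient of its polarity.
DEFAULT_REFLECTIVITIES: dict[str, float] = {
    "vitreous": 0.02,
    "RNFL": 0.85,
    "GCL+IPL": 0.55,
    "INL": 0.30,
    "OPL": 0.50,
    "ONL": 0.12,
    "IS": 0.35,
    "OS": 0.80,
    "RPE": 0.95,
    "choroid": 0.30,
}

#: Peripheral layer thicknesses in micrometres (macular, adult).
DEFAULT_THICKNESSES_UM: dict[str, float] = {
    "RNFL": 23.0,
    "GCL+IPL": 67.0,
    "INL": 32.0,
    "OPL": 20.0,
    "ONL": 61.0,
    "IS": 28.0,
    "OS": 32.0,
    "RPE": 29.0,
}

#: Inner layers attenuated by the foveal pit.
PIT_LAYERS = ("RNFL", "GCL+IPL", "INL", "OPL")


@dataclass(frozen=True)
class LayerGeometry:
    """Anatomical parameters of the phantom retina.

    Thicknesses are peripheral values in micrometres. The foveal pit
    multiplies the inner-layer thicknesses by
    ``1 - pit_depth_fraction * exp(-x^2 / 2 sigma^2)`` with sigma derived
    from ``pit_fwhm_mm``; the outer complex is pit-independent. A gentle
    parabolic curvature (``curvature_um`` of sag across the scan) and a
    band-limited seeded undulation make the traces non-trivial for the
    tracker without affecting feasibility.
    """

    thicknesses_um: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_THICKNESSES_UM))
    pit_depth_fraction: float = 0.6
    pit_fwhm_mm: float = 1.3
    fovea_offset_mm: float = 0.0
    base_depth_fraction: float = 0.62
    curvature_um: float = 25.0
    undulation_um: float = 3.0
    undulation_cycles: float = 2.5

    def __post_init__(self) -> None:
        missing = set(DEFAULT_THICKNESSES_UM) - set(self.thicknesses_um)
        if missing:
            raise InvalidGeometryError(f"missing layer thicknesses: {sorted(missing)}")
        for name, t in self.thicknesses_um.items():
            if not np.isfinite(t) or t <= 0:
                raise InvalidGeometryError(f"thickness of {name} must be positive, got {t!r}")
        if not 0.0 <= self.pit_depth_fraction <= 1.0:
            raise InvalidGeometryError(
                f"pit_depth_fraction must be in [0, 1], got {self.pit_depth_fraction}"
            )
        if self.pit_fwhm_mm <= 0:
            raise InvalidGeometryError("pit_fwhm_mm must be positive")

    def scaled(self, factor: float) -> "LayerGeometry":
        """Geometry with all layer thicknesses multiplied by ``factor``."""
        return replace(
            self, thicknesses_um={k: v * factor for k, v in self.thicknesses_um.items()}
        )


@dataclass
class PhantomTruth:
    """Ground-truth boundaries (sub-pixel rows per column) and palette."""

    boundaries: dict[str, np.ndarray]
    layer_reflectivities: dict[str, float]
    fovea_column: int
    config: InstrumentConfig

    def __post_init__(self) -> None:
        if tuple(self.boundaries) != BOUNDARY_NAMES:
            raise InvalidGeometryError(
                f"boundaries must be exactly {BOUNDARY_NAMES} in order, got {tuple(self.boundaries)}"
            )
        stack = self.trace_array()
        if np.any(np.diff(stack, axis=0) < -1e-9):
            raise InvalidGeometryError("boundary traces must be ordered at every column")
        if stack.min() < 1 or stack.max() > self.config.depth_pixels - 2:
            raise InvalidGeometryError("boundary traces must lie strictly inside the image depth")

    def trace_array(self) -> np.ndarray:
        """(9, width) array of boundary rows in anatomical order."""
        return np.stack([self.boundaries[n] for n in BOUNDARY_NAMES])

    def shifted(self, shift_px: float) -> "PhantomTruth":
        """Truth with every boundary moved axially by ``shift_px`` rows."""
        moved = {k: v + shift_px for k, v in self.boundaries.items()}
        return PhantomTruth(
            boundaries=moved,
            layer_reflectivities=dict(self.layer_reflectivities),
            fovea_column=self.fovea_column,
            config=self.config,
        )


def make_truth(
    config: InstrumentConfig | str,
    geometry: LayerGeometry | None = None,
    seed: int = 0,
    reflectivities: dict[str, float] | None = None,
) -> PhantomTruth:
    """Build ordered, band-limited ground-truth traces for one B-scan.

    Deterministic for a fixed seed; the seed drives only the smooth
    undulation phases. Raises :class:`InvalidGeometryError` when the
    requested geometry would cross boundaries or leave the image.
    """
    config = get_config(config)
    geometry = geometry or LayerGeometry()
    reflectivities = dict(reflectivities or DEFAULT_REFLECTIVITIES)
    missing = set(MEDIA_NAMES) - set(reflectivities)
    if missing:
        raise InvalidParameterError(f"missing reflectivities: {sorted(missing)}")
    if any(not 0 <= v <= 1 for v in reflectivities.values()):
        raise InvalidParameterError("reflectivities must lie in [0, 1]")
    if geometry.pit_fwhm_mm >= config.scan_width_mm:
        raise InvalidGeometryError(
            f"pit FWHM {geometry.pit_fwhm_mm} mm must be smaller than the "
            f"scan width {config.scan_width_mm} mm"
        )

    width = config.width_pixels
    depth = config.depth_pixels
    ax = config.axial_um_per_pixel
    lat = config.lateral_um_per_pixel
    cols = np.arange(width, dtype=float)

    fovea_column = int(round(width / 2 + geometry.fovea_offset_mm * 1000.0 / lat))
    if not 0 <= fovea_column < width:
        raise InvalidGeometryError("fovea_offset_mm places the fovea outside the scan")

    rng = np.random.default_rng(seed)
    # Outer reference surface (RPE/choroid): parabolic curvature plus a
    # band-limited undulation from a few random-phase cosines.
    half = (width - 1) / 2.0
    base = geometry.base_depth_fraction * depth
    curvature = geometry.curvature_um / ax * ((cols - half) / half) ** 2
    undulation = np.zeros(width)
    if geometry.undulation_um > 0:
        for k in (1.0, 1.7, 2.3):
            phase = rng.uniform(0, 2 * math.pi)
            amp = geometry.undulation_um / ax / 3.0
            undulation += amp * np.cos(
                2 * math.pi * geometry.undulation_cycles * k * cols / width + phase
            )
    outer = base + curvature + undulation

    pit_sigma_px = geometry.pit_fwhm_mm * 1000.0 / lat / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    pit = 1.0 - geometry.pit_depth_fraction * np.exp(
        -0.5 * ((cols - fovea_column) / pit_sigma_px) ** 2
    )

    thick_px = {name: geometry.thicknesses_um[name] / ax for name in DEFAULT_THICKNESSES_UM}
    # Build upward from RPE/choroid so the outer complex is pit-independent.
    traces: dict[str, np.ndarray] = {"RPE/choroid": outer}
    order_up = ("OS/RPE", "IS/OS", "ELM", "OPL/ONL", "INL/OPL", "IPL/INL", "NFL/GCL", "ILM")
    above_layer = {
        "OS/RPE": "RPE",
        "IS/OS": "OS",
        "ELM": "IS",
        "OPL/ONL": "ONL",
        "INL/OPL": "OPL",
        "IPL/INL": "INL",
        "NFL/GCL": "GCL+IPL",
        "ILM": "RNFL",
    }
    current = outer
    for bname in order_up:
        layer = above_layer[bname]
        t = thick_px[layer] * (pit if layer in PIT_LAYERS else 1.0)
        current = current - t
        traces[bname] = current

    boundaries = {name: traces[name] for name in BOUNDARY_NAMES}
    return PhantomTruth(
        boundaries=boundaries,
        layer_reflectivities=reflectivities,
        fovea_column=fovea_column,
        config=config,
    )


def reflectivity_image(truth: PhantomTruth) -> np.ndarray:
    """Piecewise-constant reflectivity map; membership at pixel centres."""
    config = truth.config
    depth, width = config.depth_pixels, config.width_pixels
    stack = truth.trace_array()  # (9, width)
    rows = np.arange(depth, dtype=float)[:, None]
    # medium index of pixel (r, c) = number of boundaries at or above the
    # pixel centre.
    idx = np.zeros((depth, width), dtype=np.int8)
    for b in range(stack.shape[0]):
        idx += rows >= stack[b][None, :]
    palette = np.array([truth.layer_reflectivities[m] for m in MEDIA_NAMES])
    return palette[idx]


def render_from_reflectivity(
    reflectivity: np.ndarray,
    config: InstrumentConfig,
    noise: float = 0.0,
    seed: int = 0,
) -> BScan:
    """Blur a reflectivity map with the axial PSF and apply speckle."""
    if not 0.0 <= noise < 1.0:
        raise InvalidParameterError(f"speckle contrast must be in [0, 1), got {noise}")
    img = np.asarray(reflectivity, dtype=float)
    sigma = config.psf_sigma_px
    if sigma > 0:
        img = ndimage.gaussian_filter1d(img, sigma=sigma, axis=0, mode="nearest")
    if noise > 0:
        rng = np.random.default_rng(seed)
        shape_k = 1.0 / noise**2
        speckle = rng.gamma(shape=shape_k, scale=1.0 / shape_k, size=img.shape)
        img = img * speckle
    img = np.clip(img, 0.0, 1.0)
    return BScan(
        pixels=img,
        axial_um_per_pixel=config.axial_um_per_pixel,
        lateral_um_per_pixel=config.lateral_um_per_pixel,
        instrument=config.name,
    )


def render_bscan(
    truth: PhantomTruth,
    config: InstrumentConfig | str | None = None,
    noise: float = 0.0,
    seed: int = 0,
) -> BScan:
    """Render a phantom truth into a speckled B-scan.

    Deterministic for a fixed seed; ``noise`` is the speckle contrast
    (SD/mean of the multiplicative field). With ``noise=0`` and a
    vanishing PSF the image equals the piecewise-constant reflectivity
    map exactly.
    """
    config = get_config(config) if config is not None else truth.config
    if config.depth_pixels != truth.config.depth_pixels or config.width_pixels != truth.config.width_pixels:
        raise InvalidGeometryError(
            "truth grid does not match config grid; regenerate the truth with make_truth(config)"
        )
    return render_from_reflectivity(reflectivity_image(truth), config, noise=noise, seed=seed)


@dataclass
class Acquisition:
    """One repeated acquisition: the image and its shifted ground truth."""

    bscan: BScan
    truth: PhantomTruth
    shift_px: float


def repeat_acquisitions(
    truth: PhantomTruth,
    config: InstrumentConfig | str | None = None,
    n: int = 2,
    jitter_px: float = 0.0,
    noise: float = 0.0,
    seed: int = 0,
) -> list[Acquisition]:
    """Simulate ``n`` re-acquisitions of the same retina.

    Each repeat draws an independent global axial shift (SD ``jitter_px``,
    emulating repositioning between captures) and independent speckle.
    Layer thicknesses are boundary differences, hence invariant under the
    shift; the shifted truths are returned so thickness remains comparable
    across repeats.
    """
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    config = get_config(config) if config is not None else truth.config
    rng = np.random.default_rng(seed)
    out: list[Acquisition] = []
    for i in range(n):
        shift = float(rng.normal(0.0, jitter_px)) if jitter_px > 0 else 0.0
        shifted = truth.shifted(shift)
        render_seed = int(rng.integers(0, 2**31 - 1))
        img = render_bscan(shifted, config, noise=noise, seed=render_seed)
        out.append(Acquisition(bscan=img, truth=shifted, shift_px=shift))
    return out


def truth_boundary_set(truth: PhantomTruth):
    """Ground truth as a :class:`~octlayers.segmentation.BoundarySet`."""
    from .segmentation import BoundarySet

    config = truth.config
    return BoundarySet(
        boundaries={k: v.copy() for k, v in truth.boundaries.items()},
        shape=(config.depth_pixels, config.width_pixels),
        axial_um_per_pixel=config.axial_um_per_pixel,
        lateral_um_per_pixel=config.lateral_um_per_pixel,
        instrument=config.name,
    )


def low_contrast_fixture(
    config: InstrumentConfig | str = "uhr",
    region_halfwidth_cols: int = 60,
    seed: int = 0,
) -> tuple[BScan, PhantomTruth, tuple[int, int]]:
    """A noise-free phantom with a local OPL/ONL signal dropout.

    Within a lateral window on the temporal side the INL, OPL and ONL
    reflectivities collapse to the ONL value, erasing the OPL/ONL edge and
    leaving the (stronger, mis-leading) IPL/INL edge as the only
    bright-to-dark feature in the search band — the classic failure mode
    where the tracker locks onto the wrong interface in a region of
    extremely low structural information. Returns the image, the truth and
    the ``(col_start, col_stop)`` dropout window.
    """
    config = get_config(config)
    # flat outer surface: inside the dropout the image carries no
    # information, so the corrected trace is judged against a truth that is
    # locally straight (as in a real correction, where the operator anchors
    # a visually obvious continuation)
    geometry = LayerGeometry(curvature_um=0.0, undulation_um=0.0)
    truth = make_truth(config, geometry=geometry, seed=seed)
    width = config.width_pixels
    c0 = width // 4 - region_halfwidth_cols
    c1 = width // 4 + region_halfwidth_cols
    refl = reflectivity_image(truth)
    stack = truth.trace_array()
    rows = np.arange(config.depth_pixels, dtype=float)[:, None]
    ipl_inl = stack[BOUNDARY_NAMES.index("IPL/INL")]
    elm = stack[BOUNDARY_NAMES.index("ELM")]
    region = np.zeros_like(refl, dtype=bool)
    region[:, c0:c1] = (rows >= ipl_inl[None, :])[:, c0:c1] & (rows < elm[None, :])[:, c0:c1]
    refl[region] = truth.layer_reflectivities["ONL"]
    img = render_from_reflectivity(refl, config, noise=0.0, seed=seed)
    return img, truth, (c0, c1)


def simulate_study(
    n_subjects: int = 20,
    instruments: tuple[str, ...] = ("uhr", "rtvue100"),
    n_repeats: int = 2,
    n_examiners: int = 2,
    between_sd_frac: float = 0.05,
    within_sd_um: float = 1.0,
    window_mm: float = 6.0,
    meridians: tuple[str, ...] = ("horizontal",),
    instrument_bias_um: dict[str, float] | None = None,
    seed: int = 0,
    geometry: LayerGeometry | None = None,
) -> pd.DataFrame:
    """Simulate a repeatability/reproducibility study on phantom retinas.

    Each subject gets a geometry scaled by an i.i.d. factor
    ``N(1, between_sd_frac)`` (so the between-subject SD of total retinal
    thickness is about ``between_sd_frac * 292`` µm, matching the spread
    seen across healthy adults). True per-layer mean thicknesses over the
    central ``window_mm`` are computed from the exact phantom boundaries;
    every acquisition then reads each quantity with independent Gaussian
    measurement noise of SD ``within_sd_um`` (the boundary-localisation
    error of a repeated scan). Examiner 1 contributes ``n_repeats``
    acquisitions, every further examiner one acquisition — the design used
    to estimate intra-observer repeatability and inter-observer
    reproducibility. ``instrument_bias_um`` optionally adds a constant
    per-instrument offset to every reading to emulate calibration
    differences between devices.

    Returns a long-format table with columns
    ``subject, layer, meridian, instrument, examiner, repeat, thickness_um``.
    """
    from .thickness import layer_profiles, mean_central

    if n_subjects < 1 or n_repeats < 1 or n_examiners < 1:
        raise InvalidParameterError("n_subjects, n_repeats and n_examiners must be >= 1")
    if between_sd_frac < 0 or within_sd_um < 0:
        raise InvalidParameterError("variance parameters must be >= 0")
    geometry = geometry or LayerGeometry()
    bias = instrument_bias_um or {}
    rng = np.random.default_rng(seed)
    records = []
    for subject in range(1, n_subjects + 1):
        factor = float(np.clip(rng.normal(1.0, between_sd_frac), 0.5, 1.5))
        geo = geometry.scaled(factor)
        for meridian in meridians:
            for inst in instruments:
                config = get_config(inst)
                truth = make_truth(config, geometry=geo, seed=subject)
                profile = layer_profiles(truth_boundary_set(truth))
                summary = mean_central(
                    profile, fovea=truth.fovea_column, window_mm=window_mm
                ).set_index("layer")["mean_um"]
                for examiner in range(1, n_examiners + 1):
                    reps = n_repeats if examiner == 1 else 1
                    for repeat in range(1, reps + 1):
                        for layer, true_um in summary.items():
                            value = (
                                true_um
                                + bias.get(inst, 0.0)
                                + float(rng.normal(0.0, within_sd_um))
                            )
                            records.append(
                                {
                                    "subject": subject,
                                    "layer": layer,
                                    "meridian": meridian,
                                    "instrument": inst,
                                    "examiner": examiner,
                                    "repeat": repeat,
                                    "thickness_um": value,
                                }
                            )
    return pd.DataFrame.from_records(records)
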