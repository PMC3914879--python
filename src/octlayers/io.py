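"""Readers and writers: images (TIFF/PNG), boundaries, thickness, config.

Boundary and thickness tables are plain CSV with ``#``-prefixed header
lines carrying the image shape, calibration and provenance, so files are
diff-able and self-describing. A JSON mirror of the boundary format is
available. Pipeline configuration is YAML with strict key checking:
unknown keys are errors, which guards against silent typos.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ConfigError, CorruptFileError, InvalidInputError, UnsupportedFormatError
from .instruments import InstrumentConfig, get_config
from .preprocess import BScan
from .segmentation import BOUNDARY_NAMES, BoundarySet


def write_bscan(bscan: BScan, path: str | Path) -> Path:
    """Write a B-scan as 32-bit float grayscale TIFF (or 16-bit PNG)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, bscan.pixels.astype(np.float32))
    elif suffix == ".png":
        import imageio.v3 as iio

        scaled = np.clip(bscan.pixels, 0.0, 1.0)
        iio.imwrite(path, (scaled * 65535.0 + 0.5).astype(np.uint16))
    else:
        raise UnsupportedFormatError(f"unsupported image format {suffix!r}")
    return path


def read_bscan(
    path: str | Path,
    config: InstrumentConfig | str | None = None,
    axial_um_per_pixel: float | None = None,
    lateral_um_per_pixel: float | None = None,
    instrument: str = "",
) -> BScan:
    """Read a 2-D grayscale TIFF/PNG and attach calibration.

    Integer images are rescaled to [0, 1] by their dtype maximum; float
    images are taken as-is. Calibration comes either from an
    :class:`InstrumentConfig` (or preset name) or from explicit
    micrometre-per-pixel values.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        pixels = tifffile.imread(path)
    elif suffix == ".png":
        import imageio.v3 as iio

        pixels = iio.imread(path)
    else:
        raise UnsupportedFormatError(f"unsupported image format {suffix!r}")
    pixels = np.asarray(pixels)
    if pixels.ndim != 2:
        raise UnsupportedFormatError(
            f"expected a single-channel 2-D image, got shape {pixels.shape}"
        )
    if np.issubdtype(pixels.dtype, np.integer):
        pixels = pixels.astype(float) / float(np.iinfo(pixels.dtype).max)
    else:
        pixels = pixels.astype(float)

    if config is not None:
        cfg = get_config(config)
        axial = cfg.axial_um_per_pixel
        lateral = cfg.lateral_um_per_pixel
        instrument = instrument or cfg.name
    else:
        if axial_um_per_pixel is None or lateral_um_per_pixel is None:
            raise ConfigError(
                "calibration required: pass config= or both axial_um_per_pixel= "
                "and lateral_um_per_pixel="
            )
        axial = axial_um_per_pixel
        lateral = lateral_um_per_pixel
    return BScan(
        pixels=pixels,
        axial_um_per_pixel=axial,
        lateral_um_per_pixel=lateral,
        instrument=instrument,
    )


def _boundary_metadata(bounds: BoundarySet) -> dict:
    return {
        "depth_pixels": bounds.shape[0],
        "width_pixels": bounds.shape[1],
        "axial_um_per_pixel": bounds.axial_um_per_pixel,
        "lateral_um_per_pixel": bounds.lateral_um_per_pixel,
        "instrument": bounds.instrument,
    }


def write_boundaries(bounds: BoundarySet, path: str | Path) -> Path:
    """Write the nine traces as CSV (with ``#`` metadata header) or JSON."""
    path = Path(path)
    meta = _boundary_metadata(bounds)
    if path.suffix.lower() == ".json":
        payload = {
            "metadata": meta,
            "boundaries": {k: v.tolist() for k, v in bounds.boundaries.items()},
        }
        path.write_text(json.dumps(payload))
        return path
    frame = pd.DataFrame({"column": np.arange(bounds.shape[1])})
    for name in BOUNDARY_NAMES:
        frame[name] = bounds.boundaries[name]
    buf = _io.StringIO()
    for key, value in meta.items():
        buf.write(f"# {key}={value}\n")
    frame.to_csv(buf, index=False)
    path.write_text(buf.getvalue())
    return path


def read_boundaries(path: str | Path) -> BoundarySet:
    """Read boundaries written by :func:`write_boundaries`.

    Parsing is header-driven: CSV column order does not matter. The
    anatomical-ordering invariant is re-checked; a violation raises
    :class:`CorruptFileError`.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        meta = payload["metadata"]
        traces = {k: np.asarray(v, dtype=float) for k, v in payload["boundaries"].items()}
    else:
        meta = {}
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for i, line in enumerate(lines):
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value.strip()
                body_start = i + 1
            else:
                break
        frame = pd.read_csv(_io.StringIO("".join(lines[body_start:])))
        missing = set(BOUNDARY_NAMES) - set(frame.columns)
        if missing:
            raise CorruptFileError(f"boundary file missing columns: {sorted(missing)}")
        traces = {name: frame[name].to_numpy(dtype=float) for name in BOUNDARY_NAMES}
    try:
        return BoundarySet(
            boundaries={name: traces[name] for name in BOUNDARY_NAMES},
            shape=(int(meta["depth_pixels"]), int(meta["width_pixels"])),
            axial_um_per_pixel=float(meta["axial_um_per_pixel"]),
            lateral_um_per_pixel=float(meta["lateral_um_per_pixel"]),
            instrument=str(meta.get("instrument", "")),
        )
    except KeyError as exc:
        raise CorruptFileError(f"boundary file missing metadata key {exc}") from exc
    except InvalidInputError as exc:
        raise CorruptFileError(f"boundary file violates invariants: {exc}") from exc


def write_truth_csv(truth, path: str | Path) -> Path:
    """Write phantom ground-truth traces (column + nine boundary rows)."""
    path = Path(path)
    frame = pd.DataFrame({"column": np.arange(truth.config.width_pixels)})
    for name in BOUNDARY_NAMES:
        frame[name] = truth.boundaries[name]
    frame.to_csv(path, index=False)
    return path


_KNOWN_CONFIG_KEYS = {
    "instrument",
    "segmentation",
    "thickness",
    "reliability",
    "seed",
    "log_level",
}
_KNOWN_THICKNESS_KEYS = {"window_mm", "smooth_window_px"}
_KNOWN_RELIABILITY_KEYS = {"design", "icc_form"}


def load_pipeline_config(path: str | Path) -> dict:
    """Load and validate a pipeline YAML config.

    Returns a dict with the instrument resolved to an
    :class:`InstrumentConfig`. Unknown keys anywhere are errors.
    """
    from .segmentation import SegmentationParams

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("pipeline config must be a YAML mapping")
    unknown = set(raw) - _KNOWN_CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    out: dict = {"seed": int(raw.get("seed", 0)), "log_level": raw.get("log_level", "INFO")}
    inst = raw.get("instrument", "uhr")
    out["instrument"] = get_config(inst) if isinstance(inst, str) else InstrumentConfig.from_dict(inst)
    seg = raw.get("segmentation", {}) or {}
    known_seg = set(SegmentationParams.__dataclass_fields__)
    unknown = set(seg) - known_seg
    if unknown:
        raise ConfigError(f"unknown segmentation keys: {sorted(unknown)}")
    out["segmentation"] = seg
    thick = raw.get("thickness", {}) or {}
    unknown = set(thick) - _KNOWN_THICKNESS_KEYS
    if unknown:
        raise ConfigError(f"unknown thickness keys: {sorted(unknown)}")
    out["thickness"] = thick
    rel = raw.get("reliability", {}) or {}
    unknown = set(rel) - _KNOWN_RELIABILITY_KEYS
    if unknown:
        raise ConfigError(f"unknown reliability keys: {sorted(unknown)}")
    out["reliability"] = rel
    return out


def read_measurement_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format thickness measurement CSV."""
    from .reliability import validate_table

    return validate_table(pd.read_csv(path))
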