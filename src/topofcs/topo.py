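"""Height-map I/O and scanning-probe topography preprocessing.

Reproduces the standard preprocessing chain for SICM cell-surface rasters:

1. 3x3 median filter of the raw height data.
2. Cell masking (raster file or polygon).
3. Slope computation along the fast-scan axis.
4. Gaussian smoothing (FWHM 8 px) of either the masked slope field with
   height reconstruction, or of the height directly, and selection of the
   highest smoothed point as the reference point.
5. Line-artifact removal: per fast-scan line, a straight line fitted over a
   user-selected region is subtracted from the whole line (removes dish tilt
   and retraction steps).

Smoothing the slope rather than the height avoids the influence of pipette
positioning inaccuracies along the slow scanning direction; the height-direct
mode is the fallback for cells adjacent to neighbours where slope smoothing
fails.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .surfaces import HeightMap

logger = logging.getLogger(__name__)

REFERENCE_SMOOTH_FWHM_PX = 8.0
_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class SlopeMap:
    """Fast-axis slope field dz/du (dimensionless) aligned with its source map."""

    slopes: np.ndarray
    source: HeightMap

    def __post_init__(self) -> None:
        if self.slopes.shape != self.source.heights.shape:
            raise ValueError("slope grid shape must match the source height map")


@dataclass
class ReferencePoint:
    """Grid indices (row, col) of the highest smoothed point inside the mask."""

    row: int
    col: int


class FormatError(ValueError):
    """Raised when a height-map or mask file does not parse."""


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FORMATS = ("ascii-matrix", "csv", "tiff")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "tiff"
    if suffix == ".csv":
        return "csv"
    return "ascii-matrix"


def _parse_text_grid(path: Path, delimiter: str | None) -> np.ndarray:
    rows: list[list[float]] = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(delimiter) if delimiter else line.split()
            try:
                row = [float(v) for v in fields if v != ""]
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric value on line {lineno}: {exc}") from None
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise FormatError(
                    f"{path}: ragged row on line {lineno} "
                    f"({len(row)} values, expected {width})"
                )
            rows.append(row)
    if not rows:
        raise FormatError(f"{path}: no numeric data found")
    return np.array(rows, dtype=float)


def read_height_map(
    path: str | Path,
    pixel_size: float,
    format: str | None = None,
    fast_axis: int = 1,
) -> HeightMap:
    """Read a height map from an ASCII matrix, CSV, or single-channel TIFF.

    ``pixel_size`` is in nm. The format is inferred from the file suffix
    unless given explicitly.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"format must be one of {_FORMATS}, got {fmt!r}")
    if fmt == "tiff":
        import tifffile

        data = np.asarray(tifffile.imread(path), dtype=float)
        if data.ndim != 2:
            raise FormatError(f"{path}: expected a single-channel 2D TIFF, got shape {data.shape}")
    else:
        data = _parse_text_grid(path, "," if fmt == "csv" else None)
    return HeightMap(data, pixel_size=pixel_size, fast_axis=fast_axis)


def write_height_map(hmap: HeightMap, path: str | Path, format: str | None = None) -> Path:
    """Write a height map; round-trips with :func:`read_height_map` within format precision."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "tiff":
        import tifffile

        tifffile.imwrite(path, hmap.heights.astype(np.float32))
    elif fmt == "csv":
        np.savetxt(path, hmap.heights, delimiter=",", fmt="%.10g")
    elif fmt == "ascii-matrix":
        np.savetxt(path, hmap.heights, fmt="%.10g")
    else:
        raise ValueError(f"format must be one of {_FORMATS}, got {fmt!r}")
    return path


def read_mask(path: str | Path, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Read a boolean mask from a PNG/CSV raster or a polygon JSON file.

    Polygon JSON: ``{"shape": [nrow, ncol], "vertices": [[row, col], ...]}``;
    pixels inside the polygon are True. Raster files are thresholded at > 0.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            spec = json.load(fh)
        try:
            poly_shape = tuple(spec["shape"]) if shape is None else shape
            vertices = np.asarray(spec["vertices"], dtype=float)
        except (KeyError, TypeError) as exc:
            raise FormatError(f"{path}: polygon JSON needs 'shape' and 'vertices': {exc}") from None
        from skimage.draw import polygon2mask

        return polygon2mask(poly_shape, vertices)
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(path))
        if arr.ndim == 3:
            arr = arr[..., 0]
        return arr > 0
    return _parse_text_grid(path, "," if path.suffix.lower() == ".csv" else None) > 0


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def median_filter_3x3(hmap: HeightMap) -> HeightMap:
    """3x3 median filter of the raw heights (edge pixels use reflected borders).

    The filter runs on the full frame; any mask applies afterwards.
    """
    if min(hmap.heights.shape) < 3:
        raise ValueError("median filter needs a grid of at least 3x3 pixels")
    out = hmap.copy()
    out.heights = ndimage.median_filter(hmap.heights, size=3, mode="reflect")
    return out


def compute_slope(hmap: HeightMap) -> SlopeMap:
    """Slope dz/du along the fast axis: central differences interior, one-sided at borders."""
    if hmap.heights.shape[hmap.fast_axis] < 2:
        raise ValueError("need at least 2 pixels along the fast axis")
    slopes = np.gradient(hmap.heights, hmap.pixel_size, axis=hmap.fast_axis)
    return SlopeMap(slopes, hmap)


def gaussian_kernel_1d(fwhm_px: float, truncate: float = 4.0) -> np.ndarray:
    """Normalized 1D Gaussian kernel with the given FWHM in pixels (sums to 1)."""
    sigma = fwhm_px / _FWHM_PER_SIGMA
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def _masked_gaussian_smooth(field: np.ndarray, mask: np.ndarray, fwhm_px: float) -> np.ndarray:
    """Normalized convolution: Gaussian smoothing that ignores out-of-mask pixels."""
    sigma = fwhm_px / _FWHM_PER_SIGMA
    weights = ndimage.gaussian_filter(mask.astype(float), sigma, mode="constant")
    values = ndimage.gaussian_filter(np.where(mask, field, 0.0), sigma, mode="constant")
    with np.errstate(invalid="ignore"):
        out = values / weights
    out[weights == 0] = np.nan
    return out


def smooth_and_locate_reference(
    hmap: HeightMap,
    mask: np.ndarray | None = None,
    fwhm_px: float = REFERENCE_SMOOTH_FWHM_PX,
    mode: str = "slope-integrate",
) -> tuple[HeightMap, ReferencePoint]:
    """Smooth the surface and locate the reference point (highest smoothed pixel).

    mode="slope-integrate" (default): the masked fast-axis slope field is
    convolved with a 2D Gaussian (FWHM ``fwhm_px`` pixels) and the height is
    reconstructed by cumulative summation along the fast axis; each line's
    integration constant is anchored to the line's pre-smoothing mean height.
    mode="height-direct": the height itself is convolved (fallback used when
    a neighbouring cell corrupts the slope route).

    Returns the smoothed map and the argmax within the mask. Ties are broken
    to the first maximum in row-major order (a warning is emitted).
    """
    if mode not in ("slope-integrate", "height-direct"):
        raise ValueError(f"unknown mode {mode!r}")
    if mask is None:
        mask = np.ones(hmap.heights.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != hmap.heights.shape:
        raise ValueError("mask shape must match the height map")
    if not mask.any():
        raise ValueError("mask selects no pixels")

    if mode == "height-direct":
        smoothed = _masked_gaussian_smooth(hmap.heights, mask, fwhm_px)
    else:
        slopes = compute_slope(hmap).slopes
        sm_slope = _masked_gaussian_smooth(slopes, mask, fwhm_px)
        sm_slope = np.nan_to_num(sm_slope, nan=0.0)
        smoothed = np.cumsum(sm_slope, axis=hmap.fast_axis) * hmap.pixel_size
        # anchor each line to its pre-smoothing mean height over the mask
        line_axis = hmap.fast_axis
        masked_h = np.where(mask, hmap.heights, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            target = np.nanmean(masked_h, axis=line_axis)
            masked_s = np.where(mask, smoothed, np.nan)
            current = np.nanmean(masked_s, axis=line_axis)
        shift = np.nan_to_num(target - current, nan=0.0)
        smoothed = smoothed + (shift[:, None] if line_axis == 1 else shift[None, :])
    smoothed_masked = np.where(mask, smoothed, -np.inf)
    smoothed_masked[~np.isfinite(smoothed_masked)] = -np.inf
    flat_idx = int(np.argmax(smoothed_masked))
    peak = smoothed_masked.flat[flat_idx]
    if np.count_nonzero(smoothed_masked == peak) > 1:
        logger.warning(
            "reference point is not unique (%d pixels at the maximum); "
            "using the first in row-major order",
            np.count_nonzero(smoothed_masked == peak),
        )
    row, col = np.unravel_index(flat_idx, smoothed.shape)
    out = hmap.copy()
    out.heights = smoothed
    out.mask = mask
    return out, ReferencePoint(int(row), int(col))


def remove_line_artifacts(hmap: HeightMap, region_mask: np.ndarray) -> HeightMap:
    """Subtract a per-line straight-line fit over ``region_mask`` from each fast-scan line.

    Removes dish tilt and per-line offset steps introduced by fast pipette
    retraction, using a flat reference region (e.g. bare substrate) selected
    by ``region_mask``. Lines with fewer than 2 region pixels are left
    unchanged with a warning.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if region_mask.shape != hmap.heights.shape:
        raise ValueError("region mask shape must match the height map")
    out = hmap.copy()
    h = out.heights if hmap.fast_axis == 1 else out.heights.T
    rmask = region_mask if hmap.fast_axis == 1 else region_mask.T
    u = np.arange(h.shape[1], dtype=float)
    skipped = 0
    for i in range(h.shape[0]):
        sel = rmask[i]
        if sel.sum() < 2:
            skipped += 1
            continue
        coef = np.polynomial.polynomial.polyfit(u[sel], h[i, sel], 1)
        h[i] -= np.polynomial.polynomial.polyval(u, coef)
    if skipped:
        logger.warning(
            "remove_line_artifacts: %d lines had < 2 region pixels and were left unchanged",
            skipped,
        )
    if hmap.fast_axis == 0:
        out.heights = h.T
    return out
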