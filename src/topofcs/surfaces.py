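"""Synthetic surface fixtures with known geometry and statistics.

Every downstream stage (preprocessing, roughness statistics, diffusion
simulation, FCS modeling) is exercised on surfaces generated here, so each
generator is deterministic given its seed and has closed-form properties a
test can check: flat and tilted planes, sinusoids, Gaussian random fields
with prescribed RMS amplitude and correlation length, and lamellar terrace
surfaces that emulate the step-like features common on epithelial cell
surfaces. Scan artifacts (per-line offsets along the slow axis, a global
tilt plane) emulate the positioning inaccuracies of scanning-probe rasters.

Heights and pixel sizes are in nanometres throughout. The default pixel
size of 125 nm mirrors typical live-cell SICM rasters; simulation fixtures
may be generated directly at finer pitch.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

DEFAULT_PIXEL_SIZE_NM = 125.0

#: FWHM of a unit-variance Gaussian; used to convert correlation lengths.
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class HeightMap:
    """Gridded surface heights with lateral sampling metadata.

    Parameters
    ----------
    heights
        2D array of surface heights in nm, indexed ``[row, col]``.
    pixel_size
        Lateral sampling in nm (> 0), identical along both axes.
    fast_axis
        Raster fast-scan axis: ``1`` means the fast direction runs along
        columns (within a row), ``0`` along rows. Roughness and line-artifact
        operations act along this axis.
    mask
        Optional boolean array of the same shape marking valid (cell) pixels.
    """

    heights: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE_NM
    fast_axis: int = 1
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2D array")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.fast_axis not in (0, 1):
            raise ValueError(f"fast_axis must be 0 or 1, got {self.fast_axis}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.heights.shape:
                raise ValueError("mask shape must match heights shape")
        region = self.heights if self.mask is None else self.heights[self.mask]
        if region.size and not np.all(np.isfinite(region)):
            raise ValueError("heights must be finite on the masked region")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    @property
    def extent_nm(self) -> tuple[float, float]:
        """(width, height) of the sampled footprint in nm, node-to-node."""
        nrow, ncol = self.heights.shape
        return ((ncol - 1) * self.pixel_size, (nrow - 1) * self.pixel_size)

    def copy(self) -> "HeightMap":
        return HeightMap(
            self.heights.copy(),
            self.pixel_size,
            self.fast_axis,
            None if self.mask is None else self.mask.copy(),
        )


@dataclass
class SurfaceSpec:
    """Declarative description of a synthetic surface, for sidecar metadata."""

    kind: str
    nx: int = 64
    ny: int = 64
    pixel_size: float = DEFAULT_PIXEL_SIZE_NM
    amplitude: float = 0.0
    period: float = 0.0
    correlation_length: float = 0.0
    step_height: float = 0.0
    terrace_width: float = 0.0
    seed: int = 0

    _KINDS = ("flat", "plane", "sinusoid", "random_field", "lamellar")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}, got {self.kind!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    def build(self) -> HeightMap:
        """Materialize the described surface (bit-exact for a given seed)."""
        if self.kind == "flat":
            return make_flat(self.nx, self.ny, self.pixel_size, self.amplitude)
        if self.kind == "plane":
            return make_plane(self.nx, self.ny, self.pixel_size, self.amplitude, 0.0)
        if self.kind == "sinusoid":
            return make_sinusoid(self.nx, self.ny, self.pixel_size, self.amplitude, self.period)
        if self.kind == "random_field":
            return make_random_field(
                self.nx, self.ny, self.pixel_size, self.amplitude, self.correlation_length, self.seed
            )
        return make_lamellar(
            self.nx, self.ny, self.pixel_size, self.step_height, self.terrace_width
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _check_dims(nx: int, ny: int) -> None:
    if nx < 8 or ny < 8:
        raise ValueError(f"grid must be at least 8x8 pixels, got {nx}x{ny}")


def make_flat(nx: int, ny: int, pixel_size: float = DEFAULT_PIXEL_SIZE_NM, height: float = 0.0) -> HeightMap:
    """Perfectly flat surface at constant ``height`` (nm); ny rows, nx columns."""
    _check_dims(nx, ny)
    return HeightMap(np.full((ny, nx), float(height)), pixel_size)


def make_plane(
    nx: int,
    ny: int,
    pixel_size: float = DEFAULT_PIXEL_SIZE_NM,
    slope_x: float = 0.0,
    slope_y: float = 0.0,
    height: float = 0.0,
) -> HeightMap:
    """Tilted plane z = height + slope_x*x + slope_y*y (slopes dimensionless nm/nm)."""
    _check_dims(nx, ny)
    x = np.arange(nx) * pixel_size
    y = np.arange(ny) * pixel_size
    z = height + slope_x * x[None, :] + slope_y * y[:, None]
    return HeightMap(z, pixel_size)


def make_sinusoid(
    nx: int,
    ny: int,
    pixel_size: float = DEFAULT_PIXEL_SIZE_NM,
    amplitude: float = 100.0,
    period: float = 1000.0,
    axis: int = 1,
) -> HeightMap:
    """Sinusoidal corrugation z = amplitude*sin(2*pi*u/period) along ``axis``.

    ``period`` must resolve on the grid (>= 4 pixels) to avoid aliasing.
    """
    _check_dims(nx, ny)
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if period < 4 * pixel_size:
        raise ValueError(
            f"period {period} nm is under-sampled at pixel size {pixel_size} nm "
            "(need period >= 4*pixel_size)"
        )
    n = nx if axis == 1 else ny
    u = np.arange(n) * pixel_size
    profile = amplitude * np.sin(2.0 * np.pi * u / period)
    z = np.tile(profile, (ny, 1)) if axis == 1 else np.tile(profile[:, None], (1, nx))
    return HeightMap(z, pixel_size)


def make_random_field(
    nx: int,
    ny: int,
    pixel_size: float = DEFAULT_PIXEL_SIZE_NM,
    rms: float = 30.0,
    correlation_length: float = 500.0,
    seed: int = 0,
) -> HeightMap:
    """Isotropic Gaussian random field with exact sample RMS and a set lateral scale.

    White Gaussian noise is low-pass filtered with a Gaussian kernel whose
    FWHM equals ``correlation_length`` (nm), then the sample is rescaled to
    zero mean and exactly the requested ``rms`` (nm). rms=0 returns a flat map.
    """
    _check_dims(nx, ny)
    if rms < 0:
        raise ValueError("rms must be >= 0")
    if rms == 0:
        return make_flat(nx, ny, pixel_size, 0.0)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((ny, nx))
    sigma_px = correlation_length / FWHM_PER_SIGMA / pixel_size
    z = ndimage.gaussian_filter(noise, sigma=sigma_px, mode="wrap")
    z -= z.mean()
    sample_rms = np.sqrt(np.mean(z**2))
    if sample_rms == 0:  # pathological: kernel wider than the patch
        raise ValueError("correlation length too large for the grid; field degenerate")
    z *= rms / sample_rms
    return HeightMap(z, pixel_size)


def make_lamellar(
    nx: int,
    ny: int,
    pixel_size: float = DEFAULT_PIXEL_SIZE_NM,
    step_height: float = 100.0,
    terrace_width: float = 2000.0,
    edge_width: float | None = None,
) -> HeightMap:
    """Terraced staircase along the fast axis emulating lamellar membrane features.

    Terraces are flat plateaus of width ``terrace_width`` (nm) separated by
    smoothed steps of height ``step_height`` (nm); abrupt height changes occur
    only at terrace fronts, mirroring lamellar structures seen on live cells.
    ``edge_width`` (nm) controls the step smoothing (default: one pixel).
    """
    _check_dims(nx, ny)
    if terrace_width <= 0:
        raise ValueError("terrace_width must be > 0")
    if edge_width is None:
        edge_width = pixel_size
    x = np.arange(nx) * pixel_size
    # smooth staircase: sum of logistic steps at terrace fronts
    n_steps = int(x[-1] // terrace_width) + 1
    profile = np.zeros_like(x)
    for k in range(1, n_steps + 1):
        profile += step_height / (1.0 + np.exp(-(x - k * terrace_width) / max(edge_width / 4.0, 1e-9)))
    return HeightMap(np.tile(profile, (ny, 1)), pixel_size)


def add_scan_artifacts(
    hmap: HeightMap,
    line_offset_sd: float = 0.0,
    tilt: float = 0.0,
    seed: int = 0,
) -> HeightMap:
    """Add raster-scan artifacts: random per-line offsets and a global tilt.

    Each slow-scan line (i.e. each line along the fast axis) receives an
    independent Normal(0, ``line_offset_sd``) height offset, emulating
    pipette-positioning inaccuracies along the slow direction; ``tilt``
    (nm per pixel along the slow axis) adds a tilt plane such as a tilted
    culture dish. The input map is not modified.
    """
    out = hmap.copy()
    slow_axis = 1 - hmap.fast_axis
    n_lines = hmap.heights.shape[slow_axis]
    offsets = np.zeros(n_lines)
    if line_offset_sd > 0:
        rng = np.random.default_rng(seed)
        offsets = rng.normal(0.0, line_offset_sd, size=n_lines)
    ramp = offsets + tilt * np.arange(n_lines)
    if slow_axis == 0:
        out.heights += ramp[:, None]
    else:
        out.heights += ramp[None, :]
    return out
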