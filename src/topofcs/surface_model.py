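"""Continuous surface representation for diffusion simulation.

A measured (or synthetic) height map is interpolated with cubic splines to a
fine grid (~5 nm pitch) providing z(x, y) for arbitrary lateral coordinates,
precomputed gradient fields on the fine grid, and the excess-area diagnostic
— the ratio of true membrane area to its flat lateral footprint, which is
the geometric driver of FCS transit-time inflation.

During simulation gradients are looked up at the nearest fine-grid node
rather than evaluated analytically, matching the grid-lookup update of the
random walk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RectBivariateSpline

from .surfaces import HeightMap

DEFAULT_FINE_PITCH_NM = 5.0


@dataclass
class InterpolatedSurface:
    """Cubic-spline surface on a fine grid with precomputed gradients.

    Coordinates: x runs along columns, y along rows, both in nm starting at 0.
    ``z_grid``, ``gx``, ``gy`` are sampled on the fine grid with spacing
    ``pitch``; ``gx = dz/dx``, ``gy = dz/dy`` (dimensionless) by central
    differences on the fine grid.
    """

    z_grid: np.ndarray
    gx: np.ndarray
    gy: np.ndarray
    pitch: float
    extent: tuple[float, float]  # (Lx, Ly) in nm
    _spline: RectBivariateSpline

    @property
    def is_flat(self) -> bool:
        return bool(np.all(self.gx == 0.0) and np.all(self.gy == 0.0))

    def _check_inside(self, x: np.ndarray, y: np.ndarray) -> None:
        Lx, Ly = self.extent
        if np.any(x < 0) or np.any(x > Lx) or np.any(y < 0) or np.any(y > Ly):
            raise ValueError(f"query outside surface extent (0..{Lx}, 0..{Ly}) nm")

    def z(self, x, y):
        """Interpolated height (nm) at arbitrary lateral coordinates inside the extent."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        self._check_inside(x, y)
        return self._spline(y, x, grid=False)

    def nearest_node(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) indices of the fine-grid node closest to (x, y)."""
        col = np.clip(np.rint(np.asarray(x) / self.pitch).astype(int), 0, self.z_grid.shape[1] - 1)
        row = np.clip(np.rint(np.asarray(y) / self.pitch).astype(int), 0, self.z_grid.shape[0] - 1)
        return row, col

    def z_nearest(self, x, y):
        """Height at the nearest fine-grid node (the simulation's lookup resolution)."""
        row, col = self.nearest_node(x, y)
        return self.z_grid[row, col]

    def gradients_nearest(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """(gx, gy) at the nearest fine-grid node."""
        row, col = self.nearest_node(x, y)
        gx = self.gx[row, col]
        gy = self.gy[row, col]
        if np.any(~np.isfinite(gx)) or np.any(~np.isfinite(gy)):
            bad = np.argwhere(~(np.isfinite(gx) & np.isfinite(gy)))
            raise ValueError(f"non-finite gradient at fine-grid node(s) {bad[:5].tolist()}")
        return gx, gy


def interpolate_surface(
    hmap: HeightMap, target_pitch: float = DEFAULT_FINE_PITCH_NM
) -> InterpolatedSurface:
    """Cubic-spline interpolation of a height map onto a ~``target_pitch`` nm grid.

    The interpolant reproduces the input nodes exactly; the fine-grid pitch is
    the largest value <= ``target_pitch`` that divides the extent into an
    integer number of intervals, so the fine grid includes the input nodes.
    """
    nrow, ncol = hmap.heights.shape
    if nrow < 4 or ncol < 4:
        raise ValueError("cubic interpolation needs a grid of at least 4x4 nodes")
    px = hmap.pixel_size
    x_nodes = np.arange(ncol) * px
    y_nodes = np.arange(nrow) * px
    spline = RectBivariateSpline(y_nodes, x_nodes, hmap.heights, kx=3, ky=3, s=0)
    Lx, Ly = x_nodes[-1], y_nodes[-1]
    # integer refinement of the input pitch keeps input nodes on the fine grid
    refine = max(1, int(np.ceil(px / target_pitch)))
    pitch = px / refine
    xf = np.arange(refine * (ncol - 1) + 1) * pitch
    yf = np.arange(refine * (nrow - 1) + 1) * pitch
    z_grid = spline(yf, xf, grid=True)
    gy, gx = np.gradient(z_grid, pitch)
    return InterpolatedSurface(z_grid, gx, gy, pitch, (float(Lx), float(Ly)), spline)


def excess_area(
    surface: InterpolatedSurface,
    region: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> float:
    """Ratio of true surface area to flat footprint area over a rectangular region.

    Integrates sqrt(1 + gx^2 + gy^2) over the fine grid with the trapezoid
    rule and divides by the footprint area; >= 1, equal to 1 only for a
    horizontal plane. ``region`` is ((x0, x1), (y0, y1)) in nm; default is
    the full extent.
    """
    Lx, Ly = surface.extent
    if region is None:
        region = ((0.0, Lx), (0.0, Ly))
    (x0, x1), (y0, y1) = region
    if not (0 <= x0 < x1 <= Lx and 0 <= y0 < y1 <= Ly):
        raise ValueError(f"region {region} empty or outside extent (0..{Lx}, 0..{Ly})")
    p = surface.pitch
    c0, c1 = int(np.floor(x0 / p)), int(np.ceil(x1 / p))
    r0, r1 = int(np.floor(y0 / p)), int(np.ceil(y1 / p))
    gx = surface.gx[r0 : r1 + 1, c0 : c1 + 1]
    gy = surface.gy[r0 : r1 + 1, c0 : c1 + 1]
    integrand = np.sqrt(1.0 + gx**2 + gy**2)
    area = np.trapezoid(np.trapezoid(integrand, dx=p, axis=1), dx=p, axis=0)
    footprint = (c1 - c0) * p * (r1 - r0) * p
    return float(area / footprint)
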