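"""Hypothetical confocal microscope: excitation profile and geometric pinhole.

The detected intensity of a molecule at position (xS, yS, zS) relative to
the beam focus is I = gamma * rho:

* gamma — 3D Gaussian excitation, gamma = (w0/wz)^2 exp(-2 (xS^2+yS^2)/wz^2),
  with w0 the 1/e^2 beam radius at focus derived from the diffraction-limited
  FWHM Gamma = lambda_exc/(2 NA), and wz the beam width at axial offset zS.
* rho — geometric pinhole transmission: the emission cone of a molecule at
  axial offset zS reaches the (M = 1) image plane as a circle of radius
  Rz = R0 + |zS| tan(alpha); rho is the fraction of that circle's area
  passing the pinhole of radius R_ph, computed from the two-circle
  intersection (lens) area.

Photophysics (quantum yield, blinking, bleaching) and detector noise are
deliberately omitted: only position-dependent factors enter, so topography
is the sole source of correlation structure.

Two beam-width conventions are provided: "paper" uses
wz = w0 (1 + (zS/z0)^2); "standard" the usual Gaussian-beam
wz = w0 sqrt(1 + (zS/z0)^2). They agree in the focal plane, which is where
all molecules sit for a flat membrane with the focus on the surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .surface_model import InterpolatedSurface

#: Airy-unit constant: Airy disk diameter = 1.22 lambda_em / NA (for M = 1).
AIRY_DIAMETER_FACTOR = 1.22

_SQRT_2LN2 = np.sqrt(2.0 * np.log(2.0))


@dataclass
class OpticalModel:
    """Optics of the modeled confocal microscope, with derived beam constants.

    Defaults follow a resolution-limit instrument: excitation 570 nm,
    emission 620 nm, oil-like medium n = 1.518, NA 1.4, magnification 1,
    pinhole radius 0.5 Airy units. ``spot_scale`` rescales the excitation
    spot *area* by s (w0 and Gamma scale by sqrt(s)) for spot-size-variation
    FCS, modeling the series as a family of wavelength-scaled instruments:
    both wavelengths scale by sqrt(s), so the emission cone and the pinhole
    (still 0.5 AU of the scaled instrument) shrink with the spot and the
    whole detection profile is geometrically similar across spot sizes.
    This keeps transit times exactly proportional to s for free diffusion
    on a flat membrane (the diffusion-law reference behavior); with a fixed
    absolute pinhole even flat-surface diffusion would read as apparently
    anomalous, an instrument artifact rather than a topographic effect.
    """

    lambda_exc: float = 570.0  # nm
    lambda_em: float = 620.0  # nm
    n_medium: float = 1.518
    NA: float = 1.4
    magnification: float = 1.0
    pinhole_au: float = 0.5  # pinhole radius in Airy units (Airy disk diameters)
    spot_scale: float = 1.0  # excitation spot area as a multiple of the reference spot
    beam_width_mode: str = "paper"  # or "standard"

    def __post_init__(self) -> None:
        if not self.NA < self.n_medium:
            raise ValueError("NA must be smaller than the medium refractive index")
        if self.spot_scale <= 0:
            raise ValueError("spot_scale must be > 0")
        if self.beam_width_mode not in ("paper", "standard"):
            raise ValueError(f"beam_width_mode must be 'paper' or 'standard', got {self.beam_width_mode!r}")

    # -- derived constants (all nm / rad) -----------------------------------
    @property
    def _scale(self) -> float:
        """sqrt(spot_scale): linear scale factor of the wavelength-scaled instrument."""
        return float(np.sqrt(self.spot_scale))

    @property
    def fwhm(self) -> float:
        """Excitation spot FWHM Gamma = lambda_exc/(2 NA), scaled by sqrt(spot_scale)."""
        return self.lambda_exc * self._scale / (2.0 * self.NA)

    @property
    def w0(self) -> float:
        """1/e^2 beam radius at focus, w0 = Gamma / sqrt(2 ln 2)."""
        return self.fwhm / _SQRT_2LN2

    @property
    def z0(self) -> float:
        """Rayleigh length z0 = pi w0^2 / lambda_exc."""
        return np.pi * self.w0**2 / (self.lambda_exc * self._scale)

    @property
    def alpha_half(self) -> float:
        """Half cone angle of the objective, arcsin(NA/n)."""
        return float(np.arcsin(self.NA / self.n_medium))

    @property
    def r0(self) -> float:
        """Minimum emission-cone radius (resolution limit), R0 = lambda_em/(2 NA)."""
        return self.lambda_em * self._scale / (2.0 * self.NA)

    @property
    def airy_unit(self) -> float:
        """Airy disk diameter, 1.22 lambda_em / NA (one AU), in nm."""
        return AIRY_DIAMETER_FACTOR * self.lambda_em * self._scale / self.NA

    @property
    def pinhole_radius_nm(self) -> float:
        return self.pinhole_au * self.airy_unit

    def with_spot_scale(self, s: float) -> "OpticalModel":
        """Copy of the model with the excitation spot area scaled by ``s``."""
        return OpticalModel(
            self.lambda_exc,
            self.lambda_em,
            self.n_medium,
            self.NA,
            self.magnification,
            self.pinhole_au,
            s,
            self.beam_width_mode,
        )

    # -- per-molecule intensity factors -------------------------------------
    def beam_width(self, z):
        """Beam width wz at axial offset z, by the configured convention."""
        z = np.asarray(z, dtype=float)
        u = 1.0 + (z / self.z0) ** 2
        return self.w0 * (u if self.beam_width_mode == "paper" else np.sqrt(u))

    def excitation(self, xs, ys, zs):
        """Excitation factor gamma in (0, 1]; gamma(0,0,0) = 1."""
        xs, ys, zs = (np.asarray(v, dtype=float) for v in (xs, ys, zs))
        wz = self.beam_width(zs)
        return (self.w0 / wz) ** 2 * np.exp(-2.0 * (xs**2 + ys**2) / wz**2)

    def pinhole_factor(self, xs, ys, zs):
        """Pinhole transmission rho in [0, 1] by two-circle geometry.

        With d the lateral distance to the optical axis and
        Rz = R0 + |zS| tan(alpha_half):

        * rho = 0 when the cone misses the pinhole (d > R_ph + Rz),
        * rho = 1 when the cone fits inside the pinhole (Rz + d <= R_ph),
        * rho = R_ph^2/Rz^2 when the pinhole is covered (d <= Rz - R_ph),
        * otherwise rho = zeta(R_ph, Rz, d) / (pi Rz^2).
        """
        xs, ys, zs = (np.asarray(v, dtype=float) for v in (xs, ys, zs))
        d = np.hypot(xs, ys)
        rz = self.r0 + np.abs(zs) * np.tan(self.alpha_half)
        rph = self.pinhole_radius_nm
        area = circle_intersection(rph, rz, d)
        return area / (np.pi * rz**2)

    def intensity(self, xs, ys, zs):
        """Detected single-molecule intensity I = gamma * rho in [0, 1]."""
        return self.excitation(xs, ys, zs) * self.pinhole_factor(xs, ys, zs)


def effective_spot_radius(model: OpticalModel, r_max: float = 2000.0, n: int = 8001) -> float:
    """1/e^2-equivalent radius of the in-focus detection profile W = gamma * rho.

    Defined through the effective detection area A_eff = (int W)^2 / int W^2
    as w_eff = sqrt(A_eff / pi); for a pure Gaussian profile (fully open
    pinhole) this equals w0 exactly. It is the modeled instrument's
    calibrated beam waist — the analogue of calibrating a real confocal
    volume with a reference dye — and sets the expected transit time
    tauD = w_eff^2 / (4 D) of the modeled readout.
    """
    r = np.linspace(0.0, r_max, n)
    w = model.intensity(r, 0.0, 0.0)
    a_eff = (2.0 * np.pi * np.trapezoid(w * r, r)) ** 2 / (
        2.0 * np.pi * np.trapezoid(w**2 * r, r)
    )
    return float(np.sqrt(a_eff / np.pi))


def circle_intersection(r1, r2, d):
    """Area of intersection of two circles with radii r1, r2 and center distance d.

    Standard two-circle lens area; handles nested (min-circle area) and
    disjoint (zero) configurations. Fully vectorized.
    """
    r1, r2, d = np.broadcast_arrays(
        np.asarray(r1, dtype=float), np.asarray(r2, dtype=float), np.asarray(d, dtype=float)
    )
    area = np.zeros(d.shape)
    nested = d <= np.abs(r1 - r2)
    area[nested] = np.pi * np.minimum(r1, r2)[nested] ** 2
    partial = (~nested) & (d < r1 + r2)
    if np.any(partial):
        R1, R2, D = r1[partial], r2[partial], d[partial]
        a1 = np.clip((D**2 + R1**2 - R2**2) / (2.0 * D * R1), -1.0, 1.0)
        a2 = np.clip((D**2 + R2**2 - R1**2) / (2.0 * D * R2), -1.0, 1.0)
        k = (-D + R1 + R2) * (D + R1 - R2) * (D - R1 + R2) * (D + R1 + R2)
        area[partial] = (
            R1**2 * np.arccos(a1)
            + R2**2 * np.arccos(a2)
            - 0.5 * np.sqrt(np.maximum(k, 0.0))
        )
    if area.ndim == 0:
        return float(area)
    return area


@dataclass
class IntensityTrace:
    """Summed detected intensity per simulation step at one beam position."""

    intensity: np.ndarray
    dt: float
    beam_x: float
    beam_y: float
    focal_z: float

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")


def detected_trace(
    positions: tuple[np.ndarray, np.ndarray, np.ndarray],
    model: OpticalModel,
    beam_x: float,
    beam_y: float,
    surface: InterpolatedSurface,
    dt: float = 1.0,
    chunk: int = 8192,
) -> IntensityTrace:
    """Detected intensity trace for a molecule ensemble trajectory.

    ``positions`` is (X, Y, Z), each of shape (n_steps, n_molecules) in nm.
    The beam is focused at (beam_x, beam_y) with its focal z set to the
    surface height at the nearest fine-grid node of that position; per step
    the trace is the sum over molecules of gamma * rho.
    """
    Lx, Ly = surface.extent
    if not (0 <= beam_x <= Lx and 0 <= beam_y <= Ly):
        raise ValueError(f"beam position ({beam_x}, {beam_y}) outside surface extent")
    X, Y, Z = positions
    focal_z = float(surface.z_nearest(beam_x, beam_y))
    n_steps = X.shape[0]
    trace = np.zeros(n_steps)
    # exact cull: rho (hence I) is zero when the molecule's emission cone
    # misses the pinhole, i.e. lateral distance > R_ph + R0 + |z| tan(alpha)
    rph, r0, tana = model.pinhole_radius_nm, model.r0, np.tan(model.alpha_half)
    for start in range(0, n_steps, chunk):
        sl = slice(start, min(start + chunk, n_steps))
        xs = X[sl] - beam_x
        ys = Y[sl] - beam_y
        zs = Z[sl] - focal_z
        reach = rph + r0 + np.abs(zs) * tana
        hit = xs**2 + ys**2 <= reach**2
        if hit.ndim > 1:
            rows, cols = np.nonzero(hit)
            if rows.size:
                zsel = zs[rows, cols] if zs.ndim > 1 else np.broadcast_to(zs, xs.shape)[rows, cols]
                contrib = model.intensity(xs[rows, cols], ys[rows, cols], zsel)
                trace[sl] = np.bincount(rows, weights=contrib, minlength=xs.shape[0])
        else:
            trace[sl][hit] = model.intensity(xs[hit], ys[hit], zs[hit])
    return IntensityTrace(trace, dt, beam_x, beam_y, focal_z)
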