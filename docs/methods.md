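# Methods

`topofcs` simulates what a confocal fluorescence correlation spectroscopy
(FCS) measurement reports when the membrane it probes is not flat. The
package has two arms: a topography-statistics arm that processes
scanning-probe (SICM-style) height rasters into windowed roughness maps and
their spatial distribution statistics, and a simulation arm that performs
Brownian dynamics constrained to an interpolated surface, models the
confocal readout, and analyzes the resulting intensity traces exactly as an
FCS experiment would. Everything below is implemented in the package; no
empirical number in this note comes from anywhere but the package's own
tests and scripts.

## Surface representation and diffusion model

A height map z(x, y) sampled on a raster (125 nm pixels by default,
matching live-cell SICM scans) is interpolated with bicubic splines onto a
fine grid of ~5 nm pitch. Gradients are precomputed on the fine grid by
central differences, and during simulation both the height and the gradient
are looked up at the fine-grid node nearest the molecule — the surface is
treated as a lookup table at 5 nm resolution, not re-evaluated analytically
per step.

Molecules perform a lateral random walk with per-axis Gaussian steps of
standard deviation sqrt(2 D dt). Before each step is applied, each lateral
component is multiplied by the projection factor of the local tangent
plane, cos(arctan g) = 1/sqrt(1 + g^2) per axis with g the local gradient
along that axis (a `literal` mode using cos(g) — equivalent to O(g^3) — is
provided); the molecule is then projected back onto the surface by setting
z from the grid. On a flat surface this reduces exactly to free 2D Brownian
motion; on a slope of gradient g the effective lateral diffusivity along
the gradient axis is D/(1 + g^2), i.e. the molecule diffuses with
coefficient D *on the membrane* while its lateral (imaged) progress slows.
Per-axis scaling, rather than the full 2x2 first-fundamental-form
projection, is the update rule of the underlying algorithm; the difference
is third order in the slope.

Boundaries are reflecting by default (implemented as folding of the free
path, which has the same law as stepwise reflection for symmetric step
distributions), periodic optionally; both conserve the molecule count
exactly. On flat surfaces the walk is evaluated in closed vectorized form;
this is a pure optimization with the same law.

## Confocal readout

The modeled microscope follows a resolution-limit instrument: excitation
570 nm, emission 620 nm, NA 1.4 in n = 1.518 medium, magnification 1, and
a pinhole radius of 0.5 Airy units (Airy disk diameter = 1.22 lambda_em/NA,
so R_ph = 270.1 nm). Derived constants: excitation FWHM Gamma =
lambda_exc/(2 NA) = 203.6 nm, 1/e^2 beam radius w0 = Gamma/sqrt(2 ln 2) =
172.9 nm, Rayleigh length z0 = pi w0^2/lambda_exc = 164.8 nm, emission-cone
minimum radius R0 = lambda_em/(2 NA) = 221.4 nm.

A molecule at (xS, yS, zS) relative to the focus contributes
I = gamma * rho:

* gamma = (w0/wz)^2 exp(-2 (xS^2+yS^2)/wz^2) with wz = w0 (1 + (zS/z0)^2)
  ("paper" beam-width convention; the textbook wz = w0 sqrt(1+(zS/z0)^2) is
  available as `beam_width_mode="standard"`; the two agree in the focal
  plane, where all molecules sit for a flat membrane in focus).
* rho is the geometric pinhole transmission: the emission cone of a
  molecule at axial offset zS reaches the image plane as a circle of radius
  Rz = R0 + |zS| tan(alpha_half), alpha_half = arcsin(NA/n); rho is the
  fraction of that circle passing the pinhole, computed from the two-circle
  lens area with the nested/disjoint special cases handled exactly.

Photophysics and detector noise are deliberately absent: position is the
only source of intensity structure.

Two consequences of this optical model matter for everything downstream:

1. **The pinhole narrows the detection profile.** With R0 = 221 nm and
   R_ph = 270 nm, rho falls below 1 for lateral offsets beyond ~49 nm, and
   the effective detection area A_eff = (int W)^2 / int W^2 of the in-focus
   profile W = gamma*rho is 0.83 pi w0^2. The package therefore defines an
   effective spot radius w_eff = sqrt(A_eff/pi) = 157.7 nm (equal to w0
   exactly when the pinhole passes everything) and uses tauD =
   w_eff^2/(4 D) as the expected transit time — the modeling analogue of
   calibrating a real instrument's focal volume with a reference dye of
   known D, which is also how the experimental beam waists in this line of
   work are obtained. Comparing against w0^2/(4 D) instead would build a
   17% "bias" into a perfectly correct pipeline.
2. **The axial profile is tight.** z0 = 165 nm makes detection fall to half
   within ~100 nm of defocus. Topographic relief therefore acts in two
   opposing ways: extra membrane path inflates transit times, while
   out-of-focus membrane is simply not seen, deflating them. Which effect
   wins depends on the amplitude and lateral scale of the relief (see
   "Fixture regimes" below).

## Spot-size-variation FCS

Spot areas are reported as multiples s of the reference spot area. The
instrument family is wavelength-scaled: both wavelengths scale by sqrt(s),
so Gamma, w0, z0, R0 and the (still 0.5 AU) pinhole all scale together and
the detection profile is geometrically similar across spot sizes. This
choice makes flat-membrane transit times exactly proportional to s — the
free-diffusion reference law alpha = 1 — which is the baseline against
which apparent anomalous diffusion is defined. (Scaling only the excitation
beam while pinning the pinhole at its 200 nm-spot size would make even
free diffusion on a flat membrane read alpha ~ 0.97, an instrument artifact
that would contaminate the topographic signal.) The default five FWHMs are
65, 100, 140, 203.6 and 300 nm; the fourth is the unscaled reference beam,
so s = 1 is a member of every scan.

The diffusion law A s^alpha is fitted to the per-spot mean transit times by
weighted least squares with weights mean/variance (spots measured more
precisely, relative to their size, count more), initialized from log-log
ordinary regression; 95% confidence intervals come from the parameter
covariance with a t(n-2) reference distribution.

## Correlation analysis

The multiple-tau correlator computes lags 1..m (m = 16) at full
resolution, then repeatedly bins the trace pairwise and computes lags
m/2+1..m of the binned trace, doubling the lag spacing per level. Each
estimate uses symmetric normalization G(k) = <a b>/(<a><b>) - 1 over the
overlapping segments. Two numerical points:

* **Finite-trace offset.** Any correlator that normalizes with the
  empirical trace mean underestimates G by ~(2 sum_tau G + G(0))/T — the
  variance of the trace mean in correlation units. For 2D diffusion the
  correlation integral grows logarithmically with the observation area, so
  at desk-scale trace lengths this offset shifts fitted transit times by a
  few percent. `autocorrelate(..., debias=True)` estimates the offset from
  the measured curve itself (unclipped trapezoid over the log-spaced lags)
  and adds it back; the pipeline uses this, while the default leaves the
  raw estimator untouched so it matches a brute-force direct estimator
  bit-for-bit.
* **Fit range.** The single-spot model G = N^-1 (1+tau/tauD)^-1 is fitted
  by bounded nonlinear least squares in two passes, the second restricted
  to lags <= 8x the first-pass tauD. This fits the decay rather than the
  long noise floor and makes the range self-scaling; initialization is
  N ~ 1/G(first lag) and tauD from the half-decay lag. A fallback
  half-amplitude estimator `tau_half` (linear interpolation of the first
  crossing of half the initial amplitude) covers curves that resist the
  one-component fit.

## Study conditions and their rationale

The stated simulation conditions are a molecule density of 10 per um^2 and
five replicate runs. The printed diffusion-coefficient/step-time values are
mutually inconsistent (0.1 um^2 per step implies steps larger than the
focal spot; 0.1 um^2/s with dt = 1 us implies ~10^5-step transits), so D
and dt are exposed independently and all calibration statements are made in
dimensionless ratios. The defaults were chosen once:

* D = w_eff^2/400 per step (62.2 nm^2/step with the default optics), i.e.
  an expected reference-spot transit time of 100 steps;
* trace length 2^17 steps (~1300 transit times);
* simulation patch 6x6 um for the flat calibration (boundary recurrence
  ~60x beyond the fitted lags; a 2x2 um patch measurably distorts the
  decay because a reflecting box thins the low-k mode spectrum);
* per replicate, the readout is modeled at two beam positions 3 um apart
  and their correlation curves averaged before fitting (the positions are
  far beyond the diffusion length over the fitted lags, so the curves are
  effectively independent).

For the flat-membrane diffusion-law scan, each spot size is measured with
doubled (2^18-step) traces and four curve-averaged beam positions — a
homogeneous surface permits this, and the largest spot's detection profile
(reaching ~0.7 um from the axis) needs both the full 6x6 um patch and the
tighter statistics for its transit time to be unbiased at the percent
level.

Under these conditions the flat-membrane calibration reproduces the
expected transit time with a mean ratio of ~1.00 (20 replicates measured
during development) and a replicate-to-replicate scatter of ~7-10%, the
precision regime the procedure is described to have. The spot-size scan on
a flat membrane recovers alpha consistent with 1 (measured 1.00 +- 0.01
during development).

## Fixture regimes (what the synthetic surfaces do and do not show)

The generators produce flat/tilted planes, sinusoids, Gaussian random
fields (spectrally filtered white noise rescaled to an exact sample RMS,
correlation length = kernel FWHM), lamellar terrace staircases, and
SICM-style scan artifacts (per-line offsets, tilt). They are controlled
fixtures, not statistical models of real cell surfaces: real scans mix
lateral scales, contain overhangs SICM cannot see, and have micrometer
global relief.

Because of the tight axial profile, the transit-time inflation that
motivates the package appears for topography that keeps the membrane near
focus: gentle large-scale relief, moderate slopes, and especially fine
structure probed by *small* spots that sit inside single features. The
acceptance fixture series (random fields, 300 nm correlation length, RMS 0,
75, 150 nm) shows, at one fixed position: monotonically increasing
excess area (1.00, 1.20, 1.64), monotonically increasing smallest-spot
(65 nm) transit time, monotonically decreasing diffusion-law exponent with
alpha < 1 on the rough members, and a negative alpha-transit-time
correlation — the apparent-subdiffusion phenomenology. Conversely,
large-RMS short-wavelength roughness (e.g. RMS >= 150 nm at 300 nm
correlation length probed at the 200 nm spot) can *deflate* transit times,
because membrane more than ~100 nm out of focus stops contributing;
passing tests on the fixture series therefore demonstrate the mechanism in
its operative regime, not a universal monotone relation between roughness
and transit time.

## Roughness statistics

Raw rasters are median-filtered (3x3, full frame, mask applied
afterwards). Roughness is computed only along the fast-scan axis: each run
of 7 consecutive pixels is detrended with its own degree-5 least-squares
polynomial (centered abscissae -3..3; the annihilator matrix is
precomputed and applied as a sliding dot product), and the roughness of the
central pixel is the RMS of the 7 residuals. With one residual degree of
freedom, i.i.d. Gaussian noise of variance sigma^2 yields a mean squared
roughness of sigma^2/7 — a sharp calibration used in the tests. A
`detrend_scope="line"` variant (degree-5 detrend per whole line before
windowed RMS) is provided because the windowed fit annihilates everything
smooth; both modes are reported in output metadata and the windowed
(literal) reading is the default.

The reference point is the highest point of the Gaussian-smoothed surface
(FWHM 8 px). The default route smooths the masked *slope* field and
reconstructs height by cumulative summation along the fast axis (immune to
slow-axis positioning offsets), anchoring each line's integration constant
to its pre-smoothing mean height — the reconstruction rule is not dictated
by the procedure's description, and this anchor is the package's choice;
`height-direct` smoothing is the fallback. Ties at the maximum break to the
first pixel in row-major order, with a warning.

Pixels are grouped by Euclidean distance from the reference point into ten
bands of equal width ((k-1)/10, k/10] of the maximum distance; distance 0
joins band 1. Band membership at exact 10% multiples is upper-closed (the
convention is not dictated; chosen once). Per band, R90 is the 90th
percentile (linear interpolation between order statistics) of valid
roughness pixels. Across cells, each band is compared with band 1 by a
paired two-sided t-test on log10 R90, Holm-adjusted; zero-variance paired
differences are reported as non-significant rather than infinitely
significant.

## Known limitations

* Gridded z(x, y) surfaces cannot represent overhangs or invaginations —
  a shared limitation with the SICM scans they model.
* The hyperbolic single-spot model is exact only for a 2D Gaussian
  detection profile; with the pinhole the fitted transit time carries a
  residual procedure dependence of ~1-2% (fit range, lag spacing), which
  is below the replicate scatter.
* Transit-time statistics at desk scale carry a per-replicate scatter of
  ~7-10%; quantities derived from few replicates (notably the replicate SD
  itself) are accordingly noisy.
* The per-axis projection update slightly underestimates the metric
  coupling for surfaces with strong mixed gradients; the effect is third
  order in the slope.
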