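"""FCS analysis: multiple-tau autocorrelation, model fits, spot-size scans.

The intensity trace from the modeled confocal readout is autocorrelated
with a multiple-tau correlator (log-spaced lags: after every ``m`` lags the
trace is binned pairwise and the lag spacing doubles), normalized as
G(tau) = <dI(t) dI(t+tau)> / <I>^2. A single-spot two-dimensional diffusion
model

    G(tau) = N^-1 (1 + tau/tauD)^-1

is fitted by nonlinear least squares, giving the mean focal occupancy N and
the transit time tauD. For a 2D Gaussian detection profile with 1/e^2
radius w0 and diffusion coefficient D, tauD = w0^2 / (4 D).

Spot-size-variation FCS repeats the full simulate -> trace -> correlate ->
fit pipeline at several excitation spot areas s (multiples of the reference
spot area); the diffusion law A * s^alpha fitted to the mean transit times
(weighted by mean/variance) yields the apparent anomalous-diffusion
exponent alpha: alpha = 1 for free Brownian diffusion, alpha < 1 reports
apparent subdiffusion — on a convoluted but otherwise barrier-free surface,
an artifact of topography alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .optics import IntensityTrace, OpticalModel, detected_trace
from .simulate import DiffusionParams, simulate
from .surface_model import InterpolatedSurface

logger = logging.getLogger(__name__)

DEFAULT_M = 16
#: Default excitation-spot FWHMs (nm) for spot-size-variation FCS; the
#: fourth entry is the reference spot (the default beam, FWHM ~200 nm), so
#: the area multiples s include exactly 1. 65 nm corresponds to STED-FCS,
#: 300 nm to near-infrared confocal FCS.
DEFAULT_SPOT_FWHMS_NM = (65.0, 100.0, 140.0, 570.0 / 2.8, 300.0)
#: Fixed per-replicate seed offsets derive replicate seeds from a master seed.
REPLICATE_SEED_STRIDE = 1009


@dataclass
class CorrelationCurve:
    """Lag-binned normalized autocorrelation G(tau) of an intensity trace."""

    lags: np.ndarray  # in units of the trace dt
    G: np.ndarray
    mean_intensity: float
    dt: float = 1.0

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if not np.all(np.isfinite(self.G)):
            raise ValueError("G must be finite")


@dataclass
class FcsFit:
    """Fitted single-spot model parameters: occupancy N and transit time tauD."""

    N: float
    tau_D: float
    N_err: float
    tau_D_err: float
    fit_start_lag: float
    residual_norm: float
    ok: bool = True

    @property
    def amplitude(self) -> float:
        """Model amplitude G(0+) = 1/N."""
        return 1.0 / self.N


@dataclass
class SpotScanResult:
    """Spot-size-variation FCS at one position: per-spot transit times and the diffusion-law fit."""

    spot_areas: np.ndarray  # s, multiples of the reference spot area
    tau_means: np.ndarray  # mean fitted tauD per spot (dt units)
    tau_sds: np.ndarray  # replicate SD per spot
    tau_all: np.ndarray  # (n_spots, n_replicates) individual fits (NaN = failed)
    A: float
    alpha: float
    alpha_ci95: float
    A_ci95: float


# ---------------------------------------------------------------------------
# Multiple-tau autocorrelation
# ---------------------------------------------------------------------------


def _correlate_lags(x: np.ndarray, ks: np.ndarray) -> np.ndarray:
    """Symmetric-normalization autocorrelation estimates of ``x`` at integer lags ``ks``.

    G(k) = mean(x[:-k] * x[k:]) / (mean(x[:-k]) * mean(x[k:])) - 1 — an
    estimator of <dI dI>/<I>^2 whose symmetric normalization removes most of
    the finite-trace bias.
    """
    out = np.empty(len(ks))
    for i, k in enumerate(ks):
        a, b = x[:-k], x[k:]
        out[i] = np.mean(a * b) / (np.mean(a) * np.mean(b)) - 1.0
    return out


def autocorrelate(
    trace: IntensityTrace | np.ndarray,
    m: int = DEFAULT_M,
    dt: float | None = None,
    debias: bool = False,
) -> CorrelationCurve:
    """Multiple-tau autocorrelation with coarsening parameter ``m``.

    Lags 1..m are computed at full resolution; the trace is then binned
    pairwise (averaged) and lags m/2+1..m of the binned trace are computed,
    doubling the lag spacing at each level, until the binned trace becomes
    shorter than 2 m. ``m`` must be even.

    ``debias=True`` adds back the finite-trace normalization offset: any
    estimator that normalizes with the empirical trace mean under-estimates
    G by approximately (2 sum_tau G(tau) + G(0)) / T (the variance of the
    trace mean expressed in correlation units). The correction is computed
    from the measured curve itself (unclipped trapezoid over the log-spaced
    lags, so tail noise enters with zero mean) and added as a constant;
    it is floored at zero. It matters only
    when the trace is not much longer than the correlation integral; the
    default leaves the plain estimator untouched.
    """
    if isinstance(trace, IntensityTrace):
        x = trace.intensity.astype(float)
        dt = trace.dt if dt is None else dt
    else:
        x = np.asarray(trace, dtype=float)
        dt = 1.0 if dt is None else dt
    if m < 2 or m % 2:
        raise ValueError(f"m must be even and >= 2, got {m}")
    if x.size < 4 * m:
        raise ValueError(f"trace length {x.size} too short for m={m} (need >= {4*m})")
    mean_i = float(x.mean())
    if mean_i <= 0:
        raise ValueError("trace mean must be positive for normalization")
    trace_len = x.size

    lags: list[np.ndarray] = []
    gs: list[np.ndarray] = []
    ks = np.arange(1, m + 1)
    lags.append(ks.astype(float))
    gs.append(_correlate_lags(x, ks))
    binwidth = 1.0
    ks_coarse = np.arange(m // 2 + 1, m + 1)
    while True:
        n = x.size - (x.size % 2)
        x = 0.5 * (x[0:n:2] + x[1:n:2])
        binwidth *= 2.0
        if x.size < 2 * m:
            break
        lags.append(ks_coarse * binwidth)
        gs.append(_correlate_lags(x, ks_coarse))
    all_lags = np.concatenate(lags)
    all_g = np.concatenate(gs)
    if debias:
        # unclipped trapezoid: tail noise enters with zero mean, so the
        # estimated offset is unbiased (clipping would rectify noise upward)
        integral = all_g[0] + np.trapezoid(all_g, all_lags)  # tau in [0,1] + [1,max]
        c = (2.0 * integral + all_g[0]) / trace_len
        all_g = all_g + max(c, 0.0)
    return CorrelationCurve(all_lags * dt, all_g, mean_i, dt)


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------


def _model(tau, amplitude, tau_d):
    return amplitude / (1.0 + tau / tau_d)


def fit_single_spot(
    curve: CorrelationCurve, fit_start_lag: float = 0.0, fit_range_mult: float = 8.0
) -> FcsFit:
    """Nonlinear least-squares fit of G(tau) = N^-1 (1 + tau/tauD)^-1.

    Initialization: amplitude from the first fitted point (N ~ 1/G) and
    tauD from the half-decay lag (linear interpolation). The fit is
    two-pass: a first fit over lags up to ``fit_range_mult`` times the
    initial tauD estimate sets the scale, and the final fit uses lags up to
    ``fit_range_mult`` times the first-pass tauD — fitting the decay rather
    than the long noise floor, with a range that adapts to the curve itself
    (``fit_range_mult=inf`` fits every lag). A curve that does not decay
    yields ``ok=False`` rather than silent garbage.
    """
    sel = curve.lags >= fit_start_lag
    tau, g = curve.lags[sel], curve.G[sel]
    if tau.size < 5:
        raise ValueError(f"need >= 5 points in the fit range, got {tau.size}")
    a0 = g[0]
    failed = FcsFit(np.nan, np.nan, np.nan, np.nan, fit_start_lag, np.nan, ok=False)
    if not a0 > 0:
        logger.warning("fit_single_spot: non-positive initial amplitude; curve does not decay from a positive value")
        return failed
    th = _half_crossing(tau, g, a0 / 2.0)
    t0 = th if th is not None else float(np.median(tau))
    try:
        popt = (a0, t0)
        for _ in range(2):
            rng_sel = tau <= fit_range_mult * popt[1]
            if rng_sel.sum() < 5:
                rng_sel = np.ones_like(tau, dtype=bool)
            popt, pcov = optimize.curve_fit(
                _model,
                tau[rng_sel],
                g[rng_sel],
                p0=popt,
                bounds=([0.0, 0.0], [np.inf, np.inf]),
                maxfev=20000,
                xtol=1e-13,
                ftol=1e-13,
                gtol=1e-13,
            )
        tau, g = tau[rng_sel], g[rng_sel]
    except (RuntimeError, ValueError):
        logger.warning("fit_single_spot: least-squares fit failed to converge")
        return failed
    perr = np.sqrt(np.diag(pcov))
    amp, tau_d = popt
    if not (amp > 0 and tau_d > 0 and np.isfinite(tau_d)):
        return failed
    resid = g - _model(tau, *popt)
    return FcsFit(
        N=1.0 / amp,
        tau_D=float(tau_d),
        N_err=float(perr[0] / amp**2),
        tau_D_err=float(perr[1]),
        fit_start_lag=fit_start_lag,
        residual_norm=float(np.sqrt(np.sum(resid**2))),
    )


def _half_crossing(tau: np.ndarray, g: np.ndarray, half: float) -> float | None:
    below = np.nonzero(g <= half)[0]
    if below.size == 0 or below[0] == 0:
        return None if below.size == 0 else float(tau[0])
    j = below[0]
    t1, t2, g1, g2 = tau[j - 1], tau[j], g[j - 1], g[j]
    if g1 == g2:
        return float(t2)
    return float(t1 + (g1 - half) * (t2 - t1) / (g1 - g2))


def tau_half(curve: CorrelationCurve, amplitude: float | None = None) -> float | None:
    """Lag at which G first crosses half its initial amplitude (linear interpolation).

    ``amplitude`` defaults to the first G value; pass the fitted amplitude
    for a model-based estimate. Returns None when the curve never crosses.
    For the exact single-component model, tau_half = tauD.
    """
    a = curve.G[0] if amplitude is None else amplitude
    if not a > 0:
        return None
    return _half_crossing(curve.lags, curve.G, a / 2.0)


# ---------------------------------------------------------------------------
# Spot-size-variation FCS and anomalous-diffusion statistics
# ---------------------------------------------------------------------------


def run_fcs_at(
    surface: InterpolatedSurface,
    position: tuple[float, float] | list[tuple[float, float]],
    params: DiffusionParams,
    model: OpticalModel,
    m: int = DEFAULT_M,
    fit_start_lag: float = 0.0,
) -> tuple[FcsFit, CorrelationCurve]:
    """One full pipeline run: simulate, model the readout, correlate, fit.

    ``position`` may be a single (x, y) beam position or a list of them; with
    several positions one simulation is read out at each and the correlation
    curves are averaged before fitting (useful on homogeneous surfaces, where
    well-separated positions give effectively independent curves).
    """
    beam_positions = [position] if isinstance(position[0], (int, float)) else list(position)
    trajectory = simulate(surface, params, record="positions")
    curves = []
    for bx, by in beam_positions:
        trace = detected_trace(trajectory, model, bx, by, surface, dt=params.dt)
        curves.append(autocorrelate(trace, m=m, debias=True))
    curve = curves[0]
    if len(curves) > 1:
        curve = CorrelationCurve(
            curve.lags,
            np.mean([c.G for c in curves], axis=0),
            float(np.mean([c.mean_intensity for c in curves])),
            curve.dt,
        )
    return fit_single_spot(curve, fit_start_lag=fit_start_lag), curve


def spot_scan(
    surface: InterpolatedSurface,
    position: tuple[float, float] | list[tuple[float, float]],
    params: DiffusionParams,
    model: OpticalModel,
    spot_fwhms_nm: tuple[float, ...] = DEFAULT_SPOT_FWHMS_NM,
    replicates: int = 5,
    m: int = DEFAULT_M,
) -> SpotScanResult:
    """Spot-size-variation FCS at one position (or curve-averaged positions).

    For each spot FWHM the beam w0 is rescaled (spot area s = (FWHM/FWHM_ref)^2
    with the reference the unscaled model) and the full pipeline is run
    ``replicates`` times with replicate seeds at fixed offsets from
    ``params.seed``. A list of positions averages the correlation curves per
    replicate (appropriate on statistically homogeneous surfaces only —
    at a single position the scan characterizes that position's topography).
    Failed fits are flagged (NaN) and excluded from the diffusion-law fit
    with a warning.
    """
    ref_fwhm = model.with_spot_scale(1.0).fwhm
    s_values = np.array([(f / ref_fwhm) ** 2 for f in spot_fwhms_nm])
    tau_all = np.full((len(s_values), replicates), np.nan)
    for i, s in enumerate(s_values):
        spot_model = model.with_spot_scale(s)
        for r in range(replicates):
            seed = params.seed + REPLICATE_SEED_STRIDE * (i * replicates + r + 1)
            fit, _ = run_fcs_at(surface, position, params.with_seed(seed), spot_model, m=m)
            if fit.ok:
                tau_all[i, r] = fit.tau_D
            else:
                logger.warning("spot_scan: fit failed for s=%.3f replicate %d", s, r)
    means = np.nanmean(tau_all, axis=1)
    sds = np.nanstd(tau_all, axis=1, ddof=1)
    good = np.isfinite(means)
    if good.sum() < 3:
        raise RuntimeError("fewer than 3 spot sizes produced usable transit times")
    A, alpha, A_ci, a_ci = fit_alpha(s_values[good], means[good], sds[good] ** 2)
    return SpotScanResult(s_values, means, sds, tau_all, A, alpha, a_ci, A_ci)


def fit_alpha(
    spot_areas: np.ndarray, tau_means: np.ndarray, tau_vars: np.ndarray
) -> tuple[float, float, float, float]:
    """Weighted least-squares fit of the diffusion law tauD = A * s^alpha.

    Weights are mean/variance per spot (smaller relative uncertainty counts
    more); zero or non-finite variances trigger an unweighted fit with a
    warning. Initialization comes from ordinary log-log regression. Returns
    (A, alpha, A_ci95, alpha_ci95) with 95% confidence half-widths from the
    parameter covariance and a t-distribution with n-2 degrees of freedom.
    """
    s = np.asarray(spot_areas, dtype=float)
    y = np.asarray(tau_means, dtype=float)
    v = np.asarray(tau_vars, dtype=float)
    if s.size < 3:
        raise ValueError("need >= 3 spot sizes to fit the diffusion law")
    if np.any(y <= 0) or np.any(s <= 0):
        raise ValueError("spot areas and transit times must be positive")
    slope, intercept = np.polyfit(np.log(s), np.log(y), 1)
    p0 = (float(np.exp(intercept)), float(slope))
    weighted = np.all(np.isfinite(v)) and np.all(v > 0)
    if not weighted:
        logger.warning("fit_alpha: non-positive variance estimate; falling back to unweighted fit")
    # weight w_i = mean_i / var_i  <->  sigma_i = sqrt(var_i / mean_i)
    sigma = np.sqrt(v / y) if weighted else None
    popt, pcov = optimize.curve_fit(
        lambda ss, A, al: A * ss**al, s, y, p0=p0, sigma=sigma, absolute_sigma=False, maxfev=20000
    )
    perr = np.sqrt(np.diag(pcov))
    tcrit = stats.t.ppf(0.975, df=max(s.size - 2, 1))
    return float(popt[0]), float(popt[1]), float(tcrit * perr[0]), float(tcrit * perr[1])


def alpha_tau_correlation(alphas: np.ndarray, taus: np.ndarray) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between per-position alpha and reference-spot tauD.

    Returns (nan, nan) when either variable has zero variance.
    """
    alphas = np.asarray(alphas, dtype=float)
    taus = np.asarray(taus, dtype=float)
    if alphas.size != taus.size or alphas.size < 3:
        raise ValueError("need >= 3 paired (alpha, tauD) observations")
    if np.std(alphas) == 0 or np.std(taus) == 0:
        logger.warning("alpha_tau_correlation: zero variance; correlation undefined")
        return float("nan"), float("nan")
    r, p = stats.pearsonr(alphas, taus)
    return float(r), float(p)


def read_curve_csv(path) -> CorrelationCurve:
    """Import an exported FCS curve as two-column CSV (lag seconds, G)."""
    data = np.loadtxt(path, delimiter=",", ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (lag, G)")
    return CorrelationCurve(data[:, 0], data[:, 1], mean_intensity=float("nan"), dt=1.0)
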