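"""Windowed surface roughness and its spatial-distribution statistics.

Roughness is computed only along the fast scanning direction to avoid
slow-axis positioning artifacts: for every run of ``window`` (default 7)
consecutive pixels, a polynomial of degree ``detrend_degree`` (default 5)
is fitted and subtracted to remove the low-frequency cell shape, and the
roughness of the central pixel is the root of the mean of the squared
residuals. Pixels are then grouped by Euclidean distance from the reference
point (the highest smoothed point of the cell) into ``n_groups`` equal
distance bands, and the 90th percentile of roughness per band (R90)
captures the occurrence of large topographical features such as lamellar
fronts. Group R90 values from many cells are compared with paired t-tests
on log10 values, Holm-corrected.

With the default window of 7 and degree 5 the fit leaves a single residual
degree of freedom, so on a flat surface with i.i.d. Gaussian noise of
standard deviation sigma the mean squared roughness is sigma^2/7.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .surfaces import HeightMap
from .topo import ReferencePoint

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 7
DEFAULT_DETREND_DEGREE = 5
DEFAULT_N_GROUPS = 10
R90_PERCENTILE = 90.0


@dataclass
class RoughnessMap:
    """Per-pixel roughness (nm) aligned with the source map; ``valid`` marks computed pixels."""

    roughness: np.ndarray
    valid: np.ndarray
    source: HeightMap

    def values(self) -> np.ndarray:
        return self.roughness[self.valid]


@dataclass
class DistanceGrouping:
    """Per-pixel group index 1..n_groups by distance from the reference point (0 elsewhere)."""

    group_index: np.ndarray
    reference: ReferencePoint
    max_distance: float
    n_groups: int


def _residual_maker(window: int, degree: int) -> np.ndarray:
    """Annihilator matrix R with R @ y = residuals of a degree-``degree`` LS fit.

    Abscissae are centered (e.g. {-3..3} for window 7) for numerical
    stability; R = I - X (X^T X)^-1 X^T is symmetric idempotent.
    """
    half = (window - 1) // 2
    x = np.arange(-half, half + 1, dtype=float)
    X = np.vander(x, degree + 1, increasing=True)
    hat = X @ np.linalg.solve(X.T @ X, X.T)
    return np.eye(window) - hat


def roughness_map(
    hmap: HeightMap,
    window: int = DEFAULT_WINDOW,
    detrend_degree: int = DEFAULT_DETREND_DEGREE,
    detrend_scope: str = "window",
) -> RoughnessMap:
    """Windowed, polynomial-detrended RMS roughness along the fast axis.

    detrend_scope="window" (default): each sliding window of ``window``
    heights is detrended by its own degree-``detrend_degree`` LS polynomial
    and the central pixel's roughness is the RMS of the ``window`` residuals.
    detrend_scope="line": the polynomial is fitted to and subtracted from the
    whole fast-scan line first, and the windowed RMS is taken of the
    detrended values.

    The ``(window-1)/2`` border pixels along the fast axis are not computed;
    masked-out pixels (and windows touching them) are invalid.
    """
    if window % 2 == 0 or window < detrend_degree + 2:
        raise ValueError(
            f"window must be odd and >= detrend_degree+2, got window={window}, "
            f"degree={detrend_degree}"
        )
    if detrend_scope not in ("window", "line"):
        raise ValueError(f"detrend_scope must be 'window' or 'line', got {detrend_scope!r}")
    h = hmap.heights if hmap.fast_axis == 1 else hmap.heights.T
    nlines, npx = h.shape
    if npx < window:
        raise ValueError(f"fast-axis length {npx} shorter than window {window}")
    half = (window - 1) // 2

    if detrend_scope == "line":
        u = np.arange(npx, dtype=float) - (npx - 1) / 2.0
        detrended = np.empty_like(h)
        for i in range(nlines):
            coef = np.polynomial.polynomial.polyfit(u, h[i], detrend_degree)
            detrended[i] = h[i] - np.polynomial.polynomial.polyval(u, coef)
        win = np.lib.stride_tricks.sliding_window_view(detrended, window, axis=1)
        msq = np.mean(win**2, axis=-1)
    else:
        R = _residual_maker(window, detrend_degree)
        win = np.lib.stride_tricks.sliding_window_view(h, window, axis=1)
        resid = win @ R.T  # (nlines, npx-window+1, window)
        msq = np.mean(resid**2, axis=-1)

    rough = np.full(h.shape, np.nan)
    rough[:, half : npx - half] = np.sqrt(msq)
    valid = np.isfinite(rough)
    if hmap.mask is not None:
        m = hmap.mask if hmap.fast_axis == 1 else hmap.mask.T
        # a window is valid only if every contributing pixel is masked-in
        full = np.lib.stride_tricks.sliding_window_view(m, window, axis=1).all(axis=-1)
        wvalid = np.zeros_like(m)
        wvalid[:, half : npx - half] = full
        valid &= wvalid
    rough[~valid] = np.nan
    if hmap.fast_axis == 0:
        rough, valid = rough.T, valid.T
    return RoughnessMap(rough, valid, hmap)


def distance_groups(
    mask: np.ndarray,
    reference: ReferencePoint,
    pixel_size: float,
    n_groups: int = DEFAULT_N_GROUPS,
) -> DistanceGrouping:
    """Partition masked pixels into equal Euclidean-distance bands from the reference.

    Group k holds pixels with distance in ((k-1)/n, k/n] of the maximum
    distance; the reference pixel (distance 0) is in group 1 and the farthest
    pixel in group n.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask selects no pixels")
    rows, cols = np.indices(mask.shape)
    dist = np.hypot(rows - reference.row, cols - reference.col) * pixel_size
    dmax = dist[mask].max()
    if dmax == 0:
        raise ValueError("mask has a single pixel; distance grouping undefined")
    # ((k-1)/n, k/n] bands; distance 0 goes to group 1
    group = np.ceil(dist / dmax * n_groups).astype(int)
    group[dist == 0] = 1
    group[~mask] = 0
    return DistanceGrouping(group, reference, float(dmax), n_groups)


def group_r90(
    rmap: RoughnessMap,
    grouping: DistanceGrouping,
    percentile: float = R90_PERCENTILE,
    min_pixels: int = 10,
) -> pd.Series:
    """Per-group 90th percentile of valid roughness (linear-interpolation convention).

    Groups with no valid pixels get NaN; groups with fewer than ``min_pixels``
    valid pixels are computed but flagged with a warning.
    """
    out = {}
    for k in range(1, grouping.n_groups + 1):
        sel = (grouping.group_index == k) & rmap.valid
        vals = rmap.roughness[sel]
        if vals.size == 0:
            out[k] = np.nan
            continue
        if vals.size < min_pixels:
            logger.warning("group %d has only %d valid roughness pixels", k, vals.size)
        out[k] = float(np.percentile(vals, percentile))
    return pd.Series(out, name=f"R{percentile:g}").rename_axis("group")


def holm_adjust(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    reject, adj, _, _ = multipletests(pvals, method="holm")
    return adj


def compare_groups(r90_table: pd.DataFrame, baseline_group: int = 1) -> pd.DataFrame:
    """Paired t-tests of log10(R90) of each group against the baseline group.

    ``r90_table`` has one row per cell and one column per group index. Each
    non-baseline group is compared with a two-sided paired t-test on
    log10-transformed values; p-values are Holm-adjusted across the
    comparisons. Zero-variance comparisons get p = 1 (non-significant).

    Returns a table with columns t, p_raw, p_holm indexed by group.
    """
    r90_table = pd.DataFrame(r90_table)
    if len(r90_table) < 2:
        raise ValueError("need R90 vectors from at least 2 cells")
    if (r90_table.values <= 0).any() or not np.all(np.isfinite(r90_table.values)):
        raise ValueError("all R90 values must be positive and finite for the log transform")
    logv = np.log10(r90_table)
    base = logv[baseline_group]
    rows = []
    for g in r90_table.columns:
        if g == baseline_group:
            continue
        diff = logv[g] - base
        if np.allclose(diff.std(ddof=1), 0.0):
            # degenerate paired differences (no within-pair variability):
            # the test statistic is undefined; report as non-significant
            t, p = np.nan, 1.0
            logger.warning("group %s has zero-variance paired differences; reported non-significant", g)
        else:
            t, p = stats.ttest_rel(logv[g], base)
        rows.append({"group": g, "t": float(t), "p_raw": float(p)})
    table = pd.DataFrame(rows).set_index("group")
    table["p_holm"] = holm_adjust(table["p_raw"].values)
    return table
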