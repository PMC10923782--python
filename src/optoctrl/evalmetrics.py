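"""Quantitative evaluation: RMSE metrics, growth rates, partitions, smoothing.

Two root-mean-square error views are used throughout: ``rmse_time`` collapses
the time axis for one cell or sample (giving a distribution of errors over
cells), and ``rmse_cells`` collapses the cell axis at each timepoint (giving
an error trajectory).  Growth rates are computed from cell area with the
artifact filters applied as NaN markers, never as dropped indices, so all
series stay aligned with the acquisition grid.

Missing-value policy: pairwise deletion inside metrics; no imputation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "rmse_time", "rmse_cells", "growth_rate", "growing_fraction", "smooth",
    "conditioned_error", "GrowthSeries",
    "AREA_FLOOR_UM2", "FLUO_FLOOR_AU", "GROWTH_FLOOR_PER_H",
    "GROWING_THRESHOLD_PER_H",
]

#: area below which a segmentation result cannot represent a cell (µm²)
AREA_FLOOR_UM2 = 0.44
#: fluorescence below which a measurement cannot represent a cell (a.u.)
FLUO_FLOOR_AU = 100.0
#: growth-rate filter removing division steps (1/h)
GROWTH_FLOOR_PER_H = -2.4
#: heuristic threshold separating "growing" from "dying" cells (1/h)
GROWING_THRESHOLD_PER_H = 0.3


def rmse_time(f: np.ndarray, g: np.ndarray) -> float:
    """RMSE across time for one cell: sqrt(mean_t (f_t - g_t)^2).

    NaN pairs are excluded; returns NaN when no valid pair remains.
    """
    f = np.asarray(f, dtype=float)
    g = np.asarray(g, dtype=float)
    if f.shape != g.shape:
        raise ValueError("series must have equal length")
    d = f - g
    valid = np.isfinite(d)
    if not valid.any():
        return float("nan")
    return float(np.sqrt(np.mean(d[valid] ** 2)))


def rmse_cells(F: np.ndarray, G: np.ndarray) -> np.ndarray:
    """RMSE across cells at each timepoint: sqrt(mean_n (f - g)^2) per t."""
    F = np.asarray(F, dtype=float)
    G = np.asarray(G, dtype=float)
    if F.shape != G.shape:
        raise ValueError("matrices must have matched shapes")
    if F.ndim == 1:
        F, G = F[None, :], G[None, :]
    d = (F - G) ** 2
    with np.errstate(invalid="ignore"):
        out = np.sqrt(np.nanmean(d, axis=0))
    out[~np.isfinite(d).any(axis=0)] = np.nan
    return out


class GrowthSeries:
    """Per-timepoint growth rates (1/h) with NaN missing markers."""

    def __init__(self, growth: np.ndarray, area: np.ndarray,
                 fluo: np.ndarray):
        self.growth = np.asarray(growth, dtype=float)
        self.area = np.asarray(area, dtype=float)
        self.fluo = np.asarray(fluo, dtype=float)


def growth_rate(area: np.ndarray, fluo: np.ndarray, dt: float = 5.0,
                ) -> GrowthSeries:
    """Relative area increase per measurement interval, converted to 1/h.

    Filters (applied as NaN, positions preserved):

    1. area < 0.44 µm² or fluorescence < 100 a.u. -> area set to NaN
       (segmentation artifacts, more frequent as cells die);
    2. growth(t) = (area(t+1) - area(t)) / area(t), divided by dt in hours;
    3. growth < -2.4 1/h -> NaN (division steps).

    The returned growth array has length len(area) - 1; an input shorter
    than 2 points yields an empty series.
    """
    area = np.asarray(area, dtype=float).copy()
    fluo = np.asarray(fluo, dtype=float)
    if area.shape != fluo.shape:
        raise ValueError("area and fluorescence series must be aligned")
    if area.size < 2:
        return GrowthSeries(np.empty(0), area, fluo)
    bad = (area < AREA_FLOOR_UM2) | (fluo < FLUO_FLOOR_AU)
    area[bad] = np.nan
    dt_h = dt / 60.0
    with np.errstate(invalid="ignore", divide="ignore"):
        growth = (area[1:] - area[:-1]) / area[:-1] / dt_h
        growth = np.where(growth < GROWTH_FLOOR_PER_H, np.nan, growth)
    return GrowthSeries(growth, area, fluo)


def growing_fraction(growth_collection, threshold: float = GROWING_THRESHOLD_PER_H,
                     ) -> np.ndarray:
    """Fraction of cells with growth >= threshold, per timepoint.

    ``growth_collection`` is an iterable of GrowthSeries or growth arrays
    (already smoothed by the caller when desired).  Only cells with valid
    data at a timepoint enter the denominator; a timepoint with no valid
    cell is NaN.
    """
    rows = [g.growth if isinstance(g, GrowthSeries) else np.asarray(g, float)
            for g in growth_collection]
    if not rows:
        raise ValueError("empty collection")
    T = max(len(r) for r in rows)
    mat = np.full((len(rows), T), np.nan)
    for i, r in enumerate(rows):
        mat[i, :len(r)] = r
    valid = np.isfinite(mat)
    n_valid = valid.sum(axis=0).astype(float)
    n_grow = (valid & (mat >= threshold)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_valid > 0, n_grow / n_valid, np.nan)
    return frac


def _nan_median_filter(x: np.ndarray, window: int) -> np.ndarray:
    half = window // 2
    out = np.empty_like(x)
    n = len(x)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)  # window shrinks at edges
        w = x[lo:hi]
        w = w[np.isfinite(w)]
        out[i] = np.median(w) if w.size else np.nan
    return out


def _nan_savgol(x: np.ndarray, window: int, order: int) -> np.ndarray:
    half = window // 2
    out = np.empty_like(x)
    n = len(x)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        t = np.arange(lo, hi, dtype=float) - i
        w = x[lo:hi]
        good = np.isfinite(w)
        if good.sum() <= order:
            out[i] = x[i] if np.isfinite(x[i]) else np.nan
            continue
        coeffs = np.polynomial.polynomial.polyfit(t[good], w[good], order)
        out[i] = coeffs[0]  # value of the local fit at the window center
    return out


def smooth(series: np.ndarray, method: str) -> np.ndarray:
    """Missing-aware smoothing of a 5-min-sampled series.

    ``method='median-1h'``: sliding median over a one-hour window
    (13 points centered); ``method='savgol'``: Savitzky-Golay filter of
    length 15 and order 2, realized as a local least-squares quadratic fit
    so NaNs are excluded and edge windows shrink.
    """
    x = np.asarray(series, dtype=float)
    if method == "median-1h":
        return _nan_median_filter(x, 13)
    if method == "savgol":
        return _nan_savgol(x, 15, 2)
    raise ValueError(f"unknown smoothing method: {method!r}")


def _signed_log(values: np.ndarray, scale: float) -> np.ndarray:
    """Symmetric log warp handling positive and negative values."""
    return np.sign(values) * np.log10(1.0 + np.abs(values) / scale)


def conditioned_error(fluo: np.ndarray, objective: np.ndarray,
                      covariate: np.ndarray, kind: str,
                      n_bins: int = 20) -> pd.DataFrame:
    """Error statistics binned by a per-(cell, timepoint) covariate.

    ``kind`` selects the binning rule: 'objective' (linear bins on the
    objective value), 'derivative' (signed-log bins, since objectives move
    both up and down across orders of magnitude), or 'growth' (percentile
    bins 1-100 of the covariate distribution).  Each row reports the bin
    interval, the across-cell RMSE, absolute-error percentiles (25/50/75)
    and the sample count; empty bins carry NaN statistics.
    """
    fluo = np.asarray(fluo, dtype=float).ravel()
    objective = np.asarray(objective, dtype=float).ravel()
    covariate = np.asarray(covariate, dtype=float).ravel()
    if not (fluo.shape == objective.shape == covariate.shape):
        raise ValueError("inputs must have matched (flattened) shapes")
    err = fluo - objective
    ok = np.isfinite(err) & np.isfinite(covariate)
    if kind == "growth":
        pct = np.arange(0, 101)
        edges = np.percentile(covariate[ok], pct)
        edges = np.unique(edges)
        idx = np.clip(np.searchsorted(edges, covariate, side="right") - 1,
                      0, len(edges) - 2)
        labels = [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]
    elif kind == "derivative":
        scale = max(float(np.percentile(np.abs(covariate[ok]), 10)), 1e-9)
        warped = _signed_log(covariate, scale)
        w_fin = warped[ok]
        edges_w = np.linspace(w_fin.min(), w_fin.max(), n_bins + 1)
        idx = np.clip(np.searchsorted(edges_w, warped, side="right") - 1,
                      0, n_bins - 1)
        # report bin edges back in original (a.u./h) units
        edges = np.sign(edges_w) * scale * (10.0 ** np.abs(edges_w) - 1.0)
        labels = [(edges[i], edges[i + 1]) for i in range(n_bins)]
    elif kind == "objective":
        edges = np.linspace(np.nanmin(covariate[ok]), np.nanmax(covariate[ok]),
                            n_bins + 1)
        idx = np.clip(np.searchsorted(edges, covariate, side="right") - 1,
                      0, n_bins - 1)
        labels = [(edges[i], edges[i + 1]) for i in range(n_bins)]
    else:
        raise ValueError(f"unknown covariate kind: {kind!r}")
    rows = []
    for b, (lo, hi) in enumerate(labels):
        sel = ok & (idx == b)
        e = err[sel]
        if e.size:
            rows.append(dict(bin=b, lo=lo, hi=hi, n=int(e.size),
                             rmse=float(np.sqrt(np.mean(e ** 2))),
                             abs_p25=float(np.percentile(np.abs(e), 25)),
                             abs_p50=float(np.percentile(np.abs(e), 50)),
                             abs_p75=float(np.percentile(np.abs(e), 75))))
        else:
            rows.append(dict(bin=b, lo=lo, hi=hi, n=0, rmse=np.nan,
                             abs_p25=np.nan, abs_p50=np.nan, abs_p75=np.nan))
    return pd.DataFrame(rows)
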