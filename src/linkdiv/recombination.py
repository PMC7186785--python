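"""Interval-wise recombination rates from genetic-map markers.

The recombination rate of a genomic interval is estimated as the slope of the
ordinary least-squares regression of genetic map position (cM) on physical
position (Mb) over the markers falling in the interval — the local slope of
the Marey map, in cM/Mb.  Rates on a coarse grid (5 Mb by default) are then
joined to analysis windows by the window midpoint, classified into
low/mid/high genome-wide percentile classes, and windows are annotated with
counts of double-strand-break hotspot intervals.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genomic_io import tile_windows

logger = logging.getLogger(__name__)


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope of y on x and the r^2 of the fit."""
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        return np.nan, np.nan
    slope = float(xc @ yc) / sxx
    syy = float(yc @ yc)
    r2 = 1.0 if syy == 0.0 else (float(xc @ yc) ** 2) / (sxx * syy)
    return slope, r2


def interval_rates(markers: pd.DataFrame, chrom_lengths: dict[str, int],
                   interval_size: int = 5_000_000,
                   min_markers: int = 3) -> pd.DataFrame:
    """Per-interval Marey-map slopes in cM/Mb.

    Intervals tile each chromosome on a fixed grid.  Intervals with fewer
    than ``min_markers`` markers, or with no spread in physical position,
    get a missing (NaN) rate.  Negative slopes are retained but logged.
    """
    grid = tile_windows(chrom_lengths, interval_size, size_class="rate_interval")
    rates = np.full(len(grid), np.nan)
    r2s = np.full(len(grid), np.nan)
    nmark = np.zeros(len(grid), dtype=np.int64)

    for chrom, gidx in grid.groupby("chrom", sort=False).groups.items():
        gidx = np.asarray(gidx)
        sub = markers[markers["chrom"] == chrom]
        if not len(sub):
            continue
        pos_bp = sub["phys_pos_mb"].to_numpy() * 1e6
        starts = grid.loc[gidx, "start"].to_numpy()
        iv = np.searchsorted(starts, pos_bp, side="right") - 1
        ends = grid.loc[gidx, "end"].to_numpy()
        ok = (iv >= 0) & (pos_bp < ends[np.clip(iv, 0, len(gidx) - 1)])
        for local in np.unique(iv[ok]):
            sel = ok & (iv == local)
            nmark[gidx[local]] = int(sel.sum())
            if sel.sum() < min_markers:
                continue
            x = sub["phys_pos_mb"].to_numpy()[sel]
            y = sub["gen_pos_cm"].to_numpy()[sel]
            slope, r2 = _ols_slope(x, y)
            if np.isnan(slope):
                logger.warning("interval %s:%d-%d: zero variance in marker positions",
                               chrom, starts[local], ends[local])
                continue
            if slope < 0:
                logger.warning("interval %s:%d-%d: negative Marey slope %.4g cM/Mb",
                               chrom, starts[local], ends[local], slope)
            rates[gidx[local]] = slope
            r2s[gidx[local]] = r2

    out = grid.drop(columns="size_class")
    out["rate"] = rates
    out["n_markers"] = nmark
    out["r2"] = r2s
    return out


def assign_window_rate(windows: pd.DataFrame, intervals: pd.DataFrame) -> pd.Series:
    """Rate of the interval containing each window's midpoint (NaN if none/missing)."""
    rate = np.full(len(windows), np.nan)
    win = windows.reset_index(drop=True)
    for chrom, widx in win.groupby("chrom", sort=False).groups.items():
        widx = np.asarray(widx)
        sub = intervals[intervals["chrom"] == chrom]
        if not len(sub):
            continue
        mid = ((win.loc[widx, "start"] + win.loc[widx, "end"]) // 2).to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        ii = np.searchsorted(starts, mid, side="right") - 1
        ok = (ii >= 0) & (mid < ends[np.clip(ii, 0, len(sub) - 1)])
        vals = sub["rate"].to_numpy()[np.clip(ii, 0, len(sub) - 1)]
        rate[widx[ok]] = vals[ok]
    return pd.Series(rate, index=windows.index, name="rate")


def percentile_classes(window_rates: pd.Series | np.ndarray,
                       low_pct: float = 5.0, high_pct: float = 95.0) -> pd.Series:
    """Classify windows into 'low'/'mid'/'high' by genome-wide rate percentiles.

    Thresholds use the linear-interpolation empirical percentile of the
    non-missing per-window rates; windows at or below the low threshold are
    'low', at or above the high threshold 'high'.  Missing rates stay NaN.
    """
    rates = pd.Series(window_rates, dtype=float)
    present = rates.dropna()
    if len(present) < 20:
        raise ValueError(f"need >= 20 windows with rates, got {len(present)}")
    if low_pct > high_pct:
        raise ValueError("low percentile exceeds high percentile")
    low_cut = float(np.percentile(present, low_pct))
    high_cut = float(np.percentile(present, high_pct))
    labels = pd.Series(pd.NA, index=rates.index, dtype="object")
    if low_cut == high_cut:
        logger.warning("degenerate rate distribution: all windows classed 'mid'")
        labels[present.index] = "mid"
        return labels
    labels[present.index] = "mid"
    labels[present[present <= low_cut].index] = "low"
    labels[present[present >= high_cut].index] = "high"
    return labels


def hotspot_counts(windows: pd.DataFrame, hotspots: pd.DataFrame) -> pd.DataFrame:
    """Count hotspot intervals whose midpoint falls in each half-open window."""
    win = windows.reset_index(drop=True)
    counts = np.zeros(len(win), dtype=np.int64)
    for chrom, widx in win.groupby("chrom", sort=False).groups.items():
        widx = np.asarray(widx)
        sub = hotspots[hotspots["chrom"] == chrom]
        if not len(sub):
            continue
        mid = ((sub["start"] + sub["end"]) // 2).to_numpy()
        wstart = win.loc[widx, "start"].to_numpy()
        wend = win.loc[widx, "end"].to_numpy()
        wi = np.searchsorted(wstart, mid, side="right") - 1
        ok = (wi >= 0) & (mid < wend[np.clip(wi, 0, len(widx) - 1)])
        counts[widx] += np.bincount(wi[ok], minlength=len(widx))
    return pd.DataFrame({"hotspot_count": counts, "hotspot_presence": counts > 0},
                        index=windows.index)
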