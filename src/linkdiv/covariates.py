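"""Per-window covariates for the diversity models.

Three window-level quantities enter the linear models alongside recombination
rate:

* the proportion of transcribed sites — a surrogate for the density of
  selective targets;
* the CpG dinucleotide count — CpG sites are hypermutable, so CpG density is
  a mutation-rate correlate;
* Jukes–Cantor-corrected divergence to an outgroup genome (mouse–rat in the
  motivating analysis) — another mutation-rate correlate, computed from
  per-window aligned/mismatch base counts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genomic_io import merge_intervals

logger = logging.getLogger(__name__)


def transcribed_proportion(windows: pd.DataFrame, tx_mask: pd.DataFrame) -> pd.Series:
    """Fraction of each window covered by the (merged) transcription mask."""
    mask = merge_intervals(tx_mask) if len(tx_mask) else tx_mask
    win = windows.reset_index(drop=True)
    prop = np.zeros(len(win))
    for chrom, widx in win.groupby("chrom", sort=False).groups.items():
        widx = np.asarray(widx)
        sub = mask[mask["chrom"] == chrom] if len(mask) else mask
        if not len(sub):
            continue
        ms = sub["start"].to_numpy()
        me = sub["end"].to_numpy()
        cum = np.concatenate([[0], np.cumsum(me - ms)])

        def covered_to(p: np.ndarray) -> np.ndarray:
            # total masked bp in [0, p)
            i = np.searchsorted(ms, p, side="right")  # intervals starting before p
            full = cum[np.maximum(i - 1, 0)]
            partial = np.clip(p - ms[np.clip(i - 1, 0, len(ms) - 1)], 0,
                              (me - ms)[np.clip(i - 1, 0, len(ms) - 1)])
            return np.where(i > 0, full + partial, 0)

        ws = win.loc[widx, "start"].to_numpy()
        we = win.loc[widx, "end"].to_numpy()
        prop[widx] = (covered_to(we) - covered_to(ws)) / (we - ws)
    return pd.Series(prop, index=windows.index, name="tx_prop")


def cpg_count(windows: pd.DataFrame, genome) -> pd.Series:
    """CpG dinucleotides per window on the forward strand.

    A CpG at window positions (i, i+1) is attributed to the window containing
    the 'C', so a dinucleotide straddling a window boundary counts for the
    left window.  Case-insensitive; pairs containing 'N' never match.
    """
    win = windows.reset_index(drop=True)
    counts = np.zeros(len(win), dtype=np.int64)
    for chrom, widx in win.groupby("chrom", sort=False).groups.items():
        widx = np.asarray(widx)
        we = win.loc[widx, "end"].to_numpy()
        length = int(we.max())
        raw = genome[chrom]
        seq = raw if isinstance(raw, str) else str(raw[: length + 1])
        arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        is_c = arr[:-1] == ord("C")
        is_g = arr[1:] == ord("G")
        cpg_at = is_c & is_g  # CpG whose C sits at this position
        cum = np.concatenate([[0], np.cumsum(cpg_at)])
        ws = win.loc[widx, "start"].to_numpy()
        hi = np.minimum(we, len(cpg_at))
        lo = np.minimum(ws, len(cpg_at))
        counts[widx] = cum[hi] - cum[lo]
    return pd.Series(counts, index=windows.index, name="cpg_count")


def jukes_cantor(p_mismatch):
    """Jukes–Cantor distance d = -(3/4) ln(1 - 4p/3), NaN at saturation (p >= 3/4)."""
    p = np.asarray(p_mismatch, dtype=float)
    if np.any(p < 0) or np.any(p[~np.isnan(p)] > 1):
        raise ValueError("mismatch proportion must lie in [0, 1]")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(p < 0.75, -0.75 * np.log1p(-(4.0 / 3.0) * np.minimum(p, 0.7499999999)),
                     np.nan)
        d = np.where(p < 0.75, d, np.nan)
    if np.any(np.isnan(d) & ~np.isnan(p)):
        logger.warning("divergence saturated (p >= 0.75) in %d window(s)",
                       int(np.sum(np.isnan(d) & ~np.isnan(p))))
    return float(d) if np.isscalar(p_mismatch) else d


def window_divergence(windows: pd.DataFrame, track: pd.DataFrame,
                      min_aligned_frac: float = 0.1) -> pd.DataFrame:
    """Aggregate an aligned/mismatch track into per-window divergence.

    Track intervals partially overlapping a window contribute proportionally
    to the overlapped fraction of the interval.  Windows whose total aligned
    bp falls below ``min_aligned_frac`` of the window length are marked
    missing (NaN), as are windows with no aligned bases.
    """
    win = windows.reset_index(drop=True)
    aligned = np.zeros(len(win))
    mism = np.zeros(len(win))
    for chrom, widx in win.groupby("chrom", sort=False).groups.items():
        widx = np.asarray(widx)
        sub = track[track["chrom"] == chrom]
        if not len(sub):
            continue
        ws = win.loc[widx, "start"].to_numpy()
        we = win.loc[widx, "end"].to_numpy()
        ts = sub["start"].to_numpy()
        te = sub["end"].to_numpy()
        ta = sub["aligned_bp"].to_numpy(dtype=float)
        tm = sub["mismatches"].to_numpy(dtype=float)
        for k in range(len(widx)):
            ov = np.minimum(we[k], te) - np.maximum(ws[k], ts)
            sel = ov > 0
            if not sel.any():
                continue
            frac = ov[sel] / (te[sel] - ts[sel])
            aligned[widx[k]] += float(frac @ ta[sel])
            mism[widx[k]] += float(frac @ tm[sel])
    wlen = (win["end"] - win["start"]).to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(aligned > 0, mism / np.maximum(aligned, 1e-300), np.nan)
    p = np.where(aligned >= min_aligned_frac * wlen, p, np.nan)
    d = jukes_cantor(np.where(np.isnan(p), np.nan, np.clip(p, 0, 1)))
    return pd.DataFrame({"p_mismatch": p, "aligned_bp": aligned, "jc_div": d},
                        index=windows.index)
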