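"""Windowed nucleotide-diversity estimators restricted to putatively neutral sites.

Two per-bp estimators of the population mutation parameter are computed per
window from a filtered SNP table:

* theta_pi — the average number of pairwise differences per site between
  sampled chromosomes, accumulated from the unbiased per-site form
  ``2 j (n - j) / (n (n - 1))`` where ``j`` is the derived/alternate allele
  count and ``n`` the number of successfully genotyped chromosomes.
* theta_w — Watterson's estimator ``k / a``, with ``a = sum_{i=1}^{n-1} 1/i``.
  Because the genotyped chromosome count can vary site to site, each site
  contributes ``1 / a(n_i)`` rather than using one fixed ``a(n)``.

Only positions that are outside the transcribed-site mask and are not 'N' in
the reference are eligible: they define the per-bp denominator
(``neutral_bp``) and SNPs at ineligible positions are ignored.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genomic_io import merge_intervals


def harmonic_a(n: int) -> float:
    """Watterson denominator a(n) = sum_{i=1}^{n-1} 1/i for n sampled chromosomes."""
    if n < 2:
        raise ValueError(f"need at least 2 chromosomes to define polymorphism, got {n}")
    return float(np.sum(1.0 / np.arange(1, n)))


def _harmonic_table(max_n: int) -> np.ndarray:
    """a(n) for n = 0..max_n; entries below n=2 are NaN."""
    table = np.full(max_n + 1, np.nan)
    if max_n >= 2:
        table[2:] = np.cumsum(1.0 / np.arange(1, max_n))
    return table


def site_pi(alt_count: int, called_chroms: int) -> float:
    """Per-site heterozygosity 2 j (n - j) / (n (n - 1)).

    Equals the mean Hamming distance over all C(n, 2) chromosome pairs at a
    biallelic site with j derived copies.
    """
    j, n = alt_count, called_chroms
    if n < 2:
        raise ValueError(f"called_chroms must be >= 2, got {n}")
    if not (1 <= j <= n - 1):
        raise ValueError(f"site not segregating: alt_count={j}, called_chroms={n}")
    return 2.0 * j * (n - j) / (n * (n - 1))


def eligible_positions(length: int, mask: pd.DataFrame | None = None,
                       chrom: str | None = None, seq: str | None = None) -> np.ndarray:
    """Boolean array over [0, length): True where nontranscribed and non-'N'."""
    ok = np.ones(length, dtype=bool)
    if mask is not None and len(mask):
        sub = mask[mask["chrom"] == chrom] if chrom is not None else mask
        for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
            ok[max(0, int(s)):min(length, int(e))] = False
    if seq is not None:
        arr = np.frombuffer(str(seq)[:length].upper().encode(), dtype=np.uint8)
        ok[: len(arr)] &= arr != ord("N")
        ok[len(arr):] = False
    return ok


def window_diversity(sites: pd.DataFrame, windows: pd.DataFrame,
                     mask: pd.DataFrame | None = None, genome=None,
                     n_chroms: int | None = None,
                     neutral_floor: float = 0.1,
                     denominator: str = "neutral") -> pd.DataFrame:
    """Per-window theta_pi and theta_w over eligible (nontranscribed, non-N) sites.

    Parameters
    ----------
    sites : filtered site table (chrom, pos, qual, alt_count, called_chroms)
    windows : window table for one size class, sorted and non-overlapping
    mask : transcription intervals; merged internally
    genome : FASTA accessor from :func:`linkdiv.genomic_io.read_fasta`, or a
        dict of chrom -> sequence string; ``None`` skips the N filter
    n_chroms : nominal sample size in chromosomes (for the output column);
        defaults to the modal called_chroms in ``sites``
    neutral_floor : minimum eligible fraction of the window length for the
        window to be flagged eligible for statistics
    denominator : "neutral" divides by eligible bp, "window" by window length

    Returns windows with added columns k, neutral_bp, theta_pi, theta_w,
    n_chroms and a boolean ``eligible`` flag.  Windows with ``neutral_bp == 0``
    get NaN estimates (marked missing, never a division by zero).
    """
    if denominator not in {"neutral", "window"}:
        raise ValueError(f"unknown denominator convention {denominator!r}")
    if mask is not None and len(mask):
        mask = merge_intervals(mask)
    if n_chroms is None:
        n_chroms = int(sites["called_chroms"].mode().iloc[0]) if len(sites) else 0

    max_n = int(sites["called_chroms"].max()) if len(sites) else 2
    a_table = _harmonic_table(max(max_n, 2))

    out = windows.reset_index(drop=True).copy()
    k_arr = np.zeros(len(out), dtype=np.int64)
    pi_sum = np.zeros(len(out))
    w_sum = np.zeros(len(out))
    neutral_bp = np.zeros(len(out), dtype=np.int64)

    for chrom, widx in out.groupby("chrom", sort=False).groups.items():
        widx = np.asarray(widx)
        wstart = out.loc[widx, "start"].to_numpy()
        wend = out.loc[widx, "end"].to_numpy()
        length = int(wend.max())
        cmask = mask[mask["chrom"] == chrom] if mask is not None and len(mask) else None
        if cmask is not None and not len(cmask):
            cmask = None
        ok = ms = me = None
        if genome is not None:
            # per-bp scan (needed for the reference-N filter)
            raw = genome[chrom]
            seq = raw if isinstance(raw, str) else str(raw[:length])
            ok = eligible_positions(length, cmask, chrom, seq)
            cum = np.concatenate([[0], np.cumsum(ok, dtype=np.int64)])
            neutral_bp[widx] = cum[np.minimum(wend, length)] - cum[np.minimum(wstart, length)]
        elif cmask is not None:
            # interval arithmetic: no reference, so eligibility is just the mask
            ms = cmask["start"].to_numpy()
            me = np.minimum(cmask["end"].to_numpy(), length)
            mcum = np.concatenate([[0], np.cumsum(me - ms)])

            def masked_to(p: np.ndarray) -> np.ndarray:
                i = np.searchsorted(ms, p, side="right")
                part = np.clip(p - ms[np.clip(i - 1, 0, len(ms) - 1)], 0,
                               (me - ms)[np.clip(i - 1, 0, len(ms) - 1)])
                return np.where(i > 0, mcum[np.maximum(i - 1, 0)] + part, 0)

            covered = masked_to(wend) - masked_to(wstart)
            neutral_bp[widx] = (wend - wstart) - covered
        else:
            neutral_bp[widx] = wend - wstart

        if len(sites):
            s = sites[sites["chrom"] == chrom]
            pos = s["pos"].to_numpy()
            inside = (pos >= wstart[0]) & (pos < length)
            s, pos = s[inside], pos[inside]
            if ok is not None:
                keep = ok[pos]
                s, pos = s[keep], pos[keep]
            elif ms is not None and len(pos):
                mi = np.searchsorted(ms, pos, side="right") - 1
                in_mask = (mi >= 0) & (pos < me[np.clip(mi, 0, len(ms) - 1)])
                s, pos = s[~in_mask], pos[~in_mask]
            if len(s):
                # windows are contiguous & sorted per chromosome
                wi = np.searchsorted(wstart, pos, side="right") - 1
                valid = (pos < wend[wi]) & (wi >= 0)
                s, wi = s[valid], wi[valid]
                j = s["alt_count"].to_numpy(dtype=float)
                n = s["called_chroms"].to_numpy(dtype=float)
                pi = 2.0 * j * (n - j) / (n * (n - 1.0))
                inv_a = 1.0 / a_table[s["called_chroms"].to_numpy()]
                k_arr[widx] += np.bincount(wi, minlength=len(widx))
                pi_sum[widx] += np.bincount(wi, weights=pi, minlength=len(widx))
                w_sum[widx] += np.bincount(wi, weights=inv_a, minlength=len(widx))

    denom = neutral_bp.astype(float) if denominator == "neutral" \
        else (out["end"] - out["start"]).to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta_pi = np.where(denom > 0, pi_sum / denom, np.nan)
        theta_w = np.where(denom > 0, w_sum / denom, np.nan)

    out["k"] = k_arr
    out["neutral_bp"] = neutral_bp
    out["theta_pi"] = theta_pi
    out["theta_w"] = theta_w
    out["n_chroms"] = n_chroms
    wlen = (out["end"] - out["start"]).to_numpy()
    out["eligible"] = neutral_bp >= neutral_floor * wlen
    return out
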