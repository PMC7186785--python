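"""Synthetic genomes, maps, covariate tracks and variants with planted effects.

The generator emits an internally consistent input bundle — genome FASTA,
transcription BED, genetic-map TSV, divergence track, hotspot BED, and one
VCF per population — in exactly the formats the pipeline consumes, together
with a truth table of the planted per-window parameters.  Per model window
the true per-bp diversity is a linear function of the window's realized
covariates,

    theta = b0 + b_rate*rate + b_div*d + b_cpg*cpg + b_tx*tx + b_cpgtx*cpg*tx

clipped below at a positive floor.  Segregating sites are then drawn under a
neutral independent-sites model: the site count is Poisson with mean
``theta * a(n) * neutral_bp``, derived-allele counts follow the neutral
frequency spectrum P(j) proportional to 1/j, and carriers are assigned to
chromosomes uniformly.  Under this model both the pairwise and the Watterson
estimator are unbiased for the planted theta, which makes every pipeline
stage testable by parameter recovery.  Intra-window linkage disequilibrium
is deliberately not modelled (sites are independent), so sampling variances
are smaller than under a coalescent with linkage; a coalescent simulator's
VCF can be substituted wherever a file bundle is consumed.

The in-memory fast path (``to_files=False``) may occasionally place two
mutations on the same base pair; the file-writing path enforces distinct
positions as a VCF requires.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .covariates import jukes_cantor
from .diversity import harmonic_a
from .genomic_io import tile_windows

logger = logging.getLogger(__name__)

_NON_CPG_TILES = [a + b for a in "ACGT" for b in "AGT" if a + b != "CG"]
# tiles never end in 'C', so no CpG can form across tile or window boundaries
_TILE_BYTES = np.frombuffer("".join(_NON_CPG_TILES).encode(), dtype=np.uint8).reshape(-1, 2)
_CG_BYTES = np.frombuffer(b"CG", dtype=np.uint8)


@dataclass
class GeneratorConfig:
    """Planted study conditions: population sizes, window grid, effect sizes.

    Planted coefficients are on the per-bp theta scale with CpG entering as
    the raw per-model-window dinucleotide count, matching how the covariates
    enter the analysis models.  Defaults emulate a wild house-mouse setting:
    three populations of 14/8/4 diploid individuals, mean theta near
    2 x 10^-3 per bp, Marey slopes bracketing 0.14-1.20 cM/Mb, ~15-17%
    mouse-rat mismatch divergence, CpG frequencies well below the GC
    expectation, and roughly a third of the genome transcribed.
    """

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000})
    populations: dict[str, int] = field(
        default_factory=lambda: {"gough": 14, "germany": 8, "france": 4})
    model_window: int = 1_000_000
    # planted linear model for per-bp theta
    beta0: float = 3.2e-3
    beta_rate: float = 1.55e-4
    beta_div: float = 3.16e-3
    beta_cpg: float = -8.53e-8
    beta_tx: float = -6.10e-4
    beta_cpg_tx: float = -2.94e-8
    theta_floor: float = 1e-5
    # genetic map
    marey_interval: int = 5_000_000
    marey_slopes: tuple[float, ...] = (0.5, 1.0, 0.14, 1.20, 0.3, 0.8)
    markers_per_interval: int = 50
    map_noise_cm: float = 0.0
    # landscape
    make_sequence: bool = True
    cpg_freq_range: tuple[float, float] = (0.005, 0.02)
    tx_prop_range: tuple[float, float] = (0.15, 0.55)
    tx_len_mean: float = 20_000.0
    tx_rate_coupling: float = 0.0
    aligned_frac: float = 0.8
    div_tile: int = 50_000
    div_p_mean: float = 0.15
    div_p_sd: float = 0.02
    hotspot_rate_per_mb: float = 5.0
    hotspot_length: int = 1_200
    hotspot_effect: float = 0.0  # extra per-bp theta inside hotspot halos
    hotspot_halo: int = 1_000
    # variant emission
    qual_pass: tuple[float, float] = (100.0, 1000.0)
    qual_fail: tuple[float, float] = (30.0, 99.9)
    fail_site_frac: float = 0.1
    missing_rate: float = 0.0

    def validate(self) -> None:
        errs = []
        if any(v <= 0 for v in self.chrom_lengths.values()):
            errs.append("chromosome lengths must be positive")
        if self.model_window <= 0:
            errs.append("model_window must be positive")
        if not (0 <= self.tx_prop_range[0] <= self.tx_prop_range[1] < 1):
            errs.append("tx_prop_range must lie in [0, 1)")
        if not (0 <= self.cpg_freq_range[0] <= self.cpg_freq_range[1] <= 0.5):
            errs.append("cpg_freq_range must lie in [0, 0.5]")
        if self.theta_floor <= 0:
            errs.append("theta_floor must be positive")
        if not (0 <= self.missing_rate < 1):
            errs.append("missing_rate must lie in [0, 1)")
        if any(n < 1 for n in self.populations.values()):
            errs.append("population sample sizes must be >= 1")
        if errs:
            raise ValueError("infeasible generator config: " + "; ".join(errs))


@dataclass
class Landscape:
    """Realized synthetic genome annotation plus the planted truth table."""

    config: GeneratorConfig
    chrom_lengths: dict[str, int]
    sequences: dict[str, str] | None
    tx_intervals: pd.DataFrame
    markers: pd.DataFrame
    divergence: pd.DataFrame
    hotspots: pd.DataFrame
    truth: pd.DataFrame  # per model window: covariates and theta_true


def _marey_slope_at(cfg: GeneratorConfig, chrom_index: int, pos: np.ndarray) -> np.ndarray:
    """True piecewise-constant Marey slope (cM/Mb) at physical positions (bp)."""
    seg = (np.asarray(pos) // cfg.marey_interval).astype(int)
    slopes = np.asarray(cfg.marey_slopes)
    return slopes[(seg + chrom_index) % len(slopes)]


def _marey_gen_pos(cfg: GeneratorConfig, chrom_index: int, length: int,
                   pos_bp: np.ndarray) -> np.ndarray:
    """Cumulative genetic position (cM) of the piecewise-linear Marey map."""
    bounds = np.arange(0, length, cfg.marey_interval)
    seg_slopes = _marey_slope_at(cfg, chrom_index, bounds)
    seg_ends = np.minimum(bounds + cfg.marey_interval, length)
    seg_cm = seg_slopes * (seg_ends - bounds) / 1e6
    cum = np.concatenate([[0.0], np.cumsum(seg_cm)])
    seg = np.minimum(pos_bp // cfg.marey_interval, len(bounds) - 1).astype(int)
    return cum[seg] + seg_slopes[seg] * (pos_bp - bounds[seg]) / 1e6


def _make_tx_intervals(rng: np.random.Generator, wstart: int, wend: int,
                       target: float, mean_len: float) -> list[tuple[int, int]]:
    """Alternating gap/transcript walk giving ~target covered fraction."""
    if target <= 0:
        return []
    gap_mean = mean_len * (1.0 - target) / target
    out = []
    pos = wstart + int(rng.exponential(gap_mean / 2))
    while pos < wend:
        tlen = max(200, int(rng.exponential(mean_len)))
        end = min(pos + tlen, wend)
        out.append((pos, end))
        pos = end + max(200, int(rng.exponential(gap_mean)))
    return out


def _window_sequence(rng: np.random.Generator, length: int, cpg_freq: float) -> bytes:
    n_tiles = length // 2
    idx = rng.integers(0, len(_NON_CPG_TILES), n_tiles)
    tiles = _TILE_BYTES[idx]
    is_cg = rng.random(n_tiles) < 2.0 * cpg_freq
    tiles[is_cg] = _CG_BYTES
    seq = tiles.tobytes()
    if length % 2:
        seq += b"A"
    return seq


def _count_cpg(seq: str, start: int, end: int) -> int:
    """CpG count with the C in [start, end); straddling pairs go to the left window."""
    return seq[start:end + 1].count("CG")


def generate_landscape(config: GeneratorConfig,
                       outdir: str | Path | None = None) -> Landscape:
    """Generate genome, annotation tracks, genetic map, and the truth table.

    With ``outdir`` set, writes genome.fa, transcripts.bed, map.tsv,
    divergence.tsv, hotspots.bed, truth.tsv and manifest.json.  The same seed
    always yields byte-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    grid = tile_windows(config.chrom_lengths, config.model_window, "model")

    sequences: dict[str, str] | None = {} if config.make_sequence else None
    tx_rows, hs_rows, div_rows, marker_rows = [], [], [], []
    truth_cols = {k: [] for k in
                  ["chrom", "start", "end", "rate_true", "cpg_count", "tx_prop",
                   "p_mismatch", "jc_div", "neutral_bp", "theta_true"]}

    for ci, (chrom, length) in enumerate(config.chrom_lengths.items()):
        # genetic map markers: jittered grid positions, piecewise-linear cM
        n_iv = int(np.ceil(length / config.marey_interval))
        for iv in range(n_iv):
            s = iv * config.marey_interval
            e = min(s + config.marey_interval, length)
            m = config.markers_per_interval
            grid_pos = s + (np.arange(m) + rng.random(m)) * (e - s) / m
            pos_bp = np.sort(grid_pos.astype(np.int64))
            gen = _marey_gen_pos(config, ci, length, pos_bp)
            if config.map_noise_cm > 0:
                gen = np.maximum(gen + rng.normal(0, config.map_noise_cm, m), 0.0)
            for p, g in zip(pos_bp, gen):
                marker_rows.append((chrom, p / 1e6, g))

        # hotspots: Poisson process along the chromosome
        n_hs = rng.poisson(config.hotspot_rate_per_mb * length / 1e6)
        hs_start = np.sort(rng.integers(0, max(length - config.hotspot_length, 1), n_hs))
        for s in hs_start:
            hs_rows.append((chrom, int(s), int(s) + config.hotspot_length))

        sub = grid[grid["chrom"] == chrom]
        chrom_seq_parts = []
        for ws, we in zip(sub["start"], sub["end"]):
            wlen = we - ws
            rate = float(_marey_slope_at(config, ci, np.array([(ws + we) // 2]))[0])
            cpg_f = rng.uniform(*config.cpg_freq_range)

            if config.make_sequence:
                part = _window_sequence(rng, wlen, cpg_f)
                chrom_seq_parts.append(part)
                cpg = part.decode().count("CG")  # no straddlers by construction
            else:
                cpg = int(rng.binomial(wlen, cpg_f))

            base_tx = rng.uniform(*config.tx_prop_range)
            mean_rate = float(np.mean(config.marey_slopes))
            target = float(np.clip(base_tx + config.tx_rate_coupling * (rate - mean_rate),
                                   0.0, 0.9))
            tx = _make_tx_intervals(rng, ws, we, target, config.tx_len_mean)
            tx_rows.extend((chrom, s, e) for s, e in tx)
            tx_bp = sum(e - s for s, e in tx)
            tx_prop = tx_bp / wlen

            # divergence track in tiles nested within the model window
            w_aligned = w_mism = 0
            for ts in range(ws, we, config.div_tile):
                te = min(ts + config.div_tile, we)
                aligned = int(round(config.aligned_frac * (te - ts)))
                p_tile = float(np.clip(rng.normal(config.div_p_mean, config.div_p_sd),
                                       0.005, 0.5))
                mism = int(rng.binomial(aligned, p_tile)) if aligned else 0
                div_rows.append((chrom, ts, te, aligned, mism))
                w_aligned += aligned
                w_mism += mism
            p_w = w_mism / w_aligned if w_aligned else np.nan
            d_w = jukes_cantor(p_w) if w_aligned else np.nan

            theta = (config.beta0 + config.beta_rate * rate + config.beta_div * d_w
                     + config.beta_cpg * cpg + config.beta_tx * tx_prop
                     + config.beta_cpg_tx * cpg * tx_prop)
            theta = max(theta, config.theta_floor)

            truth_cols["chrom"].append(chrom)
            truth_cols["start"].append(ws)
            truth_cols["end"].append(we)
            truth_cols["rate_true"].append(rate)
            truth_cols["cpg_count"].append(cpg)
            truth_cols["tx_prop"].append(tx_prop)
            truth_cols["p_mismatch"].append(p_w)
            truth_cols["jc_div"].append(d_w)
            truth_cols["neutral_bp"].append(wlen - tx_bp)
            truth_cols["theta_true"].append(theta)

        if config.make_sequence:
            sequences[chrom] = b"".join(chrom_seq_parts).decode()

    landscape = Landscape(
        config=config,
        chrom_lengths=dict(config.chrom_lengths),
        sequences=sequences,
        tx_intervals=pd.DataFrame(tx_rows, columns=["chrom", "start", "end"]),
        markers=pd.DataFrame(marker_rows, columns=["chrom", "phys_pos_mb", "gen_pos_cm"]),
        divergence=pd.DataFrame(div_rows,
                                columns=["chrom", "start", "end", "aligned_bp", "mismatches"]),
        hotspots=pd.DataFrame(hs_rows, columns=["chrom", "start", "end"]),
        truth=pd.DataFrame(truth_cols),
    )
    if outdir is not None:
        _write_landscape(landscape, Path(outdir))
    return landscape


def _neutral_segments(wstart: int, wend: int,
                      tx: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    """Complement of the transcription intervals within [wstart, wend)."""
    segs, segl = [], []
    pos = wstart
    for s, e in tx:
        if s > pos:
            segs.append(pos)
            segl.append(s - pos)
        pos = max(pos, e)
    if pos < wend:
        segs.append(pos)
        segl.append(wend - pos)
    return np.asarray(segs, dtype=np.int64), np.asarray(segl, dtype=np.int64)


def _sample_neutral_positions(rng: np.random.Generator, segs: np.ndarray,
                              segl: np.ndarray, k: int, distinct: bool) -> np.ndarray:
    total = int(segl.sum())
    if total == 0 or k == 0:
        return np.empty(0, dtype=np.int64)
    k = min(k, total) if distinct else k
    offs = (rng.choice(total, size=k, replace=False) if distinct
            else rng.integers(0, total, size=k))
    cum = np.concatenate([[0], np.cumsum(segl)])
    si = np.searchsorted(cum, offs, side="right") - 1
    return segs[si] + (offs - cum[si])


def _sfs_counts(rng: np.random.Generator, k: int, n: int) -> np.ndarray:
    """Derived-allele counts drawn from the neutral spectrum P(j) ~ 1/j."""
    j = np.arange(1, n)
    p = (1.0 / j) / np.sum(1.0 / j)
    return rng.choice(j, size=k, p=p)


def generate_variants(config: GeneratorConfig, landscape: Landscape,
                      outdir: str | Path | None = None,
                      distinct_positions: bool | None = None,
                      ) -> dict[str, pd.DataFrame]:
    """Draw segregating sites per population under the planted per-window theta.

    Returns one site table per population (chrom, pos, qual, alt_count,
    called_chroms) that includes the low-QUAL decoy sites, so the QUAL filter
    path is exercised downstream.  With ``outdir`` set, also writes a VCF per
    population (with distinct positions and explicit genotypes).
    """
    rng = np.random.default_rng(np.random.default_rng(config.seed).integers(1, 2**31))
    if distinct_positions is None:
        distinct_positions = outdir is not None
    truth = landscape.truth
    tx_by_chrom = {c: list(zip(g["start"], g["end"]))
                   for c, g in landscape.tx_intervals.groupby("chrom")}

    out: dict[str, pd.DataFrame] = {}
    vcf_rows: dict[str, list] = {}
    for pop, n_samples in config.populations.items():
        n = 2 * n_samples
        a_n = harmonic_a(n) if n >= 2 else 1.0
        rows = {k: [] for k in ["chrom", "pos", "qual", "alt_count", "called_chroms"]}
        for rec in truth.itertuples(index=False):
            tx = [(s, e) for s, e in tx_by_chrom.get(rec.chrom, [])
                  if e > rec.start and s < rec.end]
            segs, segl = _neutral_segments(rec.start, rec.end, tx)
            lam = rec.theta_true * a_n * rec.neutral_bp
            k_pass = rng.poisson(lam)
            k_fail = rng.poisson(config.fail_site_frac * lam)
            k = k_pass + k_fail
            pos = _sample_neutral_positions(rng, segs, segl, k, distinct_positions)
            k = len(pos)
            k_pass = min(k_pass, k)
            qual = np.concatenate([
                rng.uniform(*config.qual_pass, size=k_pass),
                rng.uniform(*config.qual_fail, size=k - k_pass)])
            order = np.argsort(pos, kind="mergesort")
            pos, qual = pos[order], qual[order]
            j = _sfs_counts(rng, k, n) if k else np.empty(0, dtype=np.int64)
            called = np.full(k, n, dtype=np.int64)
            if config.missing_rate > 0 and k:
                m = rng.binomial(n_samples, config.missing_rate, size=k)
                called = n - 2 * m
                ok = called >= 2
                j2 = np.array([rng.hypergeometric(jj, n - jj, c) if c < n else jj
                               for jj, c in zip(j, called)])
                keep = ok & (j2 >= 1) & (j2 <= called - 1)
                pos, qual, j, called = pos[keep], qual[keep], j2[keep], called[keep]
                k = len(pos)
            rows["chrom"].extend([rec.chrom] * k)
            rows["pos"].extend(pos.tolist())
            rows["qual"].extend(qual.tolist())
            rows["alt_count"].extend(j.tolist())
            rows["called_chroms"].extend(called.tolist())

        # extra sites inside hotspot halos, if a hotspot effect is planted
        if config.hotspot_effect > 0 and len(landscape.hotspots):
            for hs in landscape.hotspots.itertuples(index=False):
                s = max(hs.start - config.hotspot_halo, 0)
                e = min(hs.end + config.hotspot_halo, landscape.chrom_lengths[hs.chrom])
                k_hs = rng.poisson(config.hotspot_effect * a_n * (e - s))
                if not k_hs:
                    continue
                pos = rng.integers(s, e, size=k_hs)
                rows["chrom"].extend([hs.chrom] * k_hs)
                rows["pos"].extend(pos.tolist())
                rows["qual"].extend(rng.uniform(*config.qual_pass, size=k_hs).tolist())
                rows["alt_count"].extend(_sfs_counts(rng, k_hs, n).tolist())
                rows["called_chroms"].extend([n] * k_hs)

        sites = (pd.DataFrame(rows)
                 .astype({"pos": np.int64, "alt_count": np.int64,
                          "called_chroms": np.int64})
                 .sort_values(["chrom", "pos"], kind="mergesort")
                 .reset_index(drop=True))
        if distinct_positions:
            sites = sites[~sites.duplicated(["chrom", "pos"])].reset_index(drop=True)
        out[pop] = sites
        if outdir is not None:
            vcf_rows[pop] = _assign_genotypes(rng, sites, n_samples)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for pop, n_samples in config.populations.items():
            _write_vcf(outdir / f"{pop}.vcf", out[pop], vcf_rows[pop], pop,
                       n_samples, landscape)
    return out


def _assign_genotypes(rng: np.random.Generator, sites: pd.DataFrame,
                      n_samples: int) -> np.ndarray:
    """Per-site diploid genotype codes: 0/1/2 alt copies, -1 missing sample."""
    n = 2 * n_samples
    k = len(sites)
    gts = np.zeros((k, n_samples), dtype=np.int8)
    if not k:
        return gts
    r = rng.random((k, n))
    ranks = np.argsort(np.argsort(r, axis=1), axis=1)
    j = sites["alt_count"].to_numpy()
    called = sites["called_chroms"].to_numpy()
    carrier = ranks < j[:, None]
    gts = (carrier[:, 0::2].astype(np.int8) + carrier[:, 1::2].astype(np.int8))
    n_missing = ((n - called) // 2).astype(int)
    for i in np.nonzero(n_missing)[0]:
        # mark non-carrier samples missing first so alt_count stays consistent
        order = np.argsort(gts[i], kind="mergesort")
        gts[i, order[: n_missing[i]]] = -1
    return gts


def _write_vcf(path: Path, sites: pd.DataFrame, gts: np.ndarray, pop: str,
               n_samples: int, landscape: Landscape) -> None:
    samples = [f"{pop}{i + 1}" for i in range(n_samples)]
    bases = "ACGT"
    gt_str = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=linkdiv-synthetic\n")
        for chrom, length in landscape.chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        rng = np.random.default_rng(len(sites) + 7)
        alt_pick = rng.integers(0, 3, size=len(sites))
        for i, rec in enumerate(sites.itertuples(index=False)):
            if landscape.sequences is not None:
                ref = landscape.sequences[rec.chrom][rec.pos].upper()
                if ref not in bases:
                    ref = "A"
            else:
                ref = "A"
            alt = [b for b in bases if b != ref][alt_pick[i]]
            cols = [rec.chrom, str(rec.pos + 1), ".", ref, alt,
                    f"{rec.qual:.1f}", "PASS", ".", "GT"]
            cols += [gt_str[int(g)] for g in gts[i]]
            fh.write("\t".join(cols) + "\n")


def _write_landscape(ls: Landscape, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    if ls.sequences is not None:
        with open(outdir / "genome.fa", "w") as fh:
            for chrom, seq in ls.sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")
    ls.tx_intervals.to_csv(outdir / "transcripts.bed", sep="\t", header=False,
                           index=False)
    ls.hotspots.to_csv(outdir / "hotspots.bed", sep="\t", header=False, index=False)
    ls.markers.to_csv(outdir / "map.tsv", sep="\t", index=False)
    ls.divergence.to_csv(outdir / "divergence.tsv", sep="\t", index=False)
    ls.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    manifest = {"config": asdict(ls.config),
                "files": {"fasta": "genome.fa" if ls.sequences is not None else None,
                          "transcripts": "transcripts.bed", "map": "map.tsv",
                          "divergence": "divergence.tsv", "hotspots": "hotspots.bed",
                          "truth": "truth.tsv"}}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def generate_bundle(config: GeneratorConfig, outdir: str | Path) -> Landscape:
    """Landscape plus per-population VCFs written to ``outdir`` in one call."""
    ls = generate_landscape(config, outdir)
    generate_variants(config, ls, outdir=outdir)
    return ls
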