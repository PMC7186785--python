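"""End-to-end orchestration: windows -> diversity -> rates -> covariates -> statistics.

A run takes a configuration naming one VCF per population plus the shared
genome FASTA, transcription annotation, genetic map, divergence track and
(optionally) hotspot intervals, and produces per-window record TSVs, a
correlation summary (Spearman's rho of each diversity estimator against
recombination rate, per population and window size), a linear-model summary,
rank-sum contrast results, and a machine-readable run manifest.  Identical
configuration and inputs yield byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, association, covariates, diversity, genomic_io, recombination

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_SIZES = (2500, 5000, 50_000, 100_000, 500_000, 1_000_000)


@dataclass
class RunConfig:
    """All pipeline parameters; defaults encode the standard analysis settings."""

    vcfs: dict[str, str] = field(default_factory=dict)  # population -> VCF path
    samples: dict[str, list[str]] = field(default_factory=dict)  # optional subset per pop
    fasta: str = ""
    transcripts: str = ""
    genetic_map: str = ""
    divergence: str = ""
    hotspots: str | None = None
    outdir: str = "linkdiv_out"
    window_sizes: tuple[int, ...] = DEFAULT_WINDOW_SIZES
    min_qual: float = 100.0
    interval_size: int = 5_000_000
    min_markers: int = 3
    low_pct: float = 5.0
    high_pct: float = 95.0
    neutral_floor: float = 0.1
    denominator: str = "neutral"
    min_aligned_frac: float = 0.1
    model_sizes: tuple[int, ...] = (5000, 1_000_000)  # sizes to fit linear models on
    contrast_size: int = 1_000_000  # percentile contrast window size
    hotspot_size: int = 5000  # hotspot contrast window size
    chromosomes: list[str] | None = None  # default: FASTA contigs minus sex/organelle
    make_plot: bool = False

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.window_sizes = tuple(cfg.window_sizes)
        cfg.model_sizes = tuple(cfg.model_sizes)
        return cfg


def validate_config(config: RunConfig) -> list[str]:
    """Return every violation found (empty list means the config is valid)."""
    errs: list[str] = []
    for label, p in [("fasta", config.fasta), ("transcripts", config.transcripts),
                     ("genetic_map", config.genetic_map), ("divergence", config.divergence)]:
        if not p or not Path(p).exists():
            errs.append(f"{label}: path missing or does not exist: {p!r}")
    if config.hotspots is not None and not Path(config.hotspots).exists():
        errs.append(f"hotspots: path does not exist: {config.hotspots!r}")
    if not config.vcfs:
        errs.append("vcfs: at least one population VCF is required")
    for pop, p in config.vcfs.items():
        if not Path(p).exists():
            errs.append(f"vcfs[{pop}]: path does not exist: {p!r}")
    if any(w <= 0 for w in config.window_sizes):
        errs.append("window_sizes: all sizes must be positive")
    if len(set(config.window_sizes)) != len(config.window_sizes):
        errs.append("window_sizes: sizes must be distinct")
    if config.min_qual < 0:
        errs.append("min_qual must be >= 0")
    if config.interval_size <= 0:
        errs.append("interval_size must be positive")
    if not (0 <= config.low_pct <= config.high_pct <= 100):
        errs.append("percentiles must satisfy 0 <= low <= high <= 100")
    if not (0 <= config.neutral_floor <= 1):
        errs.append("neutral_floor must lie in [0, 1]")
    if config.denominator not in {"neutral", "window"}:
        errs.append("denominator must be 'neutral' or 'window'")
    if not errs:
        logger.info("effective configuration: %s", dataclasses.asdict(config))
    return errs


def _md5(path: str | Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def build_window_records(windows: pd.DataFrame, sites: pd.DataFrame,
                         tx: pd.DataFrame, genome, rate_intervals: pd.DataFrame,
                         div_track: pd.DataFrame, hotspots: pd.DataFrame | None,
                         config: RunConfig, population: str) -> pd.DataFrame:
    """Join all per-window quantities into one analysis record table."""
    rec = diversity.window_diversity(
        sites, windows, mask=tx, genome=genome,
        neutral_floor=config.neutral_floor, denominator=config.denominator)
    rec["rate"] = recombination.assign_window_rate(rec, rate_intervals)
    try:
        rec["rate_class"] = recombination.percentile_classes(
            rec["rate"], config.low_pct, config.high_pct)
    except ValueError as exc:
        logger.warning("rate classes unavailable: %s", exc)
        rec["rate_class"] = pd.NA
    rec["tx_prop"] = covariates.transcribed_proportion(rec, tx)
    if genome is not None:
        rec["cpg_count"] = covariates.cpg_count(rec, genome)
    else:
        rec["cpg_count"] = np.nan
    div = covariates.window_divergence(rec, div_track, config.min_aligned_frac)
    rec = pd.concat([rec, div], axis=1)
    if hotspots is not None and len(hotspots):
        rec = pd.concat([rec, recombination.hotspot_counts(rec, hotspots)], axis=1)
    else:
        rec["hotspot_count"] = 0
        rec["hotspot_presence"] = False
    rec["population"] = population
    return rec


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage for each population and window size; write outputs."""
    errs = validate_config(config)
    if errs:
        raise genomic_io.ConfigurationError("invalid configuration:\n  " + "\n  ".join(errs))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome = genomic_io.read_fasta(config.fasta)
    if config.chromosomes is not None:
        chroms = list(config.chromosomes)
    else:
        # autosomes only by default; sex/organelle contigs need an explicit list
        sex = {"x", "y", "m", "mt", "chrx", "chry", "chrm", "chrmt"}
        chroms = [c for c in genome.keys() if c.lower() not in sex]
    chrom_lengths = {c: len(genome[c]) for c in chroms}
    seqs = {c: str(genome[c][:]) for c in chroms}  # one decode, reused per stage

    tx = genomic_io.read_intervals(config.transcripts, merge=True)
    tx = tx[tx["chrom"].isin(chroms)].reset_index(drop=True)
    markers = genomic_io.read_map(config.genetic_map)
    div_track = genomic_io.read_divergence(config.divergence)
    hotspots = None
    if config.hotspots is not None:
        hotspots = genomic_io.read_intervals(config.hotspots)
    else:
        logger.info("no hotspot file configured; hotspot contrasts skipped")

    rate_intervals = recombination.interval_rates(
        markers, chrom_lengths, config.interval_size, config.min_markers)
    genomic_io.write_tsv(rate_intervals, outdir / "recombination_rates.tsv",
                         {"interval_size": config.interval_size,
                          "min_markers": config.min_markers})

    pop_sites = {}
    for pop, vcf_path in config.vcfs.items():
        from cyvcf2 import VCF

        sample_ids = config.samples.get(pop) or list(VCF(str(vcf_path)).samples)
        pop_sites[pop] = genomic_io.read_vcf_sites(vcf_path, sample_ids, config.min_qual)

    records: dict[tuple[str, int], pd.DataFrame] = {}
    corr_rows, model_rows, contrast_rows = [], [], []
    for wsize in sorted(config.window_sizes):
        windows = genomic_io.tile_windows(chrom_lengths, wsize)
        for pop in config.vcfs:
            rec = build_window_records(windows, pop_sites[pop], tx, seqs,
                                       rate_intervals, div_track, hotspots,
                                       config, pop)
            records[(pop, wsize)] = rec
            label = rec["size_class"].iloc[0]
            genomic_io.write_tsv(rec, outdir / f"windows_{pop}_{label}.tsv",
                                 {"population": pop, "window_size": wsize,
                                  "min_qual": config.min_qual,
                                  "denominator": config.denominator})
            use = rec[rec["eligible"]]
            for stat in ["theta_pi", "theta_w"]:
                try:
                    c = association.spearman(use[stat], use["rate"],
                                             x_label=stat, y_label="rate")
                    corr_rows.append((pop, label, stat, use[stat].mean(),
                                      use[stat].std(), c.rho, c.p_value, c.n_windows))
                except ValueError as exc:
                    logger.warning("spearman %s/%s/%s failed: %s", pop, label, stat, exc)

            if wsize in config.model_sizes:
                try:
                    fit = association.fit_linear_model(use, response="theta_pi")
                    for term, row in fit.terms.iterrows():
                        model_rows.append((pop, label, term, row["estimate"],
                                           row["std_error"], row["p_value"],
                                           fit.n, fit.r_squared))
                except ValueError as exc:
                    logger.warning("linear model %s/%s failed: %s", pop, label, exc)

            if wsize == config.contrast_size:
                for stat in ["theta_pi", "theta_w"]:
                    try:
                        t = association.percentile_contrast(use, response=stat)
                        contrast_rows.append((pop, label, f"percentile_{stat}",
                                              t.statistic, t.p_value, t.alternative,
                                              t.n1, t.n2))
                    except ValueError as exc:
                        logger.warning("percentile contrast %s/%s failed: %s",
                                       pop, label, exc)
            if wsize == config.hotspot_size and hotspots is not None and len(hotspots):
                try:
                    t = association.hotspot_contrast(use, response="theta_pi")
                    contrast_rows.append((pop, label, "hotspot_theta_pi", t.statistic,
                                          t.p_value, t.alternative, t.n1, t.n2))
                except ValueError as exc:
                    logger.warning("hotspot contrast %s/%s failed: %s", pop, label, exc)

    correlations = pd.DataFrame(corr_rows, columns=[
        "population", "size_class", "statistic", "avg", "sd", "rho", "p_value", "n"])
    models = pd.DataFrame(model_rows, columns=[
        "population", "size_class", "term", "estimate", "std_error", "p_value",
        "n", "r_squared"])
    contrasts = pd.DataFrame(contrast_rows, columns=[
        "population", "size_class", "test", "statistic", "p_value", "alternative",
        "n1", "n2"])
    params = {"min_qual": config.min_qual, "interval_size": config.interval_size,
              "low_pct": config.low_pct, "high_pct": config.high_pct}
    genomic_io.write_tsv(correlations, outdir / "correlations.tsv", params)
    genomic_io.write_tsv(models, outdir / "models.tsv", params)
    genomic_io.write_tsv(contrasts, outdir / "contrasts.tsv", params)

    if config.make_plot:
        _diagnostic_plot(records, config, outdir)

    manifest = {
        "linkdiv": __version__,
        "config": dataclasses.asdict(config),
        "inputs": {name: _md5(p) for name, p in
                   [("fasta", config.fasta), ("transcripts", config.transcripts),
                    ("genetic_map", config.genetic_map), ("divergence", config.divergence)]
                   + [(f"vcf_{pop}", p) for pop, p in config.vcfs.items()]
                   + ([("hotspots", config.hotspots)] if config.hotspots else [])},
        "site_counts": {pop: int(len(s)) for pop, s in pop_sites.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {"records": records, "correlations": correlations, "models": models,
            "contrasts": contrasts, "manifest": manifest}


def _diagnostic_plot(records: dict, config: RunConfig, outdir: Path) -> None:
    """Scatter of theta_pi against recombination rate with OLS fitted values."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    wsize = max(config.window_sizes)
    pops = sorted({pop for pop, w in records if w == wsize})
    fig, axes = plt.subplots(1, len(pops), figsize=(4 * len(pops), 3.5), squeeze=False)
    for ax, pop in zip(axes[0], pops):
        rec = records[(pop, wsize)]
        use = rec[rec["eligible"]].dropna(subset=["rate", "theta_pi"])
        ax.scatter(use["rate"], use["theta_pi"], s=4, alpha=0.4)
        try:
            fit = association.fit_linear_model(use, response="theta_pi")
            x, _ = association.build_design(use.dropna(
                subset=["rate", "jc_div", "cpg_count", "tx_prop", "theta_pi"]))
            yhat = x @ fit.terms["estimate"].to_numpy()
            order = np.argsort(x[:, 1])
            ax.plot(x[order, 1], yhat[order], lw=1)
        except ValueError:
            pass
        ax.set_xlabel("recombination rate (cM/Mb)")
        ax.set_ylabel(r"$\theta_\pi$ per bp")
        ax.set_title(pop)
    fig.tight_layout()
    fig.savefig(outdir / "theta_vs_rate.png", dpi=150)
    plt.close(fig)
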