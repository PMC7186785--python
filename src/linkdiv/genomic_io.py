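"""Input parsing, validation, and window tiling.

All internal coordinates are 0-based half-open ``[start, end)``.  VCF POS
(1-based) and GFF features (1-based inclusive) are converted on read; BED is
taken as-is.  Tables are plain :class:`pandas.DataFrame` objects with fixed
column sets:

``windows``    chrom, start, end, size_class
``sites``      chrom, pos, qual, alt_count, called_chroms
``markers``    chrom, phys_pos_mb, gen_pos_cm
``intervals``  chrom, start, end
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SITE_COLUMNS = ["chrom", "pos", "qual", "alt_count", "called_chroms"]
WINDOW_COLUMNS = ["chrom", "start", "end", "size_class"]


class ConfigurationError(ValueError):
    """Raised for invalid analysis parameters (e.g. non-positive window size)."""


@dataclass(frozen=True)
class GenomeWindow:
    """A half-open genomic interval carrying a window-size label."""

    chrom: str
    start: int
    end: int
    size_class: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid window [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


def size_class_label(window_size: int) -> str:
    """Human-readable label for a window size in bp: 2500 -> '2.5kb', 1000000 -> '1Mb'."""
    if window_size >= 1_000_000 and window_size % 1_000_000 == 0:
        return f"{window_size // 1_000_000}Mb"
    kb = window_size / 1000
    return f"{int(kb)}kb" if kb == int(kb) else f"{kb:g}kb"


def tile_windows(chrom_lengths: dict[str, int], window_size: int,
                 size_class: str | None = None) -> pd.DataFrame:
    """Tile each chromosome into consecutive half-open windows.

    The last window is truncated at the chromosome end, so the windows of one
    size partition the chromosome exactly.
    """
    if window_size <= 0:
        raise ConfigurationError(f"window size must be positive, got {window_size}")
    label = size_class if size_class is not None else size_class_label(window_size)
    frames = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ConfigurationError(f"chromosome {chrom} has non-positive length {length}")
        starts = np.arange(0, length, window_size, dtype=np.int64)
        ends = np.minimum(starts + window_size, length)
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends,
                                    "size_class": label}))
    return pd.concat(frames, ignore_index=True)


def read_vcf_sites(vcf_path: str | Path, population_samples: list[str],
                   min_qual: float = 100.0) -> pd.DataFrame:
    """Read biallelic SNPs for one population sample from a VCF.

    Keeps records with QUAL >= ``min_qual`` (inclusive) that are segregating
    within the named samples; alt_count and called_chroms are computed from
    those samples' genotypes only.  Indels and multiallelic records are
    excluded and counted in the log.
    """
    from cyvcf2 import VCF

    if min_qual < 0:
        raise ConfigurationError("min_qual must be >= 0")
    vcf = VCF(str(vcf_path))
    missing = [s for s in population_samples if s not in vcf.samples]
    if missing:
        raise ValueError(f"sample(s) not present in {vcf_path}: {', '.join(missing)}")
    vcf.set_samples(population_samples)

    rows = {k: [] for k in SITE_COLUMNS}
    n_multi = n_indel = n_lowqual = n_nonseg = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        if not v.is_snp:
            n_indel += 1
            continue
        qual = v.QUAL if v.QUAL is not None else 0.0
        if qual < min_qual:
            n_lowqual += 1
            continue
        alt = 0
        called = 0
        for gt in v.genotypes:  # [allele1, allele2, phased]
            for a in gt[:-1]:
                if a >= 0:
                    called += 1
                    if a > 0:
                        alt += 1
        if alt < 1 or alt > called - 1:
            n_nonseg += 1
            continue
        rows["chrom"].append(v.CHROM)
        rows["pos"].append(v.POS - 1)  # to 0-based
        rows["qual"].append(qual)
        rows["alt_count"].append(alt)
        rows["called_chroms"].append(called)

    sites = pd.DataFrame(rows)
    sites = sites.astype({"pos": np.int64, "alt_count": np.int64,
                          "called_chroms": np.int64}) if len(sites) else sites
    sites = sites.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    dup = sites.duplicated(["chrom", "pos"])
    if dup.any():
        logger.warning("dropping %d duplicate positions", int(dup.sum()))
        sites = sites[~dup].reset_index(drop=True)
    logger.info("read_vcf_sites: kept %d sites; excluded %d multiallelic, %d non-SNP, "
                "%d below QUAL %.3g, %d not segregating in sample",
                len(sites), n_multi, n_indel, n_lowqual, n_nonseg)
    return sites


def filter_sites(sites: pd.DataFrame, min_qual: float) -> pd.DataFrame:
    """Apply the QUAL and segregation filters to an in-memory site table (idempotent)."""
    keep = ((sites["qual"] >= min_qual)
            & (sites["alt_count"] >= 1)
            & (sites["alt_count"] <= sites["called_chroms"] - 1))
    return sites[keep].reset_index(drop=True)


def read_map(tsv_path: str | Path) -> pd.DataFrame:
    """Read a genetic map TSV with columns chrom, phys_pos_mb, gen_pos_cm."""
    markers = pd.read_csv(tsv_path, sep="\t", comment="#")
    required = {"chrom", "phys_pos_mb", "gen_pos_cm"}
    if not required.issubset(markers.columns):
        raise ValueError(f"map file {tsv_path} must have columns {sorted(required)}")
    if (markers["phys_pos_mb"] < 0).any() or (markers["gen_pos_cm"] < 0).any():
        raise ValueError("map positions must be non-negative")
    return (markers[["chrom", "phys_pos_mb", "gen_pos_cm"]]
            .sort_values(["chrom", "phys_pos_mb"], kind="mergesort")
            .reset_index(drop=True))


def _read_bed(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None, usecols=[0, 1, 2],
                     names=["chrom", "start", "end"])
    return df


def _read_gff(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["seqid", "source", "type", "start", "end", "score",
                            "strand", "phase", "attributes"])
    # GFF is 1-based inclusive -> half-open
    return pd.DataFrame({"chrom": df["seqid"], "start": df["start"] - 1,
                         "end": df["end"]})


def read_intervals(path: str | Path, merge: bool = False,
                   chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Read BED3+/GFF3 intervals into a sorted half-open interval table."""
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3", ".gtf"}:
        ivals = _read_gff(path)
    else:
        ivals = _read_bed(path)
    if (ivals["start"] >= ivals["end"]).any():
        raise ValueError(f"{path}: interval with start >= end")
    if chrom_lengths is not None:
        for chrom, grp in ivals.groupby("chrom"):
            if chrom in chrom_lengths and (grp["end"] > chrom_lengths[chrom]).any():
                raise ValueError(f"{path}: interval beyond end of {chrom}")
    ivals = (ivals.astype({"start": np.int64, "end": np.int64})
             .sort_values(["chrom", "start", "end"], kind="mergesort")
             .reset_index(drop=True))
    return merge_intervals(ivals) if merge else ivals


def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Union of overlapping or touching intervals, per chromosome."""
    out = {"chrom": [], "start": [], "end": []}
    for chrom, grp in intervals.sort_values(["chrom", "start"]).groupby(
            "chrom", sort=True):
        cur_s = cur_e = None
        for s, e in zip(grp["start"].to_numpy(), grp["end"].to_numpy()):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out["chrom"].append(chrom); out["start"].append(cur_s); out["end"].append(cur_e)
                cur_s, cur_e = s, e
        if cur_s is not None:
            out["chrom"].append(chrom); out["start"].append(cur_s); out["end"].append(cur_e)
    return pd.DataFrame(out).astype({"start": np.int64, "end": np.int64})


def read_fasta(fasta_path: str | Path):
    """Open a FASTA for random access by chromosome name (indexed on first use)."""
    from pyfaidx import Fasta

    return Fasta(str(fasta_path), sequence_always_upper=False)


def read_divergence(path: str | Path) -> pd.DataFrame:
    """Read a divergence track TSV: chrom, start, end, aligned_bp, mismatches."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"chrom", "start", "end", "aligned_bp", "mismatches"}
    if not required.issubset(df.columns):
        raise ValueError(f"divergence track {path} must have columns {sorted(required)}")
    if (df["mismatches"] > df["aligned_bp"]).any():
        raise ValueError("mismatches exceed aligned_bp in divergence track")
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def write_tsv(df: pd.DataFrame, path: str | Path, params: dict | None = None) -> None:
    """Write a result TSV with a one-line metadata header recording parameters."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"linkdiv": __version__}
    meta.update(params or {})
    header = "# " + " ".join(f"{k}={v}" for k, v in meta.items())
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
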