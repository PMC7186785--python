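import filecmp
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from linkdiv import covariates as cv
from linkdiv import diversity as dv
from linkdiv import recombination as rc
from linkdiv.genomic_io import filter_sites, tile_windows
from linkdiv.synthetic_data import (
    GeneratorConfig,
    generate_bundle,
    generate_landscape,
    generate_variants,
)


def small_config(**kw):
    defaults = dict(seed=11, chrom_lengths={"chr1": 2_000_000, "chr2": 2_000_000},
                    populations={"pop": 8}, marey_interval=1_000_000)
    defaults.update(kw)
    return GeneratorConfig(**defaults)


def null_config(**kw):
    """Constant planted theta: every covariate effect switched off."""
    defaults = dict(beta_rate=0.0, beta_div=0.0, beta_cpg=0.0, beta_tx=0.0,
                    beta_cpg_tx=0.0, beta0=0.002, make_sequence=False,
                    tx_prop_range=(0.0, 0.0), fail_site_frac=0.0)
    defaults.update(kw)
    return small_config(**defaults)


class TestDeterminism:
    def test_same_seed_byte_identical_bundle(self, tmp_path):
        cfg1 = small_config(chrom_lengths={"chr1": 1_000_000})
        cfg2 = small_config(chrom_lengths={"chr1": 1_000_000})
        generate_bundle(cfg1, tmp_path / "a")
        generate_bundle(cfg2, tmp_path / "b")
        names = [p.name for p in (tmp_path / "a").iterdir()]
        match, mismatch, errors = filecmp.cmpfiles(tmp_path / "a", tmp_path / "b",
                                                   names, shallow=False)
        assert not mismatch and not errors

    def test_different_seed_different_sites(self):
        cfg1 = small_config(seed=1, chrom_lengths={"chr1": 1_000_000})
        cfg2 = small_config(seed=2, chrom_lengths={"chr1": 1_000_000})
        s1 = generate_variants(cfg1, generate_landscape(cfg1))["pop"]
        s2 = generate_variants(cfg2, generate_landscape(cfg2))["pop"]
        assert not s1["pos"].equals(s2["pos"])


class TestLandscape:
    def test_cpg_count_within_binomial_bounds(self):
        cfg = small_config(chrom_lengths={"chr1": 1_000_000}, model_window=1_000_000,
                           cpg_freq_range=(0.02, 0.02))
        ls = generate_landscape(cfg)
        realized = int(ls.truth["cpg_count"].iloc[0])
        lo, hi = stats.binom.ppf([0.005, 0.995], 1_000_000, 0.02)
        assert lo <= realized <= hi

    def test_truth_covariates_match_pipeline_recomputation(self):
        cfg = small_config()
        ls = generate_landscape(cfg)
        windows = tile_windows(cfg.chrom_lengths, cfg.model_window)
        cpg = cv.cpg_count(windows, ls.sequences)
        tx = cv.transcribed_proportion(windows, ls.tx_intervals)
        div = cv.window_divergence(windows, ls.divergence)
        assert np.array_equal(cpg.to_numpy(), ls.truth["cpg_count"].to_numpy())
        assert np.allclose(tx.to_numpy(), ls.truth["tx_prop"].to_numpy())
        assert np.allclose(div["jc_div"].to_numpy(), ls.truth["jc_div"].to_numpy())

    def test_marey_slopes_recovered_exactly_without_noise(self):
        cfg = small_config(marey_slopes=(0.2, 1.0), map_noise_cm=0.0)
        ls = generate_landscape(cfg)
        rates = rc.interval_rates(ls.markers, cfg.chrom_lengths,
                                  cfg.marey_interval, min_markers=3)
        joined = rates.merge(ls.truth, on=["chrom", "start", "end"])
        assert np.allclose(joined["rate"], joined["rate_true"], atol=1e-9)

    def test_transcription_density_couples_to_rate(self):
        cfg = small_config(chrom_lengths={"chr1": 20_000_000},
                           marey_slopes=(0.1, 1.5), marey_interval=1_000_000,
                           tx_rate_coupling=0.4, tx_prop_range=(0.3, 0.4))
        ls = generate_landscape(cfg)
        r = stats.spearmanr(ls.truth["rate_true"], ls.truth["tx_prop"])
        assert r.statistic > 0.5

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            GeneratorConfig(tx_prop_range=(0.5, 1.5)).validate()

    def test_fasta_round_trips_through_reader(self, tmp_path):
        from linkdiv.genomic_io import read_fasta

        cfg = small_config(chrom_lengths={"chr1": 100_000})
        ls = generate_landscape(cfg, outdir=tmp_path)
        genome = read_fasta(tmp_path / "genome.fa")
        assert str(genome["chr1"][:]) == ls.sequences["chr1"]


class TestVariants:
    def test_sfs_follows_neutral_spectrum(self):
        cfg = null_config(chrom_lengths={"chr1": 30_000_000},
                          populations={"pop": 8}, model_window=1_000_000)
        ls = generate_landscape(cfg)
        sites = generate_variants(cfg, ls)["pop"]
        assert len(sites) >= 10_000
        n = 16
        obs = np.bincount(sites["alt_count"], minlength=n)[1:n]
        j = np.arange(1, n)
        expected = len(sites) * (1.0 / j) / np.sum(1.0 / j)
        chi2 = stats.chisquare(obs, expected)
        assert chi2.pvalue > 0.01

    def test_sites_avoid_transcribed_intervals(self):
        cfg = small_config(tx_prop_range=(0.4, 0.5), fail_site_frac=0.0)
        ls = generate_landscape(cfg)
        sites = generate_variants(cfg, ls)["pop"]
        for iv in ls.tx_intervals.itertuples(index=False):
            inside = sites[(sites["chrom"] == iv.chrom)
                           & (sites["pos"] >= iv.start) & (sites["pos"] < iv.end)]
            assert len(inside) == 0

    def test_qual_bands_straddle_filter_threshold(self):
        cfg = null_config(fail_site_frac=0.3)
        sites = generate_variants(cfg, generate_landscape(cfg))["pop"]
        kept = filter_sites(sites, 100)
        assert 0 < len(kept) < len(sites)
        assert (kept["qual"] >= 100).all()
        assert (sites["qual"] < 100).sum() > 0

    def test_estimators_unbiased_for_planted_theta(self):
        # adjoint pair: generator expectations match both estimators
        cfg = null_config(chrom_lengths={f"c{i}": 10_000_000 for i in range(5)},
                          populations={"pop": 14})
        ls = generate_landscape(cfg)
        sites = generate_variants(cfg, ls)["pop"]
        windows = tile_windows(cfg.chrom_lengths, 1_000_000)
        est = dv.window_diversity(filter_sites(sites, 100), windows, n_chroms=28)
        assert est["theta_pi"].mean() == pytest.approx(0.002, rel=0.03)
        assert est["theta_w"].mean() == pytest.approx(0.002, rel=0.03)

    def test_missing_genotypes_reduce_called_chroms(self):
        cfg = null_config(missing_rate=0.2)
        sites = generate_variants(cfg, generate_landscape(cfg))["pop"]
        assert (sites["called_chroms"] < 16).any()
        assert (sites["alt_count"] >= 1).all()
        assert (sites["alt_count"] <= sites["called_chroms"] - 1).all()

    def test_vcf_round_trips_through_reader(self, tmp_path):
        from linkdiv.genomic_io import read_vcf_sites

        cfg = small_config(chrom_lengths={"chr1": 1_000_000},
                           populations={"pop": 4}, fail_site_frac=0.0)
        ls = generate_landscape(cfg)
        mem = generate_variants(cfg, ls, outdir=tmp_path)["pop"]
        back = read_vcf_sites(tmp_path / "pop.vcf",
                              [f"pop{i + 1}" for i in range(4)], min_qual=0)
        mem_pass = mem.reset_index(drop=True)
        assert len(back) == len(mem_pass)
        assert np.array_equal(back["pos"].to_numpy(), mem_pass["pos"].to_numpy())
        assert np.array_equal(back["alt_count"].to_numpy(),
                              mem_pass["alt_count"].to_numpy())
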