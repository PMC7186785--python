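import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_817)


def make_vcf(path, records, samples):
    """Write a minimal VCF 4.2 text file.

    ``records`` is a list of dicts with chrom, pos (1-based), ref, alt, qual,
    gts (list of genotype strings like '0/1').
    """
    chroms = {r["chrom"] for r in records}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in sorted(chroms):
            fh.write(f"##contig=<ID={c},length=1000000>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for r in records:
            cols = [r["chrom"], str(r["pos"]), ".", r["ref"], r["alt"],
                    str(r["qual"]), "PASS", ".", "GT"] + list(r["gts"])
            fh.write("\t".join(cols) + "\n")
    return path


@pytest.fixture
def vcf_writer():
    return make_vcf


def sites_frame(rows):
    """Site table from (chrom, pos, qual, alt_count, called_chroms) tuples."""
    return pd.DataFrame(rows, columns=["chrom", "pos", "qual", "alt_count",
                                       "called_chroms"])


@pytest.fixture
def make_sites():
    return sites_frame
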