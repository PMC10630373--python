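"""Shared fixtures: tiny genotype matrices and on-disk toy files."""

import numpy as np
import pandas as pd
import pytest

from bergscan.io_formats import GenotypeMatrix


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def toy_vcf(tmp_path):
    """Three-sample VCF with het/missing/phased calls, one triallelic row
    and one indel row (both of which readers must drop)."""
    text = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000000>
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
chr1\t100\t.\tA\tG\t.\tPASS\tDP=30\tGT\t0/1\t./.\t1/1
chr1\t200\t.\tC\tT\t.\tPASS\tDP=60\tGT\t0|0\t0/1\t1|1
chr1\t300\t.\tG\tA,T\t.\tPASS\tDP=30\tGT\t0/1\t0/2\t1/2
chr1\t400\t.\tT\tTA\t.\tPASS\tDP=30\tGT\t0/1\t0/0\t0/0
chr1\t500\t.\tG\tC\t.\tPASS\tDP=15\tGT\t0/0\t1/1\t0/1
"""
    path = tmp_path / "toy.vcf"
    path.write_text(text)
    return path


@pytest.fixture()
def small_gm(rng):
    """60 random sites x 8 samples with ~10% missingness."""
    d = rng.binomial(2, rng.uniform(0.1, 0.9, size=60)[:, None], size=(60, 8))
    d = d.astype(np.int8)
    d[rng.random(d.shape) < 0.1] = -1
    return GenotypeMatrix(d, [f"s{i}" for i in range(8)])


def make_variants(n, scaffold="chr1", start=1, spacing=100):
    pos = start + spacing * np.arange(n)
    return pd.DataFrame(
        {
            "scaffold": scaffold,
            "pos": pos.astype(np.int64),
            "ref": "A",
            "alt": "G",
            "mean_depth": 10.0,
        }
    )


@pytest.fixture()
def variants_60():
    return make_variants(60)
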