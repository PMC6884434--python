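import numpy as np
import pandas as pd
import pytest

from sweepscan.panels import GenotypePanel, HaplotypePanel


def make_variants(n, chrom="1", spacing=1000, start=1000):
    pos = start + spacing * np.arange(n)
    return pd.DataFrame(
        dict(
            chrom=[chrom] * n,
            pos=pos,
            snp_id=[f"{chrom}_{i}" for i in range(n)],
            ref=["A"] * n,
            alt=["C"] * n,
        )
    )


def make_samples(n_a, n_b, group_a="prolific", group_b="non_prolific"):
    return pd.DataFrame(
        dict(
            sample_id=[f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)],
            group=[group_a] * n_a + [group_b] * n_b,
        )
    )


def random_genotype_panel(rng, n_a=6, n_b=4, n_snps=20, chrom="1"):
    calls = rng.integers(0, 3, size=(n_a + n_b, n_snps)).astype(np.int8)
    return GenotypePanel(calls, make_variants(n_snps, chrom), make_samples(n_a, n_b))


def random_haplotype_panel(rng, n_a=6, n_b=4, n_snps=20, chrom="1"):
    haps = rng.integers(0, 2, size=(2 * (n_a + n_b), n_snps)).astype(np.uint8)
    return HaplotypePanel(haps, make_variants(n_snps, chrom), make_samples(n_a, n_b))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_genotype_panel(rng):
    return random_genotype_panel(rng)


@pytest.fixture
def small_haplotype_panel(rng):
    return random_haplotype_panel(rng)
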