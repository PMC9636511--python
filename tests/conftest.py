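import numpy as np
import pytest

from mirsnp.io_model import HaplotypePanel, GenotypeMatrix, VariantRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_variants(n, chrom="chr1", spacing=1000, start=1000):
    return [
        VariantRecord(f"rs{i + 1}", chrom, start + spacing * i, "A", "G")
        for i in range(n)
    ]


@pytest.fixture
def small_panel():
    """4 variants x 8 chromosomes; v2 duplicates v1, v4 independent-ish."""
    variants = make_variants(4)
    alleles = np.array([
        [0, 1, 0, 1, 1, 0, 0, 1],
        [0, 1, 0, 1, 1, 0, 0, 1],  # perfect LD with row 0
        [1, 1, 0, 0, 1, 0, 1, 0],
        [0, 0, 1, 1, 0, 1, 0, 1],
    ], dtype=np.int8)
    return HaplotypePanel(variants=variants, alleles=alleles,
                          populations=["EUR"] * 4)


def random_panel(rng, n_variants=50, n_chrom=200, maf_range=(0.1, 0.5)):
    """Random panel with a mix of independent and correlated columns."""
    variants = make_variants(n_variants)
    mafs = rng.uniform(*maf_range, size=n_variants)
    alleles = (rng.random((n_variants, n_chrom)) < mafs[:, None]).astype(np.int8)
    # plant correlated pairs so the proxy scan has structure to find
    for j in range(1, n_variants, 7):
        parent = j - 1
        e = rng.uniform(0.0, 0.5)
        redraw = rng.random(n_chrom) < e
        fresh = (rng.random(n_chrom) < mafs[parent]).astype(np.int8)
        alleles[j] = np.where(redraw, fresh, alleles[parent])
    # guard against monomorphic columns
    for j in range(n_variants):
        if alleles[j].min() == alleles[j].max():
            alleles[j, 0] = 1 - alleles[j, 0]
    return HaplotypePanel(variants=variants, alleles=alleles)


def genotypes_from_phased(panel: HaplotypePanel) -> GenotypeMatrix:
    """Collapse a phased panel into unphased genotypes (chromosome pairs)."""
    n_ind = panel.n_chromosomes // 2
    codes = (panel.alleles[:, 0::2] + panel.alleles[:, 1::2]).T.astype(np.int8)
    return GenotypeMatrix(
        samples=[f"S{i}" for i in range(n_ind)],
        variants=list(panel.variants),
        codes=codes,
    )
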