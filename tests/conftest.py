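"""Shared fixtures: small synthetic cohorts generated at test time."""

import numpy as np
import pandas as pd
import pytest

import varpart as vp


@pytest.fixture(scope="session")
def small_cfg():
    return vp.SimConfig(
        n_chromosomes=3, n_snps=800, n_sires=30, progeny_per_sire=5, seed=7
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    """(genes, snps, genotypes, annotation) for a 150 x 800 cohort."""
    genes, snps = vp.simulate_genome(small_cfg)
    g = vp.simulate_genotypes(small_cfg, snps)
    ann = vp.annotate_snps(snps, genes)
    return genes, snps, g, ann


@pytest.fixture(scope="session")
def dense_cohort():
    """Gene-dense cohort (short flanks) so coding SNPs are plentiful."""
    cfg = vp.SimConfig(
        n_chromosomes=2, chrom_lengths=(400_000, 400_000),
        n_genes_per_chrom=25, intron_length_mean=800.0, flank_bp=500,
        n_snps=4000, n_sires=40, progeny_per_sire=5, seed=11,
    )
    genes, snps = vp.simulate_genome(cfg)
    g = vp.simulate_genotypes(cfg, snps)
    ann = vp.annotate_snps(snps, genes, flank_bp=cfg.flank_bp)
    return cfg, genes, snps, g, ann


def make_genotypes(dosages, chrom="1", start_pos=100, samples=None,
                   r2=None) -> vp.GenotypeMatrix:
    """GenotypeMatrix from a raw dosage array, with auto metadata."""
    dosages = np.asarray(dosages, dtype=np.float32)
    n, m = dosages.shape
    samples = samples or [f"s{i + 1}" for i in range(n)]
    snps = pd.DataFrame({
        "chrom": chrom, "pos": np.arange(start_pos, start_pos + m),
        "id": [f"m{j + 1}" for j in range(m)],
        "ref_allele": "A", "alt_allele": "G",
        "maf": np.nan,
        "imputation_r2": r2 if r2 is not None else 1.0,
    })
    return vp.GenotypeMatrix(samples, snps, dosages)
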