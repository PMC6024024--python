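"""Genomic relationship matrices from standardized SNP dosages.

The single formula used everywhere is the frequency-standardized
cross-product

    A_jk = (1/m) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))

over the m subset SNPs, with p_i the in-sample alt-allele frequency of SNP i
computed within the analysis sample for each subset. Missing dosages are
mean-imputed (2 p_i) before centering; monomorphic SNPs carry no information
and are dropped from m with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datatypes import GRM, GenotypeMatrix


def compute_grm(g: GenotypeMatrix, subset=None, label: str = "all") -> GRM:
    """Build the GRM for ``subset`` SNP ids (default: every SNP).

    Because the formula averages over SNPs, duplicating a SNP inside the
    subset leaves the matrix unchanged, and k disjoint subsets of sizes
    m_1..m_k covering all SNPs satisfy sum_k (m_k / M) GRM_k = GRM_all to
    machine precision.
    """
    sub = g if subset is None else g.subset_snps(subset)
    if sub.n_snps == 0:
        raise ValueError(f"subset '{label}' contains no SNPs")
    x = sub.imputed_dosages()
    p = x.mean(axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError(f"subset '{label}' is entirely monomorphic")
    if not poly.all():
        warnings.warn(
            f"subset '{label}': dropped {int((~poly).sum())} monomorphic SNPs",
            stacklevel=2,
        )
        x, p = x[:, poly], p[poly]
    z = (x - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    z = np.ascontiguousarray(z, dtype=np.float64)
    m = z.shape[1]
    a = (z @ z.T) / m
    a = (a + a.T) / 2.0  # exact symmetry
    return GRM(sample_ids=list(sub.samples), matrix=a, n_snps=m, label=label)
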