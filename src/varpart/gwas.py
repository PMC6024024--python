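"""Mixed-linear-model association scan with Bonferroni thresholds.

The scan follows the two-stage design: phenotypes are first adjusted for
year/season fixed effects and the age covariate by ordinary least squares;
the adjusted trait is then tested SNP by SNP under

    y = a + b x + g + e,      g ~ N(0, A sigma2_g),  e ~ N(0, I sigma2_e)

with variance components estimated once under the null (no SNP) by REML and
then held fixed for every test (the P3D shortcut). A single
eigendecomposition of the GRM turns each per-SNP generalized least squares
into a weighted 2x2 solve, so million-SNP scans are linear passes. The
candidate SNP stays inside the GRM (no leave-one-chromosome-out); the Wald
statistic b/SE(b) is referred to the standard normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm
from sklearn.base import BaseEstimator

from .datatypes import GRM, GenotypeMatrix, validate_phenotypes
from .reml import GREML


@dataclass
class AssocResult:
    """Per-SNP association table plus scan metadata."""

    table: pd.DataFrame  # chrom, id, pos, allele, freq, b, se, p, monomorphic
    n_tests: int
    suggestive: float
    significant: float
    sigma2_g: float
    sigma2_e: float


def bonferroni_thresholds(n_tests: int) -> tuple[float, float]:
    """(suggestive, significant) = (1/n, 0.05/n) for ``n_tests`` tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return 1.0 / n_tests, 0.05 / n_tests


def adjust_phenotypes(pheno: pd.DataFrame, trait: str) -> pd.Series:
    """OLS residuals of ``trait`` on year + season (one-hot) + age.

    Residuals have mean zero and are orthogonal to every design column;
    they are the working phenotype for the association scan.
    """
    validate_phenotypes(pheno)
    if trait not in pheno.columns:
        raise KeyError(f"trait '{trait}' not in phenotype table")
    y = pheno[trait].to_numpy(dtype=float)
    X = design_matrix(pheno)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return pd.Series(resid, index=pheno["sample_id"].to_numpy(), name=trait)


def design_matrix(pheno: pd.DataFrame) -> np.ndarray:
    """Intercept + one-hot year and season (first level dropped) + centered age."""
    n = len(pheno)
    cols = [np.ones(n)]
    for c in ("year", "season"):
        levels = pd.unique(pheno[c])
        for lv in levels[1:]:
            cols.append((pheno[c] == lv).to_numpy(dtype=float))
    age = pheno["age"].to_numpy(dtype=float)
    cols.append(age - age.mean())
    return np.column_stack(cols)


class MixedModelGWAS(BaseEstimator):
    """P3D mixed-model single-SNP association scan.

    Parameters
    ----------
    grm : GRM or ndarray
        Relationship matrix of the analysis cohort (the tested SNPs are
        inside it; proximal contamination is accepted and documented).

    Attributes (after :meth:`fit`)
    ------------------------------
    results_ : :class:`AssocResult`; sigma2_g_, sigma2_e_ : null variance
    components; n_tests_ and the two Bonferroni thresholds.
    """

    def __init__(self, grm=None):
        self.grm = grm

    def fit(self, G, y, subset=None):
        """Scan genotypes ``G`` (GenotypeMatrix) against adjusted trait ``y``.

        ``y`` may be a pandas Series indexed by sample id (it is aligned to
        the genotype sample order) or a plain vector in matrix order.
        ``subset`` restricts the tested SNPs (e.g. the genic or exonic set).
        """
        if self.grm is None:
            raise ValueError("MixedModelGWAS needs a grm")
        K = self.grm.matrix if isinstance(self.grm, GRM) else np.asarray(self.grm)
        if isinstance(y, pd.Series):
            y = y.reindex(G.samples).to_numpy(dtype=float)
            if np.isnan(y).any():
                raise ValueError("phenotype missing for some genotyped samples")
        else:
            y = np.asarray(y, dtype=float).ravel()
        n = G.n_samples
        if K.shape != (n, n) or y.size != n:
            raise ValueError("GRM / phenotype dimensions do not match genotypes")

        null = GREML().fit(K, y)  # intercept-only null model
        sg, se = float(null.sigma2_[0]), null.sigma2_e_

        sub = G if subset is None else G.subset_snps(subset)
        d, U = np.linalg.eigh(K)
        w = 1.0 / (sg * np.clip(d, 0.0, None) + se)  # inverse rotated variances
        yt = U.T @ y
        ones_t = U.T @ np.ones(n)
        X = sub.imputed_dosages()
        Xt = U.T @ X

        # GLS of y on [1, x] with diagonal weights w, vectorized across SNPs
        s11 = float(ones_t * w @ ones_t)
        s1x = (ones_t * w) @ Xt
        sxx = np.einsum("ij,ij->j", Xt * w[:, None], Xt)
        s1y = float(ones_t * w @ yt)
        sxy = (yt * w) @ Xt
        det = s11 * sxx - s1x**2
        freq = X.mean(axis=0) / 2.0
        mono = (freq <= 0.0) | (freq >= 1.0) | (det <= 1e-12 * s11 * np.maximum(sxx, 1e-30))
        det_safe = np.where(mono, 1.0, det)
        b = (s11 * sxy - s1x * s1y) / det_safe
        var_b = s11 / det_safe
        se_b = np.sqrt(var_b)
        z = np.where(mono, 0.0, b / se_b)
        p = np.where(mono, 1.0, 2.0 * norm.sf(np.abs(z)))
        b = np.where(mono, 0.0, b)

        n_tests = sub.n_snps
        suggestive, significant = bonferroni_thresholds(n_tests)
        table = pd.DataFrame({
            "chrom": sub.snps["chrom"].to_numpy(),
            "id": sub.snps["id"].to_numpy(),
            "pos": sub.snps["pos"].to_numpy(),
            "allele": sub.snps["alt_allele"].to_numpy(),
            "freq": freq,
            "b": b, "se": se_b, "p": p,
            "monomorphic": mono,
        })
        self.results_ = AssocResult(
            table=table, n_tests=n_tests,
            suggestive=suggestive, significant=significant,
            sigma2_g=sg, sigma2_e=se,
        )
        self.sigma2_g_, self.sigma2_e_ = sg, se
        self.n_tests_ = n_tests
        return self


def mlm_assoc(y_adj, g: GenotypeMatrix, grm, subset=None) -> AssocResult:
    """Functional wrapper over :class:`MixedModelGWAS`."""
    est = MixedModelGWAS(grm=grm)
    est.fit(g, y_adj, subset=subset)
    return est.results_


def genomic_control_lambda(p_values) -> float:
    """Median-chi-square inflation factor of a p-value set."""
    p = np.asarray(p_values, dtype=float)
    stats = chi2.isf(p, df=1)
    return float(np.median(stats) / chi2.isf(0.5, df=1))


def manhattan_table(result: AssocResult, chrom_lengths: dict | None = None) -> pd.DataFrame:
    """Plot-ready table: cumulative genome x-coordinate, -log10 p, per-
    chromosome color index and the two threshold lines as attributes.

    Chromosomes are laid end to end in sorted order; ``chrom_lengths``
    (bp per chromosome) defaults to the maximum observed position.
    """
    t = result.table.copy()
    chroms = sorted(t["chrom"].unique(), key=lambda c: (len(str(c)), str(c)))
    if chrom_lengths is None:
        chrom_lengths = {c: int(t.loc[t["chrom"] == c, "pos"].max()) for c in chroms}
    offset, offsets = 0, {}
    for c in chroms:
        offsets[c] = offset
        offset += int(chrom_lengths[c])
    t["x"] = t["pos"] + t["chrom"].map(offsets)
    t["neg_log10_p"] = -np.log10(np.clip(t["p"], 1e-300, None))
    color = {c: i % 2 for i, c in enumerate(chroms)}
    t["color_index"] = t["chrom"].map(color)
    t = t.sort_values(["x"], kind="mergesort").reset_index(drop=True)
    t.attrs["suggestive"] = result.suggestive
    t.attrs["significant"] = result.significant
    return t
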