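"""Core in-memory containers shared across the pipeline.

Coordinates are 1-based inclusive throughout (the convention shared by BIM and
GFF3), so no translation layer exists anywhere in the package. Missing
genotypes are ``NaN`` in the dosage matrix and are mean-imputed only at
analysis time, never at I/O time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: columns of the per-SNP metadata frame, in storage order
SNP_COLUMNS = ["chrom", "pos", "id", "ref_allele", "alt_allele", "maf", "imputation_r2"]


@dataclass
class SNPRecord:
    """A single biallelic SNP.

    ``maf`` is always the folded frequency (≤ 0.5); which allele the dosage
    counts is carried separately by the genotype matrix orientation.
    ``imputation_r2`` is 1.0 for directly genotyped markers.
    """

    chrom: str
    pos: int
    id: str
    ref_allele: str
    alt_allele: str
    maf: float = float("nan")
    imputation_r2: float = 1.0

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"SNP {self.id}: position must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"SNP {self.id}: ref and alt alleles are identical")
        if np.isfinite(self.maf) and not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"SNP {self.id}: maf {self.maf} outside [0, 0.5]")


class GenotypeMatrix:
    """Individuals × SNPs dosage matrix with per-SNP metadata.

    Parameters
    ----------
    samples : sequence of str
        Ordered individual identifiers.
    snps : pandas.DataFrame
        One row per SNP with columns :data:`SNP_COLUMNS`; ``maf`` may be NaN
        and is then recomputed from the dosages.
    dosages : ndarray, shape (n_samples, n_snps)
        Alt-allele counts in {0, 1, 2}; NaN marks missing genotypes.
    """

    def __init__(self, samples, snps: pd.DataFrame, dosages: np.ndarray):
        samples = list(samples)
        dosages = np.asarray(dosages, dtype=np.float32)
        if dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x SNPs)")
        if dosages.shape != (len(samples), len(snps)):
            raise ValueError(
                f"dosage shape {dosages.shape} does not match "
                f"{len(samples)} samples x {len(snps)} SNPs"
            )
        valid = np.isnan(dosages) | np.isin(dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be in {0, 1, 2} or NaN")
        self.samples = samples
        self.snps = snps.reset_index(drop=True).copy()
        self.dosages = dosages
        if "maf" not in self.snps or self.snps["maf"].isna().any():
            self.snps["maf"] = self.computed_maf()
        if "imputation_r2" not in self.snps:
            self.snps["imputation_r2"] = 1.0

    # -- basic geometry ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snps["id"].to_numpy()

    def snp_records(self) -> list[SNPRecord]:
        return [SNPRecord(**row) for row in self.snps[SNP_COLUMNS].to_dict("records")]

    # -- frequencies -------------------------------------------------------
    def alt_freq(self) -> np.ndarray:
        """Per-SNP alt-allele frequency over non-missing genotypes."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages.astype(np.float64), axis=0) / 2.0

    def computed_maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    # -- views -------------------------------------------------------------
    def subset_snps(self, ids) -> "GenotypeMatrix":
        """New matrix restricted to ``ids`` (kept in current SNP order)."""
        keep = set(ids)
        mask = self.snps["id"].isin(keep).to_numpy()
        return self.subset_mask(mask)

    def subset_mask(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(self.samples, self.snps.loc[mask], self.dosages[:, mask])

    def imputed_dosages(self) -> np.ndarray:
        """float64 dosage matrix with missing cells mean-imputed (2p per SNP)."""
        x = self.dosages.astype(np.float64)
        if np.isnan(x).any():
            fill = 2.0 * self.alt_freq()
            idx = np.where(np.isnan(x))
            x[idx] = fill[idx[1]]
        return x

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        if self.samples != other.samples:
            return False
        a, b = self.dosages, other.dosages
        same = np.array_equal(a, b, equal_nan=True)
        cols = ["chrom", "pos", "id", "ref_allele", "alt_allele"]
        return same and self.snps[cols].equals(other.snps[cols])

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_snps} SNPs)"


def _merge_intervals(ivs):
    ivs = sorted(ivs)
    out = []
    for s, e in ivs:
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _subtract_intervals(a, b):
    """Intervals of ``a`` not covered by ``b`` (all 1-based inclusive)."""
    out = []
    for s, e in a:
        pieces = [(s, e)]
        for bs, be in b:
            nxt = []
            for ps, pe in pieces:
                if be < ps or bs > pe:
                    nxt.append((ps, pe))
                    continue
                if bs > ps:
                    nxt.append((ps, bs - 1))
                if be < pe:
                    nxt.append((be + 1, pe))
            pieces = nxt
        out.extend(pieces)
    return sorted(out)


@dataclass
class GeneModel:
    """A gene reduced to its longest transcript, enough for consequence calls.

    ``exons`` and ``cds`` are sorted, non-overlapping, 1-based inclusive
    genomic intervals. ``cds_seq`` is the spliced coding sequence in
    transcript orientation (reverse-complemented for minus-strand genes);
    it may be ``None`` when no sequence source was provided, in which case
    coding consequences cannot be resolved. ``phase`` is the frame offset of
    the first in-transcript CDS base (almost always 0).
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list = field(default_factory=list)
    cds: list = field(default_factory=list)
    phase: int = 0
    cds_seq: str | None = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        self.exons = _merge_intervals(self.exons)
        self.cds = _merge_intervals(self.cds)
        for s, e in self.exons + self.cds:
            if not (self.start <= s <= e <= self.end):
                raise ValueError(f"gene {self.gene_id}: interval ({s},{e}) outside span")
        for s, e in self.cds:
            if not any(xs <= s and e <= xe for xs, xe in self.exons):
                raise ValueError(f"gene {self.gene_id}: CDS ({s},{e}) not inside an exon")

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def utr_intervals(self):
        """(utr5, utr3) interval lists derived as exon minus CDS, strand-aware."""
        if not self.cds:
            return [], []
        non_cds = _subtract_intervals(self.exons, self.cds)
        cds_lo = self.cds[0][0]
        cds_hi = self.cds[-1][1]
        low = [iv for iv in non_cds if iv[1] < cds_lo]
        high = [iv for iv in non_cds if iv[0] > cds_hi]
        if self.strand == "+":
            return low, high
        return high, low

    def cds_offset(self, pos: int) -> int | None:
        """0-based offset of genomic ``pos`` within the spliced CDS, in
        transcript orientation; ``None`` if ``pos`` is not in the CDS."""
        if not any(s <= pos <= e for s, e in self.cds):
            return None
        if self.strand == "+":
            off = 0
            for s, e in self.cds:
                if pos > e:
                    off += e - s + 1
                else:
                    return off + (pos - s)
        else:
            off = 0
            for s, e in reversed(self.cds):
                if pos < s:
                    off += e - s + 1
                else:
                    return off + (e - pos)
        return None  # pragma: no cover

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class GRM:
    """Genomic relationship matrix for one SNP subset."""

    sample_ids: list
    matrix: np.ndarray
    n_snps: int
    label: str = "all"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        n = len(self.sample_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("GRM matrix shape does not match sample count")
        if not np.isfinite(self.matrix).all():
            raise ValueError("GRM contains non-finite entries")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("GRM is not symmetric")
        if self.n_snps < 1:
            raise ValueError("GRM must be built from at least one SNP")

    @property
    def n(self) -> int:
        return len(self.sample_ids)


PHENO_FIXED_COLUMNS = ["year", "season", "age"]


def validate_phenotypes(df: pd.DataFrame) -> list[str]:
    """Check a phenotype table and return the trait column names.

    Expected layout: ``sample_id``, one or more numeric trait columns, then
    categorical ``year`` and ``season`` and a numeric ``age`` covariate.
    """
    missing = [c for c in ["sample_id", *PHENO_FIXED_COLUMNS] if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        raise ValueError("phenotype table has duplicated sample_id rows")
    traits = [c for c in df.columns if c not in ("sample_id", *PHENO_FIXED_COLUMNS)]
    if not traits:
        raise ValueError("phenotype table has no trait columns")
    for c in ("year", "season"):
        if df[c].astype(str).str.len().eq(0).any():
            raise ValueError(f"phenotype table has empty {c} categories")
    return traits
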