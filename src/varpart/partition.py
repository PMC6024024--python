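"""SNP quality control and partitioning by functional class, MAF bin and
chromosome.

Annotation calls one consequence per SNP. Where a SNP overlaps several genes
(or several features of one gene) the single most severe consequence wins,
with severity ordered coding > UTR > intron > regulatory flank > intergenic:

    stop_gained > stop_lost > start_lost > missense > synonymous
    > utr5 > utr3 > intron > upstream > downstream > intergenic

Regulatory flanks are measured from the gene span (not the TSS): ``upstream``
/ ``downstream`` mean within ``flank_bp`` of the span on the strand-aware
respective side; ``intergenic`` means farther than ``flank_bp`` from every
gene. Coding consequences are resolved by translating the reference and
alternate codons of the spliced CDS (standard genetic code, strand-aware
reverse complement of the alt allele on minus-strand genes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .datatypes import GeneModel, GenotypeMatrix

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: most severe first
SEVERITY_ORDER = [
    "stop_gained", "stop_lost", "start_lost", "missense", "synonymous",
    "utr5", "utr3", "intron", "upstream", "downstream", "intergenic",
]
_RANK = {c: i for i, c in enumerate(SEVERITY_ORDER)}

#: fine class -> six-class scheme (None = excluded from class GRMs)
MAJOR_CLASS = {
    "synonymous": "synonymous", "missense": "missense",
    "utr5": "utr", "utr3": "utr",
    "intron": "intron",
    "upstream": "regulatory", "downstream": "regulatory",
    "intergenic": "intergenic",
    "stop_gained": None, "stop_lost": None, "start_lost": None,
}

#: six-class scheme -> three-class scheme (exon / intron / intergenic)
GROUP3 = {
    "synonymous": "exon", "missense": "exon", "utr": "exon",
    "intron": "intron",
    "regulatory": "intergenic", "intergenic": "intergenic",
}

MAF_BIN_EDGES = [0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5]


class AnnotationConflictError(ValueError):
    """A CDS SNP's stated reference allele disagrees with the CDS sequence."""


@dataclass
class QCReport:
    """Per-criterion removal counts from :func:`qc_filter` (a SNP failing
    several criteria is counted once under each)."""

    n_input: int
    n_retained: int
    removed_maf: int
    removed_hwe: int
    removed_r2: int


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy–Weinberg test (Wigginton-style, no mid-p).

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the conditional probabilities that do not exceed the observed
    configuration's probability. Monomorphic sites return 1.0.
    """
    from scipy.special import gammaln

    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotype is required")
    n_a = 2 * n_aa + n_Aa  # count of one allele
    n_A = 2 * n_AA + n_Aa
    rare = min(n_a, n_A)
    if rare == 0:
        return 1.0
    # heterozygote counts share the parity of the rare-allele count
    het = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - het) // 2
    hom_common = n - het - hom_rare
    # log P(het | n, rare) up to a shared constant
    logp = (
        het * np.log(2.0)
        - gammaln(het + 1) - gammaln(hom_rare + 1) - gammaln(hom_common + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = prob[np.searchsorted(het, n_Aa)]
    return float(min(prob[prob <= obs * (1 + 1e-12)].sum(), 1.0))


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_filter(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-4,
    r2_min: float = 0.60,
) -> tuple[GenotypeMatrix, QCReport]:
    """Retain SNPs with ``maf >= maf_min``, HWE exact p ``>= hwe_p_min`` and
    imputation R² strictly ``> r2_min`` (the boundary rules mirror the
    quoted exclusion criteria: MAF below 0.01 and HWE below 1e-4 are removed,
    R² must exceed 0.60). SNP order is preserved."""
    if g.n_snps == 0:
        raise ValueError("genotype matrix has no SNPs")
    maf = g.computed_maf()
    pass_maf = maf >= maf_min
    d = g.dosages
    n_aa = np.nansum(d == 2.0, axis=0)
    n_Aa = np.nansum(d == 1.0, axis=0)
    n_AA = np.nansum(d == 0.0, axis=0)
    hwe_p = np.array([
        hwe_exact_test(int(a), int(h), int(b))
        for a, h, b in zip(n_AA, n_Aa, n_aa)
    ])
    pass_hwe = hwe_p >= hwe_p_min
    pass_r2 = g.snps["imputation_r2"].to_numpy() > r2_min
    keep = pass_maf & pass_hwe & pass_r2
    report = QCReport(
        n_input=g.n_snps, n_retained=int(keep.sum()),
        removed_maf=int((~pass_maf).sum()),
        removed_hwe=int((~pass_hwe).sum()),
        removed_r2=int((~pass_r2).sum()),
    )
    if report.n_retained == 0:
        warnings.warn("QC removed every SNP", stacklevel=2)
    return g.subset_mask(keep), report


# ---------------------------------------------------------------------------
# consequence annotation
# ---------------------------------------------------------------------------

def _consequence_in_gene(chrom, pos, ref, alt, gene: GeneModel, flank_bp):
    """Fine class of a SNP with respect to one gene, or None if unrelated."""
    if gene.chrom != chrom:
        return None
    if not gene.contains(pos):
        if gene.start - flank_bp <= pos < gene.start:
            return "upstream" if gene.strand == "+" else "downstream"
        if gene.end < pos <= gene.end + flank_bp:
            return "downstream" if gene.strand == "+" else "upstream"
        return None
    off = gene.cds_offset(pos) if gene.is_coding else None
    if off is not None:
        return _coding_consequence(gene, pos, off, ref, alt)
    utr5, utr3 = gene.utr_intervals()
    if any(s <= pos <= e for s, e in utr5):
        return "utr5"
    if any(s <= pos <= e for s, e in utr3):
        return "utr3"
    return "intron"  # inside the span, outside exons (or non-coding exon)


def _coding_consequence(gene: GeneModel, pos, off, ref, alt):
    if gene.cds_seq is None:
        raise AnnotationConflictError(
            f"gene {gene.gene_id} has no CDS sequence; cannot call coding "
            f"consequence at {gene.chrom}:{pos}"
        )
    off -= gene.phase
    if off < 0:  # inside the out-of-frame phase overhang; no codon to call
        return "synonymous"
    seq = gene.cds_seq[gene.phase:]
    ref_tx = ref if gene.strand == "+" else ref.translate(_COMPLEMENT)
    alt_tx = alt if gene.strand == "+" else alt.translate(_COMPLEMENT)
    if seq[off] != ref_tx:
        raise AnnotationConflictError(
            f"SNP at {gene.chrom}:{pos}: ref allele {ref} (transcript {ref_tx}) "
            f"does not match CDS base {seq[off]} of gene {gene.gene_id}"
        )
    ci = off // 3
    codon = seq[3 * ci:3 * ci + 3]
    if len(codon) < 3:
        return "synonymous"  # trailing partial codon
    alt_codon = codon[: off % 3] + alt_tx + codon[off % 3 + 1:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_alt == "*":
        return "stop_gained"
    if aa_ref == "*":
        return "stop_lost"
    if ci == 0 and codon == "ATG":
        return "start_lost"
    return "missense"


def annotate_snps(
    snps: pd.DataFrame | GenotypeMatrix,
    genes: list[GeneModel],
    flank_bp: int = 5000,
) -> pd.DataFrame:
    """Annotate each SNP with its most severe consequence over all genes.

    Returns a DataFrame indexed by SNP id with columns ``chrom``,
    ``fine_class``, ``major_class`` (six-class scheme; NaN for the excluded
    stop/start fine classes), ``group3`` (exon/intron/intergenic scheme) and
    ``maf_bin`` (1..6, 0 when MAF < 0.01). Results are independent of gene
    and SNP ordering.
    """
    from intervaltree import IntervalTree

    if isinstance(snps, GenotypeMatrix):
        snp_df = snps.snps
    else:
        snp_df = snps
    trees: dict[str, IntervalTree] = {}
    for gene in sorted(genes, key=lambda g: g.gene_id):
        t = trees.setdefault(gene.chrom, IntervalTree())
        t[gene.start - flank_bp: gene.end + flank_bp + 1] = gene

    fine = []
    for chrom, pos, ref, alt in zip(
        snp_df["chrom"], snp_df["pos"], snp_df["ref_allele"], snp_df["alt_allele"]
    ):
        best = "intergenic"
        tree = trees.get(chrom)
        if tree is not None:
            for hit in sorted(tree[pos], key=lambda h: h.data.gene_id):
                c = _consequence_in_gene(chrom, int(pos), ref, alt, hit.data, flank_bp)
                if c is not None and _RANK[c] < _RANK[best]:
                    best = c
        fine.append(best)

    out = pd.DataFrame({
        "chrom": snp_df["chrom"].to_numpy(),
        "fine_class": fine,
    }, index=pd.Index(snp_df["id"], name="id"))
    out["major_class"] = out["fine_class"].map(MAJOR_CLASS)
    out["group3"] = out["major_class"].map(lambda c: GROUP3.get(c) if pd.notna(c) else None)
    out["maf_bin"] = maf_bin(snp_df["maf"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# class schemes and MAF bins
# ---------------------------------------------------------------------------

def collapse_classes(annotation: pd.DataFrame, scheme: str = "six") -> dict[str, list]:
    """Partition SNP ids by class scheme.

    ``six``: utr (5'+3'), synonymous, missense, intron, regulatory
    (upstream+downstream), intergenic. ``three``: exon (synonymous + missense
    + UTRs), intron, intergenic (intergenic + regulatory). Stop/start fine
    classes are excluded from both schemes (they stay in the all-SNP set).
    """
    if scheme not in ("six", "three"):
        raise ValueError("scheme must be 'six' or 'three'")
    col = "major_class" if scheme == "six" else "group3"
    labeled = annotation.dropna(subset=[col])
    return {
        label: sub.index.tolist()
        for label, sub in labeled.groupby(col, sort=True)
    }


def maf_bin(maf) -> np.ndarray:
    """Half-open MAF bins 1..6: [0.01,0.05), [0.05,0.1), [0.1,0.2),
    [0.2,0.3), [0.3,0.4), [0.4,0.5]; 0 for maf < 0.01 (QC territory)."""
    maf = np.atleast_1d(np.asarray(maf, dtype=float))
    bins = np.searchsorted(MAF_BIN_EDGES, maf, side="right")
    bins[maf == 0.5] = 6  # closed top of the last bin
    bins[maf < MAF_BIN_EDGES[0]] = 0
    if (maf > 0.5).any():
        raise ValueError("folded MAF cannot exceed 0.5")
    return bins


def maf_bin_partition(annotation: pd.DataFrame) -> dict[str, list]:
    """SNP ids per occupied MAF bin, labelled '0.01-0.05', ..., '0.4-0.5'."""
    labels = {
        1: "0.01-0.05", 2: "0.05-0.1", 3: "0.1-0.2",
        4: "0.2-0.3", 5: "0.3-0.4", 6: "0.4-0.5",
    }
    keep = annotation[annotation["maf_bin"] > 0]
    return {
        labels[b]: sub.index.tolist()
        for b, sub in keep.groupby("maf_bin", sort=True)
    }


def chromosome_partition(annotation: pd.DataFrame) -> dict[str, list]:
    return {
        chrom: sub.index.tolist()
        for chrom, sub in annotation.groupby("chrom", sort=True)
    }


def class_proportions(counts: dict[str, int], total: int | None = None) -> dict[str, float]:
    """Percentage share of each class (counts / total x 100).

    ``total`` defaults to the sum of the counts; pass the full SNP count when
    the classes do not exhaust it.
    """
    if total is None:
        total = sum(counts.values())
    if total <= 0:
        raise ValueError("total must be positive")
    return {k: 100.0 * v / total for k, v in counts.items()}
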