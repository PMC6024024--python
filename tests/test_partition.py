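"""QC filtering, the HWE exact test, consequence annotation and the class
partition schemes."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

import varpart as vp
from varpart.datatypes import GeneModel
from varpart.partition import (
    AnnotationConflictError,
    MAJOR_CLASS,
    class_proportions,
    maf_bin_partition,
)

from conftest import make_genotypes


# ---------------------------------------------------------------------------
# HWE exact test against a brute-force enumeration oracle
# ---------------------------------------------------------------------------

def hwe_oracle(n_AA, n_Aa, n_aa):
    """Exact-rational enumeration over all heterozygote counts compatible
    with the observed allele counts (independent of the implementation)."""
    n = n_AA + n_Aa + n_aa
    rare = min(2 * n_aa + n_Aa, 2 * n_AA + n_Aa)
    if rare == 0:
        return 1.0
    denom = math.comb(2 * n, rare)
    probs = {}
    for het in range(rare % 2, rare + 1, 2):
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        ways = (math.factorial(n) * 2**het) // (
            math.factorial(hom_r) * math.factorial(het) * math.factorial(hom_c)
        )
        probs[het] = Fraction(ways, denom)
    obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= obs))


class TestHweExact:
    @pytest.mark.parametrize("counts", [
        (25, 50, 25), (50, 0, 50), (10, 20, 10), (3, 1, 40), (0, 5, 95),
        (7, 13, 2), (1, 1, 1), (0, 2, 0), (30, 41, 29),
    ])
    def test_matches_enumeration_oracle(self, counts):
        assert vp.hwe_exact_test(*counts) == pytest.approx(
            hwe_oracle(*counts), rel=1e-9
        )

    def test_modal_configuration_gives_one(self):
        assert vp.hwe_exact_test(25, 50, 25) == pytest.approx(1.0)

    def test_extreme_heterozygote_deficit_is_tiny(self):
        assert vp.hwe_exact_test(50, 0, 50) < 1e-20

    @pytest.mark.parametrize("counts", [(0, 0, 10), (10, 0, 0)])
    def test_monomorphic_returns_one(self, counts):
        assert vp.hwe_exact_test(*counts) == 1.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            vp.hwe_exact_test(-1, 0, 1)
        with pytest.raises(ValueError):
            vp.hwe_exact_test(0, 0, 0)


# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------

def _column(n, n_het, n_hom_alt):
    col = np.zeros(n, dtype=np.float32)
    col[:n_het] = 1.0
    col[n_het:n_het + n_hom_alt] = 2.0
    return col


class TestQcFilter:
    def test_maf_boundary_keeps_exactly_at_threshold(self):
        n = 1000
        d = np.column_stack([
            _column(n, 18, 0),   # maf 0.009 -> removed
            _column(n, 20, 0),   # maf 0.010 -> retained (inclusive keep)
        ])
        g = make_genotypes(d)
        kept, report = vp.qc_filter(g)
        assert list(kept.snp_ids) == ["m2"]
        assert report.removed_maf == 1

    def test_hwe_outlier_removed(self):
        n = 100
        d = np.column_stack([_column(n, 0, 50), _column(n, 50, 25)])
        g = make_genotypes(d)
        kept, report = vp.qc_filter(g)
        assert list(kept.snp_ids) == ["m2"]
        assert report.removed_hwe == 1

    def test_one_failure_per_criterion_counted(self):
        n = 200
        cols = [_column(n, 90, 50) for _ in range(10)]  # all well-behaved
        cols[1] = _column(n, 2, 0)        # fails MAF (0.005)
        cols[4] = _column(n, 0, 100)      # fails HWE hard
        d = np.column_stack(cols)
        r2 = np.ones(10)
        r2[7] = 0.5                        # fails imputation quality
        g = make_genotypes(d, r2=r2)
        kept, report = vp.qc_filter(g)
        assert kept.n_snps == 7
        assert (report.removed_maf, report.removed_hwe, report.removed_r2) == (1, 1, 1)
        # order preserved
        assert list(kept.snp_ids) == [f"m{i}" for i in (1, 3, 4, 6, 7, 9, 10)]

    def test_all_removed_warns_not_raises(self):
        g = make_genotypes(_column(100, 1, 0)[:, None])
        with pytest.warns(UserWarning, match="every SNP"):
            kept, _ = vp.qc_filter(g)
        assert kept.n_snps == 0


# ---------------------------------------------------------------------------
# consequence annotation
# ---------------------------------------------------------------------------

def _snp_df(rows):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref_allele", "alt_allele"])
    df["id"] = [f"v{i}" for i in range(len(df))]
    df["maf"] = 0.2
    df["imputation_r2"] = 1.0
    return df


@pytest.fixture()
def plus_gene():
    # exon 101-400, CDS 151-348 (66 codons), utr5 101-150, utr3 349-400
    seq = "ATG" + "GAA" * 64 + "TAA"
    return GeneModel(
        gene_id="gp", chrom="1", strand="+", start=101, end=400,
        exons=[(101, 400)], cds=[(151, 348)], cds_seq=seq,
    )


@pytest.fixture()
def minus_gene():
    # same span on the minus strand; CDS genomic 151-348, transcript = revcomp
    seq = "ATG" + "GAA" * 64 + "TAA"
    return GeneModel(
        gene_id="gm", chrom="2", strand="-", start=101, end=400,
        exons=[(101, 400)], cds=[(151, 348)], cds_seq=seq,
    )


class TestConsequences:
    def test_synonymous_gaa_to_gag(self, plus_gene):
        # codon 2 occupies CDS offsets 3-5 -> genomic 154-156; GAA->GAG = Glu
        ann = vp.annotate_snps(_snp_df([("1", 156, "A", "G")]), [plus_gene])
        assert ann["fine_class"].iloc[0] == "synonymous"

    def test_missense_gaa_to_gta(self, plus_gene):
        ann = vp.annotate_snps(_snp_df([("1", 155, "A", "T")]), [plus_gene])
        assert ann["fine_class"].iloc[0] == "missense"

    def test_stop_gained_gaa_to_taa(self, plus_gene):
        ann = vp.annotate_snps(_snp_df([("1", 154, "G", "T")]), [plus_gene])
        assert ann["fine_class"].iloc[0] == "stop_gained"

    def test_minus_strand_uses_reverse_complement(self, minus_gene):
        # transcript offset 3 (first base of codon 2, a G) sits at genomic
        # position 345 on the minus strand; genome ref is its complement C.
        # genome C->A means transcript G->T: GAA->TAA = stop_gained.
        ann = vp.annotate_snps(_snp_df([("2", 345, "C", "A")]), [minus_gene])
        assert ann["fine_class"].iloc[0] == "stop_gained"
        # third codon base at genomic 343: GAA->GAG synonymous (T->C genome)
        ann = vp.annotate_snps(_snp_df([("2", 343, "T", "C")]), [minus_gene])
        assert ann["fine_class"].iloc[0] == "synonymous"

    def test_utr_and_intron_and_flanks(self, plus_gene):
        rows = [
            ("1", 120, "A", "G"),    # utr5
            ("1", 380, "A", "G"),    # utr3
            ("1", 3400, "A", "G"),   # 3,000 bp past the end -> downstream
            ("1", 10401, "A", "G"),  # 10,001 bp past the end -> intergenic
            ("1", 50, "A", "G"),     # 51 bp before start -> upstream
        ]
        ann = vp.annotate_snps(_snp_df(rows), [plus_gene])
        assert list(ann["fine_class"]) == [
            "utr5", "utr3", "downstream", "intergenic", "upstream"
        ]

    def test_minus_strand_flank_labels_swap(self, minus_gene):
        ann = vp.annotate_snps(_snp_df([("2", 500, "A", "G")]), [minus_gene])
        assert ann["fine_class"].iloc[0] == "upstream"  # past end, minus strand

    def test_intron_beats_neighbor_upstream(self):
        # two-exon gene A with an intron; gene B 2 kb further downstream
        seq = "ATG" + "GAA" * 64 + "TAA"
        gene_a = GeneModel(
            gene_id="a", chrom="1", strand="+", start=101, end=2400,
            exons=[(101, 300), (2101, 2400)], cds=[(151, 300), (2101, 2148)],
            cds_seq=seq,
        )
        gene_b = GeneModel(
            gene_id="b", chrom="1", strand="+", start=3000, end=3500,
            exons=[(3000, 3500)],
        )
        ann = vp.annotate_snps(_snp_df([("1", 1000, "A", "G")]), [gene_a, gene_b])
        assert ann["fine_class"].iloc[0] == "intron"

    def test_ref_mismatch_raises_conflict(self, plus_gene):
        with pytest.raises(AnnotationConflictError, match="does not match"):
            vp.annotate_snps(_snp_df([("1", 154, "C", "T")]), [plus_gene])

    def test_gene_order_invariance(self, small_cohort):
        genes, snps, _, ann = small_cohort
        shuffled = list(reversed(genes))
        ann2 = vp.annotate_snps(snps, shuffled)
        pd.testing.assert_frame_equal(ann, ann2)

    def test_brute_force_retranslation_oracle(self, dense_cohort):
        """Coding calls agree with translating the whole mutated CDS."""
        from Bio.Seq import Seq

        cfg, genes, snps, _, ann = dense_cohort
        by_id = {g.gene_id: g for g in genes}
        coding = ann[ann["fine_class"].isin(
            ["synonymous", "missense", "stop_gained", "stop_lost", "start_lost"]
        )]
        assert len(coding) >= 100  # the fixture must actually exercise this
        snp_rows = snps.set_index("id")
        checked = 0
        for snp_id, row in coding.iterrows():
            pos = int(snp_rows.loc[snp_id, "pos"])
            alt = snp_rows.loc[snp_id, "alt_allele"]
            gene = next(
                g for g in genes
                if g.chrom == row["chrom"] and g.cds_offset(pos) is not None
            )
            off = gene.cds_offset(pos)
            alt_tx = alt if gene.strand == "+" else str(Seq(alt).complement())
            mutated = gene.cds_seq[:off] + alt_tx + gene.cds_seq[off + 1:]
            p_ref = str(Seq(gene.cds_seq).translate())
            p_alt = str(Seq(mutated).translate())
            if p_ref == p_alt:
                expect = "synonymous"
            elif off < 3:
                expect = "start_lost"
            else:
                ci = off // 3
                if p_alt[ci] == "*" and p_ref[ci] != "*":
                    expect = "stop_gained"
                elif p_ref[ci] == "*" and p_alt[ci] != "*":
                    expect = "stop_lost"
                else:
                    expect = "missense"
            assert row["fine_class"] == expect, snp_id
            checked += 1
            if checked >= 1000:
                break


# ---------------------------------------------------------------------------
# class schemes, MAF bins, partitions
# ---------------------------------------------------------------------------

class TestSchemes:
    def test_three_way_merges_flanks_into_intergenic(self):
        ann = pd.DataFrame({
            "chrom": "1",
            "fine_class": ["intergenic", "upstream", "downstream"],
            "maf_bin": 3,
        }, index=pd.Index(["a", "b", "c"], name="id"))
        ann["major_class"] = ann["fine_class"].map(MAJOR_CLASS)
        ann["group3"] = ann["major_class"].map(
            {"intergenic": "intergenic", "regulatory": "intergenic"}
        )
        parts = vp.collapse_classes(ann, scheme="three")
        assert parts == {"intergenic": ["a", "b", "c"]}

    def test_partition_property_disjoint_exhaustive(self, small_cohort):
        _, _, _, ann = small_cohort
        dropped = ann["major_class"].isna().sum()
        for scheme in ("six", "three"):
            parts = vp.collapse_classes(ann, scheme=scheme)
            ids = [i for v in parts.values() for i in v]
            assert len(ids) == len(set(ids))  # disjoint
            assert len(ids) == len(ann) - dropped  # exhaustive after drops
        chrom = {i for v in maf_bin_partition(ann).values() for i in v}
        assert chrom == set(ann.index[ann["maf_bin"] > 0])

    def test_class_counts_sum_to_total(self, small_cohort):
        _, _, _, ann = small_cohort
        counts = ann["fine_class"].value_counts()
        assert counts.sum() == len(ann)
        pct = class_proportions(counts.to_dict(), total=len(ann))
        assert sum(pct.values()) == pytest.approx(100.0)

    def test_unknown_scheme_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            vp.collapse_classes(small_cohort[3], scheme="five")


class TestMafBin:
    @pytest.mark.parametrize("maf,expected", [
        (0.03, 1), (0.05, 2), (0.0999, 2), (0.1, 3), (0.25, 4),
        (0.35, 5), (0.45, 6), (0.5, 6), (0.009, 0), (0.01, 1),
    ])
    def test_half_open_bins(self, maf, expected):
        assert vp.maf_bin(maf)[0] == expected

    def test_folded_constraint(self):
        with pytest.raises(ValueError):
            vp.maf_bin(0.6)
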