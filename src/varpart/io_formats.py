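"""Readers and writers for the on-disk formats the pipeline touches.

PLINK1 BED/BIM/FAM, VCF 4.x (via cyvcf2), GFF3 gene models (via gffutils),
the GCTA binary GRM triplet, and the phenotype TSV. No science lives here.

Dosages count the BIM allele-1 (A1) as the alt allele by default; the
``count_a2`` dialect flag flips the orientation (dosage becomes 2 - x) without
ever changing the number of samples or SNPs. PLINK files carry no imputation
quality, so the writer emits an optional ``<prefix>.r2.tsv`` sidecar
(columns ``id``, ``imputation_r2``) which the reader picks up when present;
absent quality defaults to 1.0 (directly genotyped).
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GRM, SNP_COLUMNS, GeneModel, GenotypeMatrix, validate_phenotypes

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # PLINK1 SNP-major
# two-bit code -> dosage of A1: 00 hom-A1, 01 missing, 10 het, 11 hom-A2
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0], dtype=np.float32)


class FormatError(ValueError):
    """Raised when a file violates its declared format."""


class CorruptInputError(ValueError):
    """Raised when file pieces are internally inconsistent."""


# ---------------------------------------------------------------------------
# PLINK BED / BIM / FAM
# ---------------------------------------------------------------------------

def read_plink(prefix, count_a2: bool = False) -> GenotypeMatrix:
    """Read a PLINK1 ``prefix.bed/.bim/.fam`` triplet.

    Parameters
    ----------
    prefix : str or Path
        Path prefix (without extension).
    count_a2 : bool
        When True, dosages count the BIM allele-2 instead of allele-1.
    """
    prefix = str(prefix)
    bim = pd.read_csv(
        prefix + ".bim", sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix + ".fam", sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    n, m = len(fam), len(bim)
    raw = Path(prefix + ".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(f"{prefix}.bed: bad magic bytes (not PLINK1 SNP-major)")
    bytes_per_snp = (n + 3) // 4
    if len(raw) != 3 + bytes_per_snp * m:
        raise CorruptInputError(
            f"{prefix}.bed: {len(raw)} bytes, expected 3 + {bytes_per_snp} x {m}"
        )
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    # expand each byte into 4 two-bit codes, sample index fastest, LSB first
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (data >> (2 * k)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T  # (n, m), counts A1
    if count_a2:
        dosages = 2.0 - dosages

    alt = bim["a2"] if count_a2 else bim["a1"]
    ref = bim["a1"] if count_a2 else bim["a2"]
    snps = pd.DataFrame({
        "chrom": bim["chrom"], "pos": bim["pos"], "id": bim["id"],
        "ref_allele": ref, "alt_allele": alt,
        "maf": np.nan, "imputation_r2": 1.0,
    })
    r2_path = Path(prefix + ".r2.tsv")
    if r2_path.exists():
        r2 = pd.read_csv(r2_path, sep="\t", dtype={"id": str})
        snps["imputation_r2"] = (
            snps["id"].map(r2.set_index("id")["imputation_r2"]).fillna(1.0)
        )
    return GenotypeMatrix(fam["iid"].tolist(), snps, dosages)


def write_plink(g: GenotypeMatrix, prefix, count_a2: bool = False) -> None:
    """Write ``g`` as PLINK1 BED/BIM/FAM (+ ``.r2.tsv`` sidecar if any SNP
    has imputation quality below 1)."""
    prefix = str(prefix)
    os.makedirs(os.path.dirname(prefix) or ".", exist_ok=True)
    n, m = g.n_samples, g.n_snps
    dos = g.dosages if not count_a2 else 2.0 - g.dosages
    # dosage of counted allele -> two-bit code
    codes = np.full((m, n), 1, dtype=np.uint8)  # missing
    d = dos.T
    codes[d == 2.0] = 0
    codes[d == 1.0] = 2
    codes[d == 0.0] = 3
    bytes_per_snp = (n + 3) // 4
    padded = np.ones((m, bytes_per_snp * 4), dtype=np.uint8) * 0  # pad code 0
    padded[:, :n] = codes
    packed = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        packed |= padded[:, k::4] << (2 * k)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())

    a1 = g.snps["alt_allele"] if not count_a2 else g.snps["ref_allele"]
    a2 = g.snps["ref_allele"] if not count_a2 else g.snps["alt_allele"]
    bim = pd.DataFrame({
        "chrom": g.snps["chrom"], "id": g.snps["id"], "cm": 0,
        "pos": g.snps["pos"], "a1": a1, "a2": a2,
    })
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)
    fam = pd.DataFrame({
        "fid": g.samples, "iid": g.samples, "father": 0, "mother": 0,
        "sex": 0, "pheno": -9,
    })
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)
    if (g.snps["imputation_r2"] < 1.0).any():
        g.snps[["id", "imputation_r2"]].to_csv(prefix + ".r2.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, r2_field: str = "R2", on_multiallelic: str = "error") -> GenotypeMatrix:
    """Read a VCF 4.x with GT into a :class:`GenotypeMatrix`.

    ``0/0, 0/1, 1/1`` (phased or not) map to dosages 0, 1, 2 of the ALT
    allele; ``./.`` to missing. Imputation quality is taken from the INFO key
    ``r2_field`` (default ``R2``), 1.0 when absent. Multiallelic records
    raise or are skipped per ``on_multiallelic`` ('error' | 'skip').
    """
    from cyvcf2 import VCF

    if on_multiallelic not in ("error", "skip"):
        raise ValueError("on_multiallelic must be 'error' or 'skip'")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, columns = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            if on_multiallelic == "skip":
                continue
            raise FormatError(f"multiallelic record at {var.CHROM}:{var.POS}")
        gts = var.genotypes  # [[a0, a1, phased], ...]
        if gts is None:
            raise FormatError(f"record at {var.CHROM}:{var.POS} has no GT field")
        dos = np.array(
            [a + b if a >= 0 and b >= 0 else np.nan for a, b, *_ in gts],
            dtype=np.float32,
        )
        r2 = var.INFO.get(r2_field)
        rows.append({
            "chrom": var.CHROM, "pos": var.POS,
            "id": var.ID or f"{var.CHROM}:{var.POS}",
            "ref_allele": var.REF, "alt_allele": var.ALT[0],
            "maf": np.nan,
            "imputation_r2": float(r2) if r2 is not None else 1.0,
        })
        columns.append(dos)
    snps = pd.DataFrame(rows, columns=SNP_COLUMNS)
    dosages = (
        np.stack(columns, axis=1) if columns
        else np.empty((len(samples), 0), dtype=np.float32)
    )
    return GenotypeMatrix(samples, snps, dosages)


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def read_gff3(path, cds_fasta=None) -> list[GeneModel]:
    """Parse GFF3 gene/mRNA/exon/CDS features into :class:`GeneModel` list.

    When a gene has several transcripts, the one with the largest spliced
    exon length wins (ties broken by feature id). ``cds_fasta`` is an
    optional FASTA keyed by gene id holding spliced, transcript-oriented CDS
    sequences; without it coding consequences cannot be called downstream.
    A child feature whose ``Parent`` is not in the file is a structural error.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True,
        merge_strategy="create_unique", keep_order=True,
    )
    known = {f.id for f in db.all_features()}
    for f in db.all_features():
        for parent in f.attributes.get("Parent", []):
            if parent not in known:
                raise CorruptInputError(
                    f"feature {f.id or f.featuretype} references missing parent {parent}"
                )

    seqs = {}
    if cds_fasta is not None:
        from pyfaidx import Fasta

        seqs = {k: str(v[:]) for k, v in Fasta(str(cds_fasta)).items()}

    genes = []
    for gene in db.features_of_type("gene"):
        transcripts = list(db.children(gene, featuretype=("mRNA", "transcript")))
        if transcripts:
            def spliced_len(t):
                return sum(e.end - e.start + 1 for e in db.children(t, featuretype="exon"))
            transcripts.sort(key=lambda t: (-spliced_len(t), t.id))
            t = transcripts[0]
        else:
            t = gene  # exon/CDS attached directly to the gene feature
        exons = [(e.start, e.end) for e in db.children(t, featuretype="exon")]
        cds_feats = sorted(db.children(t, featuretype="CDS"), key=lambda c: c.start)
        cds = [(c.start, c.end) for c in cds_feats]
        if cds_feats:
            first = cds_feats[0] if gene.strand == "+" else cds_feats[-1]
            phase = int(first.frame) if first.frame not in (None, ".") else 0
        else:
            phase = 0
        if not exons:
            exons = cds[:] if cds else [(gene.start, gene.end)]
        genes.append(GeneModel(
            gene_id=gene.id, chrom=gene.seqid, strand=gene.strand,
            start=gene.start, end=gene.end, exons=exons, cds=cds,
            phase=phase, cds_seq=seqs.get(gene.id),
        ))
    return genes


def write_gff3(genes: list[GeneModel], path) -> None:
    """Write gene models as minimal GFF3 (gene/mRNA/exon/CDS rows)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(f"{g.chrom}\tvarpart\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n")
            tid = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tvarpart\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={tid};Parent={g.gene_id}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\tvarpart\texon\t{s}\t{e}\t.\t{g.strand}\t.\tParent={tid}\n"
                )
            # phase is tracked in transcript order but rows are emitted by position
            cds_iter = g.cds if g.strand == "+" else list(reversed(g.cds))
            off = g.phase
            phased = []
            for s, e in cds_iter:
                phased.append((s, e, off % 3))
                off = (3 - ((e - s + 1 - off) % 3)) % 3
            for s, e, ph in sorted(phased):
                fh.write(
                    f"{g.chrom}\tvarpart\tCDS\t{s}\t{e}\t.\t{g.strand}\t{ph}\t"
                    f"Parent={tid}\n"
                )


def write_cds_fasta(genes: list[GeneModel], path) -> None:
    """FASTA of spliced, transcript-oriented CDS sequences keyed by gene id."""
    with open(path, "w") as fh:
        for g in genes:
            if g.cds_seq is None:
                continue
            fh.write(f">{g.gene_id}\n")
            for i in range(0, len(g.cds_seq), 60):
                fh.write(g.cds_seq[i:i + 60] + "\n")


# ---------------------------------------------------------------------------
# GCTA binary GRM triplet
# ---------------------------------------------------------------------------

def write_grm_gcta(grm: GRM, prefix) -> None:
    """Write ``prefix.grm.bin`` / ``.grm.N.bin`` / ``.grm.id`` (GCTA layout:
    lower triangle including the diagonal, row by row, float32)."""
    prefix = str(prefix)
    os.makedirs(os.path.dirname(prefix) or ".", exist_ok=True)
    n = grm.n
    idx = np.tril_indices(n)
    grm.matrix[idx].astype("<f4").tofile(prefix + ".grm.bin")
    np.full(len(idx[0]), grm.n_snps, dtype="<f4").tofile(prefix + ".grm.N.bin")
    with open(prefix + ".grm.id", "w") as fh:
        for sid in grm.sample_ids:
            fh.write(f"{sid}\t{sid}\n")


def read_grm_gcta(prefix, label: str = "all") -> GRM:
    prefix = str(prefix)
    ids = [line.split()[1] for line in open(prefix + ".grm.id") if line.strip()]
    n = len(ids)
    tri = np.fromfile(prefix + ".grm.bin", dtype="<f4")
    expected = n * (n + 1) // 2
    if len(tri) != expected:
        raise CorruptInputError(
            f"{prefix}.grm.bin holds {len(tri)} values, expected {expected} for n={n}"
        )
    mat = np.zeros((n, n))
    idx = np.tril_indices(n)
    mat[idx] = tri
    mat = mat + np.tril(mat, -1).T
    counts = np.fromfile(prefix + ".grm.N.bin", dtype="<f4")
    n_snps = int(counts[0]) if len(counts) else 1
    return GRM(sample_ids=ids, matrix=mat, n_snps=n_snps, label=label)


# ---------------------------------------------------------------------------
# Phenotypes and truth JSON
# ---------------------------------------------------------------------------

def read_phenotypes(path) -> pd.DataFrame:
    """Read the phenotype TSV (``sample_id``, traits..., year, season, age)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "year": str, "season": str})
    validate_phenotypes(df)
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    validate_phenotypes(df)
    df.to_csv(path, sep="\t", index=False)


def write_truth_json(truth, path) -> None:
    """Serialize a :class:`~varpart.synthetic_data.SimTruth` to JSON."""
    def _conv(x):
        if isinstance(x, np.ndarray):
            return x.tolist()
        if isinstance(x, (np.floating, np.integer)):
            return x.item()
        raise TypeError(type(x))

    from dataclasses import asdict

    with open(path, "w") as fh:
        json.dump(asdict(truth), fh, indent=1, default=_conv)
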