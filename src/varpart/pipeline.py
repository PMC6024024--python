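"""End-to-end orchestration: simulate -> qc -> partition -> grm -> reml ->
gwas -> bayesr, with a JSON run manifest and deterministic seed fan-out.

Each stage writes versioned outputs into the run directory and appends a
manifest record (parameters, input hashes, seed, wall time). The global seed
is fanned out to per-stage child streams via ``SeedSequence([seed, stage_index])``
(stage indices are their positions in :data:`STAGES`), so any stage can be
re-run in isolation reproducibly. Re-running an identical config reproduces
byte-identical numeric tables. A stage failure halts the run with the stage
name; outputs of earlier stages are left in place.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats as io
from .bayesr import MixtureConfig, component_summary, fit_bayesr
from .grm import compute_grm
from .gwas import adjust_phenotypes, manhattan_table, mlm_assoc
from .partition import (
    annotate_snps,
    chromosome_partition,
    collapse_classes,
    maf_bin_partition,
    qc_filter,
)
from .reml import partition_analysis
from .synthetic_data import (
    SimConfig,
    TraitArchitecture,
    simulate_genome,
    simulate_genotypes,
    simulate_phenotypes,
)

STAGES = ["simulate", "qc", "partition", "grm", "reml", "gwas", "bayesr"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Run settings: either real-input paths or a SimConfig, never neither."""

    out_dir: str = "varpart_run"
    seed: int = 0
    stages: list = field(default_factory=lambda: list(STAGES))
    # real inputs (used when sim is None)
    plink_prefix: str | None = None
    vcf: str | None = None
    gff3: str | None = None
    cds_fasta: str | None = None
    phenotypes: str | None = None
    # synthetic cohort
    sim: SimConfig | None = None
    arch: TraitArchitecture | None = None
    # analysis settings
    qc: dict = field(default_factory=lambda: dict(maf_min=0.01, hwe_p_min=1e-4, r2_min=0.60))
    scheme: str = "three"
    traits: list | None = None
    gwas_subset: str = "genic"  # 'genic' | 'exon' | 'all'
    bayesr: dict = field(default_factory=lambda: dict(chain_length=50_000, burn_in=20_000, thin=10))

    def __post_init__(self):
        has_real = self.plink_prefix or self.vcf
        if self.sim is None and not has_real:
            raise ValueError("config needs either input paths or a sim block")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.sim is not None and self.sim.seed != self.seed:
            self.sim = dataclasses.replace(self.sim, seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "sim" in raw and raw["sim"] is not None:
            raw["sim"] = SimConfig(**raw["sim"])
        if "arch" in raw and raw["arch"] is not None:
            arch = raw["arch"]
            if "causal_per_class" not in arch and "mixture_props" in arch:
                arch["mixture_props"] = tuple(arch["mixture_props"])
            raw["arch"] = TraitArchitecture(**arch)
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence([self.seed, STAGES.index(stage)])
        return int(ss.generate_state(1)[0] % (2**31 - 1))


def _hash_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def _write_table(df: pd.DataFrame, path, cfg: PipelineConfig, stage: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# varpart stage={stage} seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": []}
    state: dict = {}

    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        t0 = time.time()
        try:
            record = _STAGE_FUNCS[stage](cfg, out, state)
        except Exception as exc:  # halt, keeping earlier outputs
            _flush_manifest(manifest, out)
            raise StageError(f"stage '{stage}' failed: {exc}") from exc
        record.update(stage=stage, seed=cfg.stage_seed(stage),
                      wall_time_s=round(time.time() - t0, 3))
        manifest["stages"].append(record)
    _flush_manifest(manifest, out)
    return manifest


def _flush_manifest(manifest, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig, out: Path, state: dict) -> dict:
    sim = cfg.sim
    if sim is None:
        return {"skipped": "real inputs supplied"}
    genes, snps = simulate_genome(sim)
    g = simulate_genotypes(sim, snps)
    arch = cfg.arch or TraitArchitecture(
        h2_target=0.5, causal_per_class={"intergenic": 200}
    )
    ann = annotate_snps(snps, genes, flank_bp=sim.flank_bp)
    pheno, truth = simulate_phenotypes(g, ann, arch, sim)
    prefix = out / "cohort"
    io.write_plink(g, prefix)
    io.write_gff3(genes, out / "genes.gff3")
    io.write_cds_fasta(genes, out / "genes.cds.fasta")
    io.write_phenotypes(pheno, out / "phenotypes.tsv")
    io.write_truth_json(truth, out / "truth.json")
    state.update(genotypes=g, genes=genes, pheno=pheno, truth=truth)
    return {
        "n_individuals": g.n_samples, "n_snps": g.n_snps, "n_genes": len(genes),
        "outputs": ["cohort.bed", "genes.gff3", "phenotypes.tsv", "truth.json"],
    }


def _load_inputs(cfg: PipelineConfig, state: dict) -> None:
    if "genotypes" not in state:
        if cfg.plink_prefix:
            state["genotypes"] = io.read_plink(cfg.plink_prefix)
        elif cfg.vcf:
            state["genotypes"] = io.read_vcf(cfg.vcf)
        else:
            raise ValueError("no genotype source")
    if "genes" not in state and cfg.gff3:
        state["genes"] = io.read_gff3(cfg.gff3, cds_fasta=cfg.cds_fasta)
    if "pheno" not in state and cfg.phenotypes:
        state["pheno"] = io.read_phenotypes(cfg.phenotypes)


def _stage_qc(cfg: PipelineConfig, out: Path, state: dict) -> dict:
    _load_inputs(cfg, state)
    filtered, report = qc_filter(state["genotypes"], **cfg.qc)
    state["genotypes_qc"] = filtered
    rec = dataclasses.asdict(report)
    with open(out / "qc_report.json", "w") as fh:
        json.dump(rec, fh, indent=1)
    return rec


def _stage_partition(cfg: PipelineConfig, out: Path, state: dict) -> dict:
    _load_inputs(cfg, state)
    g = state.get("genotypes_qc", state["genotypes"])
    ann = annotate_snps(g, state["genes"])
    state["annotation"] = ann
    _write_table(ann.reset_index(), out / "annotations.tsv", cfg, "partition")
    return {"classes": ann["fine_class"].value_counts().to_dict()}


def _current_partitions(cfg: PipelineConfig, state: dict) -> dict:
    ann = state["annotation"]
    return collapse_classes(ann, scheme=cfg.scheme)


def _stage_grm(cfg: PipelineConfig, out: Path, state: dict) -> dict:
    g = state.get("genotypes_qc", state["genotypes"])
    parts = _current_partitions(cfg, state)
    grm_dir = out / "grm"
    grm_dir.mkdir(exist_ok=True)
    all_grm = compute_grm(g, label="all")
    io.write_grm_gcta(all_grm, grm_dir / "all")
    state["grm_all"] = all_grm
    for label, ids in parts.items():
        io.write_grm_gcta(compute_grm(g, subset=ids, label=label), grm_dir / label)
    return {"labels": ["all", *sorted(parts)], "n_snps": all_grm.n_snps}


def _traits(cfg: PipelineConfig, state: dict) -> list:
    from .datatypes import validate_phenotypes

    available = validate_phenotypes(state["pheno"])
    return cfg.traits or available


def _stage_reml(cfg: PipelineConfig, out: Path, state: dict) -> dict:
    g = state.get("genotypes_qc", state["genotypes"])
    parts = _current_partitions(cfg, state)
    rows = []
    for trait in _traits(cfg, state):
        y = adjust_phenotypes(state["pheno"], trait)
        yv = y.reindex(g.samples).to_numpy()
        for mode in ("separate", "joint"):
            tab = partition_analysis(yv, None, g, parts, mode=mode)
            tab.insert(0, "trait", trait)
            rows.append(tab)
    table = pd.concat(rows, ignore_index=True)
    _write_table(table, out / "reml.tsv", cfg, "reml")
    state["reml_table"] = table
    return {"converged": bool(table["converged"].all()), "n_fits": len(table)}


def _gwas_subset_ids(cfg: PipelineConfig, state: dict):
    if cfg.gwas_subset == "all":
        return None
    ann = state["annotation"]
    wanted = {"genic": ("exon", "intron"), "exon": ("exon",)}[cfg.gwas_subset]
    return ann.index[ann["group3"].isin(wanted)].tolist()


def _stage_gwas(cfg: PipelineConfig, out: Path, state: dict) -> dict:
    g = state.get("genotypes_qc", state["genotypes"])
    grm = state.get("grm_all") or compute_grm(g, label="all")
    subset = _gwas_subset_ids(cfg, state)
    info = {}
    for trait in _traits(cfg, state):
        y = adjust_phenotypes(state["pheno"], trait)
        res = mlm_assoc(y, g, grm, subset=subset)
        _write_table(res.table, out / f"assoc_{trait}.tsv", cfg, "gwas")
        _write_table(manhattan_table(res), out / f"manhattan_{trait}.tsv", cfg, "gwas")
        info[trait] = {
            "n_tests": res.n_tests,
            "significant_hits": int((res.table["p"] < res.significant).sum()),
        }
        state[f"assoc_{trait}"] = res
    return info


def _stage_bayesr(cfg: PipelineConfig, out: Path, state: dict) -> dict:
    g = state.get("genotypes_qc", state["genotypes"])
    ann = state["annotation"]
    exon_ids = ann.index[ann["group3"] == "exon"].tolist()
    mix = MixtureConfig(seed=cfg.stage_seed("bayesr"), **cfg.bayesr)
    info = {}
    for trait in _traits(cfg, state):
        y = adjust_phenotypes(state["pheno"], trait)
        res = fit_bayesr(y, g, subset=exon_ids, cfg=mix)
        summary = component_summary(res)
        _write_table(summary, out / f"bayesr_components_{trait}.tsv", cfg, "bayesr")
        effects = pd.DataFrame({
            "id": res.snp_ids, "beta": res.beta,
            "p_nonzero": 1.0 - res.comp_prob[:, 0],
        })
        _write_table(effects, out / f"bayesr_effects_{trait}.tsv", cfg, "bayesr")
        info[trait] = {
            "nsnp_nonzero": round(res.nsnp_nonzero, 2),
            "sigma2_G": res.sigma2_G,
        }
    return info


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "partition": _stage_partition,
    "grm": _stage_grm,
    "reml": _stage_reml,
    "gwas": _stage_gwas,
    "bayesr": _stage_bayesr,
}
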