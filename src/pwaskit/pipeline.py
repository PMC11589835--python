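"""End-to-end orchestration: simulate → qc → preprocess → train →
associate → condition → report.

Stages read and write the plain-text formats in :mod:`pwaskit.io` under a
single output directory and record a manifest (per-stage input hashes,
row counts, seeds). A stage is skipped on re-run when its input hash is
unchanged and its outputs exist. The global seed fans out to per-stage
seeds by fixed offsets.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .assoc import PWAS, LDReference
from .cismodels import ModelDB, build_models
from .preprocess import preprocess_chain
from .qc import QCThresholds, filter_samples, filter_variants, harmonize_alleles
from .report import correlate_matrices
from .sim import (
    GWAS_COLUMNS, SimConfig, simulate_annotation, simulate_genotypes,
    simulate_gwas_sumstats, simulate_proteome, simulate_rna,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    sim: SimConfig | None = None
    qc: QCThresholds = field(default_factory=QCThresholds)
    k_pcs: int = 3
    k_hidden: int = 15
    cis_window: int = 500_000
    fdr_threshold: float = 0.1
    conditional_threshold: float = 1e-4
    novelty_window: int = 1_000_000
    phenotypes: list[str] = field(default_factory=lambda: ["overall"])
    n_known_variants: int = 2
    gwas_mode: str = "analytic"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim")) if "sim" in raw else None
        qc = QCThresholds(**raw.pop("qc")) if "qc" in raw else QCThresholds()
        cfg = cls(sim=sim, qc=qc, **raw)
        if cfg.sim is not None and raw.get("seed") is not None:
            cfg.sim = cfg.sim.with_(seed=cfg.sim.seed or cfg.seed)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _hash_obj(obj) -> str:
    return hashlib.sha1(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _hash_files(paths) -> str:
    h = hashlib.sha1()
    for p in sorted(paths):
        h.update(p.encode())
        if os.path.exists(p):
            with open(p, "rb") as fh:
                h.update(fh.read())
    return h.hexdigest()[:16]


class _Manifest:
    def __init__(self, path: str):
        self.path = path
        self.data = {"stages": {}}
        if os.path.exists(path):
            with open(path) as fh:
                self.data = json.load(fh)

    def stage_current(self, name: str, in_hash: str, outputs) -> bool:
        rec = self.data["stages"].get(name)
        return (
            rec is not None
            and rec.get("in_hash") == in_hash
            and all(os.path.exists(p) for p in outputs)
        )

    def record(self, name: str, in_hash: str, outputs, **extra) -> None:
        self.data["stages"][name] = {
            "in_hash": in_hash,
            "outputs": list(outputs),
            "out_hash": _hash_files(outputs),
            **extra,
        }
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=2, default=str)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dict."""
    if config.sim is None:
        raise ValueError("run_pipeline currently requires a SimConfig "
                         "(synthetic mode); use the per-stage CLI commands "
                         "for external data")
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    manifest = _Manifest(os.path.join(out, "manifest.json"))
    sim = config.sim.with_(seed=config.sim.seed if config.sim.seed else config.seed)

    # ---- simulate ------------------------------------------------------
    sim_outputs = [
        f"{out}/tissue.dosage.tsv", f"{out}/ref.dosage.tsv",
        f"{out}/proteome.tsv", f"{out}/rna.tsv", f"{out}/annotation.tsv",
        f"{out}/age.tsv", f"{out}/known_variants.tsv",
    ] + [f"{out}/gwas.{p.replace('/', '_').replace(' ', '_')}.tsv"
         for p in config.phenotypes]
    sim_hash = _hash_obj({"sim": asdict(sim), "phenos": config.phenotypes,
                          "mode": config.gwas_mode,
                          "n_known": config.n_known_variants})
    if not manifest.stage_current("simulate", sim_hash, sim_outputs):
        tissue = simulate_genotypes(sim, role="tissue")
        ref = simulate_genotypes(sim, role="ref")
        annotation = simulate_annotation(sim)
        proteome, truth = simulate_proteome(tissue, annotation, sim)
        rna = simulate_rna(proteome, sim)
        pio.write_panel(tissue, f"{out}/tissue")
        pio.write_panel(ref, f"{out}/ref")
        pio.write_matrix(proteome, f"{out}/proteome.tsv")
        pio.write_matrix(rna, f"{out}/rna.tsv", index_label="gene_id")
        pio.write_annotation(annotation, f"{out}/annotation.tsv")
        pio.write_truth(truth, f"{out}/truth")
        rng = np.random.default_rng([sim.seed, 71])
        age = pd.Series(rng.uniform(30, 65, size=tissue.n_samples).round(1),
                        index=tissue.sample_ids, name="age")
        age.to_csv(f"{out}/age.tsv", sep="\t", index_label="sample_id")
        # known risk variants: strongest causal variants of causal proteins
        eff = truth.per_allele_effects()
        eff = eff[eff.abs() > 0].abs().sort_values(ascending=False)
        known_ids = eff.index[: config.n_known_variants]
        known = ref.variants.loc[known_ids, ["chrom", "pos"]].reset_index()
        known.to_csv(f"{out}/known_variants.tsv", sep="\t", index=False)
        for i, pheno in enumerate(config.phenotypes):
            g = simulate_gwas_sumstats(
                ref, truth, sim, mode=config.gwas_mode,
                seed=sim.seed + 1000 + i,
            )
            tag = pheno.replace("/", "_").replace(" ", "_")
            pio.write_gwas(g, f"{out}/gwas.{tag}.tsv")
        manifest.record("simulate", sim_hash, sim_outputs,
                        n_variants=int(tissue.n_variants),
                        n_tissue=int(tissue.n_samples))

    # ---- qc ------------------------------------------------------------
    qc_inputs = [f"{out}/tissue.dosage.tsv", f"{out}/ref.dosage.tsv"] + [
        f"{out}/gwas.{p.replace('/', '_').replace(' ', '_')}.tsv"
        for p in config.phenotypes
    ]
    qc_hash = _hash_obj({"qc": asdict(config.qc), "files": _hash_files(qc_inputs)})
    qc_outputs = [f"{out}/qc/tissue.dosage.tsv", f"{out}/qc/ref.dosage.tsv",
                  f"{out}/qc/report.tsv"] + [
        f"{out}/qc/gwas.{p.replace('/', '_').replace(' ', '_')}.tsv"
        for p in config.phenotypes
    ]
    if not manifest.stage_current("qc", qc_hash, qc_outputs):
        tissue = pio.read_panel(f"{out}/tissue")
        ref = pio.read_panel(f"{out}/ref")
        tissue, rep_s = filter_samples(tissue, config.qc)
        tissue, rep_v = filter_variants(tissue, config.qc)
        ref = ref.subset_variants(tissue.variant_ids)
        reports = [rep_s.to_frame(), rep_v.to_frame()]
        for pheno in config.phenotypes:
            tag = pheno.replace("/", "_").replace(" ", "_")
            gwas = pio.read_gwas(f"{out}/gwas.{tag}.tsv")
            tissue, gwas_h, rep_h = harmonize_alleles(tissue, gwas)
            ref = ref.subset_variants(tissue.variant_ids)
            pio.write_gwas(gwas_h, f"{out}/qc/gwas.{tag}.tsv")
            reports.append(rep_h.to_frame())
        pio.write_panel(tissue, f"{out}/qc/tissue")
        pio.write_panel(ref, f"{out}/qc/ref")
        pd.concat(reports, ignore_index=True).to_csv(
            f"{out}/qc/report.tsv", sep="\t", index=False)
        manifest.record("qc", qc_hash, qc_outputs,
                        n_variants=int(tissue.n_variants))

    # ---- preprocess ----------------------------------------------------
    pre_inputs = [f"{out}/qc/tissue.dosage.tsv", f"{out}/proteome.tsv",
                  f"{out}/age.tsv"]
    pre_hash = _hash_obj({"k_pcs": config.k_pcs, "k_hidden": config.k_hidden,
                          "files": _hash_files(pre_inputs)})
    pre_outputs = [f"{out}/residuals.tsv", f"{out}/covariates.tsv"]
    if not manifest.stage_current("preprocess", pre_hash, pre_outputs):
        tissue = pio.read_panel(f"{out}/qc/tissue")
        proteome = pio.read_matrix(f"{out}/proteome.tsv")
        proteome = proteome[tissue.sample_ids]
        age = pd.read_csv(f"{out}/age.tsv", sep="\t", index_col=0)["age"]
        annotation = pio.read_annotation(f"{out}/annotation.tsv")
        residuals, covars, _log = preprocess_chain(
            proteome, tissue, age, k_pcs=config.k_pcs,
            k_hidden=config.k_hidden, annotation=annotation,
        )
        pio.write_matrix(residuals, f"{out}/residuals.tsv")
        covars.to_csv(f"{out}/covariates.tsv", sep="\t", index_label="sample_id")
        manifest.record("preprocess", pre_hash, pre_outputs,
                        n_proteins=int(len(residuals)))

    # ---- train ---------------------------------------------------------
    train_inputs = [f"{out}/residuals.tsv", f"{out}/qc/tissue.dosage.tsv",
                    f"{out}/annotation.tsv"]
    train_hash = _hash_obj({"window": config.cis_window, "seed": config.seed,
                            "files": _hash_files(train_inputs)})
    train_outputs = [f"{out}/models/weights.tsv", f"{out}/models/extra.tsv"]
    if not manifest.stage_current("train", train_hash, train_outputs):
        tissue = pio.read_panel(f"{out}/qc/tissue")
        residuals = pio.read_matrix(f"{out}/residuals.tsv")
        annotation = pio.read_annotation(f"{out}/annotation.tsv")
        db = build_models(residuals, tissue, annotation,
                          flank=config.cis_window, seed=config.seed + 40)
        db.to_tsv(f"{out}/models")
        manifest.record("train", train_hash, train_outputs,
                        n_models=len(db),
                        retained_fraction=db.retained_fraction())

    # ---- associate -----------------------------------------------------
    assoc_inputs = train_outputs + [f"{out}/qc/ref.dosage.tsv"] + [
        f"{out}/qc/gwas.{p.replace('/', '_').replace(' ', '_')}.tsv"
        for p in config.phenotypes
    ]
    assoc_hash = _hash_obj({"fdr": config.fdr_threshold,
                            "novelty": config.novelty_window,
                            "files": _hash_files(assoc_inputs)})
    assoc_outputs = [f"{out}/associations.tsv"]
    if not manifest.stage_current("associate", assoc_hash, assoc_outputs):
        db = ModelDB.from_tsv(f"{out}/models")
        ref = pio.read_panel(f"{out}/qc/ref")
        annotation = pio.read_annotation(f"{out}/annotation.tsv")
        known = pd.read_csv(f"{out}/known_variants.tsv", sep="\t",
                            dtype={"chrom": str})
        gwas_map = {
            p: pio.read_gwas(
                f"{out}/qc/gwas.{p.replace('/', '_').replace(' ', '_')}.tsv")
            for p in config.phenotypes
        }
        pwas = PWAS(db, gwas_map, LDReference(ref), known_variants=known,
                    annotation=annotation, fdr_threshold=config.fdr_threshold,
                    novelty_window=config.novelty_window)
        results = pwas.fit()
        results.table.to_csv(f"{out}/associations.tsv", sep="\t", index=False)
        with open(f"{out}/associations.summary.txt", "w") as fh:
            fh.write(results.summary() + "\n")
        manifest.record("associate", assoc_hash, assoc_outputs,
                        n_significant=int(len(results.significant())))

        # ---- condition (piggybacks on the fitted results) --------------
        if len(known):
            cond = results.conditional(threshold=config.conditional_threshold,
                                       window=config.novelty_window)
            cond.to_csv(f"{out}/conditional.tsv", sep="\t", index=False)
            manifest.record("condition", assoc_hash, [f"{out}/conditional.tsv"],
                            n_independent=int(cond["independent"].sum()))

    # ---- report --------------------------------------------------------
    rep_inputs = [f"{out}/proteome.tsv", f"{out}/rna.tsv"]
    rep_hash = _hash_obj({"files": _hash_files(rep_inputs)})
    rep_outputs = [f"{out}/protein_rna_correlation.tsv"]
    if not manifest.stage_current("report", rep_hash, rep_outputs):
        proteome = pio.read_matrix(f"{out}/proteome.tsv")
        rna = pio.read_matrix(f"{out}/rna.tsv")
        corr = correlate_matrices(np.log2(proteome), np.log2(rna))
        corr.to_csv(f"{out}/protein_rna_correlation.tsv", sep="\t", index=False)
        manifest.record("report", rep_hash, rep_outputs, n_rows=int(len(corr)))

    return manifest.data
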