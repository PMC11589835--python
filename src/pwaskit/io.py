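"""Readers and writers for the pipeline's plain-text formats.

Formats:

* dosage TSV — first column ``sample_id``, one column per variant id,
  dosages in [0, 2], empty/NA for missing calls;
* variant metadata TSV — variant_id, chrom, pos, other_allele,
  effect_allele, freq, imp_r2, locus;
* PLINK-style ``.bim``/``.fam`` companions for interoperability;
* expression matrix TSV — rows proteins/genes, columns samples, "NA" missing;
* GWAS summary TSV — variant_id, chrom, pos, effect_allele, other_allele,
  beta, se, freq, n;
* model DB — PredictDB-like pair ``weights.tsv`` + ``extra.tsv``.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .sim import GWAS_COLUMNS, GenotypePanel, TruthSet

__all__ = [
    "write_panel", "read_panel",
    "write_matrix", "read_matrix",
    "write_gwas", "read_gwas",
    "write_truth", "read_truth",
    "write_annotation", "read_annotation",
]


def write_panel(panel: GenotypePanel, prefix: str) -> None:
    """Write dosage TSV + variant TSV + .bim/.fam under a path prefix."""
    os.makedirs(os.path.dirname(prefix) or ".", exist_ok=True)
    dos = pd.DataFrame(panel.dosages, columns=panel.variant_ids)
    dos.insert(0, "sample_id", panel.sample_ids)
    dos.to_csv(prefix + ".dosage.tsv", sep="\t", index=False, na_rep="NA")
    panel.variants.to_csv(prefix + ".variants.tsv", sep="\t")
    bim = pd.DataFrame({
        "chrom": panel.variants["chrom"],
        "variant_id": panel.variants.index,
        "cm": 0,
        "pos": panel.variants["pos"],
        "a1": panel.variants["effect_allele"],
        "a2": panel.variants["other_allele"],
    })
    bim.to_csv(prefix + ".bim", sep="\t", index=False, header=False)
    fam = pd.DataFrame({
        "fid": panel.sample_ids, "iid": panel.sample_ids,
        "pat": 0, "mat": 0, "sex": 2, "pheno": -9,
    })
    fam.to_csv(prefix + ".fam", sep="\t", index=False, header=False)


def read_panel(prefix: str) -> GenotypePanel:
    dos = pd.read_csv(prefix + ".dosage.tsv", sep="\t", na_values="NA")
    variants = pd.read_csv(
        prefix + ".variants.tsv", sep="\t", index_col="variant_id",
        dtype={"chrom": str},
    )
    sample_ids = dos["sample_id"].astype(str).tolist()
    dosages = dos.drop(columns="sample_id").to_numpy(dtype=float)
    return GenotypePanel(sample_ids=sample_ids, variants=variants, dosages=dosages)


def write_matrix(matrix: pd.DataFrame, path: str, index_label: str = "protein_id") -> None:
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    matrix.to_csv(path, sep="\t", na_rep="NA", index_label=index_label)


def read_matrix(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values="NA")


def write_gwas(gwas: pd.DataFrame, path: str) -> None:
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    gwas[GWAS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gwas(path: str) -> pd.DataFrame:
    gwas = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(GWAS_COLUMNS) - set(gwas.columns)
    if missing:
        raise ValueError(f"GWAS file {path} lacks columns: {sorted(missing)}")
    if (gwas["se"] <= 0).any():
        bad = gwas.loc[gwas["se"] <= 0, "variant_id"].tolist()
        raise ValueError(f"non-positive se for variants: {bad[:5]}")
    return gwas


def write_truth(truth: TruthSet, prefix: str) -> None:
    os.makedirs(os.path.dirname(prefix) or ".", exist_ok=True)
    truth.weights.to_csv(prefix + ".weights.tsv", sep="\t", index=False)
    truth.gamma.rename("gamma").to_csv(prefix + ".gamma.tsv", sep="\t")
    truth.loadings.to_csv(prefix + ".loadings.tsv", sep="\t")
    truth.factor_scores.to_csv(prefix + ".factors.tsv", sep="\t")
    truth.baselines.rename("baseline").to_csv(prefix + ".baselines.tsv", sep="\t")


def read_truth(prefix: str) -> TruthSet:
    return TruthSet(
        weights=pd.read_csv(prefix + ".weights.tsv", sep="\t"),
        gamma=pd.read_csv(prefix + ".gamma.tsv", sep="\t", index_col=0)["gamma"],
        loadings=pd.read_csv(prefix + ".loadings.tsv", sep="\t", index_col=0),
        factor_scores=pd.read_csv(prefix + ".factors.tsv", sep="\t", index_col=0),
        baselines=pd.read_csv(prefix + ".baselines.tsv", sep="\t", index_col=0)["baseline"],
    )


def write_annotation(annotation: pd.DataFrame, path: str) -> None:
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    annotation.to_csv(path, sep="\t", index=False)


def read_annotation(path: str) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if (ann["start"] > ann["end"]).any():
        raise ValueError(f"annotation with start > end in {path}")
    return ann
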