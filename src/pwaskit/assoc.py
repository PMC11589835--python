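"""Summary-statistics protein–trait association (S-PrediXcan-style).

The association statistic for protein p with model weights ``w_sp`` is

    Z_p = sum_{s in Model_p} w_sp * (sigma_s / sigma_p) * (beta_s / se_s)

where ``sigma_s`` is the dosage SD of variant s in a reference panel,
``sigma_p = sqrt(w' Gamma w)`` the SD of the model-predicted expression
(Gamma the reference dosage covariance restricted to the model's
variants), and ``beta_s / se_s`` the marginal GWAS Z score. Two-sided
normal p-values are corrected per phenotype by Benjamini-Hochberg FDR.

The statsmodels-style entry point is :class:`PWAS` (model object built
from a ModelDB, one or more harmonized GWAS summary tables, an LD
reference and optionally known risk variants) whose :meth:`PWAS.fit`
returns :class:`PWASResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .cismodels import ModelDB, ProteinModel
from .sim import GenotypePanel

__all__ = [
    "LDReference", "predicted_expression_sd", "spredixcan_z",
    "z_to_p", "bh_fdr", "annotate_novelty", "run_phenotypes",
    "PWAS", "PWASResults",
]

PHENOTYPES = [
    "overall", "luminal A", "luminal B", "luminal B/HER2-negative",
    "HER2-enriched", "triple-negative", "ER-positive", "ER-negative",
]


class LDReference:
    """Reference-panel dosage SDs and within-model covariance/correlation.

    Covariance uses the unbiased (n − 1) denominator and is computed only
    within the variant sets actually requested (model-restricted), never
    genome-wide.
    """

    def __init__(self, panel: GenotypePanel):
        self.panel = panel
        self._sigma = panel.dosage_sd(ddof=1)

    @property
    def variant_ids(self) -> pd.Index:
        return self.panel.variant_ids

    def sigma(self, ids) -> pd.Series:
        s = self._sigma.loc[list(ids)]
        return s

    def cov(self, ids) -> pd.DataFrame:
        ids = list(ids)
        cols = self.panel.variants.index.get_indexer(ids)
        if (cols < 0).any():
            missing = [i for i, c in zip(ids, cols) if c < 0]
            raise KeyError(f"variants absent from LD reference: {missing[:5]}")
        x = self.panel.dosages[:, cols]
        g = np.cov(x, rowvar=False, ddof=1)
        g = np.atleast_2d(g)
        return pd.DataFrame(g, index=ids, columns=ids)

    def corr(self, ids) -> pd.DataFrame:
        g = self.cov(ids)
        d = np.sqrt(np.diag(g.to_numpy()))
        d[d == 0] = 1.0
        r = g.to_numpy() / np.outer(d, d)
        np.fill_diagonal(r, 1.0)
        return pd.DataFrame(r, index=g.index, columns=g.columns)


def predicted_expression_sd(model: ProteinModel, ld: LDReference) -> float:
    """SD of the model-predicted expression in the reference panel:
    sqrt(w' Gamma w) over the model's variants."""
    gamma = ld.cov(model.variant_ids)
    w = model.weights.to_numpy()
    var = float(w @ gamma.to_numpy() @ w)
    return float(np.sqrt(max(var, 0.0)))


def z_to_p(z: float) -> float:
    """Two-sided standard normal tail probability."""
    if not np.isfinite(z):
        raise ValueError(f"non-finite Z: {z}")
    return float(2.0 * norm.sf(abs(z)))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spredixcan_z(
    model: ProteinModel,
    gwas: pd.DataFrame,
    ld: LDReference,
) -> dict:
    """Evaluate the summary-statistic Z for one protein model.

    ``gwas`` must already be harmonized to the model's effect alleles.
    Model variants missing from the GWAS are dropped without weight
    renormalization (drop count reported). Returns a dict with keys
    ``z, p, n_used, n_dropped, status``; status is "ok", "untestable"
    (no model variant present) or "degenerate" (sigma_p = 0).
    """
    g = gwas.set_index("variant_id") if "variant_id" in gwas.columns else gwas
    present = model.variant_ids.intersection(g.index)
    n_dropped = len(model.variant_ids) - len(present)
    if len(present) == 0:
        return {"z": np.nan, "p": np.nan, "n_used": 0,
                "n_dropped": n_dropped, "status": "untestable"}
    sub = ProteinModel(
        protein_id=model.protein_id,
        weights=model.weights.loc[present],
        effect_alleles=model.effect_alleles.loc[present],
        r=model.r, p=model.p,
        n_snps_window=model.n_snps_window, lam=model.lam,
    )
    sigma_p = predicted_expression_sd(sub, ld)
    if sigma_p <= 0:
        return {"z": np.nan, "p": np.nan, "n_used": len(present),
                "n_dropped": n_dropped, "status": "degenerate"}
    sigma_s = ld.sigma(present).to_numpy()
    marg_z = (g.loc[present, "beta"] / g.loc[present, "se"]).to_numpy(dtype=float)
    w = sub.weights.to_numpy()
    z = float(np.sum(w * (sigma_s / sigma_p) * marg_z))
    return {"z": z, "p": z_to_p(z), "n_used": int(len(present)),
            "n_dropped": int(n_dropped), "status": "ok"}


def annotate_novelty(
    gene: pd.Series,
    known: pd.DataFrame,
    window: int = 1_000_000,
) -> tuple[bool, str | None, float]:
    """Distance of a gene to the nearest known risk variant.

    Distance is 0 if a variant lies inside the gene body, else the distance
    to the nearer gene boundary; variants on other chromosomes are
    infinitely far. The gene is flagged novel iff every known variant is at
    least ``window`` bp away. Returns (novel, nearest_variant_id,
    distance_bp).
    """
    if known is None or len(known) == 0:
        return True, None, float("inf")
    same = known[known["chrom"].astype(str) == str(gene["chrom"])]
    if len(same) == 0:
        return True, None, float("inf")
    start, end = int(gene["start"]), int(gene["end"])
    pos = same["pos"].to_numpy(dtype=float)
    dist = np.where(
        (pos >= start) & (pos <= end), 0.0,
        np.minimum(np.abs(pos - start), np.abs(pos - end)),
    )
    i = int(np.argmin(dist))
    nearest = same.iloc[i]["variant_id"]
    d = float(dist[i])
    return d >= window, nearest, d


def run_phenotypes(
    model_db: ModelDB,
    gwas_map: dict[str, pd.DataFrame],
    ld: LDReference,
    known: pd.DataFrame | None = None,
    annotation: pd.DataFrame | None = None,
    novelty_window: int = 1_000_000,
) -> pd.DataFrame:
    """Full cross of retained models × phenotypes with per-phenotype FDR.

    Output is ordered deterministically: phenotype, then p ascending, ties
    broken by protein_id.
    """
    ann = annotation.set_index("protein_id") if annotation is not None else None
    frames = []
    for pheno in gwas_map:
        gwas = gwas_map[pheno]
        g = gwas.set_index("variant_id")
        rows = []
        for pid in model_db.protein_ids:
            model = model_db.get(pid)
            res = spredixcan_z(model, g, ld)
            region = None
            novel, nearest, dist = (False, None, np.nan)
            if ann is not None and pid in ann.index:
                gene = ann.loc[pid]
                region = f"{gene['chrom']}:{gene['start']}-{gene['end']}"
                novel, nearest, dist = annotate_novelty(gene, known, novelty_window)
            rows.append({
                "phenotype": pheno, "protein_id": pid, "region": region,
                "z": res["z"], "p": res["p"],
                "n_snps_used": res["n_used"], "n_snps_dropped": res["n_dropped"],
                "status": res["status"],
                "novel_locus": bool(novel),
                "nearest_variant": nearest,
                "distance_kb": dist / 1_000 if np.isfinite(dist) else np.inf,
            })
        tab = pd.DataFrame(rows)
        if tab.empty:
            continue
        testable = tab["status"] == "ok"
        tab["q"] = np.nan
        if testable.any():
            tab.loc[testable, "q"] = bh_fdr(tab.loc[testable, "p"])
        frames.append(tab)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["phenotype", "protein_id", "region", "z", "p", "q",
                 "n_snps_used", "n_snps_dropped", "status", "novel_locus",
                 "nearest_variant", "distance_kb"])
    out = out.sort_values(
        ["phenotype", "p", "protein_id"], kind="mergesort", na_position="last"
    ).reset_index(drop=True)
    return out


@dataclass
class PWAS:
    """Proteome-wide association model.

    Parameters
    ----------
    model_db : ModelDB
        Gated cis prediction models (per-allele weights).
    gwas : DataFrame or mapping of phenotype -> DataFrame
        Harmonized GWAS summary statistics. A bare DataFrame is treated as
        the single phenotype "overall".
    ld_reference : LDReference or GenotypePanel
        Source of dosage SDs and within-model LD.
    known_variants : DataFrame, optional
        Known risk variants (variant_id, chrom, pos) for novelty annotation
        and conditional analysis.
    annotation : DataFrame, optional
        Gene annotation used for regions and novelty distances.
    """

    model_db: ModelDB
    gwas: object
    ld_reference: object
    known_variants: pd.DataFrame | None = None
    annotation: pd.DataFrame | None = None
    fdr_threshold: float = 0.1
    novelty_window: int = 1_000_000

    def __post_init__(self) -> None:
        if isinstance(self.ld_reference, GenotypePanel):
            self.ld_reference = LDReference(self.ld_reference)
        if isinstance(self.gwas, pd.DataFrame):
            self.gwas = {"overall": self.gwas}

    def fit(self) -> "PWASResults":
        table = run_phenotypes(
            self.model_db, self.gwas, self.ld_reference,
            known=self.known_variants, annotation=self.annotation,
            novelty_window=self.novelty_window,
        )
        return PWASResults(model=self, table=table)


@dataclass
class PWASResults:
    """Association results: per protein × phenotype Z, p, FDR q, novelty."""

    model: PWAS
    table: pd.DataFrame

    def significant(self, fdr: float | None = None) -> pd.DataFrame:
        fdr = self.model.fdr_threshold if fdr is None else fdr
        return self.table[(self.table["status"] == "ok") & (self.table["q"] < fdr)]

    def conditional(self, threshold: float = 1e-4,
                    window: int = 1_000_000) -> pd.DataFrame:
        """Re-test significant loci after conditioning on known risk variants."""
        from .conditional import conditional_assoc, conditional_sumstats
        if self.model.known_variants is None or len(self.model.known_variants) == 0:
            raise ValueError("conditional analysis needs known risk variants")
        frames = []
        for pheno, gwas in self.model.gwas.items():
            cond = conditional_sumstats(
                gwas, self.model.ld_reference, self.model.known_variants,
                window=window,
            )
            tab = conditional_assoc(
                self.model.model_db, gwas, cond, self.model.ld_reference,
                threshold=threshold,
            )
            tab.insert(0, "phenotype", pheno)
            frames.append(tab)
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        lines = ["PWAS results", "============"]
        n_models = len(self.model.model_db)
        lines.append(f"models tested: {n_models} across "
                     f"{len(self.model.gwas)} phenotype(s)")
        sig = self.significant()
        lines.append(f"significant at FDR < {self.model.fdr_threshold:g}: {len(sig)}")
        if len(sig):
            view = sig[["phenotype", "protein_id", "z", "p", "q", "novel_locus"]]
            with pd.option_context("display.float_format", "{:.3g}".format):
                lines.append(view.to_string(index=False))
        return "\n".join(lines)
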