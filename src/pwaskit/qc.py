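"""Genotype quality control and GWAS allele harmonization.

Variant filters follow the conventional imputed-array recipe: call rate,
allele-frequency consistency against an external reference, Hardy-Weinberg
equilibrium, minor-allele frequency, and imputation quality. Boundary
conventions: variants are kept with MAF strictly > ``maf_min`` and
imputation R² >= ``imp_r2_min``. The filter order is fixed (call rate →
frequency consistency → HWE → MAF → imputation R²) so removal counts are
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .sim import GenotypePanel

__all__ = [
    "QCThresholds", "QCReport",
    "hwe_chi2_test", "filter_variants", "filter_samples", "harmonize_alleles",
]

_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass(frozen=True)
class QCThresholds:
    variant_call_rate_min: float = 0.95
    sample_call_rate_min: float = 0.95
    maf_min: float = 0.05
    hwe_p_min: float = 1e-6
    imp_r2_min: float = 0.8
    af_dev_sd: float = 4.0

    def validate(self) -> None:
        for name in ("variant_call_rate_min", "sample_call_rate_min",
                     "maf_min", "hwe_p_min", "imp_r2_min"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.af_dev_sd <= 0:
            raise ValueError("af_dev_sd must be > 0")


@dataclass
class QCReport:
    """Per-stage removal bookkeeping; counts reconcile with panel deltas."""

    stages: list[tuple[str, list[str]]] = field(default_factory=list)
    flips: list[str] = field(default_factory=list)
    drops: list[tuple[str, str]] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def add_stage(self, name: str, removed) -> None:
        self.stages.append((name, list(removed)))

    def n_removed(self, stage: str | None = None) -> int:
        if stage is None:
            return sum(len(ids) for _, ids in self.stages)
        return sum(len(ids) for nm, ids in self.stages if nm == stage)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(nm, len(ids)) for nm, ids in self.stages],
            columns=["stage", "n_removed"],
        )


def hwe_chi2_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """1-df chi-square goodness-of-fit p against Hardy-Weinberg proportions.

    Monomorphic variants return p = 1 by convention.
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    p_alt = (2 * n_hom_alt + n_het) / (2 * n)
    if p_alt in (0.0, 1.0):
        return 1.0
    q = 1.0 - p_alt
    expected = np.array([q * q, 2 * p_alt * q, p_alt * p_alt]) * n
    observed = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    stat = ((observed - expected) ** 2 / expected).sum()
    return float(chi2.sf(stat, df=1))


def _hard_calls(dosages: np.ndarray) -> np.ndarray:
    return np.where(np.isnan(dosages), np.nan, np.round(dosages))


def filter_variants(
    panel: GenotypePanel,
    thresholds: QCThresholds = QCThresholds(),
    ref_freq: pd.Series | None = None,
    ref_n: int = 503,
) -> tuple[GenotypePanel, QCReport]:
    """Apply the variant-level filter chain.

    ``ref_freq`` supplies external reference effect-allele frequencies for
    the consistency filter (|panel freq − ref freq| ≤ af_dev_sd × binomial
    SE at the reference frequency with 2·ref_n alleles); variants without a
    reference entry, or when ``ref_freq`` is None, skip that filter.
    """
    thresholds.validate()
    if panel.n_variants == 0:
        raise ValueError("empty genotype panel")
    report = QCReport()
    keep = panel.variants.index

    def _drop(stage: str, bad_ids) -> None:
        nonlocal keep
        report.add_stage(stage, bad_ids)
        keep = keep.difference(bad_ids, sort=False)

    hard = _hard_calls(panel.dosages)

    # 1. call rate
    call_rate = pd.Series(
        1.0 - np.isnan(hard).mean(axis=0), index=panel.variants.index
    )
    _drop("call_rate", call_rate.index[call_rate < thresholds.variant_call_rate_min])

    # 2. allele-frequency consistency vs reference
    if ref_freq is not None:
        freq = panel.empirical_freq()
        common = keep.intersection(ref_freq.index)
        f0 = ref_freq.loc[common].astype(float)
        se = np.sqrt(f0 * (1 - f0) / (2 * ref_n)).clip(lower=1e-12)
        dev = (freq.loc[common] - f0).abs() / se
        _drop("freq_consistency", common[dev > thresholds.af_dev_sd])
    else:
        report.add_stage("freq_consistency", [])

    # 3. Hardy-Weinberg
    bad_hwe = []
    for vid in keep:
        col = hard[:, panel.variants.index.get_loc(vid)]
        col = col[~np.isnan(col)]
        p = hwe_chi2_test(
            int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
        )
        if p < thresholds.hwe_p_min:
            bad_hwe.append(vid)
    _drop("hwe", bad_hwe)

    # 4. MAF (strict >)
    freq = panel.empirical_freq().loc[keep]
    maf = np.minimum(freq, 1.0 - freq)
    _drop("maf", keep[~(maf > thresholds.maf_min)])

    # 5. imputation quality (>=)
    r2 = panel.variants.loc[keep, "imp_r2"]
    _drop("imp_r2", keep[r2 < thresholds.imp_r2_min])

    if len(keep) == 0:
        raise ValueError("all variants removed by QC filters")
    out = panel.subset_variants(keep)
    return out, report


def filter_samples(
    panel: GenotypePanel,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[GenotypePanel, QCReport]:
    """Remove samples whose hard-call missing fraction exceeds the limit."""
    thresholds.validate()
    report = QCReport()
    miss = np.isnan(panel.dosages).mean(axis=1)
    keep = [s for s, m in zip(panel.sample_ids, miss)
            if 1.0 - m >= thresholds.sample_call_rate_min]
    removed = [s for s in panel.sample_ids if s not in set(keep)]
    report.add_stage("sample_call_rate", removed)
    return panel.subset_samples(keep), report


def harmonize_alleles(
    panel: GenotypePanel,
    gwas: pd.DataFrame,
    ambiguous_maf_max: float = 0.40,
) -> tuple[GenotypePanel, pd.DataFrame, QCReport]:
    """Intersect panel and GWAS variants and align effect alleles.

    Where the panel's effect allele equals the GWAS *other* allele the GWAS
    beta sign and frequency are flipped (logged). Variants with incompatible
    allele pairs, or strand-ambiguous pairs (A/T, C/G) with MAF >
    ``ambiguous_maf_max``, are dropped.
    """
    report = QCReport()
    g = gwas.copy()
    if g["variant_id"].duplicated().any():
        dups = g.loc[g["variant_id"].duplicated(), "variant_id"].tolist()
        raise ValueError(f"duplicate GWAS variant ids: {dups[:5]}")
    shared = panel.variants.index.intersection(g["variant_id"])
    if len(shared) == 0:
        # fall back to chrom:pos keying
        panel_key = panel.variants["chrom"].astype(str) + ":" + panel.variants["pos"].astype(str)
        gwas_key = g["chrom"].astype(str) + ":" + g["pos"].astype(str)
        if gwas_key.duplicated().any():
            dups = gwas_key[gwas_key.duplicated()].tolist()
            raise ValueError(f"duplicate GWAS position keys: {dups[:5]}")
        remap = pd.Series(panel.variants.index, index=panel_key.to_numpy())
        g["variant_id"] = gwas_key.map(remap)
        g = g.dropna(subset=["variant_id"])
        shared = panel.variants.index.intersection(g["variant_id"])
    g = g.set_index("variant_id").loc[shared].reset_index()

    pv = panel.variants.loc[shared]
    ea_p = pv["effect_allele"].to_numpy()
    oa_p = pv["other_allele"].to_numpy()
    ea_g = g["effect_allele"].to_numpy()
    oa_g = g["other_allele"].to_numpy()

    aligned = (ea_g == ea_p) & (oa_g == oa_p)
    swapped = (ea_g == oa_p) & (oa_g == ea_p)
    keep_mask = aligned | swapped

    for vid, pair_ok in zip(shared, keep_mask):
        if not pair_ok:
            report.drops.append((vid, "incompatible_alleles"))

    # strand-ambiguous pairs: unreliable to orient once MAF approaches 0.5
    amb = np.array([(a, b) in _AMBIGUOUS for a, b in zip(ea_p, oa_p)])
    freq = g["freq"].to_numpy(dtype=float)
    maf = np.minimum(freq, 1 - freq)
    amb_drop = amb & (maf > ambiguous_maf_max)
    for vid in shared[amb_drop & keep_mask]:
        report.drops.append((vid, "strand_ambiguous"))
    keep_mask = keep_mask & ~amb_drop

    g.loc[swapped, "beta"] = -g.loc[swapped, "beta"]
    g.loc[swapped, "freq"] = 1.0 - g.loc[swapped, "freq"]
    g.loc[swapped, "effect_allele"] = ea_p[swapped]
    g.loc[swapped, "other_allele"] = oa_p[swapped]
    report.flips.extend(shared[swapped & keep_mask].tolist())

    kept_ids = shared[keep_mask]
    report.add_stage("harmonize", shared.difference(kept_ids, sort=False))
    out_panel = panel.subset_variants(kept_ids)
    out_gwas = g.set_index("variant_id").loc[kept_ids].reset_index()
    return out_panel, out_gwas, report
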