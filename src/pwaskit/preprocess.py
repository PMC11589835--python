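"""Proteome normalization chain: detection filter → log2 → quantile
normalization → rank-based inverse-normal transform → covariate
residualization.

Covariates are age, the top genotype principal components, and
principal-component hidden factors standing in for latent technical
structure. Missing intensities are never filled silently: median imputation
happens only inside factor estimation and residualization, and every
imputed cell is counted in the returned log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .sim import GenotypePanel

__all__ = [
    "detection_filter", "log2_transform", "quantile_normalize",
    "inverse_normal_transform", "genotype_pcs", "estimate_hidden_factors",
    "residualize", "preprocess_chain", "sweep_hidden_factors",
]


def detection_filter(
    matrix: pd.DataFrame,
    min_fraction: float = 0.8,
    annotation: pd.DataFrame | None = None,
    autosomes_only: bool = False,
) -> pd.DataFrame:
    """Keep proteins detected (non-missing) in at least ``min_fraction`` of samples.

    With ``autosomes_only`` and an annotation, proteins whose gene sits on a
    non-autosomal chromosome are dropped as well.
    """
    if not (0.0 < min_fraction <= 1.0):
        raise ValueError(f"min_fraction must lie in (0, 1], got {min_fraction}")
    detected = matrix.notna().mean(axis=1)
    out = matrix.loc[detected >= min_fraction]
    if autosomes_only and annotation is not None:
        autosomal = set(str(c) for c in map(str, range(1, 23)))
        chrom = annotation.set_index("protein_id")["chrom"].astype(str)
        keep = [p for p in out.index
                if chrom.get(p, "1") in autosomal]
        out = out.loc[keep]
    return out


def log2_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    bad = (matrix <= 0).any(axis=1)
    if bad.any():
        prot = matrix.index[bad][0]
        sample = matrix.columns[(matrix.loc[prot] <= 0).to_numpy().nonzero()[0][0]]
        raise ValueError(f"non-positive intensity at protein {prot!r}, sample {sample!r}")
    return np.log2(matrix)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Across-sample quantile normalization (columns = samples).

    Present values in each sample are replaced by the mean across samples of
    the order statistics at the matching quantile; with unequal numbers of
    present values per sample, each sample's quantile function is linearly
    interpolated onto a common probability grid before averaging. Ties get
    the average of their target values. Afterwards every complete sample
    shares one sorted value vector.
    """
    values = matrix.to_numpy(dtype=float)
    n_present = (~np.isnan(values)).sum(axis=0)
    if (n_present < 2).any():
        bad = matrix.columns[n_present < 2].tolist()
        raise ValueError(f"samples with < 2 present values: {bad[:5]}")
    m_ref = int(n_present.max())
    grid = (np.arange(m_ref) + 0.5) / m_ref
    # average quantile function across samples
    ref = np.zeros(m_ref)
    for j in range(values.shape[1]):
        col = np.sort(values[~np.isnan(values[:, j]), j])
        probs = (np.arange(len(col)) + 0.5) / len(col)
        ref += np.interp(grid, probs, col)
    ref /= values.shape[1]

    out = values.copy()
    for j in range(values.shape[1]):
        present = ~np.isnan(values[:, j])
        col = values[present, j]
        m = len(col)
        ranks = rankdata(col, method="average")          # 1..m, ties averaged
        probs = (ranks - 0.5) / m
        out[present, j] = np.interp(probs, grid, ref)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def inverse_normal_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-protein rankit transform: value → Φ⁻¹((rank − 0.5)/n_present)."""
    values = matrix.to_numpy(dtype=float)
    out = np.full_like(values, np.nan)
    for i in range(values.shape[0]):
        present = ~np.isnan(values[i])
        x = values[i, present]
        if len(x) == 0:
            continue
        if np.ptp(x) == 0:
            out[i, present] = 0.0
            continue
        ranks = rankdata(x, method="average")
        out[i, present] = norm.ppf((ranks - 0.5) / len(x))
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def genotype_pcs(panel: GenotypePanel, k: int = 3) -> pd.DataFrame:
    """Top-k principal-component scores of the standardized dosage matrix.

    Sign convention: within each component, the loading with the largest
    magnitude is positive.
    """
    if k >= panel.n_samples:
        raise ValueError(f"k={k} must be < number of samples {panel.n_samples}")
    if k == 0:
        return pd.DataFrame(index=pd.Index(panel.sample_ids, name="sample_id"))
    x = np.nan_to_num(panel.dosages, nan=np.nanmean(panel.dosages))
    x = x - x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    x = x / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :k] * s[:k]
    for j in range(k):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            scores[:, j] = -scores[:, j]
    return pd.DataFrame(
        scores, index=pd.Index(panel.sample_ids, name="sample_id"),
        columns=[f"PC{j + 1}" for j in range(k)],
    )


def _median_impute(matrix: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    med = matrix.median(axis=1)
    n_imputed = int(matrix.isna().to_numpy().sum())
    return matrix.T.fillna(med).T, n_imputed


def estimate_hidden_factors(matrix: pd.DataFrame, k: int = 15) -> pd.DataFrame:
    """Principal-component hidden factors of a normalized proteome.

    Proteins are median-imputed and standardized; the returned sample × k
    score matrix serves as latent technical/biological covariates.
    """
    if k >= min(matrix.shape):
        raise ValueError(f"k={k} must be < min(matrix dims) {min(matrix.shape)}")
    if k == 0:
        return pd.DataFrame(index=pd.Index(matrix.columns, name="sample_id"))
    imputed, _ = _median_impute(matrix)
    x = imputed.to_numpy(dtype=float).T       # samples × proteins
    x = x - x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    x = x / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :k] * s[:k]
    for j in range(k):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            scores[:, j] = -scores[:, j]
    return pd.DataFrame(
        scores, index=pd.Index(matrix.columns, name="sample_id"),
        columns=[f"F{j + 1}" for j in range(k)],
    )


@dataclass
class ResidualizeLog:
    n_imputed: int = 0
    notes: list[str] = field(default_factory=list)


def residualize(
    matrix: pd.DataFrame,
    covariates: pd.DataFrame,
) -> tuple[pd.DataFrame, ResidualizeLog]:
    """Per-protein OLS residuals on intercept + covariates.

    Missing entries are protein-median imputed before regression (counted in
    the log); covariates must be complete and full rank.
    """
    if covariates.isna().any().any():
        bad = covariates.columns[covariates.isna().any()].tolist()
        raise ValueError(f"covariates contain missing values: {bad}")
    cov = covariates.loc[matrix.columns]
    design = np.column_stack([np.ones(len(cov)), cov.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify a collinear column by leave-one-out rank
        names = ["intercept"] + list(cov.columns)
        collinear = [
            names[j] for j in range(design.shape[1])
            if np.linalg.matrix_rank(np.delete(design, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient covariates; collinear columns: {collinear}")
    imputed, n_imputed = _median_impute(matrix)
    y = imputed.to_numpy(dtype=float).T       # samples × proteins
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    log = ResidualizeLog(n_imputed=n_imputed)
    if n_imputed:
        log.notes.append(f"median-imputed {n_imputed} missing entries before OLS")
    return (
        pd.DataFrame(resid.T, index=matrix.index, columns=matrix.columns),
        log,
    )


def preprocess_chain(
    proteome: pd.DataFrame,
    panel: GenotypePanel,
    age: pd.Series,
    k_pcs: int = 3,
    k_hidden: int = 15,
    min_fraction: float = 0.8,
    annotation: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, ResidualizeLog]:
    """Full chain: detect → log2 → quantile → inverse-normal → residualize.

    Returns (residual matrix, covariate table, log).
    """
    filtered = detection_filter(proteome, min_fraction, annotation=annotation)
    normed = inverse_normal_transform(quantile_normalize(log2_transform(filtered)))
    pcs = genotype_pcs(panel, k=k_pcs)
    k_eff = min(k_hidden, min(normed.shape) - 1)
    factors = estimate_hidden_factors(normed, k=k_eff)
    covars = pd.concat(
        [age.loc[normed.columns].rename("age"), pcs.loc[normed.columns],
         factors.loc[normed.columns]],
        axis=1,
    )
    residuals, log = residualize(normed, covars)
    return residuals, covars, log


def sweep_hidden_factors(
    normed: pd.DataFrame,
    base_covariates: pd.DataFrame,
    evaluate,
    ks=(5, 10, 15, 20, 25),
) -> pd.DataFrame:
    """Evaluate a downstream metric as a function of the hidden-factor count.

    ``evaluate(residual_matrix) -> float`` is typically the number of
    prediction models passing the performance gate; the returned table
    mirrors the factor-count selection curve used when choosing k.
    """
    rows = []
    for k in ks:
        if k >= min(normed.shape):
            continue
        factors = estimate_hidden_factors(normed, k=k)
        covars = pd.concat([base_covariates, factors.loc[base_covariates.index]], axis=1)
        residuals, _ = residualize(normed, covars)
        rows.append({"k_hidden": k, "metric": float(evaluate(residuals))})
    return pd.DataFrame(rows)
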