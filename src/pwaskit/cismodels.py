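"""Per-protein cis elastic-net prediction models.

For every protein, variants within ±500 kb of the encoding gene body are
candidate predictors. An elastic net (L1/L2 mixing 0.5, penalty chosen by
internal 5-fold cross-validated MSE, minimum rule) is trained on the
covariate-adjusted residuals; prediction performance is the Pearson
correlation R between observed residuals and pooled out-of-fold
predictions from an outer 5-fold split, with the usual t-test p-value.
Models pass the gate only with R > 0.1 and p < 0.05 (both strict); gated
models are refit on all samples and stored with per-allele weights.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold
import warnings

from .sim import GenotypePanel

__all__ = [
    "CisWindow", "ProteinModel", "ModelDB",
    "select_cis_snps", "fit_elastic_net", "cross_validated_performance",
    "build_models",
]

CIS_WINDOW = 500_000


@dataclass(frozen=True)
class CisWindow:
    chrom: str
    lo: int
    hi: int

    @classmethod
    def around(cls, gene: pd.Series, flank: int = CIS_WINDOW) -> "CisWindow":
        return cls(
            chrom=str(gene["chrom"]),
            lo=max(int(gene["start"]) - flank, 1),
            hi=int(gene["end"]) + flank,
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return str(chrom) == self.chrom and self.lo <= pos <= self.hi


@dataclass
class ProteinModel:
    """Nonzero per-allele cis weights plus training performance."""

    protein_id: str
    weights: pd.Series            # index variant_id, per-allele scale
    effect_alleles: pd.Series     # index variant_id
    r: float
    p: float
    n_snps_window: int
    lam: float

    def __post_init__(self) -> None:
        if (self.weights == 0).any():
            self.effect_alleles = self.effect_alleles[self.weights != 0]
            self.weights = self.weights[self.weights != 0]

    @property
    def variant_ids(self) -> pd.Index:
        return self.weights.index


@dataclass
class ModelDB:
    """Collection of gated protein models with build provenance.

    ``stats`` records every attempted protein (passed or not) with the gate
    outcome and reason; ``models`` holds only the retained ones.
    """

    models: dict[str, ProteinModel]
    stats: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models.values())

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.models

    def get(self, protein_id: str) -> ProteinModel:
        return self.models[protein_id]

    @property
    def protein_ids(self) -> list[str]:
        return sorted(self.models)

    def retained_fraction(self) -> float:
        if len(self.stats) == 0:
            return float("nan")
        return float(self.stats["passed"].mean())

    def to_tsv(self, directory: str) -> None:
        import os
        os.makedirs(directory, exist_ok=True)
        rows = [
            {"protein_id": m.protein_id, "variant_id": vid,
             "effect_allele": m.effect_alleles[vid], "weight": w}
            for m in self.models.values()
            for vid, w in m.weights.items()
        ]
        pd.DataFrame(rows, columns=["protein_id", "variant_id", "effect_allele", "weight"]) \
            .to_csv(f"{directory}/weights.tsv", sep="\t", index=False)
        self.stats.to_csv(f"{directory}/extra.tsv", sep="\t", index=False)

    @classmethod
    def from_tsv(cls, directory: str) -> "ModelDB":
        weights = pd.read_csv(f"{directory}/weights.tsv", sep="\t")
        stats_df = pd.read_csv(f"{directory}/extra.tsv", sep="\t")
        models = {}
        for pid, grp in weights.groupby("protein_id"):
            row = stats_df[stats_df["protein_id"] == pid].iloc[0]
            models[pid] = ProteinModel(
                protein_id=pid,
                weights=grp.set_index("variant_id")["weight"].rename(None),
                effect_alleles=grp.set_index("variant_id")["effect_allele"].rename(None),
                r=float(row["r"]), p=float(row["p"]),
                n_snps_window=int(row["n_snps_window"]),
                lam=float(row["lambda"]),
            )
        return cls(models=models, stats=stats_df)


def select_cis_snps(gene: pd.Series, panel: GenotypePanel,
                    flank: int = CIS_WINDOW) -> pd.Index:
    """Variant ids within the gene-body ± flank window (inclusive bounds)."""
    win = CisWindow.around(gene, flank)
    v = panel.variants
    mask = (v["chrom"].astype(str) == win.chrom) & (v["pos"] >= win.lo) & (v["pos"] <= win.hi)
    return v.index[mask]


def _lambda_grid(X: np.ndarray, y: np.ndarray, l1_ratio: float,
                 n_lambdas: int = 25, eps: float = 1e-2) -> np.ndarray:
    n = len(y)
    lam_max = np.max(np.abs(X.T @ (y - y.mean()))) / (n * max(l1_ratio, 1e-3))
    lam_max = max(lam_max, 1e-8)
    return np.geomspace(lam_max, lam_max * eps, n_lambdas)


def fit_elastic_net(
    X: np.ndarray,
    y: np.ndarray,
    l1_ratio: float = 0.5,
    lambdas: np.ndarray | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Elastic net on standardized predictors with CV-selected penalty.

    Minimizes ``(1/2n)||y - Xb||² + λ(l1_ratio ||b||₁ + (1−l1_ratio)/2 ||b||²)``;
    λ is chosen by ``n_folds``-fold cross-validated MSE (minimum rule).
    Returns (coefficients on the standardized scale, selected λ).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 10:
        raise ValueError(f"need n >= 10 samples, got {X.shape[0]}")
    if lambdas is None:
        lambdas = _lambda_grid(X, y, l1_ratio)
    lambdas = np.sort(np.atleast_1d(np.asarray(lambdas, dtype=float)))[::-1]
    cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        if len(lambdas) == 1:
            model = ElasticNet(alpha=lambdas[0], l1_ratio=l1_ratio,
                               max_iter=5000, tol=1e-6)
            model.fit(X, y)
            return model.coef_.copy(), float(lambdas[0])
        model = ElasticNetCV(l1_ratio=l1_ratio, alphas=lambdas, cv=cv,
                             max_iter=2000, tol=1e-4)
        model.fit(X, y)
    return model.coef_.copy(), float(model.alpha_)


def cross_validated_performance(
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
    l1_ratio: float = 0.5,
) -> tuple[float, float]:
    """Out-of-sample performance (R, p) via nested cross-validation.

    Samples are split into ``n_folds`` folds by a seeded shuffle; each
    held-out fold is predicted by an elastic net whose penalty is re-selected
    on the training folds. R is the Pearson correlation between observed y
    and the pooled out-of-fold predictions; p comes from the t-distribution
    with n − 2 df. A constant prediction vector yields (0, 1).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < n_folds:
        raise ValueError(f"need n >= {n_folds} samples, got {n}")
    preds = np.zeros(n)
    outer = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for train, test in outer.split(X):
            lambdas = _lambda_grid(X[train], y[train], l1_ratio)
            cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed + 1)
            model = ElasticNetCV(l1_ratio=l1_ratio, alphas=lambdas, cv=cv,
                                 max_iter=2000, tol=1e-4)
            model.fit(X[train], y[train])
            preds[test] = model.predict(X[test])
    if np.ptp(preds) == 0 or np.ptp(y) == 0:
        return 0.0, 1.0
    r = float(np.corrcoef(y, preds)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return r, p


def _standardize_columns(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    z = (x[:, keep] - mu[keep]) / sd[keep]
    return z, sd, keep


def build_models(
    residuals: pd.DataFrame,
    panel: GenotypePanel,
    annotation: pd.DataFrame,
    flank: int = CIS_WINDOW,
    l1_ratio: float = 0.5,
    r_min: float = 0.1,
    p_max: float = 0.05,
    n_folds: int = 5,
    seed: int = 0,
) -> ModelDB:
    """Train, gate, and collect cis models for every protein in ``residuals``.

    Gate: R > r_min and p < p_max, both strict. Gated models are refit on
    all samples and their standardized-scale weights are mapped back to the
    per-allele scale (divide by the training-panel dosage SD).
    """
    sample_cols = [s for s in residuals.columns if s in set(panel.sample_ids)]
    if len(sample_cols) != len(residuals.columns):
        raise ValueError("residual samples not all present in genotype panel")
    sub = panel.subset_samples(sample_cols)
    ann = annotation.set_index("protein_id")

    models: dict[str, ProteinModel] = {}
    rows = []
    for k, pid in enumerate(residuals.index):
        if pid not in ann.index:
            rows.append({"protein_id": pid, "r": np.nan, "p": np.nan,
                         "n_snps_window": 0, "n_snps_model": 0,
                         "lambda": np.nan, "passed": False,
                         "reason": "no_annotation"})
            continue
        gene = ann.loc[pid]
        cis = select_cis_snps(gene, sub, flank)
        if len(cis) == 0:
            rows.append({"protein_id": pid, "r": np.nan, "p": np.nan,
                         "n_snps_window": 0, "n_snps_model": 0,
                         "lambda": np.nan, "passed": False,
                         "reason": "no_cis_snps"})
            continue
        cols = sub.variants.index.get_indexer(cis)
        raw = sub.dosages[:, cols]
        z, sd, keep = _standardize_columns(raw)
        cis_kept = cis[keep]
        y = residuals.loc[pid, sample_cols].to_numpy(dtype=float)
        prot_seed = seed + (int(hashlib.sha1(pid.encode()).hexdigest(), 16) % 100_000)
        r, p = cross_validated_performance(z, y, n_folds=n_folds, seed=prot_seed,
                                           l1_ratio=l1_ratio)
        passed = (r > r_min) and (p < p_max)
        lam = np.nan
        n_model = 0
        if passed:
            coef, lam = fit_elastic_net(z, y, l1_ratio=l1_ratio,
                                        n_folds=n_folds, seed=prot_seed)
            nz = coef != 0
            n_model = int(nz.sum())
            if n_model == 0:
                passed = False
            else:
                per_allele = coef[nz] / sd[keep][nz]
                weights = pd.Series(per_allele, index=cis_kept[nz])
                models[pid] = ProteinModel(
                    protein_id=pid,
                    weights=weights,
                    effect_alleles=sub.variants.loc[weights.index, "effect_allele"],
                    r=r, p=p, n_snps_window=len(cis), lam=lam,
                )
        rows.append({
            "protein_id": pid, "r": r, "p": p,
            "n_snps_window": len(cis), "n_snps_model": n_model,
            "lambda": lam, "passed": passed,
            "reason": "ok" if passed else "gate_failed",
        })
    stats_df = pd.DataFrame(rows)
    fingerprint = hashlib.sha1(
        np.ascontiguousarray(sub.dosages).tobytes()
    ).hexdigest()[:12]
    return ModelDB(
        models=models, stats=stats_df,
        provenance={"seed": seed, "flank": flank, "l1_ratio": l1_ratio,
                    "r_min": r_min, "p_max": p_max,
                    "panel_fingerprint": fingerprint},
    )
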