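"""Synthetic genotype / proteome / GWAS generator with known ground truth.

Every downstream stage of the PWAS pipeline (QC, normalization, cis model
training, summary-statistic association, conditional analysis) can be
exercised on data produced here, with the causal structure recorded in a
:class:`TruthSet` so that recovery, calibration and oracle tests are
possible without any external download.

The population model is deliberately simple but captures the features the
pipeline is sensitive to:

* **Genotypes** — per locus, two latent haplotypes follow a first-order
  autoregressive Gaussian process across variants (adjacent correlation
  ``ld_rho``); thresholding each haplotype at the allele frequency gives
  hard genotypes in Hardy-Weinberg proportions.  Imputation uncertainty is
  emulated by shrinking the hard genotype toward its expectation ``2f`` and
  adding noise calibrated so that the squared correlation between dosage and
  hard genotype equals the variant's tagged imputation R².
* **Proteome** — latent log2 abundance per protein is a standardized cis
  genetic score (variance ``h2_cis``) plus a shared hidden-factor term
  (variance ``factor_share``) plus independent noise, exponentiated around a
  protein-specific baseline.  Missingness is intensity dependent (logistic
  in the latent abundance), emulating mass-spec detection limits.
* **GWAS summary statistics** — either computed from single-variant least
  squares on a simulated quantitative-liability cohort (``cohort`` mode) or
  drawn per locus from the standard multivariate-normal model of marginal Z
  scores given LD, ``Z ~ N(sqrt(n) * R @ lam, R)`` (``analytic`` mode).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "SimConfig",
    "GenotypePanel",
    "TruthSet",
    "simulate_genotypes",
    "simulate_annotation",
    "simulate_proteome",
    "simulate_gwas_sumstats",
    "simulate_liability",
    "marginal_sumstats",
    "inject_index_signal",
    "simulate_rna",
]

GWAS_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "se", "freq", "n",
]

_BASES = np.array(list("ACGT"))

# role → seed substream tag, so tissue/reference/GWAS panels are independent
# draws from the same population
_ROLE_TAG = {"tissue": 1, "ref": 2, "gwas": 3}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the design the pipeline targets: ~120 tissue samples
    with genotypes and proteome, a reference panel of 500 for LD, and a
    large-n GWAS whose signal flows through the simulated protein effects.
    """

    seed: int = 0
    n_tissue: int = 120
    n_ref: int = 500
    n_gwas: int = 50_000
    n_loci: int = 20
    snps_per_locus: int = 10
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.5
    h2_cis: float = 0.3
    n_causal_snps: int = 1
    k_hidden: int = 3
    factor_share: float = 0.2
    missing_rate: float = 0.1
    prop_causal_proteins: float = 0.2
    gamma_sd: float = 0.03
    imp_r2_range: tuple[float, float] = (0.8, 1.0)

    def validate(self) -> None:
        counts = {
            "n_tissue": self.n_tissue, "n_ref": self.n_ref,
            "n_gwas": self.n_gwas, "n_loci": self.n_loci,
            "snps_per_locus": self.snps_per_locus,
            "n_causal_snps": self.n_causal_snps,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        lo, hi = self.maf_range
        if not (0.01 <= lo <= hi <= 0.5):
            raise ValueError(f"maf_range must be ordered within [0.01, 0.5]: {self.maf_range}")
        if not (0.0 <= self.ld_rho < 0.99):
            raise ValueError(f"ld_rho must lie in [0, 0.99): {self.ld_rho} (near-singular LD)")
        if not (0.0 <= self.h2_cis <= 1.0):
            raise ValueError(f"h2_cis must lie in [0, 1]: {self.h2_cis}")
        if self.h2_cis + self.factor_share > 1.0:
            raise ValueError(
                f"h2_cis + factor_share must not exceed 1: "
                f"{self.h2_cis} + {self.factor_share}"
            )
        if self.k_hidden < 0:
            raise ValueError("k_hidden must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError(f"missing_rate must lie in [0, 1): {self.missing_rate}")
        if not (0.0 <= self.prop_causal_proteins <= 1.0):
            raise ValueError("prop_causal_proteins must lie in [0, 1]")
        r_lo, r_hi = self.imp_r2_range
        if not (0.0 < r_lo <= r_hi <= 1.0):
            raise ValueError(f"imp_r2_range must be ordered within (0, 1]: {self.imp_r2_range}")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class GenotypePanel:
    """Samples × variants dosage matrix with variant metadata.

    ``variants`` is indexed by variant_id with columns
    ``chrom, pos, other_allele, effect_allele, freq, imp_r2, locus``.
    Dosages lie in [0, 2]; NaN marks a missing hard call.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        if self.variants.index.has_duplicates:
            dups = self.variants.index[self.variants.index.duplicated()].tolist()
            raise ValueError(f"duplicate variant ids: {dups[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> pd.Index:
        return self.variants.index

    def empirical_freq(self) -> pd.Series:
        """Effect-allele frequency from the dosages (ignoring missing)."""
        with np.errstate(invalid="ignore"):
            f = np.nanmean(self.dosages, axis=0) / 2.0
        return pd.Series(f, index=self.variants.index, name="freq")

    def dosage_sd(self, ddof: int = 1) -> pd.Series:
        return pd.Series(
            np.nanstd(self.dosages, axis=0, ddof=ddof),
            index=self.variants.index, name="sd",
        )

    def subset_variants(self, ids) -> "GenotypePanel":
        idx = self.variants.index.get_indexer(ids)
        if (idx < 0).any():
            missing = [i for i, j in zip(ids, idx) if j < 0]
            raise KeyError(f"unknown variant ids: {missing[:5]}")
        return GenotypePanel(
            sample_ids=list(self.sample_ids),
            variants=self.variants.iloc[idx].copy(),
            dosages=self.dosages[:, idx].copy(),
        )

    def subset_samples(self, sample_ids) -> "GenotypePanel":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return GenotypePanel(
            sample_ids=list(sample_ids),
            variants=self.variants.copy(),
            dosages=self.dosages[idx, :].copy(),
        )


@dataclass
class TruthSet:
    """Ground truth of the simulation.

    ``weights`` holds per-protein causal variants with their raw (per-allele)
    weights and the per-allele scale ``u`` that makes the genetic score unit
    variance in the tissue panel; ``gamma`` is the protein → trait effect
    (0 for non-causal proteins); ``loadings``/``factor_scores`` define the
    hidden-factor structure.
    """

    weights: pd.DataFrame          # protein_id, variant_id, weight_raw, u
    gamma: pd.Series               # index protein_id
    loadings: pd.DataFrame         # proteins × factors
    factor_scores: pd.DataFrame    # samples × factors
    baselines: pd.Series           # per-protein log2 baseline

    def causal_variants(self, protein_id: str) -> pd.DataFrame:
        return self.weights[self.weights["protein_id"] == protein_id]

    def per_allele_effects(self) -> pd.Series:
        """Joint per-allele trait effect per variant: sum_p gamma_p * u_sp."""
        w = self.weights.merge(
            self.gamma.rename("gamma"), left_on="protein_id", right_index=True
        )
        eff = (w["u"] * w["gamma"]).groupby(w["variant_id"]).sum()
        eff.index.name = "variant_id"
        return eff


def _variant_table(config: SimConfig) -> pd.DataFrame:
    """Variant metadata shared by all panels drawn from one config."""
    rng = np.random.default_rng([config.seed, 101])
    rows = []
    spacing = 2_000
    for locus in range(config.n_loci):
        chrom = str(locus % 22 + 1)
        base = 1_000_000 + (locus // 22) * 10_000_000
        for j in range(config.snps_per_locus):
            maf = rng.uniform(*config.maf_range)
            r2 = rng.uniform(*config.imp_r2_range)
            a, b = rng.choice(4, size=2, replace=False)
            rows.append({
                "variant_id": f"L{locus}S{j}",
                "chrom": chrom,
                "pos": base + j * spacing,
                "other_allele": _BASES[a],
                "effect_allele": _BASES[b],
                "freq": maf,
                "imp_r2": r2,
                "locus": locus,
            })
    return pd.DataFrame(rows).set_index("variant_id")


def _draw_locus_dosages(
    rng: np.random.Generator, n: int, maf: np.ndarray, r2: np.ndarray, rho: float
) -> tuple[np.ndarray, np.ndarray]:
    """Return (hard genotypes, noisy dosages) for one locus."""
    m = len(maf)
    hard = np.zeros((n, m))
    for _hap in range(2):
        z = np.empty((n, m))
        z[:, 0] = rng.standard_normal(n)
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
        # allele carried iff latent exceeds the frequency threshold
        thresh = norm.ppf(1.0 - maf)
        hard += (z > thresh[None, :]).astype(float)
    # dosage = clip(2f + r2*(g - 2f) + sigma*eps): posterior-mean shrinkage
    # toward the population mean plus noise. Clipping to [0, 2] would bias a
    # closed-form sigma, so sigma is solved per variant on the realized
    # sample to make the post-clip squared correlation equal the tag.
    var_g = 2.0 * maf * (1.0 - maf)
    eps = rng.standard_normal((n, m))
    dos = np.empty_like(hard)
    for j in range(m):
        if r2[j] >= 1.0 - 1e-12:
            dos[:, j] = hard[:, j]
            continue
        g = hard[:, j]
        if g.std() == 0:
            dos[:, j] = g
            continue
        center = 2 * maf[j] + r2[j] * (g - 2 * maf[j])
        e = eps[:, j]

        def _gap(sigma: float) -> float:
            d = np.clip(center + sigma * e, 0.0, 2.0)
            c = np.corrcoef(d, g)[0, 1]
            return c * c - r2[j]

        hi = 4.0 * np.sqrt(var_g[j] * (1.0 - r2[j]) / r2[j]) + 1e-6
        while _gap(hi) > 0:
            hi *= 2.0
        sigma = brentq(_gap, 0.0, hi, xtol=1e-6)
        dos[:, j] = np.clip(center + sigma * e, 0.0, 2.0)
    return hard, dos


def simulate_genotypes(config: SimConfig, role: str = "tissue",
                       n_samples: int | None = None,
                       substream: int = 0) -> GenotypePanel:
    """Draw a genotype panel from the configured population.

    ``role`` selects an independent random substream ("tissue", "ref",
    "gwas") so the tissue panel, LD reference and GWAS cohort share variant
    metadata but not samples; ``substream`` yields independent replicate
    draws for the same role without changing the variant metadata.
    """
    config.validate()
    if role not in _ROLE_TAG:
        raise ValueError(f"unknown role {role!r}; expected one of {sorted(_ROLE_TAG)}")
    if n_samples is None:
        n_samples = {"tissue": config.n_tissue, "ref": config.n_ref,
                     "gwas": config.n_gwas}[role]
    variants = _variant_table(config)
    rng = np.random.default_rng([config.seed, _ROLE_TAG[role], substream])
    blocks = []
    for locus, grp in variants.groupby("locus", sort=True):
        _, dos = _draw_locus_dosages(
            rng, n_samples, grp["freq"].to_numpy(), grp["imp_r2"].to_numpy(),
            config.ld_rho,
        )
        blocks.append(dos)
    dosages = np.concatenate(blocks, axis=1)
    prefix = {"tissue": "T", "ref": "R", "gwas": "G"}[role]
    sample_ids = [f"{prefix}{i:05d}" for i in range(n_samples)]
    return GenotypePanel(sample_ids=sample_ids, variants=variants, dosages=dosages)


def simulate_annotation(config: SimConfig) -> pd.DataFrame:
    """One gene/protein per locus, centered on the locus variant span."""
    variants = _variant_table(config)
    rows = []
    for locus, grp in variants.groupby("locus", sort=True):
        lo, hi = int(grp["pos"].min()), int(grp["pos"].max())
        mid = (lo + hi) // 2
        rows.append({
            "gene_id": f"GENE{locus}",
            "protein_id": f"PROT{locus}",
            "chrom": grp["chrom"].iloc[0],
            "start": max(mid - 5_000, 1),
            "end": mid + 5_000,
            "strand": "+" if locus % 2 == 0 else "-",
        })
    ann = pd.DataFrame(rows)
    if (ann["start"] > ann["end"]).any():
        raise AssertionError("annotation start > end")
    return ann


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd


def simulate_proteome(
    panel: GenotypePanel,
    annotation: pd.DataFrame,
    config: SimConfig,
) -> tuple[pd.DataFrame, TruthSet]:
    """Simulate protein intensities (proteins × samples) plus ground truth.

    Latent log2 abundance = sqrt(h2_cis) * standardized cis score
    + hidden-factor term (variance ``factor_share``) + noise filling to
    variance 1; the reported intensity is ``2**(latent + baseline)`` with
    intensity-dependent missingness at overall rate ``missing_rate``.
    """
    config.validate()
    if panel.n_variants == 0:
        raise ValueError("empty genotype panel")
    rng = np.random.default_rng([config.seed, 11])
    n = panel.n_samples
    proteins = annotation["protein_id"].tolist()

    factor_scores = rng.standard_normal((n, config.k_hidden))
    loadings = rng.standard_normal((len(proteins), config.k_hidden))

    noise_var = 1.0 - config.h2_cis - (config.factor_share if config.k_hidden else 0.0)
    if noise_var < -1e-9:
        raise ValueError("h2_cis + factor_share exceed total variance 1")
    noise_sd = np.sqrt(max(noise_var, 0.0))

    causal_ids = []
    if config.prop_causal_proteins > 0:
        n_causal = int(round(config.prop_causal_proteins * len(proteins)))
        causal_ids = list(rng.choice(proteins, size=n_causal, replace=False))

    latents = np.zeros((len(proteins), n))
    weight_rows = []
    gamma = pd.Series(0.0, index=pd.Index(proteins, name="protein_id"))
    baselines = pd.Series(
        rng.normal(20.0, 1.0, size=len(proteins)),
        index=gamma.index, name="baseline",
    )

    for i, (_, gene) in enumerate(annotation.iterrows()):
        pid = gene["protein_id"]
        in_cis = (
            (panel.variants["chrom"] == gene["chrom"])
            & (panel.variants["pos"] >= gene["start"] - 500_000)
            & (panel.variants["pos"] <= gene["end"] + 500_000)
        )
        cis_ids = panel.variants.index[in_cis]
        if len(cis_ids) < config.n_causal_snps:
            raise ValueError(
                f"protein {pid}: only {len(cis_ids)} cis variants, "
                f"need {config.n_causal_snps}"
            )
        chosen = rng.choice(cis_ids, size=config.n_causal_snps, replace=False)
        w = rng.standard_normal(config.n_causal_snps)
        cols = panel.variants.index.get_indexer(chosen)
        score = panel.dosages[:, cols] @ w
        sd = score.std(ddof=1)
        if sd <= 0:
            sd = 1.0
        u = w / sd                                   # per-allele, unit-variance scale
        g_std = (score - score.mean()) / sd
        latent = np.sqrt(config.h2_cis) * g_std
        if config.k_hidden:
            f_term = factor_scores @ loadings[i]
            f_sd = f_term.std(ddof=1)
            if f_sd > 0:
                latent = latent + np.sqrt(config.factor_share) * f_term / f_sd
        latent = latent + noise_sd * rng.standard_normal(n)
        latents[i] = latent
        for vid, wr, us in zip(chosen, w, u):
            weight_rows.append(
                {"protein_id": pid, "variant_id": vid, "weight_raw": wr, "u": us}
            )
        if pid in causal_ids:
            gamma[pid] = rng.normal(0.0, config.gamma_sd)
            while gamma[pid] == 0.0:  # ensure truly nonzero for causal set
                gamma[pid] = rng.normal(0.0, config.gamma_sd)

    intensity = np.power(2.0, latents + baselines.to_numpy()[:, None])

    if config.missing_rate > 0:
        flat = latents.ravel()
        scale = 0.5

        def _rate(c: float) -> float:
            return float(np.mean(expit((c - flat) / scale))) - config.missing_rate

        lo, hi = flat.min() - 20, flat.max() + 20
        cutoff = brentq(_rate, lo, hi)
        p_miss = expit((cutoff - latents) / scale)
        mask = rng.random(latents.shape) < p_miss
        intensity = np.where(mask, np.nan, intensity)

    proteome = pd.DataFrame(
        intensity, index=gamma.index.copy(), columns=panel.sample_ids
    )
    truth = TruthSet(
        weights=pd.DataFrame(weight_rows),
        gamma=gamma,
        loadings=pd.DataFrame(loadings, index=gamma.index.copy()),
        factor_scores=pd.DataFrame(factor_scores, index=panel.sample_ids),
        baselines=baselines,
    )
    return proteome, truth


def simulate_rna(proteome: pd.DataFrame, config: SimConfig,
                 rho: float = 0.4) -> pd.DataFrame:
    """RNA matrix correlated with the proteome at roughly rank rho."""
    rng = np.random.default_rng([config.seed, 17])
    logp = np.log2(proteome.to_numpy())
    z = np.where(np.isnan(logp), 0.0, logp)
    z = z - np.nanmean(np.where(np.isnan(logp), np.nan, logp), axis=1, keepdims=True)
    z = np.nan_to_num(z)
    sd = z.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = z / sd
    noise = rng.standard_normal(z.shape)
    rna = rho * z + np.sqrt(1 - rho ** 2) * noise + 10.0
    out = pd.DataFrame(2.0 ** rna, index=proteome.index, columns=proteome.columns)
    out.index = [p.replace("PROT", "GENE") for p in proteome.index]
    out.index.name = "gene_id"
    return out


def _locus_corr(panel: GenotypePanel, locus: int, jitter: float = 1e-8) -> tuple[pd.Index, np.ndarray]:
    ids = panel.variants.index[panel.variants["locus"] == locus]
    sub = panel.dosages[:, panel.variants.index.get_indexer(ids)]
    r = np.corrcoef(sub, rowvar=False)
    r = np.atleast_2d(r)
    # ridge-stabilize in case of near-duplicate variants
    evals = np.linalg.eigvalsh(r)
    if evals.min() < jitter:
        lam = jitter - evals.min()
        r = (r + lam * np.eye(len(ids))) / (1.0 + lam)
    return ids, r


def simulate_liability(
    panel: GenotypePanel,
    truth: TruthSet,
    rng: np.random.Generator,
) -> np.ndarray:
    """Quantitative liability: sum of gamma-weighted protein genetic scores
    plus noise filling the variance to ~1 (centered)."""
    eff = truth.per_allele_effects()
    b = pd.Series(0.0, index=panel.variant_ids)
    b.loc[eff.index] = eff
    genetic = panel.dosages @ b.to_numpy()
    noise_var = max(1.0 - genetic.var(ddof=1), 0.05)
    y = genetic + rng.standard_normal(panel.n_samples) * np.sqrt(noise_var)
    return y - y.mean()


def marginal_sumstats(panel: GenotypePanel, y: np.ndarray,
                      n: int | None = None) -> pd.DataFrame:
    """Per-variant single-variant least-squares GWAS summary statistics."""
    y = np.asarray(y, dtype=float)
    y = y - y.mean()
    n_obs = panel.n_samples
    x = panel.dosages
    xm = x - x.mean(axis=0)
    sxx = (xm ** 2).sum(axis=0)
    sxy = xm.T @ y
    beta = sxy / sxx
    rss = (y ** 2).sum() - beta * sxy
    sigma2 = rss / (n_obs - 2)
    se = np.sqrt(sigma2 / sxx)
    variants = panel.variants
    return pd.DataFrame({
        "variant_id": panel.variant_ids,
        "chrom": variants["chrom"].to_numpy(),
        "pos": variants["pos"].to_numpy(),
        "effect_allele": variants["effect_allele"].to_numpy(),
        "other_allele": variants["other_allele"].to_numpy(),
        "beta": beta,
        "se": se,
        "freq": x.mean(axis=0) / 2.0,
        "n": n if n is not None else n_obs,
    }).reset_index(drop=True)


def simulate_gwas_sumstats(
    ld_source: GenotypePanel,
    truth: TruthSet,
    config: SimConfig,
    mode: str = "analytic",
    seed: int | None = None,
) -> pd.DataFrame:
    """GWAS summary statistics implied by the truth set.

    ``analytic`` draws per-locus marginal Z from ``N(sqrt(n) R lam, R)``
    with R the reference dosage correlation and lam the standardized joint
    effects; ``cohort`` simulates an independent cohort of ``config.n_gwas``
    individuals, builds a quantitative liability from the causal protein
    scores, and runs single-variant least squares. ``seed`` overrides the
    stochastic-draw stream only (replicates share variant metadata/truth).
    """
    config.validate()
    if mode not in {"analytic", "cohort"}:
        raise ValueError(f"mode must be 'analytic' or 'cohort', got {mode!r}")
    unknown = set(truth.weights["variant_id"]) - set(ld_source.variant_ids)
    if unknown:
        raise KeyError(f"truth weights reference unknown variants: {sorted(unknown)[:5]}")

    draw_seed = config.seed if seed is None else seed
    eff = truth.per_allele_effects()  # per-allele joint effects on the trait
    n = config.n_gwas
    variants = ld_source.variants

    if mode == "cohort":
        cohort = simulate_genotypes(config, role="gwas", n_samples=n,
                                    substream=draw_seed)
        rng = np.random.default_rng([draw_seed, 23])
        y = simulate_liability(cohort, truth, rng)
        return marginal_sumstats(cohort, y, n=n)

    # analytic mode
    rng = np.random.default_rng([draw_seed, 29])
    sd_s = ld_source.dosage_sd().to_numpy()
    freq = ld_source.empirical_freq().to_numpy()
    lam_raw = pd.Series(0.0, index=ld_source.variant_ids)
    lam_raw.loc[eff.index] = eff
    # standardized effects: per-allele effect times dosage SD
    lam_std = lam_raw.to_numpy() * sd_s
    rows_z = np.zeros(ld_source.n_variants)
    for locus in sorted(variants["locus"].unique()):
        ids, r = _locus_corr(ld_source, locus)
        cols = variants.index.get_indexer(ids)
        mean = np.sqrt(n) * r @ lam_std[cols]
        chol = np.linalg.cholesky(r)
        z = mean + chol @ rng.standard_normal(len(ids))
        rows_z[cols] = z
    se = 1.0 / (sd_s * np.sqrt(n))
    out = pd.DataFrame({
        "variant_id": ld_source.variant_ids,
        "chrom": variants["chrom"].to_numpy(),
        "pos": variants["pos"].to_numpy(),
        "effect_allele": variants["effect_allele"].to_numpy(),
        "other_allele": variants["other_allele"].to_numpy(),
        "beta": rows_z * se,
        "se": se,
        "freq": freq,
        "n": n,
    })
    return out.reset_index(drop=True)


def inject_index_signal(
    gwas: pd.DataFrame,
    ld: GenotypePanel,
    index_variant: str,
    z_target: float,
) -> pd.DataFrame:
    """Add an index-variant signal propagated through LD.

    The locus Z vector gains ``R[:, index] * z_target`` so that all apparent
    signal at the locus is attributable to the index variant — the canonical
    fixture for conditional-analysis tests.
    """
    if index_variant not in ld.variant_ids:
        raise KeyError(f"unknown variant id {index_variant!r}")
    out = gwas.copy()
    locus = ld.variants.loc[index_variant, "locus"]
    ids, r = _locus_corr(ld, locus)
    i = ids.get_loc(index_variant)
    shift = pd.Series(r[:, i] * z_target, index=ids)
    sel = out["variant_id"].isin(ids.to_series())
    z = out.loc[sel, "beta"] / out.loc[sel, "se"]
    z = z + out.loc[sel, "variant_id"].map(shift).to_numpy()
    out.loc[sel, "beta"] = z * out.loc[sel, "se"]
    return out
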