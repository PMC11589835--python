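import numpy as np
import pandas as pd
import pytest

from pwaskit.sim import GenotypePanel


def make_panel(dosages, freqs=None, imp_r2=None, chrom="1", pos0=1_000_000,
               spacing=2_000, alleles=None, locus=0):
    """Hand-built GenotypePanel for fixture tests."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if freqs is None:
        freqs = np.nanmean(dosages, axis=0) / 2.0
    if imp_r2 is None:
        imp_r2 = np.ones(m)
    if alleles is None:
        alleles = [("A", "G")] * m
    variants = pd.DataFrame({
        "chrom": chrom,
        "pos": [pos0 + i * spacing for i in range(m)],
        "other_allele": [a for a, _ in alleles],
        "effect_allele": [b for _, b in alleles],
        "freq": freqs,
        "imp_r2": imp_r2,
        "locus": locus,
    }, index=pd.Index([f"V{i}" for i in range(m)], name="variant_id"))
    return GenotypePanel(
        sample_ids=[f"S{i}" for i in range(n)],
        variants=variants,
        dosages=dosages,
    )


def correlated_columns(n, r, rng, center=1.0, scale=0.3):
    """Two mean-centered columns with *exact* sample correlation r, offset
    into the dosage range."""
    a = rng.standard_normal(n)
    b = rng.standard_normal(n)
    a = a - a.mean()
    b = b - (b @ a) / (a @ a) * a
    b = b - b.mean()
    a /= np.linalg.norm(a)
    b /= np.linalg.norm(b)
    x1 = a
    x2 = r * a + np.sqrt(max(1 - r * r, 0.0)) * b
    return center + scale * x1, center + scale * x2


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
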