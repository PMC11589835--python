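"""Integration reports: protein-vs-RNA Spearman correlation and
PWAS-vs-TWAS comparison tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import bh_fdr

__all__ = ["spearman_with_ci", "correlate_matrices", "compare_pwas_twas"]


def spearman_with_ci(x, y, conf: float = 0.95) -> dict:
    """Spearman rho with a Fisher-z confidence interval.

    Missing entries are removed pairwise (>= 4 complete pairs required).
    rho is the Pearson correlation of average-ranked values; p uses the
    t approximation with n − 2 df; the CI back-transforms a normal interval
    on atanh(rho) with SE 1/sqrt(n − 3).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ValueError(f"need >= 4 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"rho": np.nan, "ci_lo": np.nan, "ci_hi": np.nan,
                "p": np.nan, "n": n, "status": "constant"}
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        p = 0.0
        lo, hi = (rho, 1.0) if rho > 0 else (-1.0, rho)
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
        zr = np.arctanh(rho)
        se = 1.0 / np.sqrt(n - 3)
        zc = stats.norm.ppf(0.5 + conf / 2.0)
        lo, hi = np.tanh(zr - zc * se), np.tanh(zr + zc * se)
    return {"rho": rho, "ci_lo": float(lo), "ci_hi": float(hi),
            "p": p, "n": n, "status": "ok"}


def correlate_matrices(
    proteome: pd.DataFrame,
    rna: pd.DataFrame,
    id_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-protein Spearman correlation against matched RNA rows, with FDR.

    ``id_map`` maps protein_id → gene_id; by default protein ids are looked
    up directly, then with the PROT→GENE prefix convention of the synthetic
    annotation.
    """
    shared_samples = proteome.columns.intersection(rna.columns)
    rows = []
    for pid in proteome.index:
        gid = (id_map or {}).get(pid, pid)
        if gid not in rna.index and gid.replace("PROT", "GENE") in rna.index:
            gid = gid.replace("PROT", "GENE")
        if gid not in rna.index:
            continue
        try:
            res = spearman_with_ci(
                proteome.loc[pid, shared_samples], rna.loc[gid, shared_samples]
            )
        except ValueError:
            continue
        res["protein_id"] = pid
        res["gene_id"] = gid
        rows.append(res)
    out = pd.DataFrame(rows)
    if len(out):
        ok = out["status"] == "ok"
        out["q"] = np.nan
        out.loc[ok, "q"] = bh_fdr(out.loc[ok, "p"])
        out = out[["protein_id", "gene_id", "rho", "ci_lo", "ci_hi",
                   "p", "q", "n", "status"]]
    return out


def compare_pwas_twas(
    pwas: pd.DataFrame,
    twas: pd.DataFrame,
    on: str = "protein_id",
) -> tuple[pd.DataFrame, dict]:
    """Side-by-side PWAS/TWAS Z and p with sign-concordance flags.

    ``pwas`` needs columns (protein_id, z, p[, q]); ``twas`` columns
    (protein_id or gene_id, z, p). Returns the joined table plus a summary
    dict: concordant count, both-significant count, unmatched ids.
    """
    p = pwas.rename(columns={"z": "z_pwas", "p": "p_pwas", "q": "q_pwas"})
    t = twas.rename(columns={"z": "z_twas", "p": "p_twas"})
    if on not in t.columns and "gene_id" in t.columns:
        t[on] = t["gene_id"].str.replace("GENE", "PROT")
    merged = p.merge(t, on=on, suffixes=("_pwas", "_twas"), how="left")
    merged["concordant"] = (
        np.sign(merged["z_pwas"]) * np.sign(merged["z_twas"]) > 0
    ).astype("boolean")
    merged.loc[merged["z_twas"].isna(), "concordant"] = pd.NA
    matched = merged["z_twas"].notna()
    summary = {
        "n": int(len(merged)),
        "n_matched": int(matched.sum()),
        "n_concordant": int((merged["concordant"] == True).sum()),  # noqa: E712
        "n_both_sig": int(
            ((merged["p_pwas"] < 0.05) & (merged["p_twas"] < 0.05)).sum()
        ),
        "unmatched_ids": merged.loc[~matched, on].tolist(),
    }
    return merged, summary
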