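"""Summary-statistic association: sigma_p, the weighted Z formula, FDR,
novelty annotation and the PWAS model/results objects."""

import numpy as np
import pandas as pd
import pytest

from conftest import correlated_columns, make_panel
from pwaskit.assoc import (
    PWAS, LDReference, annotate_novelty, bh_fdr, predicted_expression_sd,
    run_phenotypes, spredixcan_z, z_to_p,
)
from pwaskit.cismodels import ModelDB, ProteinModel


def _model(weights, protein_id="P0", r=0.5, p=1e-4, ea=None):
    ids = list(weights.keys())
    return ProteinModel(
        protein_id=protein_id,
        weights=pd.Series(weights),
        effect_alleles=pd.Series({v: (ea or {}).get(v, "G") for v in ids}),
        r=r, p=p, n_snps_window=len(ids), lam=0.01,
    )


def _gwas_from_z(panel, z, n=10_000):
    sd = panel.dosage_sd().to_numpy()
    se = 1.0 / (sd * np.sqrt(n))
    v = panel.variants
    return pd.DataFrame({
        "variant_id": panel.variant_ids,
        "chrom": v["chrom"].to_numpy(), "pos": v["pos"].to_numpy(),
        "effect_allele": v["effect_allele"].to_numpy(),
        "other_allele": v["other_allele"].to_numpy(),
        "beta": np.asarray(z, dtype=float) * se, "se": se,
        "freq": panel.empirical_freq().to_numpy(), "n": n,
    })


class TestPredictedExpressionSd:
    def test_single_variant_identity(self, rng):
        panel = make_panel(rng.binomial(2, 0.3, (50, 1)).astype(float))
        ld = LDReference(panel)
        m = _model({"V0": 1.0})
        assert predicted_expression_sd(m, ld) == pytest.approx(
            float(ld.sigma(["V0"]).iloc[0]))

    def test_independent_unit_variants_add(self, rng):
        x1, x2 = correlated_columns(200, 0.0, rng)
        # rescale columns to unit sample SD
        x1 = (x1 - x1.mean()) / x1.std(ddof=1) + 1.0
        x2 = (x2 - x2.mean()) / x2.std(ddof=1) + 1.0
        panel = make_panel(np.column_stack([x1, x2]))
        m = _model({"V0": 1.0, "V1": 1.0})
        assert predicted_expression_sd(m, LDReference(panel)) == \
            pytest.approx(np.sqrt(2.0), rel=1e-10)

    def test_matches_per_sample_prediction_oracle(self, rng):
        dosages = rng.binomial(2, 0.4, size=(80, 5)).astype(float)
        panel = make_panel(dosages)
        w = {f"V{i}": float(x) for i, x in enumerate(rng.normal(size=5))}
        m = _model(w)
        sigma_p = predicted_expression_sd(m, LDReference(panel))
        pred = dosages @ np.array(list(w.values()))
        assert sigma_p == pytest.approx(float(np.std(pred, ddof=1)), abs=1e-10)


class TestSpredixcanZ:
    def test_single_variant_collapses_to_marginal_z(self, rng):
        panel = make_panel(rng.binomial(2, 0.3, (60, 1)).astype(float))
        gwas = _gwas_from_z(panel, [2.5])
        res = spredixcan_z(_model({"V0": 1.0}), gwas, LDReference(panel))
        assert res["z"] == pytest.approx(2.5, rel=1e-10)
        # scale invariance: w -> c*w leaves Z unchanged; negative c flips sign
        res2 = spredixcan_z(_model({"V0": 7.3}), gwas, LDReference(panel))
        assert res2["z"] == pytest.approx(2.5, rel=1e-10)
        res3 = spredixcan_z(_model({"V0": -7.3}), gwas, LDReference(panel))
        assert res3["z"] == pytest.approx(-2.5, rel=1e-10)

    def test_three_variant_hand_computed_fixture(self, rng):
        # correlated fixture with printed marginal Z and hand-evaluated sum
        n = 500
        a, b = correlated_columns(n, 0.5, rng)
        _, c = correlated_columns(n, 0.0, np.random.default_rng(5))
        dosages = np.column_stack([a, b, c])
        panel = make_panel(dosages)
        ld = LDReference(panel)
        w = {"V0": 0.5, "V1": -0.2, "V2": 0.1}
        marg_z = [2.0, 1.0, -1.0]
        gwas = _gwas_from_z(panel, marg_z)
        res = spredixcan_z(_model(w), gwas, ld)
        gamma = ld.cov(["V0", "V1", "V2"]).to_numpy()
        wv = np.array([0.5, -0.2, 0.1])
        sigma_p = np.sqrt(wv @ gamma @ wv)
        sigma_s = np.sqrt(np.diag(gamma))
        expected = float(np.sum(wv * sigma_s / sigma_p * np.array(marg_z)))
        assert res["z"] == pytest.approx(expected, rel=1e-12)

    def test_missing_variants_dropped_without_renormalization(self, rng):
        panel = make_panel(rng.binomial(2, 0.3, (60, 2)).astype(float))
        gwas = _gwas_from_z(panel, [2.0, 3.0]).iloc[:1]   # V1 absent
        full = spredixcan_z(_model({"V0": 1.0}), _gwas_from_z(panel, [2.0, 3.0]),
                            LDReference(panel))
        res = spredixcan_z(_model({"V0": 1.0, "V1": 0.5}), gwas,
                           LDReference(panel))
        assert res["n_dropped"] == 1 and res["n_used"] == 1
        assert res["z"] == pytest.approx(full["z"], rel=1e-10)

    def test_all_variants_missing_untestable(self, rng):
        panel = make_panel(rng.binomial(2, 0.3, (60, 1)).astype(float))
        gwas = _gwas_from_z(panel, [2.0]).iloc[:0]
        res = spredixcan_z(_model({"V0": 1.0}), gwas, LDReference(panel))
        assert res["status"] == "untestable"

    def test_individual_level_oracle_small(self):
        # same-sample GWAS stats and LD: summary Z matches the regression Z
        # of the trait on predicted expression
        from pwaskit.sim import (
            SimConfig, marginal_sumstats, simulate_annotation,
            simulate_genotypes, simulate_liability, simulate_proteome,
        )
        cfg = SimConfig(seed=55, n_loci=10, snps_per_locus=5, n_gwas=8000,
                        prop_causal_proteins=0.5, gamma_sd=0.02, h2_cis=0.5,
                        n_causal_snps=2, imp_r2_range=(1.0, 1.0))
        tissue = simulate_genotypes(cfg, role="tissue")
        ann = simulate_annotation(cfg)
        _, truth = simulate_proteome(tissue, ann, cfg)
        cohort = simulate_genotypes(cfg, role="gwas", n_samples=8000)
        y = simulate_liability(cohort, truth, np.random.default_rng(2))
        gwas = marginal_sumstats(cohort, y)
        ld = LDReference(cohort)
        g = gwas.set_index("variant_id")
        n = cohort.n_samples
        deltas = []
        for pid in truth.gamma.index:
            w = truth.causal_variants(pid).set_index("variant_id")["u"]
            model = _model(dict(w), protein_id=pid)
            z_sum = spredixcan_z(model, g, ld)["z"]
            cols = cohort.variants.index.get_indexer(w.index)
            pred = cohort.dosages[:, cols] @ w.to_numpy()
            r = np.corrcoef(y, pred)[0, 1]
            z_ind = r * np.sqrt((n - 2) / (1 - r * r))
            deltas.append(abs(z_sum - z_ind))
        assert max(deltas) < 0.05


class TestZToP:
    @pytest.mark.parametrize("z,expected,ulp", [
        (4.13, 3.63e-5, 0.01e-5), (3.33, 8.68e-4, 0.01e-4),
        (3.59, 3.31e-4, 0.01e-4), (4.19, 2.79e-5, 0.01e-5),
        (-0.73, 0.47, 0.01), (-0.40, 0.69, 0.01),
    ])
    def test_printed_z_p_pairs(self, z, expected, ulp):
        # agreement to the printed precision (half a unit in the last place)
        assert abs(z_to_p(z) - expected) <= 0.5 * ulp

    def test_zero_and_infinite(self):
        assert z_to_p(0.0) == 1.0
        with pytest.raises(ValueError):
            z_to_p(float("nan"))


class TestBhFdr:
    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_hand_run_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        np.testing.assert_allclose(bh_fdr([0.3]), [0.3])

    def test_q_at_least_p(self, rng):
        p = rng.uniform(size=50)
        assert (bh_fdr(p) >= p - 1e-12).all()


class TestNovelty:
    def _gene(self):
        return pd.Series({"chrom": "11", "start": 1_874_203, "end": 1_913_497})

    def test_variant_inside_gene(self):
        known = pd.DataFrame({"variant_id": ["v1"], "chrom": ["11"],
                              "pos": [1_900_000]})
        novel, nearest, d = annotate_novelty(self._gene(), known)
        assert d == 0 and not novel and nearest == "v1"

    def test_nearby_variant_distance(self):
        # 16.54 kb from the gene boundary: inside known risk locus
        known = pd.DataFrame({"variant_id": ["11:1896957"], "chrom": ["11"],
                              "pos": [1_874_203 - 16_540]})
        novel, _, d = annotate_novelty(self._gene(), known)
        assert d == pytest.approx(16_540)
        assert not novel

    def test_exactly_one_megabase_is_novel(self):
        known = pd.DataFrame({"variant_id": ["v1"], "chrom": ["11"],
                              "pos": [1_874_203 - 1_000_000]})
        novel, _, d = annotate_novelty(self._gene(), known)
        assert d == 1_000_000 and novel

    def test_other_chromosome_infinitely_far(self):
        known = pd.DataFrame({"variant_id": ["v1"], "chrom": ["2"],
                              "pos": [1_874_203]})
        novel, nearest, d = annotate_novelty(self._gene(), known)
        assert novel and nearest is None and np.isinf(d)


class TestRunPhenotypes:
    def _db_and_panel(self, rng):
        panel = make_panel(rng.binomial(2, 0.3, (80, 2)).astype(float))
        m = _model({"V0": 1.0})
        db = ModelDB(models={"P0": m}, stats=pd.DataFrame(
            [{"protein_id": "P0", "r": 0.5, "p": 1e-4, "n_snps_window": 2,
              "n_snps_model": 1, "lambda": 0.01, "passed": True,
              "reason": "ok"}]))
        return db, panel

    def test_model_by_phenotype_cross(self, rng):
        db, panel = self._db_and_panel(rng)
        gwas_map = {"overall": _gwas_from_z(panel, [2.0, 0.0]),
                    "ER-positive": _gwas_from_z(panel, [1.0, 0.0])}
        tab = run_phenotypes(db, gwas_map, LDReference(panel))
        assert len(tab) == 2
        assert set(tab["phenotype"]) == {"overall", "ER-positive"}

    def test_fdr_within_phenotype_not_pooled(self, rng):
        # pooling would rescue phenotype B's p-values; stratified must not
        db, panel = self._db_and_panel(rng)
        ld = LDReference(panel)
        za = 2.05  # p ~ 0.040
        zb = 2.17  # p ~ 0.030
        tab = run_phenotypes(db, {"A": _gwas_from_z(panel, [za, 0]),
                                  "B": _gwas_from_z(panel, [zb, 0])}, ld)
        qb = tab.loc[tab["phenotype"] == "B", "q"].iloc[0]
        pb = tab.loc[tab["phenotype"] == "B", "p"].iloc[0]
        assert qb == pytest.approx(pb)     # single test in its own stratum
        pooled_qb = bh_fdr([z_to_p(za), z_to_p(zb)])[1]
        assert abs(qb - pooled_qb) > 1e-3  # pooling would inflate B's q

    def test_empty_model_db(self, rng):
        _, panel = self._db_and_panel(rng)
        db = ModelDB(models={}, stats=pd.DataFrame())
        tab = run_phenotypes(db, {"overall": _gwas_from_z(panel, [0, 0])},
                             LDReference(panel))
        assert len(tab) == 0


class TestPwasModelObject:
    def test_fit_summary_and_significant(self, rng):
        panel = make_panel(rng.binomial(2, 0.3, (80, 1)).astype(float))
        db = ModelDB(models={"P0": _model({"V0": 1.0})}, stats=pd.DataFrame())
        ann = pd.DataFrame({"gene_id": ["G0"], "protein_id": ["P0"],
                            "chrom": ["1"], "start": [1_000_000],
                            "end": [1_010_000], "strand": ["+"]})
        res = PWAS(db, _gwas_from_z(panel, [4.5]), panel,
                   annotation=ann).fit()
        assert len(res.table) == 1
        assert len(res.significant()) == 1
        text = res.summary()
        assert "P0" in text and "FDR" in text

    def test_gwas_label_flip_invariance(self, rng):
        # flipping allele labels + beta sign in the GWAS leaves Z unchanged
        # after harmonization
        from pwaskit.qc import harmonize_alleles
        panel = make_panel(rng.binomial(2, 0.3, (80, 1)).astype(float),
                           alleles=[("A", "G")])
        gwas = _gwas_from_z(panel, [2.7])
        flipped = gwas.copy()
        flipped["effect_allele"], flipped["other_allele"] = (
            gwas["other_allele"], gwas["effect_allele"])
        flipped["beta"] = -gwas["beta"]
        flipped["freq"] = 1 - gwas["freq"]
        _, harm, _ = harmonize_alleles(panel, flipped)
        m = _model({"V0": 1.0})
        z1 = spredixcan_z(m, gwas, LDReference(panel))["z"]
        z2 = spredixcan_z(m, harm, LDReference(panel))["z"]
        assert z1 == pytest.approx(z2, rel=1e-12)
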