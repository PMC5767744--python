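import numpy as np
import pandas as pd
import pytest
from scipy import stats

from assoctx.association import (
    GEMAssociation,
    SNPAssociation,
    bonferroni_threshold,
    fdr_line,
    genomic_control,
    manhattan_table,
)
from assoctx.mlm import fit_null_mlm, gls_scan
from assoctx.structure import EncodedGenotypes


class TestThresholds:
    @pytest.mark.parametrize("alpha,m,expected,tol", [
        (0.05, 256_397, 6.71, 0.005),
        (0.05, 53_889, 6.03, 0.005),
        (0.05, 1, 1.301, 0.001),
    ])
    def test_bonferroni(self, alpha, m, expected, tol):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected,
                                                               abs=tol)

    def test_bonferroni_validation(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 10)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)

    def test_fdr_all_significant(self):
        assert fdr_line([1e-9] * 100) == pytest.approx(9.0)

    def test_fdr_hand_enumeration(self):
        # BH at q=0.05: largest p(i) <= i/4 * 0.05 is p(3) = 0.03
        assert fdr_line([0.001, 0.02, 0.03, 0.9]) == pytest.approx(
            -np.log10(0.03))

    def test_fdr_uniform_nulls_usually_flag(self):
        rng = np.random.default_rng(0)
        flagged = sum(
            np.isinf(fdr_line(rng.uniform(size=200))) for _ in range(20))
        assert flagged >= 15


class TestGenomicControl:
    def test_null_median_gives_unit_lambda(self):
        lam, adj = genomic_control(np.full(101, 0.5))
        assert lam == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(adj, 0.5)

    def test_doubled_chisquare_halved_back(self):
        rng = np.random.default_rng(1)
        chi = 2 * stats.chi2.rvs(1, size=4001, random_state=rng)
        p = stats.chi2.sf(chi, 1)
        lam, adj = genomic_control(p)
        assert lam == pytest.approx(2.0, rel=0.05)
        assert np.allclose(stats.chi2.isf(adj, 1), chi / lam)

    def test_deflated_scan_unchanged(self):
        rng = np.random.default_rng(2)
        chi = 0.6 * stats.chi2.rvs(1, size=2001, random_state=rng)
        p = stats.chi2.sf(chi, 1)
        lam, adj = genomic_control(p)
        assert lam < 1
        assert np.array_equal(adj, p)

    def test_idempotent_after_one_application(self):
        rng = np.random.default_rng(3)
        p = stats.chi2.sf(1.8 * stats.chi2.rvs(1, size=5000,
                                               random_state=rng), 1)
        lam1, adj = genomic_control(p)
        lam2, _ = genomic_control(adj)
        assert lam1 > 1
        assert lam2 == pytest.approx(1.0, abs=0.01)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            genomic_control([])


class TestManhattan:
    def _scan(self):
        return pd.DataFrame({
            "id": ["gC1:7", "gA1:3", "gA1:9", "gA2:1"],
            "model": ["gC1", "gA1", "gA1", "gA2"],
            "minus_log10_p": [1.0, 2.0, 3.0, 4.0],
            "assigned": [True, True, True, True],
        })

    def test_a_chromosomes_precede_c(self, toy_gene_order):
        tab = manhattan_table(self._scan(), toy_gene_order)
        assert list(tab["chromosome"]) == ["A1", "A1", "A8", "C1"]
        assert list(tab["x_rank"]) == [1, 2, 3, 4]

    def test_assigned_marker_dark(self, toy_gene_order):
        tab = manhattan_table(self._scan(), toy_gene_order)
        assert tab["dark"].all()

    def test_unassigned_hemi_casts_homoeologous_shadow(self, toy_gene_order):
        scan = self._scan()
        scan.loc[1, "assigned"] = False   # gA1 has homoeologue gC1
        tab = manhattan_table(scan, toy_gene_order)
        rows = tab[tab["id"] == "gA1:3"]
        assert len(rows) == 2
        assert set(rows["chromosome"]) == {"A1", "C1"}
        assert not rows["dark"].any()

    def test_unknown_model_rejected(self, toy_gene_order):
        scan = self._scan()
        scan.loc[0, "model"] = "missing"
        with pytest.raises(KeyError):
            manhattan_table(scan, toy_gene_order)


class TestMixedModel:
    def test_identity_kinship_equals_ols(self):
        rng = np.random.default_rng(42)
        n, m = 50, 200
        y = rng.normal(size=n)
        M = rng.binomial(1, 0.4, size=(n, m)).astype(float)
        null = fit_null_mlm(y, np.ones((n, 1)), np.eye(n))
        _, _, _, p = gls_scan(null, M)
        for j in range(0, m, 7):
            if M[:, j].std() > 0:
                assert p[j] == pytest.approx(
                    stats.linregress(M[:, j], y).pvalue, abs=1e-8)

    def test_pure_noise_h2_near_zero(self):
        rng = np.random.default_rng(0)
        n = 300
        y = rng.normal(size=n)
        null = fit_null_mlm(y, np.ones((n, 1)), np.eye(n))
        assert null.h2 < 0.6  # with K=I, g and e are unidentifiable; ratio
        # is irrelevant because the total variance is what enters the tests
        sigma_tot = null.varcomp.sigma_g2 + null.varcomp.sigma_e2
        assert sigma_tot == pytest.approx(float(np.var(y, ddof=1)), rel=0.1)

    def test_h2_recovery_from_kinship(self):
        rng = np.random.default_rng(10)
        n, m = 250, 1500
        recovered = []
        for _ in range(5):
            G = rng.binomial(1, rng.uniform(0.1, 0.9, m), size=(n, m))
            Gs = (G - G.mean(0)) / np.maximum(G.std(0), 1e-9)
            K = Gs @ Gs.T / m
            K /= np.diag(K).mean()
            beta = rng.normal(0, 1, m)
            g = Gs @ beta / np.sqrt(m)
            h2 = 0.8
            e = rng.normal(0, np.sqrt(g.var() * (1 - h2) / h2), n)
            null = fit_null_mlm(g + e, np.ones((n, 1)), K)
            recovered.append(null.h2)
        assert np.mean(recovered) == pytest.approx(0.8, abs=0.1)

    def test_constant_trait_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_null_mlm(np.ones(20), np.ones((20, 1)), np.eye(20))

    def test_missing_dosages_drop_accessions_per_marker(self):
        rng = np.random.default_rng(3)
        n = 80
        y = rng.normal(size=n)
        x = rng.binomial(1, 0.5, n).astype(float)
        x_missing = x.copy()
        x_missing[:10] = np.nan
        null = fit_null_mlm(y, np.ones((n, 1)), np.eye(n))
        _, _, _, p = gls_scan(null, np.column_stack([x, x_missing]))
        expected = stats.linregress(x[10:], y[10:]).pvalue
        assert p[1] == pytest.approx(expected, abs=1e-6)


class TestAssociationModels:
    def test_major_locus_is_scan_maximum(self, default_panel, called_default,
                                         structured_default):
        _, ann, _ = called_default
        geno, q, k = structured_default
        res = SNPAssociation(default_panel.trait, geno, ann, Q=q, K=k).fit()
        causal = {s for s, _, _ in default_panel.truth.causal_sites}
        top2 = set(res.scan.nlargest(2, "minus_log10_p")["id"])
        assert top2 == causal
        assert (res.significant()["id"].isin(causal)).any()
        assert res.scan["minus_log10_p"].min() >= 0

    def test_gem_exact_linear_relation(self):
        rng = np.random.default_rng(5)
        n = 60
        ids = [f"a{i}" for i in range(n)]
        x = rng.uniform(1, 10, n)
        expr = pd.DataFrame({a: [x[i], rng.uniform(1, 5)]
                             for i, a in enumerate(ids)},
                            index=pd.Index(["causal", "other"], name="model"))
        trait = pd.Series(2.0 * x, index=ids)
        res = GEMAssociation(trait, expr).fit(apply_gc=False)
        row = res.fits.set_index("model").loc["causal"]
        assert row["slope"] == pytest.approx(2.0)
        assert row["r2"] == pytest.approx(1.0)
        # the fitted line reproduces the trait of any accession
        assert row["intercept"] + row["slope"] * x[0] == pytest.approx(
            trait.iloc[0])

    def test_q_covariates_reduce_gem_inflation(self):
        rng = np.random.default_rng(8)
        n, m = 200, 400
        labels = np.arange(n) % 2
        ids = [f"a{i}" for i in range(n)]
        expr = rng.lognormal(1.0, 0.5, size=(m, n)) * (1 + 0.8 * labels)
        trait = pd.Series(2.0 * labels + rng.normal(size=n), index=ids)
        frame = pd.DataFrame(expr, index=pd.Index(
            [f"g{j}" for j in range(m)], name="model"), columns=ids)
        q = pd.DataFrame({"pop1": 1.0 - labels, "pop2": labels * 1.0},
                         index=ids)
        with_q = GEMAssociation(trait, frame, Q=q).fit()
        without_q = GEMAssociation(trait, frame, Q=None).fit()
        assert with_q.lambda_gc <= without_q.lambda_gc

    def test_negative_slope_expression_mechanism(self, default_panel,
                                                 structured_default):
        _, q, _ = structured_default
        res = GEMAssociation(default_panel.trait, default_panel.expression,
                             Q=q).fit()
        top = res.fits.nlargest(1, "minus_log10_p").iloc[0]
        assert top["model"] == default_panel.truth.causal_model
        assert top["slope"] < 0
        assert top["minus_log10_p"] > res.bonferroni
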