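import numpy as np
import pandas as pd
import pytest

from assoctx.io import SiteCallMatrix
from assoctx.prediction import TakeOneOutGEM, TakeOneOutSNP, allelic_effects


class TestAllelicEffects:
    def test_lookup_and_fallback(self):
        states = np.array(["A"] * 3 + ["R"] * 3)
        trait = np.array([10.0, 10, 10, 20, 20, 20])
        effects, overall = allelic_effects(states, trait)
        assert effects["R"] == 20.0 and effects["A"] == 10.0
        assert effects.get("G", overall) == 15.0  # unseen state -> mean

    def test_empty_or_monomorphic_training_rejected(self):
        with pytest.raises(ValueError):
            allelic_effects(np.array([]), np.array([]))
        with pytest.raises(ValueError):
            allelic_effects(np.array(["A", "A"]), np.array([1.0, 2.0]))

    def test_group_difference_recovers_effect(self):
        rng = np.random.default_rng(0)
        n = 400
        states = np.array(["A", "G"] * (n // 2))
        beta = 1.5
        trait = np.where(states == "G", beta, 0.0) + rng.normal(0, 0.5, n)
        effects, _ = allelic_effects(states, trait)
        se = 0.5 / np.sqrt(n / 2)
        assert effects["G"] - effects["A"] == pytest.approx(beta,
                                                            abs=4 * 2 * se)


def _marker_panel(n=40, noise=0.0, seed=0, n_null=30):
    """One fully informative marker plus null markers."""
    rng = np.random.default_rng(seed)
    carrier = (np.arange(n) % 2).astype(bool)
    causal = np.where(carrier, "G", "A")
    null_cols = rng.choice(["A", "G"], size=(n, n_null))
    calls = np.column_stack([causal, null_cols])
    ids = [f"a{i:02d}" for i in range(n)]
    sites = ["causal:1"] + [f"null{j:02d}:1" for j in range(n_null)]
    matrix = SiteCallMatrix(calls, ids, sites)
    ann = pd.DataFrame({
        "site_id": sites,
        "model": [s.split(":")[0] for s in sites],
        "snp_class": "simple",
        "genome_assigned": True,
        "maf": 0.5,
        "chromosome": "A1",
        "order_index": np.arange(1, len(sites) + 1),
    })
    trait = pd.Series(np.where(carrier, 5.0, 1.0) +
                      rng.normal(0, noise, n), index=ids)
    return matrix, ann, trait


class TestTakeOneOutSNP:
    def test_fully_penetrant_marker_perfect_prediction(self):
        matrix, ann, trait = _marker_panel()
        report = TakeOneOutSNP(trait, matrix, ann, k=None,
                               use_kinship=False).run()
        assert report.r2 == pytest.approx(1.0, abs=1e-9)
        assert report.fallback_fraction == 0.0

    def test_permuted_trait_no_predictive_power(self):
        matrix, ann, trait = _marker_panel(noise=0.3, seed=1)
        rng = np.random.default_rng(99)
        permuted = pd.Series(rng.permutation(trait.to_numpy()),
                             index=trait.index)
        report = TakeOneOutSNP(permuted, matrix, ann, k=None,
                               use_kinship=False).run()
        assert report.r2 < 0.1

    def test_no_leakage_of_left_out_trait(self):
        matrix, ann, trait = _marker_panel(noise=0.5, seed=2)
        base = TakeOneOutSNP(trait, matrix, ann, k=None,
                             use_kinship=False).run()
        poisoned = trait.copy()
        poisoned.iloc[0] += 1000.0
        alt = TakeOneOutSNP(poisoned, matrix, ann, k=None,
                            use_kinship=False).run()
        assert alt.frame["predicted"].iloc[0] == pytest.approx(
            base.frame["predicted"].iloc[0])

    def test_fast_and_full_modes_agree(self):
        matrix, ann, trait = _marker_panel(noise=1.0, seed=3)
        runner = TakeOneOutSNP(trait, matrix, ann, k=None, use_kinship=False)
        full = runner.run(fast=False)
        fast = runner.run(fast=True)
        assert abs(full.r2 - fast.r2) <= 0.05

    def test_too_few_accessions_rejected(self):
        matrix, ann, trait = _marker_panel(n=20)
        with pytest.raises(ValueError, match="30"):
            TakeOneOutSNP(trait, matrix, ann)


def _expression_panel(n=60, noise=0.0, seed=0, m_null=5):
    rng = np.random.default_rng(seed)
    ids = [f"a{i:02d}" for i in range(n)]
    x = rng.uniform(1, 10, n)
    rows = {"causal": x}
    for j in range(m_null):
        rows[f"null{j:02d}"] = rng.uniform(1, 10, n)
    expr = pd.DataFrame(rows, index=ids).T
    expr.index.name = "model"
    trait = pd.Series(3.0 - 0.2 * x + rng.normal(0, noise, n), index=ids)
    return expr, trait


class TestTakeOneOutGEM:
    def test_exact_linear_gene_perfect_prediction(self):
        expr, trait = _expression_panel()
        report = TakeOneOutGEM(trait, expr).run()
        assert report.r2 > 0.99

    def test_no_passing_gem_flags_full_fallback(self):
        rng = np.random.default_rng(4)
        ids = [f"a{i:02d}" for i in range(40)]
        expr = pd.DataFrame(rng.uniform(1, 10, size=(10, 40)),
                            index=pd.Index([f"g{j}" for j in range(10)],
                                           name="model"), columns=ids)
        trait = pd.Series(rng.normal(size=40), index=ids)
        report = TakeOneOutGEM(trait, expr).run()
        assert report.fallback_fraction == 1.0
        assert report.r2 == pytest.approx(0.0, abs=0.05)

    def test_no_leakage_of_left_out_expression(self):
        expr, trait = _expression_panel(noise=0.4, seed=5)
        base = TakeOneOutGEM(trait, expr).run()
        poisoned = expr.copy()
        acc0 = expr.columns[0]
        # poisoning the left-out accession's expression must not change the
        # per-round fit; only the final lookup uses it
        fits_change = poisoned.copy()
        fits_change.loc["null00", acc0] = 1e6
        alt = TakeOneOutGEM(trait, fits_change).run()
        # the causal gene's prediction for acc0 is untouched
        assert alt.frame["n_markers"].iloc[0] == \
            base.frame["n_markers"].iloc[0]
        assert alt.frame["predicted"].iloc[0] == pytest.approx(
            base.frame["predicted"].iloc[0])
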