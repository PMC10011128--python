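"""Burden counting and the Firth-penalized regression."""

import numpy as np
import pandas as pd
import pytest

from burdenmeta.annotation import RareVariantConfig
from burdenmeta.burden import (CLASS_MEMBERS, baseline_class, count_rare_burden,
                               firth_logistic_fit, global_enrichment_test,
                               _penalized_loglik)
from burdenmeta.cohort import MISSING, CohortBundle, TruthRecord


def _toy_cohort():
    """3 samples x 4 variants, hand-checkable."""
    variants = pd.DataFrame({
        "chrom": "1", "pos": [100, 200, 300, 400], "ref": "A", "alt": "G",
        "gene": ["g1", "g1", "g2", "g2"],
        "consequence": ["stop_gained"] * 3 + ["synonymous_variant"],
        "mpc": np.nan,
        "variant_class": ["PTV", "PTV", "PTV", "synonymous"],
    }, index=pd.Index([f"v{i}" for i in range(4)], name="variant_id"))
    dosages = np.array([[1, 1, 2, 0],
                        [0, 0, 0, 1],
                        [0, MISSING, 1, 0]], dtype=np.int8)
    depths = np.full_like(dosages, 30, dtype=np.int32)
    samples = pd.DataFrame({"phenotype": [1, 0, 0]},
                           index=pd.Index(["a", "b", "c"], name="sample_id"))
    panel = pd.DataFrame({"pli": [0.99, 0.1], "constrained": [True, False]},
                         index=pd.Index(["g1", "g2"], name="gene"))
    return CohortBundle(dosages=dosages, depths=depths, samples=samples,
                        variants=variants, panel=panel, truth=TruthRecord())


class TestCounting:
    def test_dosage_sum_example(self):
        cohort = _toy_cohort()
        counts = count_rare_burden(cohort, {"g1", "g2"}, "PTV")
        # sample a: het+het+hom = 4; b: 0; c: missing contributes 0, plus 1
        assert counts.tolist() == [4, 0, 1]

    def test_rarity_filter_drops_common_variant(self):
        cohort = _toy_cohort()
        counts = count_rare_burden(cohort, {"g1", "g2"}, "PTV",
                                   RareVariantConfig(mode="mac", mac_max=1))
        # v2 (alt count 3) no longer rare; v0 (count 1) and v1 (count 1) remain
        assert counts.tolist() == [2, 0, 0]

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError):
            count_rare_burden(_toy_cohort(), set(), "PTV")

    def test_counts_match_brute_force(self, small_cohort):
        cfg = RareVariantConfig(mode="mac", mac_max=5)
        gene_set = set(small_cohort.panel.index[:10])
        counts = count_rare_burden(small_cohort, gene_set, "PTV", cfg)
        called = small_cohort.dosages != MISSING
        alt = np.where(called, small_cohort.dosages, 0).sum(0)
        tot = 2 * called.sum(0)
        expected = np.zeros(len(small_cohort.samples))
        for j, (vid, row) in enumerate(small_cohort.variants.iterrows()):
            if (row["gene"] in gene_set and row["variant_class"] == "PTV"
                    and min(alt[j], tot[j] - alt[j]) <= 5):
                col = small_cohort.dosages[:, j]
                expected += np.where(col == MISSING, 0, col)
        assert np.array_equal(counts.to_numpy(), expected)

    def test_class_sum_identity(self, small_cohort):
        """burden(PTV) + burden(missense) + burden(synonymous) = burden(coding)."""
        gene_set = set(small_cohort.panel.index)
        total = sum(count_rare_burden(small_cohort, gene_set, c)
                    for c in ("PTV", "missense", "synonymous"))
        coding = count_rare_burden(small_cohort, gene_set, "coding")
        assert np.array_equal(total.to_numpy(), coding.to_numpy())

    def test_baseline_pairing_rule(self):
        assert baseline_class("PTV") == "synonymous"
        assert baseline_class("missense_tier2") == "synonymous"
        assert baseline_class("synonymous") == "nonsynonymous"
        assert set(CLASS_MEMBERS["nonsynonymous"]) == {
            "PTV", "missense_tier1", "missense_tier2", "missense_nondamaging"}


def _grid_maximize(X, y, b_range, a_range, steps=41, refinements=6):
    """Nested-grid maximization of the penalized likelihood (2-parameter)."""
    best = None
    a_lo, a_hi = a_range
    b_lo, b_hi = b_range
    for _ in range(refinements):
        aa = np.linspace(a_lo, a_hi, steps)
        bb = np.linspace(b_lo, b_hi, steps)
        vals = np.array([[_penalized_loglik(np.array([a, b]), X, y) for b in bb]
                         for a in aa])
        i, j = np.unravel_index(np.argmax(vals), vals.shape)
        best = (aa[i], bb[j])
        da, db = (a_hi - a_lo) / (steps - 1), (b_hi - b_lo) / (steps - 1)
        a_lo, a_hi = best[0] - da, best[0] + da
        b_lo, b_hi = best[1] - db, best[1] + db
    return best


class TestFirth:
    def test_null_data_small_coefficient(self):
        rng = np.random.default_rng(0)
        n = 400
        x = rng.poisson(0.6, n).astype(float)
        y = rng.integers(0, 2, n).astype(float)
        X = np.c_[np.ones(n), x]
        fit = firth_logistic_fit(y, X, ci_method="wald")
        assert abs(fit.coefficients[1]) < 3 * fit.standard_errors[1]
        assert 0 < fit.p_value <= 1

    def test_separation_stays_finite_and_matches_grid_oracle(self):
        """Complete separation: finite estimate agreeing with brute-force
        maximization of the penalized likelihood."""
        n = 40
        y = np.r_[np.ones(20), np.zeros(20)]
        x = np.zeros(n)
        x[:5] = 1  # all five carriers are cases -> ordinary ML diverges
        X = np.c_[np.ones(n), x]
        fit = firth_logistic_fit(y, X)
        assert np.isfinite(fit.coefficients).all()
        assert np.isfinite(fit.standard_errors).all()
        a, b = _grid_maximize(X, y, b_range=(0.0, 6.0), a_range=(-2.0, 2.0))
        assert abs(fit.coefficients[1] - b) < 1e-4
        assert abs(fit.coefficients[0] - a) < 1e-4

    def test_large_sample_agrees_with_unpenalized_ml(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        n = 20_000
        x = rng.poisson(0.5, n)
        base = rng.poisson(1.0, n)
        eta = -0.4 + np.log(1.5) * x
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        X = np.c_[np.ones(n), x, base]
        fit = firth_logistic_fit(y, X, ci_method="wald")
        ml = sm.Logit(y, X).fit(disp=0)
        assert abs(fit.coefficients[1] - ml.params[1]) < 0.01
        # and within Monte-Carlo distance of the truth
        assert abs(fit.coefficients[1] - np.log(1.5)) < 3 * fit.standard_errors[1]

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        n = 300
        x = rng.poisson(0.5, n).astype(float)
        z = rng.normal(size=n)
        y = rng.integers(0, 2, n).astype(float)
        X1 = np.c_[np.ones(n), x, z]
        X2 = np.c_[np.ones(n), x, 100.0 * z + 7.0]
        f1 = firth_logistic_fit(y, X1, ci_method="wald")
        f2 = firth_logistic_fit(y, X2, ci_method="wald")
        assert f1.p_value == pytest.approx(f2.p_value, abs=1e-8)
        assert f1.coefficients[1] == pytest.approx(f2.coefficients[1], abs=1e-8)

    def test_rank_deficiency_names_column(self):
        n = 50
        x = np.arange(n, dtype=float)
        X = np.c_[np.ones(n), x, 2 * x]
        with pytest.raises(ValueError, match="dup"):
            firth_logistic_fit(np.zeros(n), X, columns=("i", "x", "dup"))

    def test_wald_and_lrt_agree_in_large_samples(self):
        rng = np.random.default_rng(3)
        n = 5000
        x = rng.poisson(0.8, n).astype(float)
        eta = -0.2 + 0.08 * x
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        X = np.c_[np.ones(n), x]
        lrt = firth_logistic_fit(y, X, pvalue_method="lrt", ci_method="wald")
        wald = firth_logistic_fit(y, X, pvalue_method="wald", ci_method="wald")
        assert np.log10(lrt.p_value) == pytest.approx(np.log10(wald.p_value), abs=0.2)

    def test_p_monotone_in_planted_effect(self):
        """p decreases along the OR grid 1.0 / 1.25 / 1.5 / 2.0."""
        rng = np.random.default_rng(4)
        n = 4000
        x = rng.poisson(0.5, n).astype(float)
        ps = []
        for orr in (1.0, 1.25, 1.5, 2.0):
            eta = -0.1 + np.log(orr) * x
            rng2 = np.random.default_rng(99)  # shared noise for smoothness
            y = (rng2.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            fit = firth_logistic_fit(y, np.c_[np.ones(n), x], ci_method="wald")
            ps.append(fit.p_value)
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestEnrichmentReport:
    def test_report_row_contents(self, small_cohort):
        from burdenmeta.ancestry import compute_pcs

        common = small_cohort.variants.index[
            small_cohort.variants["consequence"] == "intron_variant"]
        sub = small_cohort.subset_variants(common)
        pcs = compute_pcs(sub.dosages, sub.sample_ids, 5).scores
        out = global_enrichment_test(small_cohort, pcs, variant_class="PTV",
                                     ci_method="wald")
        row = out.iloc[0]
        assert row["n_case"] == 200 and row["n_control"] == 200
        assert row["ci_low"] <= row["odds_ratio"] <= row["ci_high"]
        assert 0 < row["p_value"] <= 1
        assert row["n_variants"] > 0

    def test_permuted_phenotype_is_null(self, small_cohort):
        from burdenmeta.ancestry import compute_pcs

        rng = np.random.default_rng(7)
        common = small_cohort.variants.index[
            small_cohort.variants["consequence"] == "intron_variant"]
        sub = small_cohort.subset_variants(common)
        pcs = compute_pcs(sub.dosages, sub.sample_ids, 5).scores
        ps = []
        for _ in range(8):
            shuffled = small_cohort.samples.copy()
            shuffled["phenotype"] = rng.permutation(shuffled["phenotype"].to_numpy())
            permuted = CohortBundle(dosages=small_cohort.dosages,
                                    depths=small_cohort.depths, samples=shuffled,
                                    variants=small_cohort.variants,
                                    panel=small_cohort.panel, truth=small_cohort.truth)
            out = global_enrichment_test(permuted, pcs, variant_class="PTV",
                                         ci_method="wald")
            ps.append(out["p_value"].iloc[0])
        assert min(ps) > 1e-4  # no spurious strong signal under permutation
        assert max(ps) > 0.1
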