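"""Sample/site/genotype QC rules and relatedness pruning."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from burdenmeta.cohort import MISSING
from burdenmeta.qc import (METRIC_COLUMNS, SampleQCThresholds, apply_sample_qc,
                           apply_site_filter, compare_exclusions_by_phenotype,
                           flag_pairs, prune_relatives, resolve_no_calls)
from burdenmeta.simulate import SimulationConfig, plant_qc_outliers, simulate_cohort


def _passing_metrics(n, index=None):
    idx = index if index is not None else [f"S{i}" for i in range(n)]
    return pd.DataFrame({
        "mapped_reads": 2e6, "mean_depth": 60.0, "on_target": 92.0,
        "uniformity": 85.0, "missing_call_rate": 0.02, "inbreeding_f": 0.02,
        "het_hom_ratio": 1.8, "total_snps": 1500, "total_indels": 60,
    }, index=idx)


class TestNoCallResolution:
    def test_depth_rule_is_strictly_greater_than_ten(self):
        dosages = np.array([[MISSING, MISSING, 1]], dtype=np.int8)
        depths = np.array([[11, 10, 3]], dtype=np.int32)
        out = resolve_no_calls(dosages, depths)
        assert out.tolist() == [[0, MISSING, 1]]

    def test_called_genotypes_untouched(self):
        dosages = np.array([[0, 1, 2]], dtype=np.int8)
        out = resolve_no_calls(dosages, np.array([[1, 1, 1]]))
        assert out.tolist() == [[0, 1, 2]]

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            resolve_no_calls(np.zeros((1, 1), np.int8), np.array([[-1]]))

    def test_idempotent(self, toy_genotypes):
        dosages, depths = toy_genotypes
        dosages = dosages.copy()
        dosages[0, 0] = MISSING
        once = resolve_no_calls(dosages, depths)
        assert np.array_equal(once, resolve_no_calls(once, depths))


class TestSampleQC:
    def test_single_violation_named(self):
        m = _passing_metrics(2)
        m.loc["S0", "mean_depth"] = 39
        retained, excluded = apply_sample_qc(m)
        assert list(retained) == ["S1"]
        assert excluded.loc["S0", "reasons"] == "mean_depth"

    def test_boundaries_are_strict(self):
        m = _passing_metrics(1)
        m.iloc[0] = [400_000, 40, 80, 65, 0.3, 0.6, 0.6, 400, 10]
        retained, excluded = apply_sample_qc(m)
        assert len(retained) == 1 and excluded.empty

    def test_multiple_reasons_listed(self):
        m = _passing_metrics(1)
        m.loc[:, ["mean_depth", "total_snps"]] = [10, 100]
        _, excluded = apply_sample_qc(m)
        assert set(excluded.iloc[0, 0].split(";")) == {"mean_depth", "total_snps"}

    def test_missing_metric_errors_with_names(self):
        m = _passing_metrics(2).drop(columns=["uniformity"])
        with pytest.raises(ValueError, match="uniformity"):
            apply_sample_qc(m)
        m2 = _passing_metrics(2)
        m2.loc["S1", "on_target"] = np.nan
        with pytest.raises(ValueError, match="S1"):
            apply_sample_qc(m2)

    def test_idempotent_on_retained(self):
        m = _passing_metrics(5)
        m.loc["S2", "het_hom_ratio"] = 0.1
        retained, _ = apply_sample_qc(m)
        again, excluded2 = apply_sample_qc(m.loc[retained])
        assert list(again) == list(retained) and excluded2.empty

    def test_planted_outliers_recovered_exactly(self):
        """Closed loop with the generator: the planted ids and nobody else."""
        cfg = SimulationConfig(n_cases=500, n_controls=500, n_genes=10,
                               n_common_snps=20, n_qc_outliers=10,
                               per_call_depth=False, seed=9)
        cohort = simulate_cohort(cfg)
        retained, excluded = apply_sample_qc(cohort.samples[list(METRIC_COLUMNS)])
        assert set(excluded.index) == set(cohort.truth.planted_outlier_ids)
        assert len(excluded) == 10

    def test_no_planted_outliers_means_no_exclusions(self):
        cfg = SimulationConfig(n_cases=300, n_controls=300, n_genes=10,
                               n_common_snps=20, n_qc_outliers=0,
                               per_call_depth=False, seed=10)
        cohort = simulate_cohort(cfg)
        _, excluded = apply_sample_qc(cohort.samples[list(METRIC_COLUMNS)])
        assert excluded.empty


class TestSiteFilter:
    def test_boundary_strictly_greater_than_ten_percent(self):
        dosages = np.zeros((100, 2), dtype=np.int8)
        dosages[:11, 0] = MISSING
        dosages[:10, 1] = MISSING
        keep, drop = apply_site_filter(dosages, pd.Index(["v1", "v2"]))
        assert list(drop) == ["v1"] and list(keep) == ["v2"]

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(11)
        dosages = rng.integers(0, 3, size=(80, 500)).astype(np.int8)
        mask = rng.random(dosages.shape) < 0.05
        dosages[mask] = MISSING
        ids = pd.Index([f"v{i}" for i in range(500)])
        keep, drop = apply_site_filter(dosages, ids)
        for j, vid in enumerate(ids):
            frac = sum(1 for x in dosages[:, j] if x == MISSING) / 80
            assert (vid in drop) == (frac > 0.10)

    def test_idempotent(self):
        rng = np.random.default_rng(12)
        dosages = rng.integers(0, 3, size=(40, 50)).astype(np.int8)
        dosages[rng.random(dosages.shape) < 0.15] = MISSING
        ids = pd.Index([f"v{i}" for i in range(50)])
        keep, _ = apply_site_filter(dosages, ids)
        cols = ids.get_indexer(keep)
        keep2, drop2 = apply_site_filter(dosages[:, cols], keep)
        assert list(keep2) == list(keep) and len(drop2) == 0


class TestExclusionChiSquare:
    def test_published_p_value(self):
        """Case/control QC-exclusion rates: continuity-corrected p = 0.1878."""
        _, p = compare_exclusions_by_phenotype(55, 12_045, 38, 11_212)
        assert round(p, 4) == pytest.approx(0.1878)

    def test_identical_proportions_near_one(self):
        stat, p = compare_exclusions_by_phenotype(10, 100, 10, 100)
        assert p >= 0.95

    def test_against_closed_form_oracle(self):
        # Yates statistic assembled by hand, p from the 1-df chi-square CDF
        a, na, c, nc = 20, 100, 5, 100
        tab = np.array([[a, na - a], [c, nc - c]], dtype=float)
        n = tab.sum()
        exp = np.outer(tab.sum(1), tab.sum(0)) / n
        stat = ((np.abs(tab - exp) - 0.5) ** 2 / exp).sum()
        got_stat, got_p = compare_exclusions_by_phenotype(a, na, c, nc)
        assert got_stat == pytest.approx(stat, rel=1e-10)
        assert got_p == pytest.approx(stats.chi2.sf(stat, 1), rel=1e-10)

    def test_uncorrected_option(self):
        _, p = compare_exclusions_by_phenotype(55, 12_045, 38, 11_212,
                                               continuity_correction=False)
        assert p < 0.1878

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            compare_exclusions_by_phenotype(5, 0, 1, 10)
        with pytest.raises(ValueError):
            compare_exclusions_by_phenotype(11, 10, 1, 10)


def _attrs(rows):
    return pd.DataFrame(rows).set_index("id")


class TestPruneRelatives:
    def test_case_preferred_over_control(self):
        pairs = pd.DataFrame({"id_a": ["S1"], "id_b": ["S2"]})
        attrs = _attrs([
            {"id": "S1", "n_relatives": 1, "phenotype": 0, "has_snp_array": True,
             "has_sex": True, "rare_missingness": 0.0},
            {"id": "S2", "n_relatives": 1, "phenotype": 1, "has_snp_array": False,
             "has_sex": False, "rare_missingness": 0.5},
        ])
        assert list(prune_relatives(pairs, attrs)) == ["S2"]

    def test_lexicographic_tiebreak(self):
        pairs = pd.DataFrame({"id_a": ["S002"], "id_b": ["S001"]})
        base = {"n_relatives": 1, "phenotype": 1, "has_snp_array": True,
                "has_sex": True, "rare_missingness": 0.1}
        attrs = _attrs([{"id": "S001", **base}, {"id": "S002", **base}])
        assert list(prune_relatives(pairs, attrs)) == ["S001"]

    def test_control_hub_dropped_once(self):
        pairs = pd.DataFrame({"id_a": ["A", "B"], "id_b": ["B", "C"]})
        mk = lambda i, ph, nr: {"id": i, "n_relatives": nr, "phenotype": ph,
                                "has_snp_array": False, "has_sex": False,
                                "rare_missingness": 0.0}
        attrs = _attrs([mk("A", 1, 1), mk("B", 0, 2), mk("C", 1, 1)])
        assert list(prune_relatives(pairs, attrs)) == ["A", "C"]

    def test_no_flagged_pair_survives_random_graphs(self):
        rng = np.random.default_rng(13)
        for trial in range(10):
            n = 20
            ids = [f"S{i:02d}" for i in range(n)]
            attrs = _attrs([
                {"id": i, "n_relatives": 0, "phenotype": int(rng.random() < 0.5),
                 "has_snp_array": bool(rng.random() < 0.5),
                 "has_sex": bool(rng.random() < 0.5),
                 "rare_missingness": float(rng.random())} for i in ids])
            edges = set()
            while len(edges) < 12:
                a, b = rng.choice(n, 2, replace=False)
                edges.add((ids[min(a, b)], ids[max(a, b)]))
            pairs = pd.DataFrame(sorted(edges), columns=["id_a", "id_b"])
            counts = pd.concat([pairs["id_a"], pairs["id_b"]]).value_counts()
            attrs["n_relatives"] = [int(counts.get(i, 0)) for i in ids]
            kept = set(prune_relatives(pairs, attrs))
            for a, b in edges:
                assert not (a in kept and b in kept)

    def test_unknown_sample_rejected(self):
        pairs = pd.DataFrame({"id_a": ["S1"], "id_b": ["ghost"]})
        attrs = _attrs([{"id": "S1", "n_relatives": 1, "phenotype": 1,
                         "has_snp_array": True, "has_sex": True,
                         "rare_missingness": 0.0}])
        with pytest.raises(ValueError):
            prune_relatives(pairs, attrs)


def test_flag_pairs_threshold():
    kin = pd.DataFrame({"id_a": ["a", "a"], "id_b": ["b", "c"],
                        "kinship": [0.0442, 0.0441]})
    assert len(flag_pairs(kin)) == 1
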