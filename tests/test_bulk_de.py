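"""NB Wald differential expression: size factors, GLM oracle, calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dtcsig.bulk_de import (bh_adjust, estimate_dispersions, nb_wald_test,
                            size_factors)
from dtcsig.io import CountMatrix, SampleSheet, ValidationError
from dtcsig.simulate import BulkSimConfig, simulate_bulk_models


class TestSizeFactors:
    def test_pure_scaling_recovered(self):
        c1 = np.array([5, 10, 50])
        arr = np.column_stack([c1, 2 * c1])
        f = size_factors(arr)
        assert f[1] / f[0] == pytest.approx(2.0)

    def test_single_sample_is_one(self):
        assert size_factors(np.array([[4], [2]]))[0] == 1.0

    def test_median_of_ratios_by_hand(self):
        # counts [[2,4],[8,16],[2,2]]; geometric means (sqrt8, sqrt128, 2)
        # ratios col1: {2/sqrt8, 8/sqrt128, 1} -> median 1/sqrt2
        arr = np.array([[2, 4], [8, 16], [2, 2]])
        f = size_factors(arr)
        assert f[0] == pytest.approx(np.median([2 / np.sqrt(8),
                                                8 / np.sqrt(128), 1.0]))
        assert f[1] == pytest.approx(np.median([4 / np.sqrt(8),
                                                16 / np.sqrt(128), 1.0]))

    def test_no_common_nonzero_gene_advises_fallback(self):
        arr = np.array([[3, 0], [0, 5]])
        with pytest.raises(ValidationError, match="pseudo"):
            size_factors(arr)
        f = size_factors(arr, allow_pseudo_reference=True)
        assert (f > 0).all()


class TestBh:
    def _brute_force(self, p):
        # literal step-up definition: padj_i = min over j with p_j >= p_i of
        # min(1, n*p_j/rank_j)
        n = len(p)
        order = np.argsort(p)
        adj = np.empty(n)
        running = 1.0
        for rank_from_top in range(n - 1, -1, -1):
            i = order[rank_from_top]
            running = min(running, n * p[i] / (rank_from_top + 1))
            adj[i] = running
        return adj

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_brute_force_definition(self, p):
        p = np.array(p)
        assert np.allclose(bh_adjust(p), self._brute_force(p))

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(0)
        p = rng.random(40)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestWald:
    def test_identical_groups_lfc_zero_p_one(self):
        counts = np.array([[5, 5, 5, 5], [9, 9, 9, 9], [3, 3, 3, 3]])
        cm = CountMatrix(["A", "B", "C"], ["c1", "c2", "t1", "t2"], counts)
        sheet = SampleSheet(pd.DataFrame({
            "sample_id": ["c1", "c2", "t1", "t2"], "model_id": "m",
            "condition": ["control", "control", "DTC", "DTC"]}))
        t = nb_wald_test(cm, sheet, ("DTC", "control")).table
        assert t["log2fc"].abs().max() == 0.0
        assert (t["p_value"] == 1.0).all()

    def test_contrast_swap_negates_lfc_keeps_p(self, tiny_counts):
        cm, sheet = tiny_counts
        a = nb_wald_test(cm, sheet, ("DTC", "control")).table
        b = nb_wald_test(cm, sheet, ("control", "DTC")).table
        assert np.allclose(a["log2fc"], -b["log2fc"])
        assert np.allclose(a["p_value"], b["p_value"])

    def test_sample_scaling_absorbed_by_normalization(self, tiny_counts):
        cm, sheet = tiny_counts
        scaled = CountMatrix(cm.gene_ids, cm.sample_ids,
                             cm.counts * np.array([1, 1, 3, 3]))
        a = nb_wald_test(cm, sheet, ("DTC", "control")).table
        b = nb_wald_test(scaled, sheet, ("DTC", "control")).table
        assert np.allclose(a["log2fc"], b["log2fc"], atol=1e-8)

    def test_all_zero_gene_gets_na_and_skips_bh(self, tiny_counts):
        cm, sheet = tiny_counts
        withzero = CountMatrix(cm.gene_ids + ["GZ"], cm.sample_ids,
                               np.vstack([cm.counts, np.zeros(4, int)]))
        t = nb_wald_test(withzero, sheet, ("DTC", "control")).table
        assert np.isnan(t.loc["GZ", "p_value"])
        assert t.loc[["GA", "GB", "GC"], "p_value"].notna().all()

    def test_unknown_condition_rejected(self, tiny_counts):
        cm, sheet = tiny_counts
        with pytest.raises(ValidationError, match="absent"):
            nb_wald_test(cm, sheet, ("RPC", "control"))

    def test_glm_fit_matches_statsmodels_oracle(self):
        """The vectorized IRLS must reproduce statsmodels' NB GLM coefficient
        and Wald SE when run at the same fixed dispersion."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        y = rng.negative_binomial(10, 0.3, size=8)  # one gene, 4 vs 4
        x = np.repeat([0, 1], 4)
        alpha = 0.15
        cm = CountMatrix(["G1"], [f"s{i}" for i in range(8)], y[None, :])
        sheet = SampleSheet(pd.DataFrame({
            "sample_id": cm.sample_ids, "model_id": "m",
            "condition": ["control"] * 4 + ["DTC"] * 4}))
        from dtcsig.bulk_de import _fit_group_mean
        sf = np.ones(8)
        m_c = _fit_group_mean(y[None, :4].astype(float), sf[:4],
                              np.array([alpha]))[0]
        m_t = _fit_group_mean(y[None, 4:].astype(float), sf[4:],
                              np.array([alpha]))[0]
        X = np.column_stack([np.ones(8), x])
        fit = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha)).fit()
        assert np.log(m_c) == pytest.approx(fit.params[0], rel=1e-5)
        assert np.log(m_t) - np.log(m_c) == pytest.approx(fit.params[1], rel=1e-5)
        mu_c, mu_t = m_c, m_t
        info_c = 4 * mu_c / (1 + alpha * mu_c)
        info_t = 4 * mu_t / (1 + alpha * mu_t)
        se = np.sqrt(1 / info_c + 1 / info_t)
        assert se == pytest.approx(fit.bse[1], rel=1e-5)

    def test_planted_fold_change_recovered_at_large_n(self):
        # balanced up/down program so the library composition shift that
        # median-of-ratios normalization cannot remove stays negligible
        cfg = BulkSimConfig(n_models=1, genes_total=300, n_up_planted=15,
                            n_down_planted=15, dropout_models_per_gene=0,
                            effect_log2fc=2.0, samples_per_condition=40,
                            library_size_mean=3e5, seed=21)
        mats, sheet, truth = simulate_bulk_models(cfg)
        t = nb_wald_test(mats[0], sheet, ("DTC", "control")).table
        assert t.loc[truth.planted_up, "log2fc"].mean() == pytest.approx(2.0, abs=0.1)
        assert t.loc[truth.planted_down, "log2fc"].mean() == pytest.approx(-2.0, abs=0.1)

    def test_null_type_one_error_calibrated(self):
        cfg = BulkSimConfig(n_models=1, genes_total=2000, n_up_planted=0,
                            n_down_planted=0, dropout_models_per_gene=0,
                            library_size_mean=8e5, seed=33)
        mats, sheet, _ = simulate_bulk_models(cfg)
        p = nb_wald_test(mats[0], sheet, ("DTC", "control")).table["p_value"]
        frac = (p.dropna() < 0.05).mean()
        assert abs(frac - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / len(p.dropna()))

    def test_null_p_values_uniform(self):
        from scipy import stats
        cfg = BulkSimConfig(n_models=1, genes_total=5000, n_up_planted=0,
                            n_down_planted=0, dropout_models_per_gene=0,
                            seed=11)
        mats, sheet, _ = simulate_bulk_models(cfg)
        p = nb_wald_test(mats[0], sheet, ("DTC", "control")).table["p_value"]
        assert stats.kstest(p.dropna(), "uniform").pvalue > 0.01


class TestDispersion:
    def test_pooled_estimate_near_truth(self):
        cfg = BulkSimConfig(n_models=1, genes_total=3000, n_up_planted=0,
                            n_down_planted=0, dropout_models_per_gene=0,
                            nb_dispersion=0.1, samples_per_condition=5,
                            library_size_mean=3e6, seed=17)
        mats, _, _ = simulate_bulk_models(cfg)
        arr = mats[0].counts.astype(float)
        norm = arr / size_factors(arr)[None, :]
        groups = [np.arange(5), np.arange(5, 10)]
        alpha = estimate_dispersions(norm, groups)
        assert np.median(alpha) == pytest.approx(0.1, rel=0.25)

    def test_floor_applied(self):
        norm = np.tile([10.0, 10, 10, 10], (5, 1))  # zero variance
        alpha = estimate_dispersions(norm, [np.array([0, 1]), np.array([2, 3])])
        assert (alpha >= 1e-8).all()
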