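"""Weighted-KS enrichment: brute-force oracle, symmetries, permutation p."""

import numpy as np
import pandas as pd
import pytest

from dtcsig.bulk_de import DETable
from dtcsig.enrichment import (EnrichmentResult, enrichment_score,
                               es_from_positions, nes_and_p, rank_genes,
                               sharing_count)
from dtcsig.io import ValidationError


def _ranked(scores, genes=None):
    genes = genes or [f"G{i:03d}" for i in range(len(scores))]
    tab = DETable(pd.DataFrame({"base_mean": 1.0, "log2fc": scores,
                                "p_value": 0.5, "p_adjusted": 0.5},
                               index=pd.Index(genes, name="gene")))
    return rank_genes(tab)


def brute_force_es(scores, hit_mask, weight_p):
    """Literal running-sum enumeration (independent of the implementation)."""
    scores = np.asarray(scores, float)
    hit = np.asarray(hit_mask, bool)
    n, k = len(scores), hit.sum()
    w = np.abs(scores) ** weight_p
    nr = w[hit].sum()
    if nr == 0:
        w = np.ones(n)
        nr = float(k)
    running, cur, best = [], 0.0, 0.0
    for i in range(n):
        cur += w[i] / nr if hit[i] else -1.0 / (n - k)
        running.append(cur)
    running = np.array(running)
    return running[np.argmax(np.abs(running))]


class TestRankGenes:
    def test_order_and_tie_break(self):
        r = _ranked([1.0, -1.0, 0.0], ["A", "B", "C"])
        assert list(r.index) == ["A", "C", "B"]
        r = _ranked([1.0, 1.0], ["B", "A"])
        assert list(r.index) == ["A", "B"]

    def test_matches_independent_sort(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=30)
        genes = [f"G{i}" for i in range(30)]
        r = _ranked(list(scores), genes)
        expect = [g for _, g in sorted(zip(-scores, genes))]
        assert list(r.index) == expect

    def test_signed_logp_metric(self):
        tab = DETable(pd.DataFrame({
            "base_mean": 1.0, "log2fc": [1.0, -1.0], "p_value": [0.01, 0.001],
            "p_adjusted": [0.02, 0.002]}, index=pd.Index(["A", "B"])))
        r = rank_genes(tab, metric="signed_logp")
        assert r["A"] == pytest.approx(2.0)
        assert r["B"] == pytest.approx(-3.0)


class TestEnrichmentScore:
    def test_single_top_gene_es_is_plus_one(self):
        r = _ranked([3.0, 2.0, 1.0, 0.5])
        es, _ = enrichment_score(r, [r.index[0]])
        assert es == 1.0

    def test_single_bottom_gene_equal_scores_by_enumeration(self):
        # N=10 equal-magnitude scores; set = bottom gene: oracle running sum
        scores = [1.0] * 10
        r = _ranked(scores)
        es, _ = enrichment_score(r, [r.index[-1]])
        hit = np.zeros(10, bool)
        hit[-1] = True
        assert es == pytest.approx(brute_force_es(np.ones(10), hit, 1.0))
        assert es == pytest.approx(-9 / 9)  # deficit right before the last hit

    def test_whole_universe_set_scores_one(self):
        r = _ranked([2.0, 1.0, -1.0])
        es, running = enrichment_score(r, list(r.index))
        assert es == pytest.approx(1.0)
        assert running[-1] == pytest.approx(1.0)

    def test_no_member_in_universe_rejected(self):
        r = _ranked([1.0, 2.0])
        with pytest.raises(ValidationError):
            enrichment_score(r, ["ABSENT"])

    @pytest.mark.parametrize("weight_p", [0.0, 1.0])
    def test_matches_brute_force_on_random_instances(self, weight_p):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = rng.integers(5, 20)
            scores = np.round(rng.normal(size=n), 3)
            r = _ranked(list(scores))
            k = int(rng.integers(1, n))
            members = list(rng.choice(r.index, k, replace=False))
            es, _ = enrichment_score(r, members, weight_p=weight_p)
            hit = np.isin(r.index, members)
            assert es == pytest.approx(
                brute_force_es(r.to_numpy(), hit, weight_p))

    def test_complement_symmetry_unweighted(self):
        # with weight_p=0 the set and its complement have opposite ES
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(4, 20))
            r = _ranked(list(np.round(rng.normal(size=n), 3)))
            k = int(rng.integers(1, n))
            members = list(rng.choice(r.index, k, replace=False))
            rest = [g for g in r.index if g not in members]
            es_a, _ = enrichment_score(r, members, weight_p=0.0)
            es_b, _ = enrichment_score(r, rest, weight_p=0.0)
            assert es_a == pytest.approx(-es_b, abs=1e-12)

    def test_reversed_ranking_negates_unweighted_es(self):
        rng = np.random.default_rng(9)
        scores = np.round(rng.normal(size=12), 3)
        r = _ranked(list(scores))
        rev = pd.Series(r.to_numpy()[::-1], index=r.index[::-1])
        members = list(rng.choice(r.index, 4, replace=False))
        es_f, _ = enrichment_score(r, members, weight_p=0.0)
        es_r, _ = enrichment_score(rev, members, weight_p=0.0)
        assert es_f == pytest.approx(-es_r, abs=1e-12)

    def test_vectorized_positions_equal_profile_version(self):
        rng = np.random.default_rng(10)
        scores = np.sort(rng.normal(size=40))[::-1]
        r = _ranked(list(scores))
        for _ in range(20):
            k = int(rng.integers(1, 15))
            pos = rng.choice(40, k, replace=False)
            members = [r.index[i] for i in pos]
            es, _ = enrichment_score(r, members)
            fast = es_from_positions(pos[None, :],
                                     np.abs(r.to_numpy())[pos][None, :], 40)
            assert fast[0] == pytest.approx(es)


class TestPermutation:
    def test_determinism(self):
        r = _ranked(list(np.linspace(3, -3, 50)))
        members = list(r.index[:5])
        a = nes_and_p(r, members, n_perm=200, seed=4)
        b = nes_and_p(r, members, n_perm=200, seed=4)
        assert (a.es, a.nes, a.nominal_p) == (b.es, b.nes, b.nominal_p)

    def test_p_never_exactly_zero(self):
        # top-decile set of a strongly signed ranking: the observed ES is the
        # maximal +1, no null matches it, and the +1-corrected p attains its
        # floor 1/(1 + same-sign nulls) — close to, and never below,
        # 1/(1+n_perm), and never exactly zero
        r = _ranked(list(np.linspace(5, 0.1, 100)))
        res = nes_and_p(r, list(r.index[:10]), n_perm=500, seed=1)
        assert res.es == 1.0
        assert 1 / (1 + 500) <= res.nominal_p <= 1 / (1 + 400)
        assert res.nes > 1 and res.direction == "up"

    def test_small_n_perm_rejected(self):
        r = _ranked([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            nes_and_p(r, [r.index[0]], n_perm=50)


class TestSharing:
    def _res(self, name, model, nes, p):
        return EnrichmentResult(set_name=name, es=np.sign(nes) * 0.5, nes=nes,
                                nominal_p=p, n_hits=5, model_id=model)

    def test_unanimous_up(self):
        results = [self._res("S", f"m{i}", 2.0, 0.001) for i in range(7)]
        t = sharing_count(results)
        assert t.loc["S", "n_models_up"] == 7
        assert t.loc["S", "n_models_down"] == 0

    def test_mixed_directions_counted_separately(self):
        results = ([self._res("S", f"m{i}", 1.8, 0.01) for i in range(3)]
                   + [self._res("S", f"m{i+3}", -1.5, 0.01) for i in range(2)]
                   + [self._res("S", "m5", 1.9, 0.5),   # not significant
                      self._res("S", "m6", 0.8, 0.001)])  # |NES| <= 1
        t = sharing_count(results)
        assert (t.loc["S", "n_models_up"], t.loc["S", "n_models_down"]) == (3, 2)

    def test_most_shared_first(self):
        results = ([self._res("RARE", "m0", 2.0, 0.001)]
                   + [self._res("COMMON", f"m{i}", 2.0, 0.001) for i in range(4)])
        t = sharing_count(results)
        assert list(t.index) == ["COMMON", "RARE"]

    def test_planted_shared_program_reaches_all_models(self):
        """A gene program up-regulated in every simulated model is detected as
        shared 7/7 while random decoy sets stay rare."""
        from dtcsig.simulate import BulkSimConfig, simulate_bulk_models
        from dtcsig.bulk_de import nb_wald_test
        from dtcsig.io import SampleSheet

        cfg = BulkSimConfig(n_models=7, genes_total=600, n_up_planted=30,
                            n_down_planted=30, dropout_models_per_gene=0,
                            library_size_mean=6e5, seed=19)
        mats, sheet, truth = simulate_bulk_models(cfg)
        rng = np.random.default_rng(20)
        nonplanted = [g for g in mats[0].gene_ids
                      if g not in truth.planted_up + truth.planted_down]
        sets = {"PLANTED_UP": truth.planted_up}
        for d in range(4):
            sets[f"DECOY{d}"] = list(rng.choice(nonplanted, 30, replace=False))
        results = []
        for cm in mats:
            model = cm.sample_ids[0].rsplit("_", 2)[0]
            sub = SampleSheet(sheet.table[sheet.table["model_id"] == model])
            ranked = rank_genes(nb_wald_test(cm, sub, ("DTC", "control"),
                                             model_id=model))
            for name, members in sets.items():
                results.append(nes_and_p(ranked, members, set_name=name,
                                         n_perm=200, seed=100, model_id=model))
        t = sharing_count(results, p_threshold=0.05)
        assert t.loc["PLANTED_UP", "n_models_up"] == 7
        decoys = t.loc[[f"DECOY{d}" for d in range(4)]]
        assert (decoys["n_models_up"] <= 2).all()
        assert (decoys["n_models_down"] <= 2).all()
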