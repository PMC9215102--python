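import numpy as np
import pandas as pd
import pytest

from supertax import (
    BlockPartition, OtuMapping, OtuTable, SampleMetadata,
    compare_aic, fit_logistic, run_discovery, split_halves, verify,
)
from supertax.association import test_block as run_block_test
from supertax.depth_forest import ForestParams
from supertax.supertaxon import SuperTaxonFeature


class TestFitLogistic:
    def test_binary_predictor_reproduces_2x2_odds_ratio(self):
        # exposed: 30 cases / 10 controls; unexposed: 20 cases / 40 controls
        S = np.r_[np.ones(40), np.zeros(60)]
        y = np.r_[np.ones(30), np.zeros(10), np.ones(20), np.zeros(40)]
        res = fit_logistic(S, y)
        assert res.odds_ratio == pytest.approx((30 * 40) / (10 * 20), rel=1e-4)
        assert res.n == 100

    def test_ci_is_wald_interval(self, rng):
        S = rng.normal(size=200)
        y = (rng.random(200) < 1 / (1 + np.exp(-S))).astype(int)
        res = fit_logistic(S, y)
        assert res.ci95[0] == pytest.approx(np.exp(res.beta - 1.96 * res.se),
                                            rel=1e-3)
        assert res.ci95[1] == pytest.approx(np.exp(res.beta + 1.96 * res.se),
                                            rel=1e-3)
        assert res.odds_ratio == pytest.approx(np.exp(res.beta))

    def test_null_predictor_small_effect(self, rng):
        pvals = []
        for _ in range(40):
            S = rng.normal(size=150)
            y = rng.integers(0, 2, 150)
            pvals.append(fit_logistic(S, y).pvalue)
        # under the null, p-values are roughly uniform
        assert 0.2 < np.mean(pvals) < 0.8
        assert min(pvals) > 1e-6

    def test_matches_statsmodels_on_raw_scale(self, rng):
        import statsmodels.api as sm
        S = np.round(rng.gamma(2, 300, size=120))   # large raw counts
        y = rng.integers(0, 2, 120)
        res = fit_logistic(S, y)
        fit = sm.Logit(y, sm.add_constant((S - S.mean()) / S.std())).fit(disp=0)
        assert res.pvalue == pytest.approx(float(fit.pvalues[1]), rel=1e-6)
        assert res.beta == pytest.approx(float(fit.params[1]) / S.std(), rel=1e-6)

    def test_constant_feature_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(np.ones(10), np.r_[np.ones(5), np.zeros(5)])

    def test_separation_flagged_with_lrt(self):
        S = np.r_[np.ones(20), np.zeros(20)]
        y = np.r_[np.ones(20), np.zeros(20)]
        res = fit_logistic(S, y)
        assert res.flagged
        assert res.pvalue < 1e-6


class TestSplitHalves:
    def _meta(self, n0, n1):
        n = n0 + n1
        return SampleMetadata([f"s{i}" for i in range(n)],
                              np.r_[np.zeros(n0), np.ones(n1)])

    def test_stratified_even_split(self):
        meta = self._meta(400, 400)
        tr, te = split_halves(meta, 7)
        y = meta.labels
        assert len(tr) == len(te) == 400
        assert y[tr].sum() == y[te].sum() == 200

    def test_partition_property(self):
        meta = self._meta(31, 45)
        tr, te = split_halves(meta, 3)
        assert len(np.intersect1d(tr, te)) == 0
        assert len(np.union1d(tr, te)) == 76
        for k in (0, 1):
            nk_tr = (meta.labels[tr] == k).sum()
            nk_te = (meta.labels[te] == k).sum()
            assert abs(nk_tr - nk_te) <= 1

    def test_deterministic_and_seed_sensitive(self):
        meta = self._meta(50, 50)
        a1, _ = split_halves(meta, 5)
        a2, _ = split_halves(meta, 5)
        b1, _ = split_halves(meta, 6)
        assert np.array_equal(a1, a2)
        assert not np.array_equal(a1, b1)

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            split_halves(self._meta(1, 10), 0)


class TestTestBlock:
    def test_perfect_marker_is_significant_with_large_or(self, toy_cohort):
        table, meta, blocks = toy_cohort
        res = run_block_test(table, blocks["genusA"], meta, "STB",
                         ForestParams(n_trees=10, min_node_size=4, seed=0),
                         alpha=0.05, split_seed=1, block_id="genusA")
        assert res.significant
        assert res.test_result.odds_ratio > 5 or res.test_result.flagged

    def test_null_block_rarely_significant(self, toy_cohort):
        table, meta, blocks = toy_cohort
        hits = 0
        for seed in range(12):
            res = run_block_test(table, blocks["genusB"], meta, "STB",
                             ForestParams(n_trees=10, min_node_size=4, seed=seed),
                             alpha=0.0025, split_seed=seed)
            hits += int(res.significant)
        assert hits <= 1

    def test_single_otu_block_reduces_to_presence_test(self, toy_cohort):
        table, meta, _ = toy_cohort
        res = run_block_test(table, [0], meta, "STB",
                         ForestParams(n_trees=5, min_node_size=4, seed=0),
                         alpha=0.05, split_seed=2)
        # J=1: the only informative cutoff is c=2, S = presence of the OTU
        assert res.cutoff in (1, 2)
        if res.test_result is not None:
            assert set(np.unique(res.test_result.n)) is not None
            assert res.contributing_otus == [0]


class TestRunDiscovery:
    def _inputs(self, toy_cohort):
        table, meta, blocks = toy_cohort
        part = BlockPartition(level="genus", blocks=blocks)
        return table, part, meta

    def test_planted_block_is_stable(self, toy_cohort):
        table, part, meta = self._inputs(toy_cohort)
        rep = run_discovery(table, part, meta, mode="STB", n_repeats=2,
                            retain_threshold=2,
                            forest_params=ForestParams(n_trees=10,
                                                       min_node_size=4),
                            base_seed=0, alpha=0.05 / 3)
        assert "genusA" in rep.stable_blocks
        assert rep.selection_counts["genusA"] == 2
        assert "genusA" in rep.full_fit
        assert rep.full_fit["genusA"].cutoff is not None

    def test_single_repeat_reduces_to_single_split(self, toy_cohort):
        table, part, meta = self._inputs(toy_cohort)
        rep = run_discovery(table, part, meta, mode="STB", n_repeats=1,
                            retain_threshold=1,
                            forest_params=ForestParams(n_trees=10,
                                                       min_node_size=4),
                            base_seed=3)
        sig = {b for b, r in rep.repeats[0].items() if r.significant}
        assert set(rep.stable_blocks) == sig

    def test_reproducible_given_base_seed(self, toy_cohort):
        table, part, meta = self._inputs(toy_cohort)
        kw = dict(mode="STB", n_repeats=2, retain_threshold=1,
                  forest_params=ForestParams(n_trees=8, min_node_size=4),
                  base_seed=9)
        r1 = run_discovery(table, part, meta, **kw)
        r2 = run_discovery(table, part, meta, **kw)
        assert r1.selection_counts == r2.selection_counts
        for bid in r1.full_fit:
            assert (r1.full_fit[bid].test_result.pvalue
                    == r2.full_fit[bid].test_result.pvalue)


class TestVerify:
    def test_identity_mapping_reproduces_full_fit(self, toy_cohort):
        table, meta, blocks = toy_cohort
        part = BlockPartition(level="genus", blocks=blocks)
        rep = run_discovery(table, part, meta, mode="STB", n_repeats=2,
                            retain_threshold=1,
                            forest_params=ForestParams(n_trees=10,
                                                       min_node_size=4),
                            base_seed=0, alpha=0.05 / 3)
        assert rep.stable_blocks, "fixture should yield a stable block"
        # translate block-column positions to table-level ids
        for bid, fit in rep.full_fit.items():
            fit.contributing_otus = [part.blocks[bid][p]
                                     for p in fit.contributing_otus]
        mapping = OtuMapping.identity(table.otu_ids)
        rep = verify(rep, table, meta, mapping, table.otu_ids)
        for bid in rep.stable_blocks:
            full = rep.full_fit[bid].test_result
            ver = rep.verification_fit[bid].test_result
            assert ver.pvalue == pytest.approx(full.pvalue, rel=1e-9)
            assert ver.odds_ratio == pytest.approx(full.odds_ratio, rel=1e-9)

    def test_unmapped_otu_is_an_error(self, toy_cohort):
        table, meta, blocks = toy_cohort
        mapping = OtuMapping(pd.DataFrame({
            "discovery_otu_id": ["otu0"], "verification_otu_id": ["x"],
            "identity_score": [99.0]}))
        with pytest.raises(KeyError, match="otu1"):
            mapping.translate(["otu0", "otu1"])

    def test_best_identity_match_kept(self):
        mapping = OtuMapping(pd.DataFrame({
            "discovery_otu_id": ["a", "a", "b"],
            "verification_otu_id": ["v1", "v2", "v3"],
            "identity_score": [90.0, 97.5, 88.0]}))
        assert mapping.translate(["a", "b"]) == ["v2", "v3"]


class TestCompareAic:
    def test_shape_contract(self, toy_cohort):
        table, meta, _ = toy_cohort
        S = (table.values[:, 0] > 0) | (table.values[:, 1] > 0)
        feat = SuperTaxonFeature(mode="STB", cutoff=2, S=S.astype(float),
                                 contributing_otus=[0, 1])
        out = compare_aic(table, meta, feat)
        assert len(out) == 3
        assert out["model"].iloc[0] == "super-taxon"

    def test_joint_model_beats_marginals_with_two_effects(self):
        rng = np.random.default_rng(21)
        n = 300
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
        # two OTUs with independent presence effects
        p = np.where(y == 1, 0.45, 0.15)
        X = np.zeros((n, 2))
        for j in range(2):
            X[:, j] = (rng.random(n) < p) * rng.integers(1, 20, n)
        table = OtuTable(X, [f"s{i}" for i in range(n)], ["oA", "oB"])
        meta = SampleMetadata(table.sample_ids, y)
        S = (X > 0).any(axis=1).astype(float)
        feat = SuperTaxonFeature(mode="STB", cutoff=2, S=S,
                                 contributing_otus=[0, 1])
        out = compare_aic(table, meta, feat)
        joint = out.loc[out.model == "super-taxon", "aic"].iloc[0]
        singles = out.loc[out.model != "super-taxon", "aic"]
        assert joint < singles.min()

    def test_requires_two_contributing_otus(self, toy_cohort):
        table, meta, _ = toy_cohort
        feat = SuperTaxonFeature(mode="STB", cutoff=1,
                                 S=(table.values[:, 0] > 0).astype(float),
                                 contributing_otus=[0])
        with pytest.raises(ValueError):
            compare_aic(table, meta, feat)
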