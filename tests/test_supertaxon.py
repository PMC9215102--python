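import numpy as np
import pytest
import statsmodels.api as sm

from supertax.depth_forest import ImportanceRanking
from supertax.supertaxon import (
    compute_exposure, select_cutoff, stb_feature, stc_feature,
)
from tests.conftest import planted_block


def _ranking(order):
    return ImportanceRanking(block_id="g", order=np.asarray(order))


def _sm_slope_pvalue(S, y):
    """Independent re-fit of one candidate: statsmodels Wald p, or the
    statsmodels likelihood-ratio p when the slope diverges (for a
    two-valued predictor the slope diverges exactly when a cell of the
    2x2 table is empty)."""
    import warnings
    from scipy import stats

    uniq = np.unique(S)
    separated = False
    if len(uniq) == 2:
        pos = S == uniq[1]
        cells = [np.sum(pos & (y == 1)), np.sum(pos & (y == 0)),
                 np.sum(~pos & (y == 1)), np.sum(~pos & (y == 0))]
        separated = min(cells) == 0
    sd = S.std()
    X = sm.add_constant((S - S.mean()) / sd)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, X).fit(disp=0, maxiter=2000, warn_convergence=False)
        if (not separated and fit.mle_retvals.get("converged", True) and
                np.isfinite(fit.bse[1]) and abs(fit.params[1]) < 15):
            return float(fit.pvalues[1])
        fit0 = sm.Logit(y, X[:, [0]]).fit(disp=0)
    return float(stats.chi2.sf(max(2 * (fit.llf - fit0.llf), 0.0), 1))


class TestComputeExposure:
    # worked ordering d_g = (4,2,3,1,5): 0-based positions (3,1,2,0,4)
    D = _ranking([3, 1, 2, 0, 4])

    def test_second_ranked_otu_first_present(self):
        v = np.array([[0.0, 1.0, 0.0, 0.0, 0.0]])
        # rank-1 OTU is column 3 (absent), rank-2 is column 1 (present)
        assert compute_exposure(v, self.D).x.tolist() == [2]

    def test_all_absent_gets_j_plus_one(self):
        v = np.zeros((1, 5))
        assert compute_exposure(v, self.D).x.tolist() == [6]

    def test_top_ranked_present_gives_one(self):
        v = np.array([[0.0, 0.0, 0.0, 2.0, 0.0]])
        assert compute_exposure(v, self.D).x.tolist() == [1]

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_exposure(np.zeros((1, 4)), self.D)


class TestStbFeature:
    def test_indicator_is_strict(self):
        x = compute_exposure(np.array([[0.0, 1.0, 0.0, 0.0, 0.0]]),
                             TestComputeExposure.D)
        assert stb_feature(x, 3).S.tolist() == [1.0]   # x=2 < 3
        assert stb_feature(x, 2).S.tolist() == [0.0]   # x=2 not < 2

    def test_absent_block_never_exposed(self):
        x = compute_exposure(np.zeros((1, 5)), TestComputeExposure.D)
        for c in range(1, 7):
            assert stb_feature(x, c).S.tolist() == [0.0] if c <= 6 else None

    def test_cutoff_one_degenerate_zero(self):
        x = compute_exposure(np.ones((4, 5)), TestComputeExposure.D)
        assert np.all(stb_feature(x, 1).S == 0.0)

    def test_monotone_in_cutoff(self, rng):
        X = (rng.random((30, 5)) < 0.4) * rng.integers(1, 9, (30, 5))
        x = compute_exposure(X.astype(float), TestComputeExposure.D)
        prev = np.zeros(30)
        for c in range(1, 7):
            S = stb_feature(x, c).S
            assert np.all(S >= prev)
            prev = S

    def test_max_cutoff_equals_any_presence(self, rng):
        X = (rng.random((30, 5)) < 0.4) * rng.integers(1, 9, (30, 5))
        x = compute_exposure(X.astype(float), TestComputeExposure.D)
        S = stb_feature(x, 6).S
        assert np.array_equal(S, (X.sum(axis=1) > 0).astype(float))

    def test_out_of_range_cutoff_rejected(self):
        x = compute_exposure(np.ones((2, 5)), TestComputeExposure.D)
        with pytest.raises(ValueError):
            stb_feature(x, 7)


class TestStcFeature:
    D = _ranking([1, 0])

    def test_mean_excludes_zeros(self):
        # ranked top-2 values per sample: (0, 5) -> mean of nonzero = 5
        v = np.array([[5.0, 0.0]])
        assert stc_feature(v, self.D, 2).S.tolist() == [5.0]

    def test_plain_mean_when_no_zeros(self):
        v = np.array([[4.0, 2.0]])
        assert stc_feature(v, self.D, 2).S.tolist() == [3.0]

    def test_all_zero_convention(self):
        v = np.zeros((1, 2))
        assert stc_feature(v, self.D, 2).S.tolist() == [0.0]

    def test_cutoff_one_is_top_otu_value(self, rng):
        X = (rng.random((20, 2)) < 0.5) * rng.integers(1, 9, (20, 2)).astype(float)
        S = stc_feature(X, self.D, 1).S
        top = X[:, 1]    # rank-1 OTU is column 1
        assert np.array_equal(S, top)


class TestSelectCutoff:
    def test_matches_exhaustive_statsmodels_scan(self):
        """Oracle: independently refit every candidate cutoff with
        statsmodels and require the same (cutoff, p-value) optimum."""
        for seed in range(8):
            X, y = planted_block(n=90, n_otus=6, seed=seed)
            ranking = _ranking(np.random.default_rng(seed).permutation(6))
            for mode in ("STB", "STC"):
                res = select_cutoff(X, ranking, y, mode=mode)
                x = compute_exposure(X, ranking).x
                best = None
                for c in np.unique(x):
                    if mode == "STB":
                        S = (x < c).astype(float)
                    else:
                        S = stc_feature(X, ranking, int(c)).S
                    if len(np.unique(S)) < 2:
                        continue
                    p = _sm_slope_pvalue(S, y)
                    if best is None or p < best[1] - 1e-12:
                        best = (int(c), p)
                assert res.best_cutoff == best[0], (seed, mode)
                assert res.best_pvalue == pytest.approx(best[1], rel=1e-3)

    def test_single_candidate_returned(self):
        # every sample has the top-ranked OTU present -> x constant = 1,
        # only candidate c=1 is degenerate -> untestable
        X = np.ones((10, 2))
        y = np.array([0, 1] * 5)
        res = select_cutoff(X, _ranking([0, 1]), y, mode="STB")
        assert res.untestable

    def test_degenerate_candidates_skipped_not_penalised(self):
        X, y = planted_block(n=60, n_otus=4, seed=3)
        res = select_cutoff(X, _ranking([0, 1, 2, 3]), y, mode="STB")
        degenerate = [c for c, p, d in res.candidate_table if d]
        tested = [c for c, p, d in res.candidate_table if not d]
        assert res.best_cutoff in tested
        assert all(p is None for c, p, d in res.candidate_table if d)

    def test_labels_must_vary(self):
        X = np.ones((4, 2))
        with pytest.raises(ValueError):
            select_cutoff(X, _ranking([0, 1]), np.zeros(4), mode="STB")


class TestExposureProperties:
    """Structural invariants of the exposure/aggregation pipeline."""

    from hypothesis import given, settings, strategies as st

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_stb_monotone_and_bounded_for_random_blocks(self, seed):
        r = np.random.default_rng(seed)
        n, J = int(r.integers(5, 30)), int(r.integers(2, 8))
        X = (r.random((n, J)) < 0.5) * r.integers(1, 9, (n, J)).astype(float)
        rk = _ranking(r.permutation(J))
        x = compute_exposure(X, rk)
        # x = J+1 exactly when the whole block is absent
        absent = X.sum(axis=1) == 0
        assert np.array_equal(x.x == J + 1, absent)
        prev = np.zeros(n)
        for c in range(1, J + 2):
            S = stb_feature(x, c).S
            assert np.all((S == 0) | (S == 1))
            assert np.all(S >= prev)      # monotone in the cutoff
            prev = S
        # the widest cutoff is exactly the any-presence indicator
        assert np.array_equal(prev, (~absent).astype(float))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_stc_lies_between_min_and_max_of_contributing_values(self, seed):
        r = np.random.default_rng(seed)
        n, J = int(r.integers(5, 20)), int(r.integers(2, 6))
        X = (r.random((n, J)) < 0.6) * r.integers(1, 50, (n, J)).astype(float)
        rk = _ranking(r.permutation(J))
        for c in range(1, J + 1):
            S = stc_feature(X, rk, c).S
            top = X[:, rk.order[:c]]
            nz = top > 0
            has = nz.any(axis=1)
            assert np.all(S[~has] == 0)
            with np.errstate(invalid="ignore"):
                lo = np.where(has, np.min(np.where(nz, top, np.inf), axis=1), 0)
                hi = top.max(axis=1)
            assert np.all(S[has] >= lo[has] - 1e-9)
            assert np.all(S[has] <= hi[has] + 1e-9)
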