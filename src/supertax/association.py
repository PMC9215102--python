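"""Split-sample association testing of super-taxa and the
discovery/verification workflow.

Family-wise error control relies on a clean split: one half of the
cohort derives the OTU ranking and aggregation cutoff for each block,
the other half tests the frozen super-taxon with a logistic regression.
The split is repeated (10 times by default) and blocks significant in at
least ``retain_threshold`` repeats are declared stable; stable blocks
are refit on the complete discovery cohort and, with their OTU lists
translated through a sequence-identity mapping, tested once more in an
independent verification cohort at level 0.05 / (#stable blocks).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from supertax.otu_data import OtuTable, SampleMetadata, BlockPartition
from supertax.depth_forest import (ForestParams, ImportanceRanking,
                                   forest_importance, rank_otus)
from supertax.supertaxon import (CutoffSearchResult, compute_exposure,
                                 stb_feature, stc_feature, select_cutoff)

__all__ = [
    "AssociationResult", "BlockTestResult", "DiscoveryReport", "OtuMapping",
    "fit_logistic", "split_halves", "test_block", "run_discovery",
    "verify", "compare_aic",
]


@dataclass
class AssociationResult:
    """Logistic-regression summary for one super-taxon (or OTU)."""

    beta: float
    se: float
    odds_ratio: float
    ci95: tuple[float, float]
    pvalue: float
    aic: float
    n: int
    flagged: bool = False      # separation / LRT fallback

    def to_dict(self) -> dict:
        return {"beta": self.beta, "se": self.se, "odds_ratio": self.odds_ratio,
                "ci95_low": self.ci95[0], "ci95_high": self.ci95[1],
                "pvalue": self.pvalue, "aic": self.aic, "n": self.n,
                "flagged": self.flagged}


@dataclass
class BlockTestResult:
    """One block's split-sample outcome."""

    block_id: str
    mode: str
    ranking: Optional[ImportanceRanking]
    cutoff: Optional[int]
    contributing_otus: list[int]
    train_result: Optional[CutoffSearchResult]
    test_result: Optional[AssociationResult]
    significant: bool
    reason: str = ""


@dataclass
class DiscoveryReport:
    """Result of the repeated-split discovery procedure."""

    mode: str
    repeats: list[dict[str, BlockTestResult]]
    selection_counts: dict[str, int]
    stable_blocks: list[str]
    full_fit: dict[str, BlockTestResult] = field(default_factory=dict)
    verification_fit: dict[str, BlockTestResult] = field(default_factory=dict)
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cohort, results in (("full_discovery", self.full_fit),
                                ("verification", self.verification_fit)):
            for bid, r in results.items():
                d = {"block_id": bid, "mode": self.mode, "cohort": cohort,
                     "cutoff": r.cutoff,
                     "contributing_otus": ",".join(map(str, r.contributing_otus)),
                     "significant": r.significant}
                if r.test_result is not None:
                    d.update(r.test_result.to_dict())
                rows.append(d)
        return pd.DataFrame(rows)


@dataclass
class OtuMapping:
    """Best sequence-identity match per discovery OTU."""

    rows: pd.DataFrame    # discovery_otu_id, verification_otu_id, identity_score

    def __post_init__(self) -> None:
        req = {"discovery_otu_id", "verification_otu_id", "identity_score"}
        if not req <= set(self.rows.columns):
            raise ValueError(f"mapping table needs columns {sorted(req)}")
        # keep only the best match per discovery OTU
        best = (self.rows.sort_values("identity_score", ascending=False)
                .drop_duplicates("discovery_otu_id"))
        self._lookup = dict(zip(best["discovery_otu_id"].astype(str),
                                best["verification_otu_id"].astype(str)))

    def translate(self, otu_ids: Sequence[str]) -> list[str]:
        missing = [o for o in otu_ids if str(o) not in self._lookup]
        if missing:
            raise KeyError(f"discovery OTUs without a verification match: {missing}")
        return [self._lookup[str(o)] for o in otu_ids]

    @classmethod
    def identity(cls, otu_ids: Sequence[str]) -> "OtuMapping":
        return cls(pd.DataFrame({"discovery_otu_id": list(otu_ids),
                                 "verification_otu_id": list(otu_ids),
                                 "identity_score": 100.0}))


def fit_logistic(S: np.ndarray, labels: np.ndarray,
                 covariates: Optional[np.ndarray] = None) -> AssociationResult:
    """Maximum-likelihood logistic fit of label on intercept + S (+ covariates).

    Reports the Wald p-value, odds ratio exp(beta) with 95% Wald CI, and
    AIC.  Under separation or non-convergence the p-value falls back to
    the likelihood-ratio test and the result is flagged.
    """
    import statsmodels.api as sm
    import warnings

    from supertax._logistic import logit_pvalue

    S = np.asarray(S, dtype=float)
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    if len(np.unique(S)) < 2:
        raise ValueError("constant super-taxon feature")
    # fit on the standardized predictor for numerical stability (raw
    # abundances span orders of magnitude); Wald z, p and AIC are
    # invariant, beta/se are rescaled back afterwards
    sd = float(S.std())
    s = (S - S.mean()) / sd
    cols = [s]
    if covariates is None:
        k_params = 2
    else:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != len(y):
            cov = cov.T
        cols.append(cov)
        k_params = 2 + cov.shape[1]
    X = sm.add_constant(np.column_stack(cols))
    flagged = False
    fit = None
    try:
        with warnings.catch_warnings(), np.errstate(all="ignore"):
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        converged = fit.mle_retvals.get("converged", True)
        beta_s = float(fit.params[1])
        se_s = float(fit.bse[1])
        pvalue = float(fit.pvalues[1])
        aic = float(fit.aic)
        if not converged or not np.isfinite(se_s) or abs(beta_s) > 30:
            raise ValueError("separation")
    except Exception:
        # separation / singular Hessian: likelihood-ratio p-value
        flagged = True
        scan = logit_pvalue(S, y)
        if covariates is None:
            beta_s, se_s = scan.beta * sd, scan.se * sd
            pvalue = scan.pvalue
            aic = 2 * k_params - 2 * scan.loglik
        else:
            with warnings.catch_warnings(), np.errstate(all="ignore"):
                warnings.simplefilter("ignore")
                fit1 = sm.Logit(y, X).fit(disp=0, maxiter=50,
                                          warn_convergence=False)
                fit0 = sm.Logit(y, np.delete(X, 1, axis=1)).fit(
                    disp=0, maxiter=200, warn_convergence=False)
            beta_s = float(fit1.params[1])
            se_s = float(fit1.bse[1]) if np.isfinite(fit1.bse[1]) else np.inf
            pvalue = float(stats.chi2.sf(max(2 * (fit1.llf - fit0.llf), 0.0), 1))
            aic = float(fit1.aic)
    beta, se = beta_s / sd, se_s / sd
    lo = float(np.exp(beta - 1.959963984540054 * se))
    hi = float(np.exp(beta + 1.959963984540054 * se))
    return AssociationResult(beta=beta, se=se, odds_ratio=float(np.exp(beta)),
                             ci95=(lo, hi), pvalue=pvalue,
                             aic=aic, n=len(y), flagged=flagged)


def split_halves(meta: SampleMetadata, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Random even split of the samples, stratified by label.

    Returns (train, test) index arrays; within each class the halves
    differ by at most one sample.  Deterministic given the seed.
    """
    y = meta.labels
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("each class needs at least 2 samples to split")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for k in classes:
        idx = np.flatnonzero(y == k)
        rng.shuffle(idx)
        half = len(idx) // 2
        train.append(idx[:half])
        test.append(idx[half:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def mode_forest_params(fp: ForestParams, mode: str) -> ForestParams:
    """STB operates on binary (presence/absence) features throughout, so
    its ranking forest splits presence rather than abundance; STC keeps
    the original abundances."""
    from dataclasses import replace
    if mode == "STB" and not fp.binarize:
        return replace(fp, binarize=True)
    return fp


def derive_block(features: np.ndarray, labels: np.ndarray, mode: str,
                 forest_params: ForestParams, block_id: str = "",
                 covariates: Optional[np.ndarray] = None,
                 ) -> tuple[ImportanceRanking, CutoffSearchResult]:
    """Rank a block's OTUs and select the aggregation cutoff (train side)."""
    scores = forest_importance(features, labels,
                               mode_forest_params(forest_params, mode),
                               block_id=block_id)
    ranking = rank_otus(scores)
    search = select_cutoff(features, ranking, labels, mode=mode,
                           covariates=covariates)
    return ranking, search


def freeze_and_fit(features: np.ndarray, labels: np.ndarray,
                   ranking: ImportanceRanking, cutoff: int, mode: str,
                   covariates: Optional[np.ndarray] = None,
                   ) -> tuple[Optional[AssociationResult], np.ndarray]:
    """Build the frozen super-taxon on held-out data and fit it.

    Returns (result, S); result is None when S is constant (untestable).
    """
    if mode == "STB":
        x = compute_exposure(features, ranking)
        feat = stb_feature(x, cutoff, ranking)
    elif mode == "STC":
        feat = stc_feature(features, ranking, cutoff)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if len(np.unique(feat.S)) < 2:
        return None, feat.S
    return fit_logistic(feat.S, labels, covariates), feat.S


def test_block(table: OtuTable, block: Sequence[int], meta: SampleMetadata,
               mode: str, forest_params: ForestParams, alpha: float,
               split: Optional[tuple[np.ndarray, np.ndarray]] = None,
               split_seed: int = 0, block_id: str = "",
               ranking: Optional[ImportanceRanking] = None,
               ) -> BlockTestResult:
    """Split-sample test of one block.

    Ranking and cutoff come from the train half only; the test half sees
    the frozen super-taxon.  A precomputed train-half ``ranking`` may be
    supplied (e.g. when STB and STC share one forest).
    """
    if split is None:
        split = split_halves(meta, split_seed)
    train_idx, test_idx = split
    feats = table.values[:, list(block)]
    y = meta.labels
    if ranking is None:
        scores = forest_importance(feats[train_idx], y[train_idx],
                                   mode_forest_params(forest_params, mode),
                                   block_id=block_id)
        ranking = rank_otus(scores)
    search = select_cutoff(feats[train_idx], ranking, y[train_idx], mode=mode)
    if search.untestable:
        return BlockTestResult(block_id, mode, ranking, None, [], search, None,
                               significant=False,
                               reason="all cutoff candidates degenerate on train half")
    c = search.best_cutoff
    contributing = [int(p) for p in ranking.order[:min(c, len(block))]]
    result, _ = freeze_and_fit(feats[test_idx], y[test_idx], ranking, c, mode)
    if result is None:
        return BlockTestResult(block_id, mode, ranking, c, contributing,
                               search, None, significant=False,
                               reason="super-taxon constant on test half")
    return BlockTestResult(block_id, mode, ranking, c, contributing, search,
                           result, significant=bool(result.pvalue < alpha))


def run_discovery(table: OtuTable, partition: BlockPartition,
                  meta: SampleMetadata, mode: str = "STB",
                  n_repeats: int = 10, retain_threshold: int = 2,
                  forest_params: Optional[ForestParams] = None,
                  base_seed: int = 0,
                  alpha: Optional[float] = None) -> DiscoveryReport:
    """Repeated-split discovery with a stability filter.

    Per-block significance level defaults to Bonferroni 0.05/n_blocks.
    Repeat r uses split seed ``base_seed + r`` and a forest seed derived
    from it.  Blocks significant in at least ``retain_threshold`` repeats
    are stable and refit (ranking + cutoff re-derived) on the complete
    cohort.
    """
    forest_params = forest_params or ForestParams()
    meta = meta.aligned_to(table)
    if alpha is None:
        alpha = 0.05 / partition.n_blocks
    repeats: list[dict[str, BlockTestResult]] = []
    counts = {bid: 0 for bid in partition.blocks}
    for r in range(n_repeats):
        split = split_halves(meta, base_seed + r)
        fp = _reseed(forest_params, base_seed, r + 1)
        rep: dict[str, BlockTestResult] = {}
        for bid, block in partition.blocks.items():
            res = test_block(table, block, meta, mode, fp, alpha,
                             split=split, block_id=bid)
            rep[bid] = res
            counts[bid] += int(res.significant)
        repeats.append(rep)
    stable = [bid for bid, k in counts.items() if k >= retain_threshold]
    full_fit: dict[str, BlockTestResult] = {}
    fp_full = _reseed(forest_params, base_seed, 0)
    for bid in stable:
        block = partition.blocks[bid]
        feats = table.values[:, list(block)]
        ranking, search = derive_block(feats, meta.labels, mode, fp_full,
                                       block_id=bid)
        if search.untestable:
            full_fit[bid] = BlockTestResult(bid, mode, ranking, None, [],
                                            search, None, False,
                                            reason="untestable on full cohort")
            continue
        c = search.best_cutoff
        contributing = [int(p) for p in ranking.order[:min(c, len(block))]]
        result, _ = freeze_and_fit(feats, meta.labels, ranking, c, mode)
        full_fit[bid] = BlockTestResult(
            bid, mode, ranking, c, contributing, search, result,
            significant=bool(result is not None and result.pvalue < alpha))
    return DiscoveryReport(mode=mode, repeats=repeats, selection_counts=counts,
                           stable_blocks=stable, full_fit=full_fit, alpha=alpha)


def _reseed(fp: ForestParams, base_seed: int, offset: int) -> ForestParams:
    from dataclasses import replace
    return replace(fp, seed=(base_seed * 1009 + offset * 7919 + fp.seed) % (2**31))


def verify(report: DiscoveryReport, verif_table: OtuTable,
           verif_meta: SampleMetadata, mapping: OtuMapping,
           discovery_otu_ids: Sequence[str],
           alpha: Optional[float] = None) -> DiscoveryReport:
    """Test each stable block in an independent cohort.

    The contributing OTUs of the full-discovery fit are translated
    through the sequence-identity mapping; their discovery rank order
    and the discovery cutoff are frozen.  The default significance level
    is 0.05 / (#stable blocks).
    """
    verif_meta = verif_meta.aligned_to(verif_table)
    if alpha is None:
        alpha = 0.05 / max(len(report.stable_blocks), 1)
    col = {o: j for j, o in enumerate(verif_table.otu_ids)}
    for bid in report.stable_blocks:
        fit = report.full_fit.get(bid)
        if fit is None or fit.cutoff is None:
            continue
        disc_ids = [str(discovery_otu_ids[p]) for p in fit.contributing_otus]
        verif_ids = mapping.translate(disc_ids)
        missing = [o for o in verif_ids if o not in col]
        if missing:
            raise KeyError(f"verification table lacks mapped OTUs: {missing}")
        feats = verif_table.values[:, [col[o] for o in verif_ids]]
        # the c mapped columns are already in discovery rank order
        ranking = ImportanceRanking(block_id=bid,
                                    order=np.arange(feats.shape[1]))
        result, _ = freeze_and_fit(feats, verif_meta.labels, ranking,
                                   fit.cutoff, report.mode)
        if result is None:
            report.verification_fit[bid] = BlockTestResult(
                bid, report.mode, ranking, fit.cutoff, fit.contributing_otus,
                None, None, False, reason="super-taxon constant in verification")
        else:
            report.verification_fit[bid] = BlockTestResult(
                bid, report.mode, ranking, fit.cutoff, fit.contributing_otus,
                None, result, significant=bool(result.pvalue < alpha))
    return report


def compare_aic(table: OtuTable, meta: SampleMetadata,
                supertaxon_feature) -> pd.DataFrame:
    """AIC comparison: joint super-taxon model vs each contributing OTU alone.

    Individual OTUs enter on the same transform family as the mode:
    presence indicator for STB, raw (nonzero) abundance for STC.
    """
    meta = meta.aligned_to(table)
    y = meta.labels
    feat = supertaxon_feature
    if len(feat.contributing_otus) < 2:
        raise ValueError("super-taxon must have >= 2 contributing OTUs")
    rows = []
    res = fit_logistic(feat.S, y)
    rows.append({"model": "super-taxon", "aic": res.aic,
                 "odds_ratio": res.odds_ratio, "pvalue": res.pvalue,
                 "flagged": res.flagged})
    for pos in feat.contributing_otus:
        otu_id = table.otu_ids[pos]
        v = table.values[:, pos]
        s = (v > 0).astype(float) if feat.mode == "STB" else v
        if len(np.unique(s)) < 2:
            rows.append({"model": f"otu:{otu_id}", "aic": np.nan,
                         "odds_ratio": np.nan, "pvalue": np.nan,
                         "flagged": True})
            continue
        r = fit_logistic(s, y)
        rows.append({"model": f"otu:{otu_id}", "aic": r.aic,
                     "odds_ratio": r.odds_ratio, "pvalue": r.pvalue,
                     "flagged": r.flagged})
    return pd.DataFrame(rows)
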