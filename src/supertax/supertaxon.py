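"""Super-taxon features and best-cutoff selection.

Given the depth-importance ranking d_g of a block's OTUs, each sample's
*exposure rank* x_ig is the smallest rank position whose OTU is present
(J_g + 1 if the whole block is absent).  A cutoff c then aggregates the
top-ranked OTUs into one per-sample feature:

* STB:  S_ig = I(x_ig < c)            (any of the top OTUs present)
* STC:  S_ig = mean of the nonzero abundances among the top-c ranked
        OTUs (0 when all are absent)

The cutoff is chosen among the observed exposure ranks by minimising the
slope p-value of a univariate logistic regression of disease status on
S; ties go to the smallest cutoff.  Zeros are excluded from the STC mean
so unobserved taxa do not dilute the aggregate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from supertax._logistic import logit_pvalue
from supertax.depth_forest import ImportanceRanking

__all__ = [
    "RankedExposure", "SuperTaxonFeature", "CutoffSearchResult",
    "compute_exposure", "stb_feature", "stc_feature", "select_cutoff",
]


@dataclass
class RankedExposure:
    """Per-sample first-presence rank x_ig within one block."""

    x: np.ndarray
    n_otus: int

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=int)
        if np.any(self.x < 1) or np.any(self.x > self.n_otus + 1):
            raise ValueError("exposure ranks must lie in 1..J+1")


@dataclass
class SuperTaxonFeature:
    """One aggregated per-sample feature for a block.

    ``contributing_otus`` are the block-column positions of the top
    min(c, J) ranked OTUs, in rank order.
    """

    mode: str
    cutoff: int
    S: np.ndarray
    contributing_otus: list[int]

    def __post_init__(self) -> None:
        if self.mode not in ("STB", "STC"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.S = np.asarray(self.S, dtype=float)
        if self.mode == "STB" and not set(np.unique(self.S)) <= {0.0, 1.0}:
            raise ValueError("STB features must be 0/1")
        if np.any(self.S < 0):
            raise ValueError("super-taxon features are non-negative")


@dataclass
class CutoffSearchResult:
    """Outcome of the exhaustive cutoff scan for one block."""

    best_cutoff: Optional[int]
    best_pvalue: Optional[float]
    candidate_table: list[tuple[int, Optional[float], bool]] = field(
        default_factory=list)
    untestable: bool = False
    separated: bool = False

    def to_frame(self, block_id: str = "", mode: str = "") -> pd.DataFrame:
        rows = [{"block_id": block_id, "mode": mode, "c": c,
                 "p": p, "degenerate": deg}
                for c, p, deg in self.candidate_table]
        return pd.DataFrame(rows)


def _ranked_values(features: np.ndarray, ranking: ImportanceRanking) -> np.ndarray:
    features = np.asarray(features, dtype=float)
    if features.ndim != 2:
        raise ValueError("features must be a 2-d block sub-matrix")
    if features.shape[1] != len(ranking.order):
        raise ValueError("ranking does not cover the block's OTUs")
    return features[:, ranking.order]


def compute_exposure(features: np.ndarray,
                     ranking: ImportanceRanking) -> RankedExposure:
    """First-presence rank per sample: min{ j : ranked OTU j > 0 }, else J+1."""
    ranked = _ranked_values(features, ranking)
    n, J = ranked.shape
    present = ranked > 0
    any_present = present.any(axis=1)
    first = np.argmax(present, axis=1) + 1       # 1-based rank position
    x = np.where(any_present, first, J + 1)
    return RankedExposure(x=x, n_otus=J)


def stb_feature(x: RankedExposure, c: int,
                ranking: Optional[ImportanceRanking] = None) -> SuperTaxonFeature:
    """Binary super-taxon: S_i = I(x_i < c)."""
    J = x.n_otus
    if not 1 <= c <= J + 1:
        raise ValueError(f"cutoff {c} out of range 1..{J + 1}")
    S = (x.x < c).astype(float)
    contributing = _contributing(ranking, c, J)
    return SuperTaxonFeature(mode="STB", cutoff=c, S=S,
                             contributing_otus=contributing)


def stc_feature(features: np.ndarray, ranking: ImportanceRanking,
                c: int) -> SuperTaxonFeature:
    """Continuous super-taxon: mean of nonzero values among the top-c
    ranked OTUs; 0 when all of them are absent in a sample."""
    ranked = _ranked_values(features, ranking)
    n, J = ranked.shape
    if not 1 <= c <= J + 1:
        raise ValueError(f"cutoff {c} out of range 1..{J + 1}")
    top = ranked[:, :min(c, J)]
    nz = (top > 0).sum(axis=1)
    total = top.sum(axis=1)
    with np.errstate(invalid="ignore"):
        S = np.where(nz > 0, total / np.maximum(nz, 1), 0.0)
    return SuperTaxonFeature(mode="STC", cutoff=c, S=S,
                             contributing_otus=_contributing(ranking, c, J))


def _contributing(ranking: Optional[ImportanceRanking], c: int, J: int) -> list[int]:
    if ranking is None:
        return []
    return [int(p) for p in ranking.order[:min(c, J)]]


def select_cutoff(features: np.ndarray, ranking: ImportanceRanking,
                  labels: np.ndarray, mode: str = "STB",
                  covariates: Optional[np.ndarray] = None,
                  ) -> CutoffSearchResult:
    """Scan the observed exposure ranks for the most significant cutoff.

    For every distinct observed x value c (the candidate set), builds
    the mode's super-taxon feature and records the logistic slope
    p-value; candidates with a constant feature are degenerate and
    skipped.  Returns the smallest-p candidate, ties broken toward the
    smallest c.  If every candidate is degenerate the block is marked
    untestable.
    """
    labels = np.asarray(labels)
    if len(set(np.unique(labels))) < 2:
        raise ValueError("labels must contain both classes")
    x = compute_exposure(features, ranking)
    candidates = np.unique(x.x)
    table: list[tuple[int, Optional[float], bool]] = []
    best_c: Optional[int] = None
    best_p: Optional[float] = None
    best_sep = False
    for c in candidates:
        c = int(c)
        if mode == "STB":
            S = (x.x < c).astype(float)
        elif mode == "STC":
            S = stc_feature(features, ranking, c).S
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if covariates is None:
            res = logit_pvalue(S, labels)
            if res is None:
                table.append((c, None, True))
                continue
            p, sep = res.pvalue, res.separated
        else:
            p, sep = _adjusted_pvalue(S, labels, covariates)
            if p is None:
                table.append((c, None, True))
                continue
        table.append((c, float(p), False))
        if best_p is None or p < best_p:
            best_c, best_p, best_sep = c, float(p), sep
    if best_c is None:
        return CutoffSearchResult(None, None, table, untestable=True)
    return CutoffSearchResult(best_c, best_p, table, separated=best_sep)


def _adjusted_pvalue(S, labels, covariates):
    """Covariate-adjusted slope p-value via statsmodels (cold path)."""
    import statsmodels.api as sm

    if len(np.unique(S)) < 2:
        return None, False
    X = sm.add_constant(np.column_stack([S, np.asarray(covariates, dtype=float)]))
    try:
        fit = sm.Logit(np.asarray(labels, dtype=float), X).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", True) or abs(fit.params[1]) > 30:
            raise ValueError("separation")
        return float(fit.pvalues[1]), False
    except Exception:
        fit0 = sm.Logit(np.asarray(labels, dtype=float),
                        sm.add_constant(np.asarray(covariates, dtype=float))
                        ).fit(disp=0, maxiter=200)
        try:
            fit1 = sm.Logit(np.asarray(labels, dtype=float), X).fit(
                disp=0, maxiter=50)
            from scipy import stats as _st
            lrt = 2 * (fit1.llf - fit0.llf)
            return float(_st.chi2.sf(max(lrt, 0.0), 1)), True
        except Exception:
            return None, True
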