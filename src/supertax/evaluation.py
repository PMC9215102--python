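"""Benchmark harness: FWER, identification rates and confusion metrics.

A *method adapter* maps a simulated dataset to a
:class:`SelectionOutcome` (the blocks it rejects and the OTUs it
selects).  Built-in adapters run the split-sample super-taxon pipeline
(STB/STC); external per-OTU methods can be plugged in, with a block
regarded as selected if any OTU in it is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from supertax.association import (split_halves, test_block)
from supertax.depth_forest import ForestParams, forest_importance, rank_otus
from supertax.simulator import SimScenario, SimulatedDataset, simulate_dataset

__all__ = [
    "SelectionOutcome", "MetricsReport", "compute_fwer",
    "compute_power_metrics", "run_benchmark", "supertaxon_adapter",
]


@dataclass
class SelectionOutcome:
    """Blocks and OTUs selected by one method in one replicate."""

    replicate_id: int
    selected_blocks: set[int]
    selected_otus: set[int]
    failed: bool = False


def _ms(vals) -> tuple[float, float]:
    arr = np.asarray(list(vals), dtype=float)
    if arr.size == 0:
        return float("nan"), float("nan")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


@dataclass
class MetricsReport:
    """Aggregated simulation metrics over replicates."""

    n_replicates: int
    n_blocks: int
    n_otus: int
    fwer: Optional[float] = None
    fwer_se: Optional[float] = None
    per_block_identification: dict[int, float] = field(default_factory=dict)
    avg_identification: tuple[float, float] = (float("nan"), float("nan"))
    avg_identification_replicate_sd: float = float("nan")
    block_sensitivity: tuple[float, float] = (float("nan"), float("nan"))
    block_specificity: tuple[float, float] = (float("nan"), float("nan"))
    block_precision: tuple[float, float] = (float("nan"), float("nan"))
    block_precision_na: int = 0
    otu_sensitivity: tuple[float, float] = (float("nan"), float("nan"))
    otu_specificity: tuple[float, float] = (float("nan"), float("nan"))
    otu_precision: tuple[float, float] = (float("nan"), float("nan"))
    otu_precision_na: int = 0
    n_failed: int = 0

    def to_frame(self) -> pd.DataFrame:
        d = {"n_replicates": self.n_replicates, "fwer": self.fwer,
             "fwer_se": self.fwer_se,
             "avg_identification": self.avg_identification[0],
             "avg_identification_sd": self.avg_identification[1]}
        for name in ("block_sensitivity", "block_specificity", "block_precision",
                     "otu_sensitivity", "otu_specificity", "otu_precision"):
            m, s = getattr(self, name)
            d[name] = m
            d[f"{name}_sd"] = s
        return pd.DataFrame([d])


def compute_fwer(outcomes: Sequence[SelectionOutcome],
                 truth_blocks: Sequence[int] = ()) -> tuple[float, float]:
    """Fraction of replicates rejecting any block, with binomial SE.

    Only defined under the global null (empty truth)."""
    if len(truth_blocks) > 0:
        raise ValueError("FWER is defined for the null scenario only; "
                         "use compute_power_metrics")
    ok = [o for o in outcomes if not o.failed]
    if not ok:
        return float("nan"), float("nan")
    hits = np.array([len(o.selected_blocks) > 0 for o in ok], dtype=float)
    f = float(hits.mean())
    se = float(np.sqrt(f * (1 - f) / len(hits)))
    return f, se


def _confusion(selected: set[int], truth: set[int], universe: int):
    tp = len(selected & truth)
    fp = len(selected - truth)
    fn = len(truth - selected)
    tn = universe - tp - fp - fn
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    prec = tp / (tp + fp) if (tp + fp) else None     # None = NA (empty selection)
    return sens, spec, prec


def compute_power_metrics(outcomes: Sequence[SelectionOutcome],
                          truth_blocks: Sequence[int],
                          truth_otus: Sequence[int],
                          n_blocks: int, n_otus: int) -> MetricsReport:
    """Block- and OTU-level identification and confusion metrics.

    Per-block identification rate = fraction of replicates selecting the
    block; the headline average (and SD) is taken across the true
    blocks.  Precision is NA for a replicate that selects nothing and is
    excluded from the mean, with the exclusion count reported.
    """
    tb, to = set(truth_blocks), set(truth_otus)
    if not tb:
        raise ValueError("power metrics need a non-empty truth set")
    ok = [o for o in outcomes if not o.failed]
    R = len(ok)
    ident = {b: sum(b in o.selected_blocks for o in ok) / R for b in sorted(tb)}
    per_rep_hits = [len(o.selected_blocks & tb) / len(tb) for o in ok]

    b_sens, b_spec, b_prec = [], [], []
    o_sens, o_spec, o_prec = [], [], []
    b_na = o_na = 0
    for o in ok:
        s, sp, pr = _confusion(o.selected_blocks, tb, n_blocks)
        b_sens.append(s)
        b_spec.append(sp)
        if pr is None:
            b_na += 1
        else:
            b_prec.append(pr)
        s, sp, pr = _confusion(o.selected_otus, to, n_otus)
        o_sens.append(s)
        o_spec.append(sp)
        if pr is None:
            o_na += 1
        else:
            o_prec.append(pr)

    return MetricsReport(
        n_replicates=R, n_blocks=n_blocks, n_otus=n_otus,
        per_block_identification=ident,
        avg_identification=_ms(ident.values()),
        avg_identification_replicate_sd=_ms(per_rep_hits)[1],
        block_sensitivity=_ms(b_sens), block_specificity=_ms(b_spec),
        block_precision=_ms(b_prec), block_precision_na=b_na,
        otu_sensitivity=_ms(o_sens), otu_specificity=_ms(o_spec),
        otu_precision=_ms(o_prec), otu_precision_na=o_na,
        n_failed=len(outcomes) - R,
    )


def supertaxon_adapter(dataset: SimulatedDataset, modes: Sequence[str],
                       forest_params: ForestParams, alpha: float,
                       split_seed: int) -> dict[str, SelectionOutcome]:
    """Run the split-sample super-taxon pipeline on one dataset.

    STB ranks on presence/absence features, STC on raw abundances, so
    each mode grows its own forest; modes sharing a feature scale share
    the ranking.
    """
    from supertax.association import mode_forest_params

    scen = dataset.scenario
    split = split_halves(dataset.meta, split_seed)
    train_idx, test_idx = split
    y = dataset.meta.labels
    blocks = list(scen.block_partition().items())
    out = {m: SelectionOutcome(split_seed, set(), set()) for m in modes}
    for g, (bid, block) in enumerate(blocks):
        feats = dataset.table.values[:, block]
        rankings: dict[bool, object] = {}
        for m in modes:
            fp = mode_forest_params(forest_params, m)
            if fp.binarize not in rankings:
                scores = forest_importance(feats[train_idx], y[train_idx],
                                           fp, block_id=bid)
                rankings[fp.binarize] = rank_otus(scores)
            res = test_block(dataset.table, block, dataset.meta, m,
                             forest_params, alpha, split=split,
                             block_id=bid, ranking=rankings[fp.binarize])
            if res.significant:
                out[m].selected_blocks.add(g)
                out[m].selected_otus.update(block[p] for p in res.contributing_otus)
    return out


def run_benchmark(scenario: SimScenario,
                  methods: Sequence[str] | str = ("STB",),
                  n_replicates: int = 100, base_seed: int = 0,
                  forest_params: Optional[ForestParams] = None,
                  alpha: Optional[float] = None,
                  adapter: Optional[Callable[[SimulatedDataset], SelectionOutcome]] = None,
                  ) -> dict[str, MetricsReport]:
    """Simulate -> run method(s) -> aggregate metrics.

    Replicate r redraws the dataset with seed ``base_seed + r`` (Omega
    and B0 included) and splits it with the same seed.  ``alpha``
    defaults to Bonferroni 0.05/n_blocks per block on the held-out
    half.  With a custom ``adapter`` the per-OTU selections it returns
    are collapsed to blocks by the any-OTU rule before scoring.
    """
    if isinstance(methods, str):
        methods = (methods,)
    methods = tuple(m.upper() for m in methods) if adapter is None else ("ADAPTER",)
    forest_params = forest_params or ForestParams(n_trees=50)
    if alpha is None:
        alpha = 0.05 / scenario.n_blocks
    collected: dict[str, list[SelectionOutcome]] = {m: [] for m in methods}
    for r in range(n_replicates):
        seed = (base_seed + r) % (2**31)
        ds = simulate_dataset(replace(scenario, seed=seed))
        if adapter is not None:
            try:
                o = adapter(ds)
                o.replicate_id = r
                # collapse per-OTU selections to blocks: any OTU selects its block
                o.selected_blocks = ({b for b in o.selected_blocks} |
                                     {j // scenario.block_size
                                      for j in o.selected_otus})
            except Exception:
                o = SelectionOutcome(r, set(), set(), failed=True)
            collected["ADAPTER"].append(o)
        else:
            res = supertaxon_adapter(ds, methods, forest_params, alpha,
                                     split_seed=seed)
            for m in methods:
                res[m].replicate_id = r
                collected[m].append(res[m])
    reports: dict[str, MetricsReport] = {}
    for m, outcomes in collected.items():
        if scenario.true_otus:
            rep = compute_power_metrics(outcomes, scenario.true_blocks,
                                        scenario.true_otus,
                                        scenario.n_blocks, scenario.n_otus)
        else:
            f, se = compute_fwer(outcomes)
            rep = MetricsReport(n_replicates=len(outcomes),
                                n_blocks=scenario.n_blocks,
                                n_otus=scenario.n_otus, fwer=f, fwer_se=se,
                                n_failed=sum(o.failed for o in outcomes))
        reports[m] = rep
    return reports
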