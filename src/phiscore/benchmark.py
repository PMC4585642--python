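"""Benchmarking of scoring methods on simulated screens.

A score is judged by how well it separates the known active perturbations
from the inactive ones: the area under the ROC curve (AUC), computed as the
rank (Mann–Whitney) statistic with ties counted one half — exact and
tie-safe, with no threshold sweep.  An AUC of 0.5 is random hit picking, 1
is perfect separation.  Score-distribution quality for control wells is
summarized by the Z' factor, 1 − 3(σ₊+σ₋)/|μ₊−μ₋|, applied to the score
distributions of positive and negative controls.  Replicated simulation
grids (e.g. AUC versus mean cells per well) are compared head-to-head by a
paired Wilcoxon signed-rank test, pairing the AUCs of two methods computed
on identical simulated screens.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import replace
from scipy import stats

from . import simulate as sim
from .scores import score_plate

__all__ = ["roc_auc", "zprime", "benchmark_grid", "compare_methods_wilcoxon"]

#: methods whose large values indicate a phenotype increase
_SIGNED_METHODS = ("phi", "phin", "z", "zn", "rz", "ssmd", "k")


def roc_auc(scores, truth, direction: str = "decrease") -> float:
    """Probability that a random active perturbation out-scores a random
    inactive one, with ties counted one half.

    ``direction`` orients the scores: with ``"decrease"`` (active
    perturbations push the phenotype down) a more negative score counts as
    stronger evidence of activity.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if truth.all() or not truth.any():
        raise ValueError("AUC needs at least one active and one inactive perturbation")
    oriented = -scores if direction == "decrease" else scores
    ranks = stats.rankdata(oriented)
    n_act = int(truth.sum())
    n_inact = truth.size - n_act
    u = ranks[truth].sum() - n_act * (n_act + 1) / 2.0
    return float(u / (n_act * n_inact))


def zprime(pos_scores, neg_scores) -> float:
    """Z' separation factor of two score distributions.

    Z' = 1 − 3(σ₊ + σ₋)/|μ₊ − μ₋| with sample means and SDs; above 0.5 is
    conventionally a screenable assay, 1 is the perfect-separation limit.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("Z' needs at least 2 values per group")
    sep = abs(pos.mean() - neg.mean())
    if sep == 0.0:
        raise ValueError("Z' undefined: equal group means")
    return float(1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / sep)


def _score_and_auc(screen: sim.SimulatedScreen, methods) -> dict[str, float]:
    table = score_plate(screen.cells, methods=methods)
    merged = table.merge(screen.truth, on="perturbation_id")
    return {
        m: roc_auc(merged[m], merged["active"], direction=screen.config.direction)
        for m in methods
    }


def benchmark_grid(
    config: sim.SimulationConfig,
    grid: dict[str, list],
    methods=("phi", "z"),
    n_reps: int = 50,
    base_seed: int = 1,
) -> pd.DataFrame:
    """AUC of each method over a parameter grid of replicated simulations.

    ``grid`` maps one or more config field names (e.g. ``cells_mean``,
    ``penetrance``) to value lists; the product is enumerated.  Replicate
    ``r`` of every grid point uses seed ``base_seed + r``, so all methods —
    and all grid points — are compared on reproducible screens.  Returns a
    tidy frame with one row per (grid point, replicate, method).
    """
    points: list[dict] = [{}]
    for param, values in grid.items():
        points = [{**pt, param: v} for pt in points for v in values]
    rows = []
    for pt in points:
        for r in range(n_reps):
            cfg = replace(config, **pt, seed=base_seed + r)
            aucs = _score_and_auc(sim.simulate_screen(cfg), methods)
            for m in methods:
                rows.append({**pt, "replicate": r, "method": m, "auc": aucs[m]})
    return pd.DataFrame(rows)


def summarize_benchmark(results: pd.DataFrame) -> pd.DataFrame:
    """Per grid point and method: mean and SD of AUC over replicates
    (SD is NaN for a single replicate)."""
    keys = [c for c in results.columns if c not in ("replicate", "auc")]
    return (
        results.groupby(keys, sort=True)["auc"]
        .agg(mean_auc="mean", sd_auc="std", n_reps="size")
        .reset_index()
    )


def compare_methods_wilcoxon(aucs_a, aucs_b, paired: bool = True) -> float:
    """Two-sided Wilcoxon P-value comparing two methods' AUC vectors.

    Paired by default (signed-rank on per-screen differences, since both
    methods score identical simulated screens); ``paired=False`` falls back
    to the rank-sum test.  All-zero differences return P = 1.
    """
    a = np.asarray(aucs_a, dtype=float)
    b = np.asarray(aucs_b, dtype=float)
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison needs equal-length AUC vectors")
        if np.all(a == b):
            return 1.0
        return float(stats.wilcoxon(a, b, alternative="two-sided").pvalue)
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
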