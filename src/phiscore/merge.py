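"""Gene-level merging of per-siRNA scores, hit calling, and hit-quality tests.

Several siRNAs (typically three) target each gene.  The merged gene score
keeps the spirit of the classical "2-of-3 above threshold" hit rule while
producing a single, graded number per gene:

1. each siRNA score is *clipped*: values within ±L (lower limit, default 3)
   are set to 0, values beyond ±U (ceiling, default 6) are capped at ±U —
   the lower limit suppresses small artifactual effects, the ceiling stops
   one strong (possibly off-target) siRNA from dominating;
2. clipped scores are summed;
3. a *bonus* of (k−1)·L is added when k ≥ 2 surviving scores share the same
   sign and no surviving score opposes them, separating genes whose
   evidence is concordant from genes carried by a single siRNA.

With L=3, U=6 this gives bonus 3 for two concordant active siRNAs and 6 for
three, and hit tiers at |merged| > 9 (hit), 12 (strong: two actives cannot
be below it without both exceeding 4.5 on average), 15 (high confidence:
requires all three siRNAs active in the same direction).

The absolute gene score (plain sum of |siRNA score|) is provided for
benchmarking only — it is deliberately sensitive to single-siRNA artifacts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "MergePolicy",
    "clip_score",
    "merged_gene_score",
    "absolute_gene_score",
    "merge_gene_scores",
    "call_hits",
    "sign_consistency_test",
    "enrichment_test",
]


@dataclass(frozen=True)
class MergePolicy:
    """Clipping limits, bonus rule and hit tiers for gene-level merging.

    ``lower`` (L) and ``upper`` (U) are in score units; ``tiers`` are the
    nondecreasing |merged score| thresholds for hit / strong / high-
    confidence calls.  The bonus for k same-sign active siRNAs is (k−1)·L.
    """

    lower: float = 3.0
    upper: float = 6.0
    tiers: tuple[float, ...] = (9.0, 12.0, 15.0)

    def __post_init__(self):
        if not (0 < self.lower <= self.upper):
            raise ValueError(f"need 0 < lower <= upper, got {self.lower}, {self.upper}")
        if any(b < a for a, b in zip(self.tiers, self.tiers[1:])):
            raise ValueError(f"hit tiers must be nondecreasing, got {self.tiers}")

    def bonus(self, k: int) -> float:
        """Bonus for ``k`` concordant active siRNAs: 0 for k<2, else (k−1)·L."""
        return 0.0 if k < 2 else (k - 1) * self.lower


DEFAULT_POLICY = MergePolicy()


def clip_score(s: float, policy: MergePolicy = DEFAULT_POLICY) -> float:
    """Modified siRNA score: 0 inside ±lower, capped at ±upper outside.

    "Exceeding" a limit is strict: a score exactly at the lower limit is
    inactive (clipped to 0); a score exactly at the ceiling is kept.
    """
    if not math.isfinite(s):
        raise ValueError(f"siRNA score must be finite, got {s}")
    if abs(s) <= policy.lower:
        return 0.0
    if abs(s) > policy.upper:
        return math.copysign(policy.upper, s)
    return float(s)


def merged_gene_score(sirna_scores, policy: MergePolicy = DEFAULT_POLICY) -> dict:
    """Merge the scores of the siRNAs targeting one gene.

    Returns a dict with the clipped (modified) scores, the bonus, the merged
    score and the absolute score.  The bonus is granted only when at least
    two surviving scores share a sign and *no* surviving score has the
    opposite sign; genes with contradictory active siRNAs get no bonus.
    """
    scores = [float(s) for s in sirna_scores]
    if len(scores) == 0:
        raise ValueError("a gene needs at least one siRNA score")
    modified = [clip_score(s, policy) for s in scores]
    n_pos = sum(1 for m in modified if m > 0)
    n_neg = sum(1 for m in modified if m < 0)
    if n_pos >= 2 and n_neg == 0:
        bonus = policy.bonus(n_pos)
    elif n_neg >= 2 and n_pos == 0:
        bonus = -policy.bonus(n_neg)
    else:
        bonus = 0.0
    merged = sum(modified) + bonus
    return {
        "sirna_scores": scores,
        "modified_scores": modified,
        "bonus": bonus,
        "merged": merged,
        "absolute": absolute_gene_score(scores),
    }


def absolute_gene_score(sirna_scores) -> float:
    """Sum of |siRNA score| over the gene (benchmarking only: sensitive to
    single-siRNA artifacts such as off-target effects)."""
    scores = np.asarray(list(sirna_scores), dtype=float)
    if scores.size == 0:
        raise ValueError("a gene needs at least one siRNA score")
    return float(np.abs(scores).sum())


def _tier_label(merged: float, tiers) -> tuple[str, int]:
    names = ["hit", "strong", "high_confidence"]
    tier = 0
    for t in tiers:
        if abs(merged) > t:
            tier += 1
    if tier == 0:
        return "none", 0
    label = names[min(tier, len(names)) - 1]
    signed = int(math.copysign(tier, merged))
    return ("+" if signed > 0 else "-") + label, signed


def call_hits(gene_scores: pd.DataFrame, policy: MergePolicy = DEFAULT_POLICY) -> pd.DataFrame:
    """Label each gene with the highest tier its |merged| strictly exceeds.

    Adds ``hit_tier`` (signed integer, 0 = none, ±1/±2/±3 for the default
    9/12/15 tiers) and a readable ``hit_class`` column.
    """
    out = gene_scores.copy()
    labels, tiers = zip(*(_tier_label(m, policy.tiers) for m in out["merged"]))
    out["hit_class"] = list(labels)
    out["hit_tier"] = list(tiers)
    return out


def merge_gene_scores(
    scores: pd.DataFrame,
    annotation: pd.DataFrame,
    *,
    method: str = "phi",
    policy: MergePolicy = DEFAULT_POLICY,
) -> pd.DataFrame:
    """Merge a per-perturbation score table into per-gene merged scores.

    ``scores`` must carry ``perturbation_id`` and the requested score
    column; ``annotation`` maps perturbations to genes.  Perturbations
    without annotation are dropped with a logged count.
    """
    if method not in scores.columns:
        raise ValueError(f"score column {method!r} not present in score table")
    joined = scores.merge(annotation, on="perturbation_id", how="left")
    unannotated = joined["gene_id"].isna()
    if unannotated.any():
        logger.info("dropping %d perturbation(s) without gene annotation", int(unannotated.sum()))
        joined = joined[~unannotated]
    records = []
    for gene, grp in joined.groupby("gene_id", sort=True):
        res = merged_gene_score(grp[method].tolist(), policy)
        records.append(
            {
                "gene_id": gene,
                "n_sirna": len(res["sirna_scores"]),
                "sirna_scores": ";".join(f"{s:g}" for s in res["sirna_scores"]),
                "bonus": res["bonus"],
                "merged": res["merged"],
                "absolute": res["absolute"],
            }
        )
    return call_hits(pd.DataFrame.from_records(records), policy)


def sign_consistency_test(
    sign_triples: pd.DataFrame | np.ndarray,
    background_p: float | None = None,
) -> dict:
    """Test whether top genes have all three siRNA scores of the same sign
    more often than chance.

    Parameters
    ----------
    sign_triples
        One row per gene, three columns of score signs (+1/-1), or any
        array-like coercible to an (M, 3) sign matrix.  Genes with a zero
        sign are kept (a zero never counts as agreeing).
    background_p
        Null probability that a single siRNA score is positive.  Defaults
        to the observed positive fraction among all included siRNAs.

    Returns a dict per direction with the observed count of all-same-sign
    genes, the expected count M·p³ (or M·(1−p)³), and a one-sided upper
    binomial P-value.
    """
    signs = np.sign(np.asarray(sign_triples, dtype=float))
    if signs.ndim != 2 or signs.shape[1] != 3:
        raise ValueError("sign_consistency_test expects an (M, 3) matrix of signs")
    m = signs.shape[0]
    if background_p is None:
        background_p = float((signs > 0).mean())
    if not (0.0 < background_p < 1.0):
        # degenerate null: the observed count can never be surprising
        background_p = min(max(background_p, 0.0), 1.0)
    result = {"n_genes": m, "background_p": background_p}
    for direction, p1 in (("positive", background_p), ("negative", 1.0 - background_p)):
        all_same = (signs > 0).all(axis=1) if direction == "positive" else (signs < 0).all(axis=1)
        observed = int(all_same.sum())
        p_gene = p1**3
        p_value = float(stats.binom.sf(observed - 1, m, p_gene)) if p_gene > 0 else float(observed == 0)
        if p_gene >= 1.0:
            p_value = 1.0
        result[direction] = {
            "count_all_same": observed,
            "expected": m * p_gene,
            "p_value": p_value,
        }
    return result


def enrichment_test(hits: set, universe: set, category: set) -> float:
    """One-sided Fisher exact test for over-representation of ``category``
    among ``hits`` within ``universe``.

    No multiple-testing correction is applied (gene-ontology categories are
    nested, so independent-test corrections are overly conservative);
    downstream reporting should disregard P-values above 1e-3.
    """
    hits, universe, category = set(hits), set(universe), set(category)
    if not universe:
        raise ValueError("empty gene universe")
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    category &= universe
    a = len(hits & category)
    b = len(hits - category)
    c = len(category - hits)
    d = len(universe) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(p)
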