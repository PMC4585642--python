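"""Per-perturbation scores: Φ, Φn, Z, Zn, robust Z, SSMD and the K-score.

The Φ-score
-----------
After the per-plate rank-to-Gaussian transform (:mod:`phiscore.rank`), the
score of a perturbation starts as the arithmetic mean ``x̄`` of its cells'
Gaussian scores, pooling replicate wells at the cell level.  Under the null
(the perturbation's cells are an exchangeable draw from the plate), ``x̄`` of
``n`` cells out of ``N`` has variance

    v(n) = (1/n) * (N - n) / (N - 1)

— the variance of a without-replacement sample mean from a score population
of unit variance.  Real plates carry extra well-to-well variability beyond
this sampling floor, which we model as an additive overdispersion ``τ²``
estimated robustly from the bulk of (presumed inactive) perturbations by
matching the χ²₁ distribution of the standardized squared means (see
:func:`estimate_null_calibration` for the two-regime robust matching
scheme).  The Φ-score is then

    Φ_g = x̄_g / sqrt(v(n_g) + τ̂²)

which is approximately standard normal for inactive perturbations — this is
what makes Φ directly translatable into a P-value (P(Φ > 3) ≈ 1.3e-3) and
what penalizes perturbations measured on few cells.

Φn replaces the implicit whole-plate reference by negative controls: cells
are centered on the mean control cell score and ``τ²`` is estimated from
per-well control means, so Φn stays calibrated even when a large fraction
(>20%) of perturbations is genuinely active.

Comparator scores
-----------------
Z (plate mean/SD of per-perturbation raw-value aggregates), robust Z
(median / 1.4826·MAD), Zn (centered and scaled on negative-control well
aggregates), SSMD (standardized mean difference of raw cell values against
the rest of the plate) and the K-score (signed Kolmogorov–Smirnov
sup-distance between a perturbation's cells and the rest of the plate,
computed in O(n log n)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .rank import gaussianize_plate

__all__ = [
    "NullCalibration",
    "summarize_perturbations",
    "estimate_null_calibration",
    "phi_scores",
    "phi_scores_normalized",
    "z_scores",
    "ssmd_scores",
    "k_scores",
    "score_to_pvalue",
    "score_plate",
    "score_screen",
    "METHODS",
]

#: median of the chi-square distribution with 1 degree of freedom
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))

#: consistency constant making MAD estimate a Gaussian SD
MAD_SCALE = 1.4826

#: recognised scoring method tags
METHODS = ("phi", "phin", "z", "zn", "rz", "ssmd", "k")

MIN_REFERENCE = 8


@dataclass(frozen=True)
class NullCalibration:
    """Calibrated null-variance model for perturbation mean scores.

    Attributes
    ----------
    tau2 : float
        Extra variance beyond without-replacement sampling, in score units².
    N : int
        Plate cell total entering ``v(n)``.
    center : float
        Reference location subtracted from mean scores (0 for the
        whole-plate Φ, the mean control cell score for Φn).
    method : str
        Tag recording which reference set was used.
    """

    tau2: float
    N: int
    center: float = 0.0
    method: str = "samples"

    def null_sd(self, n) -> np.ndarray:
        """Null standard deviation of a mean score over ``n`` of ``N`` cells.

        A (small, sampling-noise-driven) negative τ̂² estimated on the
        reference set could push the modeled variance of a perturbation
        pooled over many more cells below zero; the variance is therefore
        clamped at 10% of that perturbation's sampling floor v(n).
        """
        v = sampling_variance(np.asarray(n, dtype=float), self.N)
        return np.sqrt(np.maximum(v + self.tau2, 0.1 * v))


def sampling_variance(n, N: int):
    """v(n) = (1/n)(N−n)/(N−1): variance of a without-replacement mean of
    ``n`` unit-variance scores drawn from a plate of ``N``."""
    n = np.asarray(n, dtype=float)
    return (1.0 / n) * (N - n) / (N - 1.0)


def summarize_perturbations(gaussianized: pd.DataFrame) -> pd.DataFrame:
    """Pool the cells of one gaussianized plate by perturbation.

    Replicate wells of a perturbation are pooled at the cell level (the
    perturbation score is the average Gaussian score of *cells*, not of
    wells).  Returns one row per perturbation with its cell count, mean
    cell score and raw-value moments.
    """
    plates = gaussianized["plate_id"].unique()
    if len(plates) != 1:
        raise ValueError("summarize_perturbations expects cells of a single plate")
    grouped = gaussianized.groupby("perturbation_id", sort=False)
    out = grouped.agg(
        plate_id=("plate_id", "first"),
        role=("role", "first"),
        n_cells=("cell_score", "size"),
        mean_cell_score=("cell_score", "mean"),
        mean_value=("value", "mean"),
        sd_value=("value", "std"),
    ).reset_index()
    return out


#: Winsorizing cap on the χ² ratios (90th percentile of χ²₁)
_WINSOR_CAP = float(stats.chi2.ppf(0.90, df=1))
#: outlier-rejection cutoff for the contaminated regime (99th pct of χ²₁)
_REJECT_CUTOFF = float(stats.chi2.ppf(0.99, df=1))
_REJECT_RATE = 0.01


def _winsorized_target(cap: float, cutoff: float | None = None) -> float:
    """E[min(X, cap)] for X ~ χ²₁, optionally conditioned on X ≤ cutoff.

    Uses the identity x·f₁(x) = f₃(x), so E[X·1{X≤c}] = F₃(c).
    """
    if cutoff is None:
        return float(stats.chi2.cdf(cap, 3) + cap * stats.chi2.sf(cap, 1))
    p_keep = float(stats.chi2.cdf(cutoff, 1))
    num = float(stats.chi2.cdf(cap, 3) + cap * (p_keep - stats.chi2.cdf(cap, 1)))
    return num / p_keep


def _match(sq: np.ndarray, v: np.ndarray, stat, target: float, lo: float) -> float:
    """Solve stat(sq / (v + τ²)) = target for τ² on [lo, hi]; ``stat`` must be
    decreasing in τ², so the root is unique when bracketed."""

    def excess(tau2: float) -> float:
        return float(stat(sq / (v + tau2))) - target

    if excess(lo) <= 0.0:
        return lo
    hi = max(float(np.max(sq)) / target, lo + 1e-12)
    return float(brentq(excess, lo, hi, rtol=1e-10, maxiter=200))


def estimate_null_calibration(
    xbar: np.ndarray,
    n: np.ndarray,
    N: int,
    *,
    center: float = 0.0,
    method: str = "samples",
) -> NullCalibration:
    """Estimate the extra-variance term τ² by robust χ²-moment matching.

    Under the null, r_g = (x̄_g − center)² / (v(n_g) + τ²) is χ²₁-distributed,
    so τ̂² is found by matching a robust functional of the observed ratios to
    its χ²₁ expectation.  Two regimes:

    * **Clean regime** (default): match the Winsorized mean
      ``E[min(r, c)]`` with cap ``c`` at the χ²₁ 90th percentile — far more
      efficient than a single quantile, which matters because per-plate
      calibration noise both blurs the Gaussian null and, through the
      convexity of the tail, inflates P(Φ > 3).  Small *negative* τ̂² is
      allowed (floored so every per-perturbation variance stays positive),
      the classical method-of-moments convention for variance components:
      clipping at zero would bias the calibration upward and deflate the
      null tail.
    * **Contaminated regime**: a median-matched pre-fit counts ratios above
      the χ²₁ 99th percentile; if their number exceeds what a binomial null
      can plausibly produce (0.999 quantile), the reference set is deemed
      to contain gross actives and τ̂² is re-fit by iterated outlier
      rejection — presumed actives (ratio above the cutoff) are excluded
      and the trimmed mean of the survivors is matched to the conditional
      χ²₁ expectation, iterating to a fixed point.  This keeps strong,
      plentiful actives (a ~30% active fraction of clearly separated
      effects) from inflating the null variance.

    Perturbations with weak, non-separable activity inflate τ̂² somewhat in
    any scheme; plates expected to be dominated by actives should be scored
    against negative controls (Φn) instead.
    """
    xbar = np.asarray(xbar, dtype=float)
    n = np.asarray(n)
    if xbar.size < MIN_REFERENCE:
        raise ValueError(
            f"null calibration needs at least {MIN_REFERENCE} reference perturbations, "
            f"got {xbar.size}; for control-based scoring add negative-control wells"
        )
    sq = (xbar - center) ** 2
    v = sampling_variance(n, N)
    if np.all(sq == 0.0):
        return NullCalibration(tau2=0.0, N=int(N), center=center, method=method)
    lo = -0.9 * float(np.min(v))
    G = sq.size

    tau_med = _match(sq, v, np.median, CHI2_1_MEDIAN, lo)
    n_out = int(np.sum(sq / (v + tau_med) > _REJECT_CUTOFF))
    max_null_out = int(stats.binom.ppf(0.999, G, _REJECT_RATE))

    if n_out <= max_null_out:
        cap = _WINSOR_CAP
        tau2 = _match(sq, v, lambda r: np.mean(np.minimum(r, cap)),
                      _winsorized_target(cap), lo)
        return NullCalibration(tau2=tau2, N=int(N), center=center, method=method)

    # contaminated regime: iterated rejection of presumed actives
    # E[X | X <= cutoff] for X ~ χ²₁
    target = float(stats.chi2.cdf(_REJECT_CUTOFF, 3) / stats.chi2.cdf(_REJECT_CUTOFF, 1))
    tau2 = tau_med
    for _ in range(50):
        keep = sq / (v + tau2) <= _REJECT_CUTOFF
        if keep.sum() < max(4, G // 2):
            break
        new = _match(sq[keep], v[keep], np.mean, target, lo)
        if abs(new - tau2) <= 1e-12 + 1e-10 * abs(tau2):
            tau2 = new
            break
        tau2 = new
    return NullCalibration(tau2=float(tau2), N=int(N), center=center, method=method)


def phi_scores(summaries: pd.DataFrame, calibration: NullCalibration) -> pd.Series:
    """Φ_g = (x̄_g − center) / sqrt(v(n_g) + τ̂²), indexed like ``summaries``."""
    n = summaries["n_cells"].to_numpy()
    if np.any(n >= calibration.N):
        raise ValueError("a single perturbation occupies the whole plate; Φ is undefined")
    phi = (summaries["mean_cell_score"].to_numpy() - calibration.center) / calibration.null_sd(n)
    return pd.Series(phi, index=summaries.index, name="phi")


def _negative_control_wells(gaussianized: pd.DataFrame, neg_role: str) -> pd.DataFrame:
    neg = gaussianized[gaussianized["role"] == neg_role]
    wells = neg.groupby("well_id").agg(
        n_cells=("cell_score", "size"),
        mean_cell_score=("cell_score", "mean"),
        mean_value=("value", "mean"),
    ).reset_index()
    return wells


def phi_scores_normalized(
    summaries: pd.DataFrame,
    gaussianized: pd.DataFrame,
    *,
    neg_role: str = "neg_control",
) -> tuple[pd.Series, NullCalibration]:
    """Control-normalized Φn for plates with many active perturbations.

    Each negative-control well is treated as an independent pseudo-
    perturbation; the mean control cell score recenters all perturbation
    means, and τ² is re-estimated from the per-well control means so the
    Gaussian P-value association survives.
    """
    wells = _negative_control_wells(gaussianized, neg_role)
    if len(wells) < MIN_REFERENCE:
        raise ValueError(
            f"Φn needs at least {MIN_REFERENCE} negative-control wells, got {len(wells)}"
        )
    N = len(gaussianized)
    neg_cells = gaussianized.loc[gaussianized["role"] == neg_role, "cell_score"]
    center = float(neg_cells.mean())
    calib = estimate_null_calibration(
        wells["mean_cell_score"].to_numpy(),
        wells["n_cells"].to_numpy(),
        N,
        center=center,
        method="neg_control_wells",
    )
    phin = phi_scores(summaries, calib)
    phin.name = "phin"
    return phin, calib


def z_scores(
    summaries: pd.DataFrame,
    *,
    robust: bool = False,
    reference_aggregates: np.ndarray | None = None,
) -> pd.Series:
    """Plate Z-score of per-perturbation raw-value aggregates.

    The aggregate is the mean raw cell value of the perturbation (cells
    pooled over replicate wells).  The reference population is the
    sample-role aggregates (controls are scored against it but excluded
    from it) unless ``reference_aggregates`` is given, e.g. per-well
    negative-control means for the Zn variant.  ``robust`` switches to
    median and 1.4826·MAD.
    """
    agg = summaries["mean_value"].to_numpy(dtype=float)
    if reference_aggregates is None:
        ref = agg[(summaries["role"] == "sample").to_numpy()]
        if ref.size < MIN_REFERENCE:
            raise ValueError(f"Z-score needs at least {MIN_REFERENCE} sample perturbations")
    else:
        ref = np.asarray(reference_aggregates, dtype=float)
        if ref.size < 2:
            raise ValueError("Z-score reference needs at least 2 aggregates")
    if robust:
        loc = np.median(ref)
        scale = MAD_SCALE * np.median(np.abs(ref - loc))
    else:
        loc = ref.mean()
        scale = ref.std(ddof=1)
    if scale == 0.0:
        raise ValueError("degenerate plate: zero spread in reference aggregates")
    return pd.Series((agg - loc) / scale, index=summaries.index, name="rz" if robust else "z")


def ssmd_scores(
    gaussianized: pd.DataFrame,
    summaries: pd.DataFrame,
    *,
    reference: str = "samples",
    neg_role: str = "neg_control",
) -> pd.Series:
    """Strictly standardized mean difference on raw cell values.

    SSMD_g = (μ_g − μ_ref) / sqrt(s_g² + s_ref²) with sample moments, where
    the reference is every *other* sample-role cell in the plate (default)
    or the negative-control cells (``reference="neg_control"``).
    """
    values = gaussianized["value"].to_numpy(dtype=float)
    pert = gaussianized["perturbation_id"].to_numpy()
    is_sample = (gaussianized["role"] == "sample").to_numpy()
    out = np.empty(len(summaries))
    for i, row in enumerate(summaries.itertuples(index=False)):
        own = pert == row.perturbation_id
        if reference == "neg_control":
            ref_mask = (gaussianized["role"] == neg_role).to_numpy() & ~own
        else:
            ref_mask = is_sample & ~own
        ref = values[ref_mask]
        if ref.size < 2:
            raise ValueError("SSMD reference population is empty or degenerate")
        g = values[own]
        s2g = g.var(ddof=1) if g.size > 1 else 0.0
        s2r = ref.var(ddof=1)
        denom = np.sqrt(s2g + s2r)
        if denom == 0.0:
            raise ValueError("SSMD undefined: zero variance in both populations")
        out[i] = (g.mean() - ref.mean()) / denom
    return pd.Series(out, index=summaries.index, name="ssmd")


def _signed_ks(own_sorted: np.ndarray, all_sorted: np.ndarray) -> float:
    """Signed sup-distance between the ECDF of a perturbation's cells and the
    ECDF of the rest of the plate, evaluated by a single pass over the pooled
    sorted sample.

    Sign convention: positive when the perturbation's values sit above the
    rest (its ECDF lags), matching the direction of Φ.  If the sup is
    attained at several points with differing signs, the smallest attaining
    value wins.
    """
    n_g = own_sorted.size
    n_all = all_sorted.size
    n_r = n_all - n_g
    if n_g == 0 or n_r == 0:
        raise ValueError("K-score needs a non-empty perturbation and rest-of-plate")
    # counts ≤ x at every pooled data point (ECDFs only step there)
    cum_g = np.searchsorted(own_sorted, all_sorted, side="right")
    cum_all = np.arange(1, n_all + 1)
    # value ties: keep only the last index of each run of equal values
    last = np.ones(n_all, dtype=bool)
    last[:-1] = all_sorted[:-1] != all_sorted[1:]
    f_g = cum_g[last] / n_g
    f_r = (cum_all[last] - cum_g[last]) / n_r
    diff = f_r - f_g
    i = int(np.argmax(np.abs(diff)))
    return float(diff[i])


def k_scores(gaussianized: pd.DataFrame, summaries: pd.DataFrame) -> pd.Series:
    """Signed Kolmogorov–Smirnov score of each perturbation against the rest
    of its plate, computed on the Gaussian cell scores (rank-invariant, so
    identical on raw values)."""
    order = np.argsort(gaussianized["cell_score"].to_numpy(), kind="stable")
    sorted_scores = gaussianized["cell_score"].to_numpy()[order]
    sorted_pert = gaussianized["perturbation_id"].to_numpy()[order]
    out = np.empty(len(summaries))
    for i, pid in enumerate(summaries["perturbation_id"]):
        own = sorted_scores[sorted_pert == pid]
        out[i] = _signed_ks(own, sorted_scores)
    return pd.Series(out, index=summaries.index, name="k")


def score_to_pvalue(score, *, sided: str = "two") -> np.ndarray:
    """Gaussian-null P-value for a Φ or Φn score.

    ``sided``: "two" (default), "upper" or "lower".  E.g. the upper
    one-sided P of a score of 3 is 1.35e-3.
    """
    score = np.asarray(score, dtype=float)
    if sided == "upper":
        return stats.norm.sf(score)
    if sided == "lower":
        return stats.norm.cdf(score)
    if sided == "two":
        return 2.0 * stats.norm.sf(np.abs(score))
    raise ValueError(f"sided must be 'two', 'upper' or 'lower', not {sided!r}")


def score_plate(
    cells: pd.DataFrame,
    *,
    methods=("phi",),
    neg_role: str = "neg_control",
    sided: str = "two",
    ssmd_reference: str = "samples",
) -> pd.DataFrame:
    """Compute all requested scores for the cells of one plate.

    Returns one row per perturbation with identity columns and one column
    per requested method; Φ and Φn carry Gaussian P-value columns.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown scoring method(s): {sorted(unknown)}")
    g = gaussianize_plate(cells) if "cell_score" not in cells.columns else cells
    summaries = summarize_perturbations(g)
    N = len(g)
    table = summaries[["perturbation_id", "plate_id", "role", "n_cells"]].copy()

    if "phi" in methods:
        samples = summaries[summaries["role"] == "sample"]
        calib = estimate_null_calibration(
            samples["mean_cell_score"].to_numpy(), samples["n_cells"].to_numpy(), N
        )
        table["phi"] = phi_scores(summaries, calib)
        table["p_phi"] = score_to_pvalue(table["phi"], sided=sided)
    if "phin" in methods:
        phin, _ = phi_scores_normalized(summaries, g, neg_role=neg_role)
        table["phin"] = phin
        table["p_phin"] = score_to_pvalue(phin, sided=sided)
    if "z" in methods:
        table["z"] = z_scores(summaries, robust=False)
    if "rz" in methods:
        table["rz"] = z_scores(summaries, robust=True)
    if "zn" in methods:
        wells = _negative_control_wells(g, neg_role)
        if len(wells) < MIN_REFERENCE:
            raise ValueError(
                f"Zn needs at least {MIN_REFERENCE} negative-control wells, got {len(wells)}"
            )
        table["zn"] = z_scores(
            summaries, robust=False, reference_aggregates=wells["mean_value"].to_numpy()
        )
    if "ssmd" in methods:
        table["ssmd"] = ssmd_scores(g, summaries, reference=ssmd_reference, neg_role=neg_role)
    if "k" in methods:
        table["k"] = k_scores(g, summaries)
    return table


def score_screen(
    cells: pd.DataFrame,
    *,
    methods=("phi",),
    neg_role: str = "neg_control",
    sided: str = "two",
    ssmd_reference: str = "samples",
    combine_plates: bool = False,
) -> pd.DataFrame:
    """Score every plate of a screen independently.

    With ``combine_plates=True``, cross-plate replicates of a perturbation
    are combined by Stouffer's method (sum of per-plate scores divided by
    the square root of the number of plates), which preserves the Gaussian
    null of Φ/Φn; P-values are recomputed from the combined scores.
    """
    parts = [
        score_plate(
            grp, methods=methods, neg_role=neg_role, sided=sided, ssmd_reference=ssmd_reference
        )
        for _, grp in cells.groupby("plate_id", sort=False)
    ]
    table = pd.concat(parts, ignore_index=True)
    if not combine_plates:
        return table
    score_cols = [c for c in table.columns if c in METHODS]
    grouped = table.groupby("perturbation_id", sort=False)
    combined = grouped.agg(role=("role", "first"), n_cells=("n_cells", "sum"))
    n_plates = grouped.size()
    for c in score_cols:
        combined[c] = grouped[c].sum() / np.sqrt(n_plates)
    combined = combined.reset_index()
    for c in ("phi", "phin"):
        if c in combined.columns:
            combined[f"p_{c}"] = score_to_pvalue(combined[c], sided=sided)
    return combined
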