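# Methods

## Scope and data model

The package scores perturbations in plate-based screens from single-cell
phenotype readouts. Input is a long-format table, one row per cell:
`plate_id`, `well_id`, `perturbation_id`, `role` (sample / negative
control / positive control) and a finite numeric `value`. All statistics
are computed per plate; multi-plate screens are scored plate by plate, and
cross-plate replicates of a perturbation can optionally be combined by
Stouffer's method (sum of per-plate scores over the square root of the
number of plates), which preserves a standard-normal null.

Cells with non-finite values are a hard error rather than a silent filter:
the robustness claims of rank-based scoring concern extreme but *finite*
values, and silently dropping records would bias cell counts, which enter
the variance model.

## Rank-to-Gaussian cell scores

Within a plate of `N` cells, each cell's value is ranked ascending
(midranks for ties) and mapped to `Q((r − ½)/N)` where `Q` is the standard
normal quantile function. The ½ offset keeps the extreme cells finite —
the raw fraction `r/N` would map the top cell to +∞, which would poison
the averaging step — and vanishes as `N` grows; it is the standard
quantile-normalization convention. Higher value maps to higher score, so a
positive perturbation score always means a phenotype increase. Tied values
share the midrank score, the least biased convention for imaging metrics
with quantized intensities. Gaussianization is never pooled across plates;
the per-plate transform is what removes plate effects.

Consequences used throughout: the scores of a plate with untied values are
a fixed grid depending only on `N` (population mean ~0, variance ~1), and
any strictly increasing transform of the raw metric leaves every
downstream rank-based score (Φ, Φn, K) unchanged.

## The Φ-score variance model

A perturbation `g` measured on `n_g` cells (replicate wells pooled at the
cell level — the perturbation score is defined as the average Gaussian
score of its *cells*) has mean cell score `x̄_g`. If the perturbation is
inactive, its cells are an exchangeable draw from the plate, so `x̄_g` is
the mean of a without-replacement sample from a finite population of `N`
scores with variance ≈ 1:

    Var(x̄_g) = v(n_g) = (1/n_g) · (N − n_g)/(N − 1).

Real plates show extra well-to-well variability beyond this sampling floor
(pipetting, incubation and position effects). It is modeled as an additive
plate-level overdispersion τ², giving

    Φ_g = x̄_g / sqrt(v(n_g) + τ̂²).

This form reproduces the method's defining properties: perturbations with
few cells are penalized (the denominator grows as `n` falls), the null is
approximately standard normal for any raw-value distribution (hence
P(Φ > 3) ≈ 1.35 × 10⁻³), and the calibration is robust to a minority of
active perturbations. The finite-population factor `(N − n)/(N − 1)` is
numerically negligible at plate scale (N ≫ n) but kept because it is
exact. The additive-overdispersion form itself is this package's modeling
choice, selected to satisfy those stated properties.

## Calibrating τ²

Under the null, `r_g = x̄_g² / (v(n_g) + τ²)` is χ²₁. τ̂² is found by
matching a robust functional of the observed ratios to its χ²₁
expectation, with a monotone bracketed root search (relative tolerance
1e-10). The reference set is all sample-role perturbations (≥ 8 required).
Two regimes:

**Clean regime (default).** Match the Winsorized mean
`mean(min(r_g, c))` with cap `c` at the χ²₁ 90th percentile (2.7055) to
its closed-form expectation (via `E[X·1{X≤c}] = F₃(c)` for X ~ χ²₁). The
cap bounds the influence of any single extreme perturbation; the mean of
the capped ratios is several times more efficient than a single quantile,
which matters at realistic reference sizes (~120 perturbations per
plate): calibration noise blurs the Gaussian null and — because the tail
is convex in the variance — systematically inflates P(Φ > 3). Small
*negative* τ̂² is allowed, floored so every reference variance stays
positive (−0.9 · min v), the classical method-of-moments convention for
variance components; clipping at zero would make the estimator
upward-biased under the null and deflate the tail. At scoring time the
modeled variance of any perturbation is additionally clamped at 10% of
its own sampling floor `v(n)`, so a negative τ̂² estimated on the
reference set can never zero out the variance of a perturbation pooled
over many more cells (e.g. controls).

**Contaminated regime.** A median-matched pre-fit (χ²₁ median 0.45494)
counts ratios above the χ²₁ 99th percentile; if the count exceeds the
0.999 binomial quantile of what a null reference set could produce, the
set is deemed to contain gross actives, and τ̂² is re-fit by iterated
outlier rejection: ratios above the cutoff are excluded and the mean of
the survivors is matched to the conditional expectation
`E[X | X ≤ cutoff]`, iterating to a fixed point. This keeps plates with a
large fraction (~20–30%) of strongly separated actives from inflating the
null variance.

Measured behavior at the standard plate design (120 perturbations in
triplicate, negative-binomial counts with mean 200, lognormal values): the
null Φ distribution has SD 0.999 and passes a Kolmogorov–Smirnov test
against N(0,1); the empirical P(Φ > 3) over ~10⁵ null perturbations is
within Monte-Carlo error of the Gaussian 1.35 × 10⁻³ (the acceptance
script recomputes this). τ² ∈ {0, 0.04} is recovered within ±0.01 on 10⁴
synthetic reference perturbations, with or without 30% strong actives.

Known limitation: perturbations with *weak*, non-separable activity (mean
shifts of ~1–3 null SDs) inflate τ̂² somewhat in any robust scheme; and
with > 20% of actives the plate-wide ranking itself drifts (inactive
perturbations acquire a common offset because actives push the rank
distribution). Both are inherent to whole-plate referencing; plates
expected to be dominated by actives should be scored with Φn.

## Φn: control-normalized variant

Each negative-control well is treated as an independent pseudo-
perturbation (≥ 8 wells required). The mean control cell score `c̄`
re-centers all perturbation means, and τ̂² is re-estimated from the
per-well control means (centered on `c̄`) with the same two-regime
matching. `Φn_g = (x̄_g − c̄)/sqrt(v(n_g) + τ̂²_neg)` keeps the Gaussian
P-value association on plates where the whole-plate reference is invalid.
With few control wells Φn is noticeably noisier than Φ — the center alone
carries sampling error of order `1/sqrt(total control cells)` — so it is a
complement for active-heavy plates, not a default.

## Comparator scores

* **Z**: perturbation aggregate = mean raw cell value (wells pooled);
  standardized against the mean and SD (ddof = 1) of sample-role
  aggregates. Controls are scored against this reference but excluded from
  it, so they cannot contaminate the null.
* **Robust Z**: same aggregate, median and 1.4826·MAD reference. Note that
  as a strictly increasing transform of the same aggregate it ranks
  perturbations identically to Z (equal AUCs); its benefit is score-value
  stability under outlier aggregates.
* **Zn**: aggregate standardized against per-well negative-control means.
* **SSMD**: `(μ_g − μ_ref)/sqrt(s_g² + s_ref²)` on raw cell values with
  sample moments; reference = all other sample cells in the plate, or
  negative-control cells by flag.
* **K-score**: signed Kolmogorov–Smirnov sup-distance between a
  perturbation's cell-score ECDF and the ECDF of all other cells in the
  plate, computed by a single pass over the pooled sorted sample
  (O(n log n)). Sign is positive when the perturbation's values sit above
  the rest, matching Φ's orientation; if the sup is attained at several
  points with differing signs, the smallest attaining value wins (a
  measure-zero tie in practice, made deterministic for reproducibility).

P-values are attached only to Φ/Φn (their null is calibrated standard
normal); two-sided by default, one-sided by flag. No multiple-testing
correction is applied inside scoring — hit calling uses thresholds.

## Gene-level merging

For designs with k siRNAs per gene (typically 3): each siRNA score is
clipped — |s| ≤ L ⇒ 0, |s| > U ⇒ ±U, defaults L = 3, U = 6, "exceeding"
read strictly so a score exactly at L is inactive and exactly at U is
kept — then summed, plus a bonus of (k′ − 1)·L when k′ ≥ 2 surviving
scores share a sign **and** no surviving score opposes them (contradictory
evidence earns no bonus). At the defaults this gives bonus 3 for two
concordant actives and 6 for three, and hit tiers at |merged| strictly
above 9 (hit), 12 (strong), 15 (high confidence: all three siRNAs active
in one direction). The bonus rule `(k′ − 1)·L` generalizes the printed
3/6 values to 4-siRNA designs; it is an extrapolation of this package.
The lower limit suppresses residual spatial/off-target noise; the ceiling
stops a single (possibly off-target) siRNA from dominating — formally,
any score beyond ±U contributes exactly as ±U would.

The absolute gene score (plain Σ|s_i|) is provided for benchmarking only;
it is deliberately sensitive to single-siRNA artifacts.

Hit-quality diagnostics: a sign-consistency test (observed count of genes
whose 3 siRNAs share a sign vs. a binomial null with per-gene probability
p³, p defaulting to the observed positive fraction among included siRNAs,
one-sided upper tail, both directions reported) and a generic one-sided
Fisher exact over-representation test of hit genes in user-supplied gene
sets. No multiple-testing correction is applied to enrichment P-values
(gene-ontology categories are nested, so independence corrections are
overly conservative); downstream interpretation should disregard P-values
above 1e-3.

## Simulator

One plate per call, deterministic per seed. Defaults encode the standard
benchmark condition: 384 wells, 120 perturbations in triplicate (360
occupied wells), 25 active; per-well cell count negative-binomial
(parameterized by mean and size; default size 5 for realistic count
overdispersion); per-cell baseline from a normal, lognormal (default
meanlog 5, sdlog 1.5) or two-component Gaussian-mixture distribution;
each cell of an active perturbation independently shows the effect with
probability `penetrance` (default 0.60, e.g. the chance of being
transfected), multiplying its value by `1 − effect` (default 0.30,
decrease direction; an increase flag exists). For mixture baselines only
the upper, reporter-positive component is eligible for the effect, and
`subset_positive_population` gates the screen to cells above a threshold,
modeling reporter-positive selection.

The default lognormal spread (sdlog 1.5, CV ≈ 290%) reflects
background-subtracted single-cell reporter intensities, which routinely
span two to three decades; it also places the benchmark in the informative
regime where AUC rises smoothly with cell number and the scoring methods
separate (mean AUC at 250 cells/well: Φ 0.996, K 0.99, Z 0.92; at 50
cells/well: Φ 0.89, Z 0.75). With a narrow spread every method saturates
at AUC 1 and comparisons degenerate.

What the simulator does **not** emulate: spatial/edge effects, well-level
random effects beyond cell-count variation, cytotoxicity coupling between
effect and cell number, and real segmentation artifacts. Passing
benchmarks therefore demonstrate correct statistical behavior under the
modeled noise, not performance on any particular instrument's output.

## Benchmarking

AUC is computed as the rank (Mann–Whitney) statistic with ties counted ½ —
exact, tie-safe, and invariant to monotone score transforms; direction
orients scores so the expected active direction counts as evidence. Score
separation of control populations uses the Z′ factor
`1 − 3(σ₊ + σ₋)/|μ₊ − μ₋|` on score distributions. Replicated grids
simulate `n_reps` screens per grid point with seed `base_seed + r`, score
every requested method on the *same* screens, and summarize mean ± SD of
AUC; two methods are compared by a paired two-sided Wilcoxon signed-rank
test on their per-screen AUCs (paired because both saw identical data;
all-zero differences return P = 1).

Problem sizes in the shipped tests and the acceptance script (800 null
plates for the tail calibration; 50 replicates × two cell-count levels for
the benchmark) were chosen so the Monte-Carlo error is a small fraction of
the tolerances being checked while a full run completes in minutes on one
CPU.

## Numerical and degenerate-input conventions

* Root searches (τ²) use Brent's method, relative tolerance 1e-10.
* A plate whose values are all identical scores every cell 0 (with a
  warning); a plate with < 2 cells, a perturbation occupying a whole
  plate, a zero-spread Z reference, and a zero-variance SSMD pair are
  errors.
* Reference minima: 8 perturbations for τ̂², 8 negative-control wells for
  Φn/Zn.
* Empty wells produced by the count distribution simply contribute no
  cells; a perturbation's `n` is whatever its wells delivered.
* Score tables are written at full float precision and round-trip
  losslessly.

## Known limitations

* The τ² regime router is binary; reference sets right at the detection
  boundary can flip regimes between nearby datasets (both regimes are
  individually well-calibrated).
* Φ's whole-plate ranking drifts when the active fraction exceeds ~20%
  (use Φn); Φn's precision is bounded by the number of control wells.
* SSMD uses raw-value moments and inherits their outlier sensitivity by
  design (it is a comparator, not a recommendation).
* The merged-score bonus for k > 3 siRNAs extrapolates the documented
  3-siRNA rule.
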