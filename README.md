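# phiscore

Rank-based, cell-number-corrected hit scoring for cell-based phenotypic
screens (RNAi or chemical, HTS/HCS), for screeners who have per-cell
phenotype readouts — one row per cell with its plate, well, perturbation and
a numeric metric such as mean reporter intensity — and need to decide which
perturbations are hits.

The classical plate Z-score aggregates cells per perturbation and
standardizes against the plate, which makes it sensitive to heavy-tailed
single-cell distributions, blind to how many cells a perturbation was
measured on, and only loosely attached to a P-value. The **Φ-score**
addresses all three:

1. Within each plate, every cell's value is rank-transformed to a Gaussian
   cell score, `Q((r − ½)/N)` with `Q` the standard normal quantile
   function, `r` the cell's rank and `N` the plate's cell total — robust to
   outliers and invariant to any monotone rescaling of the metric.
2. A perturbation's cells (pooled across its replicate wells) are averaged:
   `x̄_g` over `n_g` cells.
3. Under the null, `Var(x̄_g) = v(n_g) + τ²`, where
   `v(n) = (1/n)(N − n)/(N − 1)` is the exact variance of a
   without-replacement mean of `n` unit-variance scores and `τ² ≥ 0` is
   plate-level overdispersion, estimated robustly from the bulk of
   (presumed inactive) perturbations by χ²₁ moment matching. The score is

   `Φ_g = x̄_g / sqrt(v(n_g) + τ̂²)`.

Inactive perturbations score approximately standard normal, so Φ carries a
direct P-value (P(Φ > 3) ≈ 1.3 × 10⁻³) and perturbations measured on few
cells are automatically penalized. A control-normalized variant **Φn**
re-centers on negative-control wells for plates where a large fraction of
perturbations is genuinely active. Comparator scores (plate Z, robust Z,
Zn, SSMD, and the signed Kolmogorov–Smirnov **K-score** computed in
O(n log n)), a gene-level merging scheme for multi-siRNA designs, a plate
simulator with ground truth, and ROC/AUC benchmarking are included.

## Worked example

Simulate one 384-well plate (120 perturbations in triplicate, 12 active
with a 50% phenotype reduction at 90% penetrance, ~250 cells/well,
lognormal single-cell values), score it, and merge sets of three "siRNAs"
per gene:

```python
import pandas as pd
from phiscore import (SimulationConfig, simulate_screen,
                      score_screen, merge_gene_scores)

screen = simulate_screen(SimulationConfig(
    cells_mean=250, n_active=12, effect=0.5, penetrance=0.9, seed=1))
scores = score_screen(screen.cells, methods=("phi", "z", "k"))
print(scores.sort_values("phi").head(5).round(4))
```

```
perturbation_id  n_cells     phi  p_phi       z       k
      pert_0107      642 -7.7896    0.0 -2.6581 -0.2145
      pert_0057      656 -7.1378    0.0 -2.3030 -0.1797
      pert_0104      856 -7.0651    0.0 -2.7976 -0.1643
      pert_0095     1133 -6.7992    0.0 -1.9933 -0.1445
      pert_0037      645 -6.7214    0.0 -2.5586 -0.1620
```

All five are truly active. Negative scores mean the perturbation *reduced*
the phenotype; `p_phi` is the two-sided Gaussian P-value (here below 1e-10
and displayed as 0.0 at this rounding). Merging three siRNAs per gene
(clip at ±3/±6, same-sign bonus, hit tiers at |merged| > 9/12/15):

```python
genes = merge_gene_scores(scores, annotation, method="phi")
print(genes[genes.hit_tier != 0].round(2))
```

```
gene_id               sirna_scores  bonus  merged        hit_class
gene_03 -7.06515;-7.78964;-6.15168   -6.0  -24.00 -high_confidence
gene_02  -7.1378;-5.78498;-6.79924   -6.0  -23.78 -high_confidence
gene_00 -6.55165;-6.26332;-5.67302   -6.0  -23.67 -high_confidence
gene_01 -6.72137;-5.76579;-5.50894   -6.0  -23.27 -high_confidence
```

Exactly the four truly active genes are called, all at the
high-confidence tier (three concordant siRNAs), with no false positives.
On the standard benchmark design (25/120 active, 60% penetrance, 30%
effect, 50 simulation replicates) the mean AUC at 250 cells/well is 0.996
for Φ against 0.917 for Z (paired Wilcoxon P = 7.6e-10), and 0.888 against
0.748 at 50 cells/well.

The same pipeline is available from the shell:

```sh
phiscore simulate --config sim.yaml --seed 1 --out cells.csv --truth truth.csv
phiscore score --cells cells.csv --methods phi,phin,z,rz,ssmd,k --out scores.csv
phiscore merge --scores scores.csv --annotation genes.csv --method phi --out genes.csv
phiscore benchmark --grid cells_mean=50,100,150,200,250 --methods phi,z --reps 50 --seed 1 --out bench.csv
```

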