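"""Per-plate rank-to-Gaussian transform of raw phenotype values.

Every cell in a plate is ranked by its phenotype value (ascending, midranks
for ties) and the rank fraction is pushed through the standard normal
quantile function:

    cell_score = Phi^{-1}((r - 0.5) / N)

where ``r`` is the cell's rank and ``N`` the plate cell total.  The half
offset keeps every score finite (the raw fraction r/N would send the top
cell to +inf); it is the standard quantile-normalization convention and
vanishes as N grows.  Under exchangeability the scores are standard-normal
distributed, which is what makes the downstream perturbation score
calibratable to a Gaussian null.

Higher phenotype value always maps to higher cell score, so a positive
perturbation score means the perturbation increased the phenotype.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def gaussian_cell_scores(values: np.ndarray) -> np.ndarray:
    """Map raw values of one plate to van der Waerden-style Gaussian scores.

    Ties receive the average rank, so tied values get identical scores and
    any strictly increasing transform of ``values`` leaves the output
    unchanged.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError(f"a plate needs at least 2 cells to be ranked (got {n})")
    if not np.all(np.isfinite(values)):
        raise ValueError("phenotype values must be finite")
    ranks = stats.rankdata(values, method="average")
    if np.ptp(values) == 0.0:
        logger.warning("all %d phenotype values in plate are identical; all cell scores are 0", n)
    return stats.norm.ppf((ranks - 0.5) / n)


def gaussianize_plate(cells: pd.DataFrame) -> pd.DataFrame:
    """Attach a ``cell_score`` column to the cells of a single plate."""
    plates = cells["plate_id"].unique()
    if len(plates) != 1:
        raise ValueError(f"expected cells of exactly one plate, got {len(plates)}")
    out = cells.copy()
    out["cell_score"] = gaussian_cell_scores(out["value"].to_numpy())
    return out


def gaussianize(cells: pd.DataFrame) -> pd.DataFrame:
    """Gaussianize every plate of a multi-plate cell table independently.

    The transform is always per plate — pooling plates would let plate
    effects leak into the scores, defeating the point of the per-plate
    normalization.
    """
    parts = [gaussianize_plate(grp) for _, grp in cells.groupby("plate_id", sort=False)]
    return pd.concat(parts, ignore_index=False).loc[cells.index]
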