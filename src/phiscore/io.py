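"""Reading, validating and writing the tabular formats the tool touches.

All in-memory containers are plain :class:`pandas.DataFrame` objects in long
("tidy") layout:

* **cell table** — one row per cell with columns ``plate_id``, ``well_id``,
  ``perturbation_id``, ``role`` and ``value``.  High-content exports
  (InCell, Harmony, CellProfiler) are trivially reshaped to this layout;
  a column-name mapping accommodates dialects.
* **annotation table** — ``perturbation_id``, ``gene_id`` (one gene per
  perturbation, typically three siRNAs per gene).
* **score table** — one row per perturbation per plate with one column per
  requested score.

No statistics happen here; this module only validates structure.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Roles a well can carry.
ROLES = ("sample", "neg_control", "pos_control")

#: Required columns of a cell table, in canonical order.
CELL_COLUMNS = ("plate_id", "well_id", "perturbation_id", "role", "value")


class FormatError(ValueError):
    """A file does not have the expected structure (missing columns...)."""


class ValidationError(ValueError):
    """A file parses but violates a content invariant."""


def validate_cell_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Validate an in-memory cell table and return it with canonical dtypes.

    Raises
    ------
    FormatError
        If a required column is missing.
    ValidationError
        If values are non-finite, roles are unknown, a plate is empty, or a
        (plate, well) pair carries conflicting perturbation identifiers.
    """
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise FormatError(f"cell table is missing required column(s): {missing}")
    cells = cells.loc[:, list(CELL_COLUMNS)].copy()
    cells["value"] = pd.to_numeric(cells["value"], errors="coerce")
    bad = ~np.isfinite(cells["value"].to_numpy())
    if bad.any():
        idx = cells.index[bad][:10].tolist()
        raise ValidationError(
            f"{int(bad.sum())} cell(s) have non-finite phenotype values "
            f"(first offending row indices: {idx})"
        )
    unknown = set(cells["role"].unique()) - set(ROLES)
    if unknown:
        raise ValidationError(f"unknown role(s) {sorted(unknown)}; expected one of {ROLES}")
    if len(cells) == 0:
        raise ValidationError("cell table is empty")
    # a physical well carries exactly one perturbation
    per_well = cells.groupby(["plate_id", "well_id"], sort=False)["perturbation_id"].nunique()
    conflicts = per_well[per_well > 1]
    if len(conflicts):
        first = conflicts.index[0]
        raise ValidationError(
            f"{len(conflicts)} well(s) carry conflicting perturbation_ids "
            f"(first: plate={first[0]!r} well={first[1]!r})"
        )
    for plate_id, grp in cells.groupby("plate_id", sort=False):
        logger.info(
            "plate %s: %d cells in %d wells, %d perturbations",
            plate_id, len(grp), grp["well_id"].nunique(), grp["perturbation_id"].nunique(),
        )
    return cells


def read_cell_table(
    path,
    *,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> pd.DataFrame:
    """Read a long-format single-cell CSV into a validated cell table.

    Parameters
    ----------
    path
        CSV file with one row per cell.
    column_map
        Optional mapping from canonical names (``plate_id``...) to the names
        used in the file, for vendor dialects.
    delimiter
        Field separator, default ``","``.
    """
    raw = pd.read_csv(path, sep=delimiter, encoding="utf-8")
    if column_map:
        rename = {src: canon for canon, src in column_map.items()}
        missing = [s for s in rename if s not in raw.columns]
        if missing:
            raise FormatError(f"mapped column(s) not found in file: {missing}")
        raw = raw.rename(columns=rename)
    return validate_cell_table(raw)


def read_annotation(path, *, delimiter: str = ",") -> pd.DataFrame:
    """Read a perturbation-to-gene annotation CSV.

    Exact duplicate rows are deduplicated; a perturbation mapped to two
    different genes is a :class:`ValidationError`.
    """
    ann = pd.read_csv(path, sep=delimiter, encoding="utf-8")
    missing = [c for c in ("perturbation_id", "gene_id") if c not in ann.columns]
    if missing:
        raise FormatError(f"annotation is missing required column(s): {missing}")
    ann = ann.loc[:, ["perturbation_id", "gene_id"]].drop_duplicates(ignore_index=True)
    if len(ann) == 0:
        logger.warning("annotation file %s is empty", path)
        return ann
    genes_per = ann.groupby("perturbation_id")["gene_id"].nunique()
    conflict = genes_per[genes_per > 1]
    if len(conflict):
        raise ValidationError(
            f"perturbation(s) mapped to multiple genes: {conflict.index[:10].tolist()}"
        )
    return ann


def write_score_table(scores: pd.DataFrame, path) -> None:
    """Write a score table as CSV at full float precision (lossless round-trip)."""
    scores.to_csv(path, index=False, float_format="%.17g")


def read_score_table(path) -> pd.DataFrame:
    """Read back a score table written by :func:`write_score_table`."""
    return pd.read_csv(path)
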