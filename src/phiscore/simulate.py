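"""Synthetic plate-based screens with ground-truth activity labels.

The generator emulates a single 384-well high-content screening plate read
out at the single-cell level:

* perturbations occupy ``replicates`` wells each (default 120 perturbations
  in triplicate → 360 of 384 wells), assigned to well positions by a seeded
  permutation;
* the number of cells per well is negative-binomial (overdispersed counts,
  parameterized by mean and size);
* each cell's baseline phenotype value is drawn from a normal, lognormal or
  two-component Gaussian-mixture distribution (the mixture models reporter
  assays where only part of the population carries the reporter);
* in an *active* perturbation each cell independently shows the effect with
  probability ``penetrance`` (e.g. the probability of being transfected),
  multiplying its value by (1 − effect) — the default 60% penetrance and
  30% reduction;
* for mixture baselines only the upper (reporter-positive) component is
  eligible for the effect.

Default condition: 384 wells, 120 perturbations in triplicate of which 25
are active, penetrance 0.60, multiplicative reduction 0.30, lognormal
phenotypes and negative-binomial counts.  The default noise magnitudes are
the package's choice: lognormal sdlog 1.5 gives the heavy right tail of
background-subtracted single-cell reporter intensities (values spanning
two to three decades) and enough variability that hit recovery is neither
trivial nor hopeless across realistic cell counts; negative-binomial size
5 gives realistic well-to-well count overdispersion.  Both are exposed in
the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = ["PhenotypeDist", "SimulationConfig", "SimulatedScreen",
           "simulate_screen", "subset_positive_population"]


@dataclass(frozen=True)
class PhenotypeDist:
    """Baseline distribution of single-cell phenotype values.

    ``kind`` is one of ``"normal"`` (params: mean, sd), ``"lognormal"``
    (params: meanlog, sdlog) or ``"mixture"`` — a two-component Gaussian
    mixture with weight ``w`` on the upper, reporter-positive component
    (params: w, mean1, sd1, mean2, sd2; component 2 is the reporter-positive
    one eligible for the perturbation effect).
    """

    kind: str = "lognormal"
    params: dict = field(default_factory=lambda: {"meanlog": 5.0, "sdlog": 1.5})

    def __post_init__(self):
        required = {
            "normal": {"mean", "sd"},
            "lognormal": {"meanlog", "sdlog"},
            "mixture": {"w", "mean1", "sd1", "mean2", "sd2"},
        }
        if self.kind not in required:
            raise ValueError(f"unknown phenotype distribution kind {self.kind!r}")
        missing = required[self.kind] - set(self.params)
        if missing:
            raise ValueError(f"{self.kind} distribution missing parameter(s) {sorted(missing)}")

    def sample(self, size: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Draw baseline values; second return is the effect-eligibility mask
        (all cells except the reporter-negative mixture component)."""
        p = self.params
        if self.kind == "normal":
            return rng.normal(p["mean"], p["sd"], size), np.ones(size, dtype=bool)
        if self.kind == "lognormal":
            return rng.lognormal(p["meanlog"], p["sdlog"], size), np.ones(size, dtype=bool)
        positive = rng.random(size) < p["w"]
        values = np.where(
            positive,
            rng.normal(p["mean2"], p["sd2"], size),
            rng.normal(p["mean1"], p["sd1"], size),
        )
        return values, positive


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated plate."""

    n_wells: int = 384
    n_perturbations: int = 120
    replicates: int = 3
    n_active: int = 25
    penetrance: float = 0.60
    effect: float = 0.30
    cells_mean: float = 150.0
    cells_dispersion: float = 5.0
    phenotype: PhenotypeDist = field(default_factory=PhenotypeDist)
    direction: str = "decrease"
    seed: int = 0

    def __post_init__(self):
        if self.n_perturbations * self.replicates > self.n_wells:
            raise ValueError(
                f"{self.n_perturbations} perturbations x {self.replicates} replicates "
                f"do not fit in {self.n_wells} wells"
            )
        if not 0 <= self.n_active <= self.n_perturbations:
            raise ValueError("n_active must lie in [0, n_perturbations]")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must lie in [0, 1]")
        if not 0.0 <= self.effect < 1.0:
            raise ValueError("effect must lie in [0, 1)")
        if self.cells_mean <= 0 or self.cells_dispersion <= 0:
            raise ValueError("cells_mean and cells_dispersion must be positive")
        if self.direction not in ("decrease", "increase"):
            raise ValueError("direction must be 'decrease' or 'increase'")


@dataclass(frozen=True)
class SimulatedScreen:
    """A simulated cell table plus its ground truth and provenance."""

    cells: pd.DataFrame
    truth: pd.DataFrame  # perturbation_id, active (bool)
    config: SimulationConfig


def _well_names(n_wells: int) -> list[str]:
    rows = max(1, int(np.ceil(n_wells / 24)))
    names = [f"{chr(ord('A') + r)}{c + 1:02d}" for r in range(rows) for c in range(24)]
    return names[:n_wells]


def simulate_screen(config: SimulationConfig) -> SimulatedScreen:
    """Generate one plate according to ``config`` (deterministic per seed)."""
    rng = np.random.default_rng(config.seed)
    pert_ids = [f"pert_{i + 1:04d}" for i in range(config.n_perturbations)]
    active_idx = rng.choice(config.n_perturbations, size=config.n_active, replace=False)
    active = np.zeros(config.n_perturbations, dtype=bool)
    active[active_idx] = True

    wells = _well_names(config.n_wells)
    occupied = rng.permutation(config.n_wells)[: config.n_perturbations * config.replicates]
    # well i of the shuffled block belongs to perturbation i // replicates
    k = config.cells_dispersion
    p_nb = k / (k + config.cells_mean)
    factor = (1.0 - config.effect) if config.direction == "decrease" else 1.0 / (1.0 - config.effect)

    n_occ = occupied.size
    counts = rng.negative_binomial(k, p_nb, size=n_occ)
    well_col, pert_col, value_parts = [], [], []
    for j, well_idx in enumerate(occupied):
        pert = j // config.replicates
        n_cells = int(counts[j])
        if n_cells == 0:
            continue
        values, eligible = config.phenotype.sample(n_cells, rng)
        if active[pert] and config.penetrance > 0:
            affected = eligible & (rng.random(n_cells) < config.penetrance)
            values = np.where(affected, values * factor, values)
        well_col.append(np.full(n_cells, wells[well_idx]))
        pert_col.append(np.full(n_cells, pert_ids[pert]))
        value_parts.append(values)
    cells = pd.DataFrame(
        {
            "plate_id": "sim_plate",
            "well_id": np.concatenate(well_col),
            "perturbation_id": np.concatenate(pert_col),
            "role": "sample",
            "value": np.concatenate(value_parts),
        }
    )
    truth = pd.DataFrame({"perturbation_id": pert_ids, "active": active})
    return SimulatedScreen(cells=cells, truth=truth, config=config)


def subset_positive_population(screen: SimulatedScreen, threshold: float) -> SimulatedScreen:
    """Gate a mixture-phenotype screen to cells above ``threshold``.

    Models selecting the reporter-positive subpopulation before scoring,
    which restores rank-based scores' power when reporter-negative cells
    would otherwise dilute the signal.
    """
    if screen.config.phenotype.kind != "mixture":
        raise ValueError("positive-population gating requires a mixture phenotype")
    kept = screen.cells[screen.cells["value"] > threshold].reset_index(drop=True)
    if len(kept) == 0:
        raise ValueError("threshold removed every cell")
    return SimulatedScreen(cells=kept, truth=screen.truth, config=screen.config)


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a config from a plain dict (YAML/JSON file contents)."""
    d = dict(d)
    if "phenotype" in d and isinstance(d["phenotype"], dict):
        ph = dict(d["phenotype"])
        d["phenotype"] = PhenotypeDist(kind=ph.pop("kind", "lognormal"), params=ph.get("params", ph))
    return SimulationConfig(**d)


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["phenotype"] = {"kind": config.phenotype.kind, **config.phenotype.params}
    return d
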