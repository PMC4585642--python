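import numpy as np
import pandas as pd
import pytest

from phiscore import SimulationConfig, simulate_screen


@pytest.fixture
def small_plate():
    """Deterministic null plate: 12 sample perturbations x 2 wells x 30 cells,
    10 negative-control wells, 2 positive-control wells."""
    rng = np.random.default_rng(42)
    rows = []
    well = 0
    for p in range(12):
        for _ in range(2):
            well += 1
            for _ in range(30):
                rows.append(("P1", f"W{well:02d}", f"si{p:02d}", "sample", rng.lognormal(5, 1)))
    for w in range(10):
        well += 1
        for _ in range(30):
            rows.append(("P1", f"W{well:02d}", "neg", "neg_control", rng.lognormal(5, 1)))
    for w in range(2):
        well += 1
        for _ in range(30):
            rows.append(("P1", f"W{well:02d}", "pos", "pos_control", rng.lognormal(4.3, 1)))
    return pd.DataFrame(rows, columns=["plate_id", "well_id", "perturbation_id", "role", "value"])


@pytest.fixture
def tiny_screen():
    """Small simulated screen with known actives (fast to score)."""
    cfg = SimulationConfig(
        n_wells=96, n_perturbations=24, replicates=3, n_active=6,
        cells_mean=40, seed=7,
    )
    return simulate_screen(cfg)
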