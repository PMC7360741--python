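import numpy as np
import pandas as pd
import pytest

from tmadissect.simulate import PlantedFeature, SyntheticCohortConfig, generate_cohort
from tmadissect.tables import CellTable


def make_cells(
    n=8,
    panel=("mA", "mB"),
    spot_id="p000",
    slide_id="s0",
    seed=0,
    epi_fraction=0.5,
    **overrides,
):
    """Small hand-controllable cell table for unit tests."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "spot_id": spot_id,
            "slide_id": slide_id,
            "x": rng.uniform(0, 100, n),
            "y": rng.uniform(0, 100, n),
            "size_px": np.full(n, 30.0),
            "quality_index": np.ones(n),
            "ecad_positive": np.arange(n) < int(round(epi_fraction * n)),
        }
    )
    for m in panel:
        df[m] = rng.uniform(2, 10, n)
    for col, vals in overrides.items():
        df[col] = vals
    return CellTable(df=df, panel=list(panel), log2_applied=True)


@pytest.fixture(scope="session")
def planted_cohort():
    """Cell-level cohort with planted domain-specific prognostic signal."""
    cfg = SyntheticCohortConfig(
        n_patients=40,
        panel_size=8,
        n_epithelial=150,
        n_stromal=150,
        planted=(
            PlantedFeature("epithelial", "mean__m02", 1.0),
            PlantedFeature("stromal", "mean__m05", -1.0),
        ),
        target_event_fraction=0.4,
        seed=17,
    )
    return generate_cohort(cfg)
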