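import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import edi

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def tiny_cellmap() -> edi.CellMap:
    """Twelve cells in four 200-um tiles: three pure tiles and one mixed."""
    rows = []
    # tiles (0,0)/(0,1)/(1,0) hold 3 cells of a single class; (1,1) one of each
    for x, y, t in [
        (10, 10, "cancer"),
        (50, 90, "cancer"),
        (150, 150, "cancer"),
        (210, 10, "lymphocyte"),
        (350, 90, "lymphocyte"),
        (390, 150, "lymphocyte"),
        (10, 210, "stromal"),
        (90, 350, "stromal"),
        (150, 390, "stromal"),
        (210, 210, "cancer"),
        (290, 290, "lymphocyte"),
        (390, 390, "stromal"),
    ]:
        rows.append({"x_um": float(x), "y_um": float(y), "cell_type": t})
    return edi.CellMap(cells=pd.DataFrame(rows), tumor_id="tiny")


@pytest.fixture
def two_level_profile() -> np.ndarray:
    """Well-separated two-component score sample."""
    rng = np.random.default_rng(7)
    return np.concatenate(
        [rng.normal(0.3, 0.02, 200), rng.normal(1.0, 0.02, 200)]
    )


@pytest.fixture
def cohort_df() -> pd.DataFrame:
    return edi.validate_cohort(
        edi.simulate_cohort(edi.CohortSpec(n=400, hr_edi_high=2.0), seed=11)
    )
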