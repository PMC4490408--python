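import numpy as np
import pandas as pd
import pytest

from glycosurf import (
    CountMatrix,
    DesignEntry,
    SimulationConfig,
    TimecourseDesign,
    simulate_psm_table,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_groups=40, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """One PSM-level fixture shared across the suite (expensive-ish)."""
    return simulate_psm_table(small_config)


@pytest.fixture
def toy_design():
    entries = [
        DesignEntry("s1", 0, "MEF", 1),
        DesignEntry("s2", 0, "MEF", 2),
        DesignEntry("s3", 0, "MEF", 3),
        DesignEntry("s4", 2, "DOXH", 1),
        DesignEntry("s5", 2, "DOXH", 2),
        DesignEntry("s6", 2, "DOXH", 3),
    ]
    return TimecourseDesign(entries)


def make_averaged(values: np.ndarray, columns, points=None, groups=None):
    """Hand-build an averaged CountMatrix for downstream-analysis tests."""
    values = np.asarray(values, dtype=float)
    groups = groups or [f"g{i}" for i in range(values.shape[0])]
    points = points or {c: (i * 2, "DOXH") for i, c in enumerate(columns)}
    entries = [
        DesignEntry(f"{c}_r1", day, cond, 1) for c, (day, cond) in points.items()
    ]
    design = TimecourseDesign(entries)
    df = pd.DataFrame(np.asarray(values, dtype=float), index=groups, columns=columns)
    return CountMatrix(
        values=df, design=design, state="averaged", column_points=dict(points)
    )
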