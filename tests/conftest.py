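import numpy as np
import pandas as pd
import pytest

from trajgru.schema import default_schema
from trajgru.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def small_cohort():
    """30 subjects/group, 4 annual visits, 20% intermittent missingness."""
    cfg = SimulationConfig(n_subjects=30, n_visits=4, p_miss=0.2, p_drop=0.0, seed=7)
    return simulate(cfg).observed


@pytest.fixture(scope="session")
def small_truth():
    cfg = SimulationConfig(n_subjects=30, n_visits=4, p_miss=0.2, p_drop=0.0, seed=7)
    return simulate(cfg)


def make_cohort_csv(path, schema, n_subjects=2, n_visits=3, blank=()):
    """Write a complete long-format toy cohort CSV; ``blank`` holds
    (subject_row, feature_name, visit) cells to leave empty."""
    rng = np.random.default_rng(0)
    rows = []
    for si in range(n_subjects):
        base = {name: round(float(rng.uniform(1, 10)), 3) for name in schema.names}
        base["apoe_e4"] = float(si % 2)
        base["gender"] = float(si % 2)
        for t in range(n_visits):
            row = {
                "subject_id": f"S{si}",
                "visit_year": t,
                "label": "abeta_pos" if si % 2 else "abeta_neg",
            }
            for name in schema.names:
                val = base[name] + (t if name == "age" else 0.0)
                row[name] = np.nan if (si, name, t) in blank else val
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
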