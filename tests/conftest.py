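import numpy as np
import pandas as pd
import pytest

import rumenstab as rs


@pytest.fixture(scope="session")
def small_study():
    """A 20-animal x 6-timepoint study with 120 features, fixed seed."""
    return rs.simulate_study(rs.SimulationParams(n_features=120, seed=5))


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic study (400 features, 30 planted biomarkers)."""
    return rs.simulate_study(rs.SimulationParams(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def balanced_meta():
    """20 animals x 6 timepoints metadata with balanced diet/breed/additive."""
    animals = [f"A{j:02d}" for j in range(20)]
    rows = []
    for j, a in enumerate(animals):
        for t in range(1, 7):
            rows.append(
                {
                    "animal_id": a,
                    "timepoint": f"T{t}",
                    "diet": "CON" if j < 10 else "FOR",
                    "breed": "Charolais" if j % 2 == 0 else "Luing",
                    "additive": ["CTL", "NIT", "RSC"][j % 3],
                }
            )
    meta = pd.DataFrame(rows)
    meta.index = meta["animal_id"] + "_" + meta["timepoint"]
    return meta
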