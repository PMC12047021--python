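import numpy as np
import pandas as pd
import pytest

from mixrisk import exposure as exp
from mixrisk import synthetic as syn


@pytest.fixture(scope="session")
def table1():
    return exp.load_table1()


@pytest.fixture(scope="session")
def intext_noecs():
    return exp.load_intext_noecs()


@pytest.fixture()
def small_sim():
    """A small, fast synthetic campaign configuration."""
    return syn.SimConfig(n_sites=2, n_pesticides=4, n_samples_per_site=8, seed=123)


@pytest.fixture()
def small_truth(small_sim):
    return syn.draw_true_state(small_sim)


@pytest.fixture()
def control_jars():
    """A clean set of five control jars passing all validity criteria."""
    return pd.DataFrame({
        "site": "s", "treatment": "solvent_control",
        "replicate": range(1, 6), "introduced": 10,
        "adults_surviving": [9, 9, 8, 9, 10],
        "juveniles": [150, 140, 160, 120, 130],
        "adult_sizes": [[1.5, 1.4], [1.5], [1.6], [1.4], [1.5]],
    })


def jar_frame(treatment_to_juveniles: dict, adults: int = 9,
              site: str = "s") -> pd.DataFrame:
    """Build a jar table from a mapping treatment -> juvenile counts."""
    rows = []
    for treatment, juveniles in treatment_to_juveniles.items():
        for i, j in enumerate(juveniles):
            rows.append({
                "site": site, "treatment": treatment, "replicate": i + 1,
                "introduced": 10, "adults_surviving": adults, "juveniles": j,
                "adult_sizes": [1.5, 1.4, 1.6],
            })
    return pd.DataFrame(rows)
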