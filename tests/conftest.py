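import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_cell_table(n: int, seed: int, n_types: int = 3, section: str = "S1") -> pd.DataFrame:
    """Random cell table on a 1000 um field with lognormal volumes."""
    rng = np.random.default_rng(seed)
    types = [f"T{i}" for i in range(n_types)]
    return pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(n)],
        "section_id": section,
        "x_um": rng.uniform(0, 1000, n),
        "y_um": rng.uniform(0, 1000, n),
        "volume": rng.lognormal(6.0, 0.4, n),
        "cell_type": rng.choice(types, n),
    })


@pytest.fixture
def random_cells():
    return make_cell_table(30, seed=1)
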