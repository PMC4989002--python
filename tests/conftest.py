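import numpy as np
import pandas as pd
import pytest

from savagb.synthetic import SimulationConfig


@pytest.fixture
def config():
    return SimulationConfig(seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def three_species_occurrences():
    """Three species whose stem, frequency and basal-area shares coincide
    (50/30/20 %), so every IVI component equals the same proportion."""
    rows = []
    presence = {"A": 5, "B": 3, "C": 2}
    stems = {"A": 50, "B": 30, "C": 20}
    basal = {"A": 500.0, "B": 300.0, "C": 200.0}
    for sp, n_plots in presence.items():
        for j in range(n_plots):
            rows.append(
                {
                    "plot_id": f"P{j + 1}",
                    "species": sp,
                    "stem_count": stems[sp] / n_plots,
                    "basal_area_cm2": basal[sp] / n_plots,
                }
            )
    return pd.DataFrame(rows)
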