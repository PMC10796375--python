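import numpy as np
import pandas as pd
import pytest

from seedviab import ViabilityTable, all_seeds, gen_viability_table
from seedviab.seedcore import HUMAN_COLUMNS, MOUSE_COLUMNS


@pytest.fixture(scope="session")
def viab():
    """A complete synthetic viability screen shared across tests."""
    return gen_viability_table(2024)


def make_viability_table(overrides=None):
    """Complete table with all-50 values, selectively overridden.

    ``overrides`` maps seed -> (three human values, three mouse values).
    """
    seeds = all_seeds()
    frame = pd.DataFrame(
        50.0,
        index=pd.Index(seeds, name="seed"),
        columns=list(HUMAN_COLUMNS) + list(MOUSE_COLUMNS),
    )
    for seed, (human, mouse) in (overrides or {}).items():
        frame.loc[seed, list(HUMAN_COLUMNS)] = human
        frame.loc[seed, list(MOUSE_COLUMNS)] = mouse
    return ViabilityTable(frame)


@pytest.fixture(scope="session")
def flat_viab():
    """All-50 table with a few seeds pinned to known averages."""
    return make_viability_table(
        {
            "GGCAGU": ((20, 40, 60), (10, 20, 30)),
            "AAAAAA": ((100, 100, 100), (100, 100, 100)),
            "AAAAAC": ((20, 20, 20), (20, 20, 20)),
            "AAAAAG": ((80, 80, 80), (80, 80, 80)),
        }
    )


@pytest.fixture()
def random_annotated():
    """Factory for random annotated-like tables (seed, viability, weight)."""

    def _make(rng, n_rows, max_weight=5000.0):
        seeds = rng.choice(all_seeds(), size=n_rows, replace=True)
        seed_viab = {s: float(rng.uniform(0, 130)) for s in set(seeds)}
        return pd.DataFrame(
            {
                "seed": seeds,
                "rna_type": rng.choice(["miRNA", "RNAworld", "unknown"], size=n_rows),
                "viability": [seed_viab[s] for s in seeds],
                "weight": rng.uniform(0, max_weight, size=n_rows),
            }
        )

    return _make
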