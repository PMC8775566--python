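import numpy as np
import pandas as pd
import pytest

from linesense import SimConfig, simdata


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A small but fully featured panel: 20 lines, 2 ages, 2 treatments,
    3 blocks, 300 variants, 60-gene network."""
    return SimConfig(
        n_lines=20,
        n_flies_per_cell=6,
        n_variants=300,
        network_n_genes=60,
        planted_module_size=6,
        module_extra_edges=6,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simdata.simulate_dataset(small_config)


@pytest.fixture()
def two_line_mass_records() -> pd.DataFrame:
    """Two lines with unbalanced masses: the mass-adjustment worked
    example (common slope 1, adjusted means 2.0 and 4.0)."""
    return pd.DataFrame(
        {
            "line_id": ["L1", "L1", "L2", "L2"],
            "age": "young",
            "treatment": "control",
            "block": "b1",
            "mass_mg": [1.0, 2.0, 2.0, 3.0],
            "trait": "speed",
            "value": [1.0, 2.0, 4.0, 5.0],
        }
    )


def make_linemeans(age, control_means, treated_means, lines=None):
    """Assemble a line-means table from two dicts/lists of per-line means."""
    lines = lines or [f"L{i}" for i in range(1, len(control_means) + 1)]
    rows = []
    for treatment, means in (("control", control_means), ("treated", treated_means)):
        for line, m in zip(lines, means):
            if m is None:
                continue
            rows.append(
                {"line_id": line, "age": age, "treatment": treatment,
                 "lsmean": m, "se": 0.0, "n": 1}
            )
    return pd.DataFrame(rows)
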