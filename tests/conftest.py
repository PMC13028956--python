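import numpy as np
import pandas as pd
import pytest

from microlake import OtuTable, SimulationConfig, simulate_communities, to_relative


@pytest.fixture
def toy_table() -> OtuTable:
    return OtuTable(
        pd.DataFrame(
            [[5, 0], [3, 7], [2, 3]],
            index=["t1", "t2", "t3"],
            columns=["s1", "s2"],
        )
    )


@pytest.fixture
def toy_meta() -> pd.DataFrame:
    rows = []
    for region, n in (("hPollut", 4), ("HABs", 4), ("SubmP", 4)):
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{region}_{i + 1:02d}",
                    "region": region,
                    "plot": f"{region}_P1",
                    "replicate": str(i % 3 + 1),
                    "date": "2024-07-16",
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


@pytest.fixture(scope="session")
def neutral_sim():
    """Small neutral survey reused across read-only tests."""
    cfg = SimulationConfig(
        n_taxa=200, depth=5000, regime="neutral", samples_per_region=(4, 4, 4), seed=7
    )
    table, meta, truth = simulate_communities(cfg)
    return table, meta, truth


@pytest.fixture(scope="session")
def neutral_rel(neutral_sim):
    table, meta, _ = neutral_sim
    return to_relative(table), meta
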