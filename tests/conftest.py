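import numpy as np
import pandas as pd
import pytest

import pvstrat as pv


@pytest.fixture(scope="session")
def masking_ds():
    """One shared masking-scenario dataset (generation self-verifies)."""
    return pv.masking_scenario(seed=11)


@pytest.fixture(scope="session")
def default_ds():
    """A 50,000-report dataset from the default generative settings."""
    return pv.generate(pv.SimulationConfig(seed=3))


@pytest.fixture()
def small_counts():
    """Three-DEC table with hand-checkable margins."""
    return pv.DECCountTable.from_mapping(
        {("D1", "A1"): 2, ("D1", "A2"): 3, ("D2", "A1"): 4})


@pytest.fixture()
def random_counts():
    """A moderate random count table for conservation-style properties."""
    rng = np.random.default_rng(42)
    drugs = [f"D{i}" for i in rng.integers(0, 30, size=200)]
    adrs = [f"A{i}" for i in rng.integers(0, 15, size=200)]
    reports = pv.ReportSet.from_records(zip(drugs, adrs))
    return pv.aggregate(reports)


def signal_frame(rows):
    """Build a signal-table DataFrame from (drug, adr, ic025, positive) rows."""
    df = pd.DataFrame(rows, columns=["drug", "adr", "ic025", "positive"])
    df["stratum"] = "root"
    df["n11"] = 1
    df["expected"] = 1.0
    df["ic"] = df["ic025"] + 1.0
    return pv.io.make_signal_table(df)
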