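import numpy as np
import pandas as pd
import pytest

from dove import MortalityPanel, Period, SearchPanel, generate_panel


@pytest.fixture(scope="session")
def small_panel():
    """Small synthetic panel: 12 regions, 6 yearly periods, 12 keywords (2 informative)."""
    return generate_panel(
        n_regions=12, n_periods=6, n_keywords=12, m_informative=2, snr=4.0, seed=42
    )


@pytest.fixture(scope="session")
def medium_panel():
    """Study-shaped panel: 51 regions, 10 yearly periods, 80 keywords (5 informative)."""
    return generate_panel(n_regions=51, n_periods=10, n_keywords=80, m_informative=5, snr=2.0, seed=7)


def make_mortality(rates: dict[str, dict[Period, float]], population: float = 1_000_000.0) -> MortalityPanel:
    """Build a mortality panel from region -> period -> rate per 100,000."""
    idx, counts, pops = [], [], []
    for region, series in rates.items():
        for period, rate in series.items():
            idx.append((region, period))
            counts.append(rate * population / 1e5)
            pops.append(population)
    return MortalityPanel(
        pd.DataFrame(
            {"count": counts, "population": pops, "suppressed": False},
            index=pd.MultiIndex.from_tuples(idx, names=["region_id", "period"]),
        )
    )


def make_search(entries: dict[tuple[str, Period], dict[str, float]]) -> SearchPanel:
    """Build a search panel from (region, period) -> keyword -> rate."""
    df = pd.DataFrame.from_dict(entries, orient="index")
    df.index = pd.MultiIndex.from_tuples(df.index, names=["region_id", "period"])
    return SearchPanel(df)
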