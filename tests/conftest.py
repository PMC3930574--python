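import numpy as np
import pytest

from dysphonia import FeatureTable, SimConfig, VocalRecord, simulate_table, synthetic_uci_table

FOUR_MEASURES = ["MDVP:Fo(Hz)", "MDVP:Jitter(%)", "DFA", "spread2"]


@pytest.fixture(scope="session")
def uci_standin() -> FeatureTable:
    """Synthetic stand-in for the UCI-layout table (48 CO / 147 PD, 31 subjects)."""
    return synthetic_uci_table(seed=1)


@pytest.fixture(scope="session")
def four_measures() -> list[str]:
    return list(FOUR_MEASURES)


@pytest.fixture()
def separated_table() -> FeatureTable:
    """Two well-separated classes (mean shift = 10 SD), two measures."""
    table, _ = simulate_table(SimConfig(
        n_co=40, n_pd=80,
        informative={"m1": (0.0, 1.0, 10.0, 1.0), "m2": (0.0, 1.0, 10.0, 1.0)},
        seed=7))
    return table


def make_table(columns: dict[str, np.ndarray], labels: np.ndarray) -> FeatureTable:
    """Assemble a FeatureTable from raw column arrays (test helper)."""
    names = list(columns)
    n = len(labels)
    records = [
        VocalRecord(f"phon_R01_S{i // 4 + 1:02d}_{i % 4 + 1}", f"S{i // 4 + 1:02d}",
                    {m: float(columns[m][i]) for m in names}, str(labels[i]))
        for i in range(n)
    ]
    return FeatureTable(records, names)
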