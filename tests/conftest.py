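import numpy as np
import pytest

from mirnetox.io import CountMatrix, SampleRecord, SampleSheet
from mirnetox.simulate import SimulationConfig, simulate


@pytest.fixture
def tiny_matrix() -> CountMatrix:
    return CountMatrix(
        ["f1", "f2"], ["s1", "s2"], np.array([[3, 0], [7, 5]])
    )


@pytest.fixture
def triplicate_sheet() -> SampleSheet:
    records = []
    for regimen in ("co", "pre"):
        for condition in ("control", "treated"):
            for rep in (1, 2, 3):
                s = f"{regimen}_{condition}_{rep}"
                records.append(
                    SampleRecord(s, condition, regimen, rep, f"mi_{s}", f"mr_{s}")
                )
    return SampleSheet(records)


@pytest.fixture(scope="session")
def recovery_sim():
    """One strong-effect simulation shared by the recovery tests."""
    cfg = SimulationConfig(
        n_mirna=200, n_mrna=300, treatment_effect=3.0, dispersion=0.1,
        repression_strength=1.0, n_planted_pairs=40, seed=42,
    )
    return cfg, simulate(cfg)
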