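import numpy as np
import pandas as pd
import pytest

import fmen


@pytest.fixture(scope="session")
def small_catalog() -> pd.DataFrame:
    return fmen.generate_catalog(800, seed=41)


@pytest.fixture(scope="session")
def small_config() -> fmen.SimulationConfig:
    return fmen.SimulationConfig(
        n_probes=800,
        module_spec=[fmen.ModuleSpec(10, 0.9, "HL") for _ in range(4)]
        + [fmen.ModuleSpec(10, 0.95, "RAL") for _ in range(2)],
    )


@pytest.fixture(scope="session")
def small_dataset(small_catalog, small_config):
    sm, truth = fmen.simulate_two_lake(small_catalog, small_config, seed=42)
    return sm, truth


@pytest.fixture(scope="session")
def small_normalized(small_dataset):
    sm, _ = small_dataset
    nm, log = fmen.preprocess(sm)
    return nm


def make_signal_matrix(signal: np.ndarray, snr: np.ndarray | None = None,
                       groups=("A", "A", "B", "B")) -> fmen.SignalMatrix:
    """Tiny hand-built SignalMatrix for unit tests."""
    signal = np.asarray(signal, dtype=float)
    n, m = signal.shape
    samples = [f"{g}{i}" for i, g in enumerate(groups[:m], start=1)]
    probes = [f"p{i}" for i in range(n)]
    sig = pd.DataFrame(signal, index=probes, columns=samples)
    snr_df = pd.DataFrame(
        np.full_like(signal, 10.0) if snr is None else np.asarray(snr, dtype=float),
        index=probes, columns=samples)
    grp = pd.Series(list(groups[:m]), index=samples)
    return fmen.SignalMatrix(sig, snr_df, grp)
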