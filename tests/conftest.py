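import numpy as np
import pandas as pd
import pytest

from adipoewas import SynthConfig, simulate_study


@pytest.fixture(scope="session")
def bundle():
    """Medium synthetic study reused across read-only tests."""
    cfg = SynthConfig(n_per_stratum=100, n_probes=300, seed=11)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def corrupt_bundle():
    """Study with deliberately corrupted samples for the QC filters."""
    cfg = SynthConfig(n_per_stratum=50, n_probes=200, seed=23,
                      corrupt_missing_samples=2, corrupt_sex_samples=2)
    return simulate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_intensity(M, U, beadcount=None, neg=None, manifest=None):
    """Small IntensityData from plain arrays (probes x samples)."""
    from adipoewas import IntensityData

    M = pd.DataFrame(np.asarray(M, dtype=float))
    M.index = [f"p{i}" for i in range(M.shape[0])]
    M.columns = [f"s{j}" for j in range(M.shape[1])]
    U = pd.DataFrame(np.asarray(U, dtype=float), index=M.index, columns=M.columns)
    if beadcount is None:
        beadcount = pd.DataFrame(10, index=M.index, columns=M.columns)
    else:
        beadcount = pd.DataFrame(np.asarray(beadcount), index=M.index,
                                 columns=M.columns)
    if neg is None:
        neg = np.zeros((2, M.shape[1]))
    neg = np.asarray(neg, dtype=float)
    controls = pd.DataFrame(neg, columns=M.columns,
                            index=[f"neg{i}" for i in range(neg.shape[0])])
    controls.insert(0, "control_type", "NEGATIVE")
    if manifest is None:
        manifest = pd.DataFrame(
            {"chr": "1", "pos": np.arange(1, M.shape[0] + 1) * 1000},
            index=M.index)
    return IntensityData(M=M, U=U, beadcount=beadcount, controls=controls,
                         manifest=manifest)
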