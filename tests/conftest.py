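import numpy as np
import pandas as pd
import pytest

from gg1tx.io_qc import normalize_log2
from gg1tx.simulate import SimulationConfig, simulate_cohort

# Dirichlet regimes with strongly separated tumour/benign compositions, used
# by the recovery-style checks that assume well-separated mixture profiles.
STRONG_MIXTURES = {
    "tumour": (1.0, 15.0, 1.5, 1.5, 0.8),
    "benign": (5.0, 2.0, 8.0, 5.0, 2.5),
}


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at package defaults (34/26/47 samples, 2000 genes)."""
    cfg = SimulationConfig(seed=11)
    cm, md, truth = simulate_cohort(cfg)
    return cfg, cm, md, truth


@pytest.fixture(scope="session")
def default_expression(default_cohort):
    _, cm, md, truth = default_cohort
    return normalize_log2(cm), md, truth


@pytest.fixture()
def tiny_counts():
    """Hand-sized count matrix for filter/normalisation checks."""
    rng = np.random.default_rng(0)
    cm = pd.DataFrame(
        rng.integers(0, 200, size=(30, 6)),
        index=[f"g{i:02d}" for i in range(30)],
        columns=[f"s{j}" for j in range(6)],
    )
    return cm


def ancestry_groups(md):
    """Group labels for the ancestry contrast among cancer samples
    (African GG1-PCa vs European GG1-PCa) — exchangeable under a null
    simulation because both groups share the tumour mixture regime."""
    return pd.Series(
        np.where(
            (md["ancestry"] == "African") & (md["cancer_status"] == "PCa"),
            "African",
            np.where(md["ancestry"] == "European", "European", "other"),
        ),
        index=md.index,
    )
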