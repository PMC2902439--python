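import numpy as np
import pandas as pd
import pytest

from eigencis import synthdata


@pytest.fixture(scope="session")
def small_bundle():
    """One small paired dataset shared across read-only tests."""
    cfg = synthdata.SynthConfig(
        seed=42, n_genes_a=300, n_genes_b=250, frac_shared=0.4, n_motif_families=15
    )
    return synthdata.simulate(cfg)


@pytest.fixture
def toy_design():
    """Two conditions x three arrays each."""
    rows = []
    for c in ("c1", "c2"):
        for r in (1, 2, 3):
            rows.append((f"{c}_r{r}", c, 0.0, "treated", r))
    return pd.DataFrame(
        rows, columns=["array_id", "condition_id", "time_h", "treatment", "replicate"]
    )


def make_signal(toy_design, values_by_probeset):
    cols = list(toy_design["array_id"])
    return pd.DataFrame(values_by_probeset, index=cols).T


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
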