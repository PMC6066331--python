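import logging

import numpy as np
import pandas as pd
import pytest

from mirdyn import simulate
from mirdyn.windows import default_windows

# The pipeline logs filter casualties at INFO; keep test output readable.
logging.getLogger("mirdyn").setLevel(logging.ERROR)

WINDOW_LABELS = [w.label for w in default_windows()]
UNIFORM_2H = tuple((2 * i, 2 * i + 2) for i in range(8))


@pytest.fixture(scope="session")
def small_panel():
    """A small neutral SNP panel shared by popgen tests."""
    cfg = simulate.SimConfig(
        a=[0.1], b=[1.0], m0=[1.0], pulses=[[]],
        popgen=simulate.PopgenConfig(n_sites=100, n_lines=21),
        rng_seed=42,
    )
    return simulate.simulate_snp_panel(cfg)


def time_course(values, genes=None, labels=None) -> pd.DataFrame:
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    labels = labels or WINDOW_LABELS[: arr.shape[1]]
    return pd.DataFrame(arr, index=pd.Index(genes, name="gene"), columns=labels)
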