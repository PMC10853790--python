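import numpy as np
import pandas as pd
import pytest

from hkcre.pipeline import run_pipeline
from hkcre.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def bundle_truth():
    """One default synthetic bundle shared across the suite."""
    return generate(SyntheticConfig(), seed=11)


@pytest.fixture(scope="session")
def bundle(bundle_truth):
    return bundle_truth[0]


@pytest.fixture(scope="session")
def truth(bundle_truth):
    return bundle_truth[1]


@pytest.fixture(scope="session")
def pipeline_result(bundle):
    cfg = SyntheticConfig().pipeline_config()
    return run_pipeline(bundle, cfg, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_region_frame(rng, n, n_chroms=2, max_pos=10_000, max_len=300, cell_types=None):
    """Small random interval table for oracle comparisons."""
    chroms = [f"chr{i+1}" for i in rng.integers(0, n_chroms, size=n)]
    starts = rng.integers(0, max_pos, size=n)
    lengths = rng.integers(1, max_len, size=n)
    df = pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": starts + lengths}
    )
    if cell_types is not None:
        df["cell_type"] = rng.choice(cell_types, size=n)
    return df
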