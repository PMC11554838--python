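import numpy as np
import pandas as pd
import pytest

from chemoresist import LOG2, AnalyteMatrix, RunConfig, SignedGeneSet


@pytest.fixture
def config():
    return RunConfig(seed=123)


@pytest.fixture
def sfk_set():
    return SignedGeneSet("SFK", ["SRC", "FYN"], ["SRC_pY527"])


@pytest.fixture
def tiny_log2_matrix():
    """3-analyte, 1-sample matrix for the worked PAS example."""
    values = pd.DataFrame({"s1": [1.0, 2.0, 0.5]}, index=["SRC", "FYN", "SRC_pY527"])
    return AnalyteMatrix(values, scale=LOG2)


def random_log2_matrix(rng, n_analytes=20, n_samples=8, missing_fraction=0.0):
    vals = rng.normal(0.0, 1.0, size=(n_analytes, n_samples))
    if missing_fraction:
        mask = rng.random(vals.shape) < missing_fraction
        # keep every row and column partially observed
        mask[:, 0] = False
        mask[0, :] = False
        vals = np.where(mask, np.nan, vals)
    idx = [f"A{i:03d}" for i in range(n_analytes)]
    cols = [f"s{j:03d}" for j in range(n_samples)]
    return AnalyteMatrix(pd.DataFrame(vals, index=idx, columns=cols), scale=LOG2)
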