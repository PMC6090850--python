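import numpy as np
import pandas as pd
import pytest

from neutromap.expression import ExpressionMatrix


def make_matrix(values, samples=None, scale="linear", **meta_overrides):
    """Build an ExpressionMatrix from a 2-D array with default metadata."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    genes = [f"g{i}" for i in range(n_genes)]
    meta = pd.DataFrame(
        {
            "species": meta_overrides.get("species", ["human"] * n_samples),
            "lab": meta_overrides.get("lab", ["lab1"] * n_samples),
            "condition": meta_overrides.get("condition", ["c"] * n_samples),
            "replicate": meta_overrides.get("replicate", list(range(n_samples))),
            "day": meta_overrides.get("day", [0] * n_samples),
            "reference_group": meta_overrides.get("reference_group", [True] * n_samples),
        },
        index=samples,
    )
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), meta, scale)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    """10 genes x 3 samples of positive FPKM-like values."""
    return make_matrix(10.0 ** rng.normal(0.5, 1.0, size=(10, 3)))
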