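import numpy as np
import pandas as pd
import pytest

from cholnet import ExpressionMatrix, RunConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_two_group():
    """3 genes x 4 samples, groups A/B of size 2."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [5.0, 5.0, 5.0, 5.0],
         [0.0, 0.0, 1.0, 1.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    design = {"s1": "A", "s2": "A", "s3": "B", "s4": "B"}
    return ExpressionMatrix(values=values, design=design)


@pytest.fixture
def default_config():
    return RunConfig()


def random_matrix(rng, n_genes, n_per_group, labels=("A", "B")):
    la, lb = labels
    samples = [f"{la}{i}" for i in range(n_per_group)] + \
              [f"{lb}{i}" for i in range(n_per_group)]
    design = {s: (la if i < n_per_group else lb) for i, s in enumerate(samples)}
    values = pd.DataFrame(
        rng.normal(7, 1.5, size=(n_genes, 2 * n_per_group)),
        index=[f"g{i:03d}" for i in range(n_genes)],
        columns=samples,
    )
    return ExpressionMatrix(values=values, design=design)
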