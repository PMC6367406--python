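import numpy as np
import pytest

from tnbclayers.io import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    """4 probes (3 genes: G1 has two probes) x 5 samples, raw scale."""
    values = rng.uniform(5.0, 50.0, size=(4, 5))
    return ExpressionMatrix(
        probe_ids=["p1", "p2", "p3", "p4"],
        gene_ids=["G1", "G1", "G2", "G3"],
        sample_ids=[f"S{i}" for i in range(1, 6)],
        values=values,
        scale_flag="raw",
    )


@pytest.fixture
def centered_matrix(rng):
    """20 genes x 30 samples, mean-centered, unique gene ids."""
    values = rng.standard_normal((20, 30))
    values -= values.mean(axis=1, keepdims=True)
    genes = [f"G{i:02d}" for i in range(20)]
    return ExpressionMatrix(
        probe_ids=genes,
        gene_ids=genes,
        sample_ids=[f"S{i:02d}" for i in range(30)],
        values=values,
        scale_flag="centered",
    )
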