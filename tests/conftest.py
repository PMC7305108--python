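import numpy as np
import pandas as pd
import pytest

from codc.containers import PairedExpression, RawCountMatrix


def build_paired(normal: np.ndarray, tumor: np.ndarray) -> PairedExpression:
    """Wrap two genes x pairs arrays into a PairedExpression with default ids."""
    p, n = np.shape(normal)
    genes = [f"g{i:03d}" for i in range(p)]
    pairs = [f"p{k:03d}" for k in range(n)]
    return PairedExpression(
        normal=pd.DataFrame(np.asarray(normal, float), index=genes, columns=pairs),
        tumor=pd.DataFrame(np.asarray(tumor, float), index=genes, columns=pairs),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def make_paired():
    return build_paired


@pytest.fixture
def small_paired(rng) -> PairedExpression:
    """10 independent Gaussian genes, 20 matched pairs."""
    return build_paired(rng.normal(5, 1, (10, 20)), rng.normal(5, 1, (10, 20)))


@pytest.fixture
def raw_counts() -> RawCountMatrix:
    """6 genes x 6 samples (3 matched pairs) with simple integer counts."""
    rng = np.random.default_rng(7)
    counts = pd.DataFrame(
        rng.integers(0, 50, (6, 6)),
        index=[f"g{i}" for i in range(6)],
        columns=[f"s{i}" for i in range(6)],
    )
    samples = pd.DataFrame(
        {
            "condition": ["normal", "normal", "normal", "tumor", "tumor", "tumor"],
            "pair_id": ["a", "b", "c", "a", "b", "c"],
        },
        index=counts.columns,
    )
    return RawCountMatrix(counts=counts, samples=samples)
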