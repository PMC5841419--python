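import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cerna_net import ExpressionMatrix, SyntheticConfig, generate_dataset

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """A reduced planted configuration for fast unit tests."""
    return SyntheticConfig(
        n_mirna=100,
        n_mrna=120,
        n_lncrna=20,
        per_gene_targets=15.0,
        n_planted_pairs=6,
        shared_k=10,
        n_blocks=3,
        lnc_per_block=1,
        n_de_mrna=40,
        n_de_lncrna=8,
        n_group0=15,
        n_group1=15,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return generate_dataset(small_cfg)


def make_expression(values: np.ndarray, classes=None, prefix="G") -> ExpressionMatrix:
    """Wrap a raw array as an ExpressionMatrix with default mRNA classes."""
    values = np.asarray(values, dtype=float)
    genes = [f"{prefix}{i}" for i in range(values.shape[0])]
    samples = [f"S{j}" for j in range(values.shape[1])]
    if classes is None:
        classes = ["mRNA"] * len(genes)
    df = pd.DataFrame(values, index=genes, columns=samples)
    return ExpressionMatrix(df, pd.Series(classes, index=genes))


def make_labels(n0: int, n1: int) -> pd.Series:
    return pd.Series(
        [0] * n0 + [1] * n1, index=[f"S{j}" for j in range(n0 + n1)], name="label"
    )
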