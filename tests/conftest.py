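import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from diffcoex import CoexpressionTable, ExpressionDataset

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(2021)


@pytest.fixture
def small_dataset(rng):
    """5 genes x (6 disease + 5 normal) samples, unstructured noise."""
    genes = [f"G{i}" for i in range(5)]
    samples = [f"D{i}" for i in range(6)] + [f"N{i}" for i in range(5)]
    values = pd.DataFrame(
        rng.standard_normal((5, 11)), index=genes, columns=samples
    )
    group_of = {s: ("disease" if s.startswith("D") else "normal") for s in samples}
    return ExpressionDataset(values, group_of)


def random_pair_table(rng, n_pairs):
    """A synthetic coexpression table with uniform-random levels."""
    genes = [f"g{i}" for i in range(n_pairs + 1)]
    r_d = rng.uniform(-1, 1, n_pairs)
    r_n = rng.uniform(-1, 1, n_pairs)
    df = pd.DataFrame(
        {
            "gene_a": genes[:-1],
            "gene_b": genes[1:],
            "r_disease": r_d,
            "r_normal": r_n,
            "c_disease": np.abs(r_d),
            "c_normal": np.abs(r_n),
        }
    )
    # chain pairs g0-g1, g1-g2, ... gives a valid unordered pair universe
    df[["gene_a", "gene_b"]] = np.sort(df[["gene_a", "gene_b"]].to_numpy(), axis=1)
    return CoexpressionTable(df, n_genes=n_pairs + 1)
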