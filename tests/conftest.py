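import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from nbclass import (
    ExpressionMatrix,
    LabeledDataset,
    label_dataset,
)
from nbclass.synthetic import SyntheticSpec, generate_dataset

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def tiny_expr() -> ExpressionMatrix:
    """3 genes x 4 cell lines, small enough to reason about by hand."""
    data = pd.DataFrame(
        {
            "A": [0.1, 1.0, 5.0],
            "B": [0.2, 2.0, 5.0],
            "C": [0.9, 3.0, 5.0],
            "D": [1.0, 4.0, 5.0],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene"),
    )
    return ExpressionMatrix(data)


def _labeled(ds) -> LabeledDataset:
    return label_dataset(ds.expression, ds.responses.for_drug(ds.drug), ds.cutoffs)


@pytest.fixture(scope="session")
def recovery_dataset():
    """Two classes distinguished only by which genes co-vary (divergence 1)."""
    return generate_dataset(SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def recovery_labeled(recovery_dataset) -> LabeledDataset:
    return _labeled(recovery_dataset)


@pytest.fixture(scope="session")
def null_dataset():
    """Exchangeable classes: identical block structure (divergence 0)."""
    return generate_dataset(SyntheticSpec(block_assignment_divergence=0.0, seed=7))


@pytest.fixture(scope="session")
def null_labeled(null_dataset) -> LabeledDataset:
    return _labeled(null_dataset)


@pytest.fixture(scope="session")
def small_two_class():
    """Compact dataset (30 genes, 40/class) for fast model-level tests."""
    ds = generate_dataset(
        SyntheticSpec(n_genes=30, n_per_class=40, n_blocks=3, seed=11)
    )
    labeled = _labeled(ds)
    return ds, labeled


def random_class_expr(rng: np.random.Generator, n_samples: int, n_genes: int) -> pd.DataFrame:
    """Unstructured samples x genes frame used by brute-force oracle tests."""
    genes = [f"g{i}" for i in range(n_genes)]
    return pd.DataFrame(rng.normal(size=(n_samples, n_genes)), columns=genes)
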