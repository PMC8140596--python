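import numpy as np
import pandas as pd
import pytest

from mirgrank import ExpressionMatrix, PairedDataset, SyntheticSpec, generate


def matrix_from_arrays(values, classes, samples=None, features=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    samples = samples or [f"s{i+1}" for i in range(n)]
    features = features or [f"f{j+1}" for j in range(p)]
    index = pd.Index(samples, name="Case ID")
    return ExpressionMatrix(
        pd.DataFrame(values, index=index, columns=features),
        pd.Series(list(classes), index=index, name="class"),
    )


@pytest.fixture
def make_matrix():
    return matrix_from_arrays


@pytest.fixture
def table3_csv(tmp_path):
    """A gene expression table in the documented input layout."""
    path = tmp_path / "genes.csv"
    path.write_text(
        "Case ID,Class,A1BG,A2LD1,ZZZ3\n"
        "TCGA-DK-A6AV,neg,32.877,28.283,721.166\n"
        "TCGA-DK-A3WX,neg,39.634,57.526,593.293\n"
        "TCGA-GC-A3WC,pos,29.789,98.344,1057.069\n"
        "TCGA-BT-A20N,pos,37.378,55.011,755.688\n"
    )
    return path


@pytest.fixture(scope="session")
def small_planted_pair():
    """A small planted-signal paired dataset plus its ground truth."""
    spec = SyntheticSpec(
        n_samples_per_class=60,
        n_mirna=12,
        n_genes=120,
        n_planted=3,
        targets_per_planted=8,
        target_correlation=-0.8,
        class_effect=1.5,
        seed=42,
    )
    return generate(spec)
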