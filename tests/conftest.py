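import numpy as np
import pandas as pd
import pytest

from mucocilia.genesets import builtin_registry
from mucocilia.preprocess import CountMatrix, ExpressionMatrix, SampleMetadata


@pytest.fixture
def registry():
    return builtin_registry()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_expr(values, genes, samples, space="log2cpm1"):
    return ExpressionMatrix(
        pd.DataFrame(np.asarray(values, float), index=genes, columns=samples), space=space
    )


def make_counts(values, genes=None, samples=None):
    arr = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return CountMatrix(pd.DataFrame(arr, index=genes, columns=samples))


def singleton_metadata(sample_ids, groups):
    """Metadata where every sample is its own patient (cross-sectional)."""
    return SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": list(sample_ids),
                "patient_id": [f"pt_{s}" for s in sample_ids],
                "group": list(groups),
            }
        )
    )


def paired_metadata(n_patients, prefix="E"):
    """Pre/Post paired design with one Pre and one Post sample per patient."""
    pats = [f"{prefix}{i:02d}" for i in range(n_patients)]
    return SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": [f"{p}_Pre" for p in pats] + [f"{p}_Post" for p in pats],
                "patient_id": pats * 2,
                "group": ["PreECRS"] * n_patients + ["PostECRS"] * n_patients,
            }
        )
    )
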