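import numpy as np
import pytest

from pasl.containers import ExpressionMatrix, GenesetCollection
from pasl.io import build_membership


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_expression(rng):
    """30x40 random matrix with ids, standard normal entries."""
    values = rng.normal(size=(30, 40))
    return ExpressionMatrix(
        values=values,
        sample_ids=[f"s{i}" for i in range(30)],
        feature_ids=[f"f{j}" for j in range(40)],
    )


@pytest.fixture
def all_covering_membership(random_expression):
    """A single geneset spanning every feature (reduces the method to PCA)."""
    genesets = GenesetCollection(
        [("ALL", "covers everything", frozenset(random_expression.feature_ids))]
    )
    return build_membership(genesets, random_expression.feature_ids)


def make_expression(values, prefix=("s", "f")):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values=values,
        sample_ids=[f"{prefix[0]}{i}" for i in range(values.shape[0])],
        feature_ids=[f"{prefix[1]}{j}" for j in range(values.shape[1])],
    )
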