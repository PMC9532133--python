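import numpy as np
import pandas as pd
import pytest

from mirnetprox.io import ExpressionMatrix
from mirnetprox.synthetic_data import generate_study


def make_matrix(data: dict[str, list[float]], groups: dict[str, str]) -> ExpressionMatrix:
    """Tiny expression matrix from {feature: row values} plus sample->group."""
    samples = list(groups)
    values = pd.DataFrame.from_dict(data, orient="index", columns=samples)
    return ExpressionMatrix(values, pd.Series(groups))


def two_group_labels(n_case: int, n_ctrl: int, case="HF", ctrl="healthy") -> dict[str, str]:
    labels = {f"{case}_{i}": case for i in range(n_case)}
    labels.update({f"{ctrl}_{i}": ctrl for i in range(n_ctrl)})
    return labels


def random_matrix(rng, n_features: int, groups: dict[str, str]) -> ExpressionMatrix:
    samples = list(groups)
    values = pd.DataFrame(
        rng.normal(7.0, 1.0, size=(n_features, len(samples))),
        index=[f"G{i:04d}" for i in range(n_features)],
        columns=samples,
    )
    return ExpressionMatrix(values, pd.Series(groups))


@pytest.fixture(scope="session")
def study():
    """One coherent planted-truth study shared across tests."""
    return generate_study(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
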