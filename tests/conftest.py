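import numpy as np
import pytest

from coexscreen import ExpressionMatrix


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples, fixed values."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [4.0, 3.0, 2.0, 1.0],
            [2.5, 2.5, 2.5, 2.5],
        ]
    )
    return ExpressionMatrix(["G1", "G2", "G3"], ["S1", "S2", "S3", "S4"], values)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def pearson(x, y):
    """Independent Pearson correlation oracle used by several test modules."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        return 0.0
    return float((xc * yc).sum() / denom)
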