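import numpy as np
import pytest

from sccausal.expression import ExpressionMatrix


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes × 4 cells raw fixture with one silent gene."""
    values = np.array(
        [
            [0.0, 0.0, 4.0, 4.0],
            [1.0, 2.0, 3.0, 4.0],
            [0.0, 0.0, 0.0, 0.0],
        ]
    )
    return ExpressionMatrix(values, ("GATA1", "TAL1", "SPI1"), ("c1", "c2", "c3", "c4"))


def make_matrix(values: np.ndarray, transform: str = "zscore") -> ExpressionMatrix:
    genes = tuple(f"g{i:03d}" for i in range(values.shape[0]))
    cells = tuple(f"c{j}" for j in range(values.shape[1]))
    return ExpressionMatrix(values, genes, cells, transform)
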