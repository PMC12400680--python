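import numpy as np
import pandas as pd
import pytest

from bcsagree.io import ScoreMatrix


@pytest.fixture
def small_matrix() -> ScoreMatrix:
    """3 subjects x 3 raters, complete, scores in the clinic range."""
    return ScoreMatrix.from_dict(
        {"A": [5, 6, 8], "B": [5, 7, 8], "C": [6, 6, 9]},
        subjects=["s1", "s2", "s3"],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_score_matrix(rng: np.random.Generator, n: int, m: int, p_missing: float = 0.0) -> ScoreMatrix:
    frame = pd.DataFrame(
        rng.integers(1, 10, size=(n, m)).astype(float),
        index=[f"s{i}" for i in range(n)],
        columns=[f"r{j}" for j in range(m)],
    )
    if p_missing > 0:
        mask = rng.random(size=frame.shape) < p_missing
        frame = frame.mask(mask)
    return ScoreMatrix(frame)
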