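import numpy as np
import pytest

from predcurve import ScreeningDataset


@pytest.fixture
def toy_dataset():
    """4 compounds, scores 1..4, the two best active."""
    return ScreeningDataset(("a", "b", "c", "d"), [1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1])


@pytest.fixture
def overlapping_dataset():
    """Moderately informative dataset, no separation: 30 actives of 300."""
    rng = np.random.default_rng(42)
    labels = (np.arange(300) < 30).astype(int)
    scores = rng.normal(labels * 1.0, 1.0)
    return ScreeningDataset(
        tuple(f"c{i}" for i in range(300)), scores, labels, orientation="higher_is_better"
    )


def random_overlapping_dataset(rng, n_min=20, n_max=500):
    """Random dataset with overlapping score distributions (rarely separated)."""
    n = int(rng.integers(n_min, n_max + 1))
    labels = rng.binomial(1, 0.3, n)
    while labels.sum() in (0, n):
        labels = rng.binomial(1, 0.3, n)
    scores = rng.normal(0.8 * labels, 1.0)
    return ScreeningDataset(tuple(f"c{i}" for i in range(n)), scores, labels)
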