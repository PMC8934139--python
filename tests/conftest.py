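import numpy as np
import pytest

from bmdkit.data_io import ExpressionDataset


@pytest.fixture()
def toy_dataset():
    """3 probes x 6 samples, doses (0,0,1,1,10,10): one flat probe, one
    increasing, one decreasing."""
    rng = np.random.default_rng(11)
    doses = np.array([0.0, 0.0, 1.0, 1.0, 10.0, 10.0])
    flat = 7.0 + 0.1 * rng.standard_normal(6)
    up = 7.0 + 0.3 * doses / 10 * 4 + 0.1 * rng.standard_normal(6)
    down = 7.0 - 0.5 * doses / 10 * 4 + 0.1 * rng.standard_normal(6)
    return ExpressionDataset(["pF", "pU", "pD"], np.vstack([flat, up, down]),
                             doses, 2, [f"s{i}" for i in range(6)])


@pytest.fixture()
def five_level_dataset():
    """20 probes x (5 levels x 4), half responsive with strong linear trends."""
    rng = np.random.default_rng(5)
    doses = np.repeat([0.0, 12.5, 25.0, 50.0, 100.0], 4)
    vals = np.empty((20, doses.size))
    for i in range(20):
        base = rng.uniform(6, 10)
        slope = 2.0 if i < 10 else 0.0
        vals[i] = base + slope * doses / 100 + 0.25 * rng.standard_normal(doses.size)
    return ExpressionDataset([f"p{i:02d}" for i in range(20)], vals, doses, 2,
                             [f"s{i}" for i in range(doses.size)])
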