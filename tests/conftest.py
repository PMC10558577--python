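import numpy as np
import pytest

from implantsize import simulate
from implantsize.labels import CODES


@pytest.fixture
def rng():
    return np.random.default_rng(20230906)


@pytest.fixture(scope="session")
def default_noise_dataset():
    """Medium-size dataset at default (clinically plausible) noise levels."""
    cfg = simulate.SimulationConfig(
        per_class_counts={c: 40 for c in CODES}, seed=11
    )
    records = simulate.generate_records(cfg)
    X, y = simulate.features_and_codes(records)
    return X, y


@pytest.fixture(scope="session")
def low_noise_dataset():
    """Nearly separable dataset (tight magnification, small angles)."""
    cfg = simulate.low_noise_preset(per_class=40, seed=23)
    records = simulate.generate_records(cfg)
    X, y = simulate.features_and_codes(records)
    return X, y
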