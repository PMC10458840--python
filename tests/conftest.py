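import numpy as np
import pandas as pd
import pytest

from felacc.features import FEATURE_NAMES
from felacc.synthetic_data import SimConfig, generate_study


def make_gaussian_dataset(seed: int, n_per_class: int = 200,
                          separation: float = 4.0,
                          labels=("a", "b")) -> pd.DataFrame:
    """Well-separated Gaussian feature clusters, one per label."""
    rng = np.random.default_rng(seed)
    blocks = []
    for i, label in enumerate(labels):
        X = rng.normal(i * separation, 1.0, size=(n_per_class, 32))
        df = pd.DataFrame(X, columns=list(FEATURE_NAMES))
        df.insert(0, "label", label)
        blocks.append(df)
    out = pd.concat(blocks, ignore_index=True)
    out.insert(0, "mount", "collar")
    out.insert(0, "cat_id", "cat01")
    return out


@pytest.fixture(scope="session")
def small_study():
    """A 2-cat, 1-day study with a 15 min annotated window."""
    config = SimConfig(n_cats=2, n_days=1, annotated_window=(0, 900), seed=11)
    return generate_study(config)


@pytest.fixture(scope="session")
def default_protocol():
    """The full fixed-plan protocol on the default-scale study (seed 1).

    Shared by the tests that check the protocol's structural output and
    its held-out performance; this is the expensive session fixture.
    """
    from felacc.pipeline import run_full_protocol

    study = generate_study(SimConfig(seed=1))
    return run_full_protocol(study, base_seed=1)
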