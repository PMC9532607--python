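import dataclasses
import logging

import numpy as np
import pandas as pd
import pytest

from panmethnet.data_model import OmicsMatrix
from panmethnet.synthetic_cohort import SimulationConfig, generate

logging.getLogger("panmethnet").setLevel(logging.WARNING)


def small_config(**overrides) -> SimulationConfig:
    defaults = dict(n_cohorts=3, n_tumor=60, n_normal=20, seed=7)
    defaults.update(overrides)
    return dataclasses.replace(SimulationConfig(), **defaults)


@pytest.fixture(scope="session")
def small_bundle():
    """Three cohorts, 60 tumor / 20 normal samples each, default effects."""
    return generate(small_config())


@pytest.fixture()
def tiny_matrix():
    frame = pd.DataFrame(
        [[1.0, 2.0], [3.0, np.nan], [5.0, 6.0]],
        index=["f1", "f2", "f3"],
        columns=["s1", "s2"],
    )
    return OmicsMatrix(frame, "expression_log2fpkm")
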