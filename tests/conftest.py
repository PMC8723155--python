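import numpy as np
import pandas as pd
import pytest

from sgi import OutcomeEffect, PlantedDesign, PlantedSplit, SubgroupIdentification, generate_planted


@pytest.fixture(scope="session")
def planted():
    """Small planted two-group cohort with one outcome of each type."""
    design = PlantedDesign(
        n_samples=80,
        n_features=30,
        splits=[PlantedSplit(parent="", delta_x=2.5, features=tuple(range(10)))],
        outcomes=[
            OutcomeEffect("bmi", "continuous", "", 1.5),
            OutcomeEffect("sex", "categorical", "", 2.0),
            OutcomeEffect("os", "survival", "", 3.0),
        ],
        seed=7,
    )
    return generate_planted(design)


@pytest.fixture(scope="session")
def fitted(planted):
    data, outcomes, _ = planted
    return SubgroupIdentification(min_size=0.05).fit(data, outcomes)


@pytest.fixture
def tiny_matrix():
    """Four samples in two obvious pairs."""
    return pd.DataFrame(
        [[0.0, 0.0], [0.1, 0.0], [5.0, 5.0], [5.1, 5.0]],
        index=["a", "b", "c", "d"],
        columns=["f1", "f2"],
    )
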