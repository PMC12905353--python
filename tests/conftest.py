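import numpy as np
import pytest

import fireglm as fg
from fireglm.pipeline import stage_fit


@pytest.fixture(scope="session")
def dataset() -> fg.SyntheticDataset:
    """Desk-scale synthetic study: 40 x 20 cells, 26% observed-zero."""
    return fg.generate_dataset(seed=7)


@pytest.fixture(scope="session")
def models(dataset):
    return stage_fit(dataset)


@pytest.fixture(scope="session")
def fitted_ba(dataset, models) -> np.ndarray:
    return fg.predict(models["BA"], dataset.predictors).ravel()
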