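import numpy as np
import pandas as pd
import pytest

from kinlink.config import RunConfig
from kinlink.motifs import ALPHABET, KinaseMotifModel, POSITIONS


@pytest.fixture
def config():
    return RunConfig(seed=1)


def toy_model(name="TOY", entries=None, acceptor=None, background=None):
    """A PSSM that is zero except for the given (position, residue) entries."""
    matrix = pd.DataFrame(0.0, index=list(POSITIONS), columns=list(ALPHABET))
    for (pos, res), value in (entries or {}).items():
        matrix.at[pos, res] = value
    model = KinaseMotifModel(name=name, matrix=matrix,
                             acceptor_pref=acceptor or {"S": 0.5, "T": 0.5})
    if background is not None:
        model.set_background(np.asarray(background, dtype=float))
    return model


@pytest.fixture
def toy_model_factory():
    return toy_model
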