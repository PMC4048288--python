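import numpy as np
import pandas as pd
import pytest

from eemsom import EEM, GridSpec, SOMModel, TrainingSchedule, assemble_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_eem(
    intensity, ex=None, em=None, sample_id="s", mask=None, units_state="raw"
):
    intensity = np.asarray(intensity, dtype=float)
    n_ex, n_em = intensity.shape
    if ex is None:
        ex = 240.0 + 10.0 * np.arange(n_ex)
    if em is None:
        em = 300.0 + 10.0 * np.arange(n_em)
    return EEM(sample_id, ex, em, intensity, mask=mask, units_state=units_state)


@pytest.fixture
def random_eem(rng):
    return make_eem(rng.uniform(0.1, 5.0, size=(6, 8)), sample_id="rand")


@pytest.fixture
def flat_unit_eem():
    """Constant-1 EEM on 1-nm grids covering every index window."""
    ex = np.arange(250.0, 381.0)
    em = np.arange(300.0, 531.0)
    return EEM("flat", ex, em, np.ones((len(ex), len(em))))


@pytest.fixture
def two_cluster_data(rng):
    """Two well-separated Gaussian clusters in 5 dimensions."""
    a = rng.normal(0.0, 0.1, size=(20, 5))
    b = rng.normal(10.0, 0.1, size=(20, 5))
    return np.vstack([a, b])


@pytest.fixture
def small_dataset(rng):
    eems = [
        make_eem(rng.uniform(0.5, 2.0, size=(4, 5)), sample_id=f"s{i}")
        for i in range(6)
    ]
    return assemble_dataset(eems)


def toy_model(codebook, n_rows=1, n_cols=None):
    codebook = np.atleast_2d(np.asarray(codebook, dtype=float))
    if n_cols is None:
        n_cols = codebook.shape[0] // n_rows
    return SOMModel(
        grid=GridSpec(n_rows, n_cols),
        codebook=codebook,
        schedule=TrainingSchedule(n_epochs=1, seed=0),
    )
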