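import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from toxpi.data import DataTable
from toxpi.fixtures import default_model, generate_dataset
from toxpi.model import SliceDef, ToxPiModel

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def small_table() -> DataTable:
    """4 entities x 4 metrics with one NA, fully hand-checkable."""
    values = np.array(
        [
            [1.0, 2.0, 0.0, 4.0],
            [2.0, 4.0, 1.0, 0.0],
            [4.0, np.nan, 2.0, 2.0],
            [0.0, 1.0, 3.0, 1.0],
        ]
    )
    mask = np.isnan(values)
    return DataTable(
        entity_ids=["e1", "e2", "e3", "e4"],
        metric_ids=["m1", "m2", "m3", "m4"],
        values=values,
        missing_mask=mask,
        entity_class=["A", "A", "B", "B"],
    )


@pytest.fixture
def small_model(small_table) -> ToxPiModel:
    return ToxPiModel(
        (
            SliceDef("S1", ("m1", "m2"), weight=3.0, color="#FF0000"),
            SliceDef("S2", ("m3", "m4"), weight=1.0, color="#00FF00"),
        )
    )


@pytest.fixture
def medium_table() -> DataTable:
    return generate_dataset(n_entities=30, n_metrics=12, missing_frac=0.1,
                            negative_frac=0.0, seed=7).to_table()


@pytest.fixture
def medium_model(medium_table):
    return default_model(medium_table)


def random_table_and_model(rng, n_max=10, m_max=8):
    """Small random (table, model) pair for property sweeps."""
    n = int(rng.integers(2, n_max + 1))
    m = int(rng.integers(2, m_max + 1))
    values = rng.lognormal(size=(n, m))
    mask = rng.random((n, m)) < 0.15
    table = DataTable(
        entity_ids=[f"e{i}" for i in range(n)],
        metric_ids=[f"x{j}" for j in range(m)],
        values=np.where(mask, np.nan, values),
        missing_mask=mask,
    )
    n_slices = int(rng.integers(1, min(4, m) + 1))
    bounds = np.linspace(0, m, n_slices + 1).astype(int)
    transforms = ["linear", "log10", "sqrt", "linear_inverted", "log10_inverted"]
    slices = tuple(
        SliceDef(
            f"s{i}",
            tuple(table.metric_ids[bounds[i]: bounds[i + 1]]),
            weight=float(rng.uniform(0.5, 3.0)),
            transform=transforms[int(rng.integers(0, len(transforms)))],
        )
        for i in range(n_slices)
    )
    return table, ToxPiModel(slices)
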