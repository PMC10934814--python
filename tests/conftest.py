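import numpy as np
import pytest

from polarccs.data_model import AdductRecord, PropertyDataset
from polarccs.synthetic import default_twim_config, generate_dataset

#: tiny single-point hyperparameter grid for tests that exercise the
#: protocol shape rather than the tuning itself
SINGLE_POINT_GRID = {"kernel": ["rbf"], "C": [1000.0], "gamma": [0.1], "epsilon": [0.1]}


def make_record(i: int, adduct: str = "M-H", **overrides) -> AdductRecord:
    fields = dict(
        compound_id=f"cmpd-{i:03d}",
        adduct_type=adduct,
        mz=100.0 + 3.0 * i,
        ccs=120.0 + 2.0 * i,
        polarizability=10.0 + 0.5 * i,
        vdw_volume=100.0 + 5.0 * i,
        ovality=1.1 + 0.01 * i,
    )
    fields.update(overrides)
    return AdductRecord(**fields)


@pytest.fixture
def toy_dataset() -> PropertyDataset:
    """12 deterministic records across the three adduct types."""
    records = [make_record(i, adduct) for i, adduct in enumerate(
        ["M+H"] * 4 + ["M+Na"] * 4 + ["M-H"] * 4)]
    return PropertyDataset(records=records, provenance="toy")


@pytest.fixture(scope="session")
def twim_dataset() -> PropertyDataset:
    """One 197-record draw from the traveling-wave defaults (seed 1)."""
    ds, _ = generate_dataset(default_twim_config(seed=1))
    return ds
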