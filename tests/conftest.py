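import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from polyomic.omics_io import CohortMetadata, Layer, OmicLayerTable

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_metadata(
    n_participants: int = 6,
    samples_each: int = 2,
    n_cases: int = 3,
    sites=("MGH", "Emory"),
) -> CohortMetadata:
    rows = []
    for i in range(n_participants):
        pid = f"P{i:02d}"
        dx = "CD" if i < n_cases else "nonIBD"
        for j in range(samples_each):
            rows.append(
                {
                    "sample_id": f"{pid}_S{j}",
                    "participant_id": pid,
                    "diagnosis": dx,
                    "age": 30.0 + i,
                    "sex": "female" if i % 2 else "male",
                    "race": "White",
                    "antibiotic_use": bool(i % 3 == 0),
                    "site": sites[i % len(sites)],
                    "week": 2 * j,
                }
            )
    return CohortMetadata(pd.DataFrame(rows))


def make_count_table(
    meta: CohortMetadata,
    n_features: int = 5,
    layer: Layer = Layer.MGN,
    seed: int = 0,
) -> OmicLayerTable:
    rng = np.random.default_rng(seed)
    values = rng.integers(0, 50, size=(len(meta.sample_ids), n_features)).astype(float)
    df = pd.DataFrame(
        values,
        index=meta.sample_ids,
        columns=[f"{layer.value}_F{j}" for j in range(n_features)],
    )
    return OmicLayerTable(layer, df)


@pytest.fixture
def meta6():
    return make_metadata()


@pytest.fixture
def counts6(meta6):
    return make_count_table(meta6)
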