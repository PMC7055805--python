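from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from gdistinct import (
    PopulationConfig,
    generate_population,
    run_pipeline,
    scenario_presets,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def key_frame(tuples) -> pd.DataFrame:
    """Build a quasi-identifier key frame from (dob, gender, zip) tuples."""
    return pd.DataFrame(tuples, columns=["dob_key", "gender", "zip_key"]).astype("string")


def encoded_frame(rows) -> pd.DataFrame:
    """Build an encoded record table from (dob, gender, zip) tuples."""
    df = pd.DataFrame(rows, columns=["dob", "gender", "zip"]).astype("string")
    df.insert(0, "record_id", [f"R{i}" for i in range(len(df))])
    return df


def random_key_tuples(seed: int, n: int | None = None) -> list[tuple]:
    """A seeded key set with varied class-size structure (n ≤ 500)."""
    rng = np.random.default_rng(seed)
    if n is None:
        n = int(rng.integers(10, 501))
    n_dob = int(rng.integers(1, 30))
    n_zip = int(rng.integers(1, 30))
    dob = rng.integers(0, n_dob, size=n)
    gender = rng.integers(0, 2, size=n)
    zc = rng.integers(0, n_zip, size=n)
    return [
        (f"19{d:02d}", "MF"[g], f"{z:06d}")
        for d, g, z in zip(dob.tolist(), gender.tolist(), zc.tolist())
    ]


@pytest.fixture(scope="session")
def tiny_bundle():
    return generate_population(
        PopulationConfig(**{**scenario_presets()["tiny"].as_dict(), "seed": 11})
    )


@pytest.fixture(scope="session")
def paper_like_bundle():
    return generate_population(
        PopulationConfig(**{**scenario_presets()["paper_like"].as_dict(), "seed": 1})
    )


@pytest.fixture(scope="session")
def paper_like_result(paper_like_bundle):
    return run_pipeline(paper_like_bundle.records, paper_like_bundle.gazetteer)
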