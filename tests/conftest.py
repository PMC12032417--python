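import warnings

import numpy as np
import pandas as pd
import pytest

from coda24.composition import DEFAULT_LABELS, pivot_order
from coda24.decomposition import decompose
from coda24.model import ModelSpec, build_design, fit
from coda24.synthetic import GeneratorConfig, generate

SMALL_SEED = 42  # 20 participants x 6 days fixture
STUDY_SCALE_SEED = 5  # 199 participants, 3-22 days fixture


@pytest.fixture(scope="session")
def small_data():
    cfg = GeneratorConfig(
        n_participants=20, days_fixed=6, seed=SMALL_SEED, missing_outcome_rate=0.0
    )
    data, truth = generate(cfg)
    return data, truth


@pytest.fixture(scope="session")
def study_scale_data():
    data, truth = generate(GeneratorConfig(seed=STUDY_SCALE_SEED))
    return data, truth


@pytest.fixture(scope="session")
def small_decomposed(small_data):
    data, _ = small_data
    return decompose(data, pivot_order("mvpa", DEFAULT_LABELS))


@pytest.fixture(scope="session")
def small_fit(small_decomposed):
    """A reduced fit on the small fixture, shared across tests."""
    spec = ModelSpec(
        outcome="valence", chains=2, iterations=800, warmup=400, seed=3
    )
    design = build_design(small_decomposed, spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        draws, diag = fit(design, spec)
    return design, draws, diag


@pytest.fixture()
def toy_filter_table():
    """10 participant-days crafted to trip each day-level validity filter."""
    parts = {"sleep_min": 480.0, "sedentary_min": 600.0, "standing_min": 200.0,
             "lpa_min": 90.0, "mvpa_min": 70.0}
    rows = []
    #  p1: 4 days, one with low wear, one with zero sleep -> keeps 2 -> excluded
    #  p2: 4 valid days -> retained
    #  p3: 2 valid days -> excluded by the min-valid-days rule
    specs = [
        ("p1", 1, 21.0, 480.0, 1), ("p1", 2, 18.0, 480.0, 1),
        ("p1", 3, 21.5, 0.0, 1), ("p1", 4, 22.0, 480.0, 1),
        ("p2", 1, 20.5, 480.0, 1), ("p2", 2, 23.0, 480.0, 1),
        ("p2", 3, 21.0, 480.0, 1), ("p2", 4, 20.0, 480.0, 1),
        ("p3", 1, 22.0, 480.0, 1), ("p3", 2, 21.0, 480.0, 1),
    ]
    for pid, day, wear, sleep, walk in specs:
        row = {"pid": pid, "day": day, **parts, "sleep_min": sleep,
               "wear_h": wear, "walk_detected": walk, "valence": 60.0,
               "age": 30.0, "sex": "female", "bmi": 24.0}
        rows.append(row)
    return pd.DataFrame(rows)


def random_compositions(n, rng, labels=DEFAULT_LABELS, total=1440.0):
    """Positive random compositions with broad log-ratio spread."""
    logs = rng.normal(0.0, 1.0, size=(n, len(labels)))
    x = np.exp(logs)
    return x * (total / x.sum(axis=1, keepdims=True))
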