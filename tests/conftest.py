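"""Shared fixtures: the packaged food database and (session-scoped, because
they are the expensive part of the suite) the two reference training runs —
one on the default noisy cohort and one on a noiseless cohort."""

from __future__ import annotations

import dataclasses
from importlib import resources

import pytest

from nutrikiosk import food_db
from nutrikiosk.cohort import CohortConfig, generate_cohort, split_train_test
from nutrikiosk.recommender import MLPSpec, predict_batch, train

FOODS_CSV = resources.files("nutrikiosk") / "data" / "foods.csv"
RECIPES_CSV = resources.files("nutrikiosk") / "data" / "recipes.csv"


@pytest.fixture(scope="session")
def food_items():
    items, rejected = food_db.load_foods_csv(str(FOODS_CSV))
    assert not rejected, rejected
    return items


@pytest.fixture()
def db(food_items, tmp_path):
    conn = food_db.init_db(food_items, path=tmp_path / "kiosk.db")
    yield conn
    conn.close()


@pytest.fixture(scope="session")
def noisy_run():
    """Default study conditions: n=10,000, 12% label noise, 80/20 split."""
    cfg = CohortConfig(seed=7)
    records, _ = generate_cohort(cfg)
    train_recs, test_recs = split_train_test(records, 0.8, seed=7)
    model = train(MLPSpec(seed=7), train_recs)
    predictions = predict_batch(model, test_recs)
    return {
        "records": records,
        "train": train_recs,
        "test": test_recs,
        "model": model,
        "predictions": predictions,
    }


@pytest.fixture(scope="session")
def noiseless_run():
    """Noise-free rule-labeled cohort (n=5,000): the rule-learnability case."""
    cfg = dataclasses.replace(
        CohortConfig(seed=3, n_target=5000), label_noise_rate=0.0
    )
    records, _ = generate_cohort(cfg)
    model = train(MLPSpec(seed=3), records)
    return {"records": records, "model": model}
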