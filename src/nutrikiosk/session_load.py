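"""Request factory for the load harness: one request = encode a varied
patient profile, predict its triage class, and compose its meal plan — the
same in-process path a kiosk session exercises."""

from __future__ import annotations

import numpy as np

from .cohort import CohortConfig, StratumSpec, _sample_raw, assign_label, default_strata
from .energy import MacroDistribution
from .food_db import open_db, read_foods
from .planner import PlanConstraints, compose_plan
from .recommender import load_model, predict_class
from dataclasses import replace


def make_request_fn(db_path: str, model_dir: str):
    """Build a thread-safe single-request callable.

    The food list and model are loaded once; each request draws a fresh
    profile from the default strata (seeded per request), runs the triage
    prediction, and composes a plan for the profile's energy need.
    """
    db = open_db(db_path)
    foods = read_foods(db)  # snapshot; sqlite connections are not thread-safe
    db.close()
    model = load_model(model_dir)
    strata = default_strata()

    def request(request_seed: int):
        rng = np.random.default_rng(request_seed % 2**31)
        stratum: StratumSpec = strata[int(rng.integers(0, len(strata)))]
        rec = _sample_raw(stratum, rng)
        rec = replace(rec, label=assign_label(rec))
        label, _ = predict_class(model, rec)
        constraints = PlanConstraints(
            daily_kcal_target=rec.kcal_need,
            macro=MacroDistribution(50, 20, 30),
        )
        plan = compose_plan(foods, constraints)
        return label, plan

    return request
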